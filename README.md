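# dboxkit

Analysis toolkit for the **D-box**, a conserved motif in the periplasmic
linker of TonB that is captured as a β-strand by a dimer of ExbD
periplasmic domains — the attachment point through which the inner-membrane
ExbBD motor is thought to pull on TonB during TonB-dependent nutrient
transport in Gram-negative bacteria.

The package is written for structural bioinformaticians and biophysicists
studying β-strand recruitment. It covers the full analysis chain:

- **Sequence** — classify residues into hydrophobic (Φ) / hydrophilic (ζ) /
  proline classes and scan sequences for the D-box pattern **ΦζΦζΦΦζ**
  flanked by prolines, gated on a Chou–Fasman-style β-strand propensity
  profile (`dboxkit.motif`).
- **Binding** — fit the two standard solution assays with statsmodels-style
  model objects (`dboxkit.binding`). Both reduce to the exact
  ligand-depletion equilibrium: with totals `P_t`, `L_t` and dissociation
  constant `K_d`, the complex concentration is the smaller quadratic root

  `C = [(K_d + L_t + P_t) − √((K_d + L_t + P_t)² − 4·P_t·L_t)] / 2`.

  `ItcModel` simulates/fits per-injection heats
  `q_i = V₀·ΔH·Δ[C]_i` with overflow-cell dilution bookkeeping and fitted
  stoichiometry `n`; `AnisotropyModel` fits
  `A = A₀ + (A_max − A₀)·C/L_t` for a fixed labelled peptide. `fit()`
  returns a `BindingResults` with standard errors, residual-resampling
  bootstrap CIs and a `summary()` table.
- **Structure** — read PDB/mmCIF (gemmi), Kabsch least-squares
  superposition with chain-mapping search, Shrake–Rupley solvent-accessible
  surface area and fractional side-chain burial, Kabsch–Sander backbone
  hydrogen bonds (`E = 27.888·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) <
  −0.5 kcal/mol`), parallel/antiparallel β-bridge typing, sheet/helix
  topology, and β-strand recruitment detection (`dboxkit.structure`).
- **Conservation** — pairwise global alignment (BLOSUM62, affine gaps),
  percent identity, Clustal-style strong/weak column classes, and mapping
  of conservation onto structure residues (`dboxkit.conservation`).
- **Synthetic data** — seeded generators for every input class with exact
  ground truth: ITC thermograms, anisotropy titrations, motif-bearing
  sequences, ideal β-strand pairs with analytically enumerated H-bond
  ladders, a two-sheet recruitment fixture, and burial cages
  (`dboxkit.synthetic`).

## Worked example

Scan the *E. coli* TonB D-box peptide (author residues 43–54) and fit a
simulated calorimetry titration at the experimental conditions:

```python
from dboxkit.sequences import AnnotatedSequence
from dboxkit.motif import scan_dbox
from dboxkit.binding import BindingTruth, ItcProtocol, fit_itc
from dboxkit.synthetic import gen_itc_series

pep = AnnotatedSequence("tonb_dbox", "QPISVTMVTPAD", numbering_offset=43)
print(scan_dbox(pep, proline_window=1)[0])

truth = BindingTruth(Kd=19.0, n=0.5, dH=-8.0)   # 1 peptide : 2 ExbD
series, _ = gen_itc_series(truth, ItcProtocol(), seed=7)
print(fit_itc(series).summary())
```

prints

```
MotifMatch(seq_id='tonb_dbox', core_start=45, core_end=51,
           core_sequence='ISVTMVT', upstream_proline=44,
           downstream_proline=52, mean_core_propensity=1.1999999999999997,
           passes_propensity=True)
ItcModel fit (converged, nfev=37, chi-square=0.6257)
----------------------------------------------------------------
   param     estimate    std err
      Kd       19.239      2.158
       n      0.50721    0.02739
      dH      -7.9946     0.5674
```

i.e. the peptide contains exactly one D-box (core ISVTMVT at residues
45–51, prolines at 44 and 52), and the fit recovers the generating
parameters: `Kd` ≈ 19 µM and `n` ≈ 0.5 peptide sites per ExbD monomer —
one D-box per ExbD dimer.

The same operations are available from the shell:

```sh
dboxkit scan peptide.fasta --out report
dboxkit fit itc.csv --mode itc --out fit.json
dboxkit analyze-complex --model complex.pdb --peptide-chain P --compare other.pdb
dboxkit conserve orthologs.fasta --reference ecoli --model complex.pdb
dboxkit --seed 7 simulate itc --out-dir sim/
```

## Layout

```
src/dboxkit/
  sequences.py      annotated sequences, FASTA I/O
  motif.py          hydropathy classes, propensity, D-box scanning
  binding/          isotherm math, Model/Results fits, CSV dialects
  structure/        model I/O, superposition, SASA, H-bonds, bridges
  conservation.py   alignment, identity, conservation classes
  synthetic.py      seeded generators with ground truth
  cli.py            the `dboxkit` command
docs/methods.md     model assumptions, parameters, design notes
```
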