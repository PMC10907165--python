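# Methods

This note documents the models, parameter choices and numerical decisions
behind dboxkit, and what the synthetic-data tests do and do not establish
about real data.

## Motif model

The D-box is modelled as a seven-residue hydropathy pattern ΦζΦζΦΦζ with
proline flanks. Residues are partitioned into three classes: proline is
its own class (it cannot occupy a recruited-strand position and delimits
the recruitable segment); the hydrophobic set Φ is fixed to
{A, C, F, I, L, M, V, W, Y}; everything else, including glycine,
histidine and the ambiguity code X, is hydrophilic ζ. Glycine and
histidine are borderline on most hydropathy scales; they are assigned ζ
because neither occurs at a Φ position in any known D-box, and the set is
an explicit argument (`phi_set`) for users who prefer a scale-threshold
definition.

β-strand propensity uses the Chou–Fasman β-sheet conformational
preferences (P(β), normalised to 1.0 for an average residue), averaged
over a sliding window. Defaults: window 5 (odd, so the window centres on
a residue; 5 spans a typical short strand), gate threshold 1.0 (the
neutral value of the scale). At sequence ends the window shrinks to the
available context and the position is flagged rather than silently
scored. This propensity heuristic reproduces the qualitative call that
the D-box core has strand character; it is not a secondary-structure
predictor and makes no claim at the per-residue accuracy of trained
methods.

The scanner reports every 7-mer whose hydropathy string matches the
pattern (overlaps included, ascending order). With the proline gate on
(default), a proline must occur within `proline_window` residues
(default 2) outside each core end; exact adjacency (window 1) holds for
the *E. coli* sequence, while some orthologs space the downstream proline
by one residue. The composite `score_motif` multiplies mean core
propensity by exp(−d/50) where d is the distance to a user-supplied
membrane-anchor end — the biologically plausible D-box sits immediately
downstream of the anchor; the decay scale 50 is a soft prior, not a
fitted constant.

Positions are reported in author (1-based, inclusive) numbering through a
per-sequence `numbering_offset`, because the same peptide is commonly
referred to under different numbering schemes (e.g. 43–54 in one scheme
and 55–63 in another, offset +12); internally all indices are 0-based
half-open, and no scheme is declared canonical.

## Binding models

Both assays share the exact single-site ligand-depletion equilibrium.
The complex concentration is computed in the numerically stable root form
`C = 2·P_t·L_t / (S + √(S² − 4·P_t·L_t))`, S = K_d + L_t + P_t, which
avoids cancellation when binding is weak (4·P_t·L_t ≪ S²); C is clamped
to [0, min(P_t, L_t)] against rounding.

**ITC.** The cell is modelled with the overflow (displacement)
convention: each injection of volume dV displaces an equal volume of
well-mixed pre-injection cell contents, so both totals are diluted by
(1 − dV/V₀) before injectant is added. The measured heat of injection i
is `q_i = V₀·ΔH·(C_i − C_{i−1}·(1 − dV_i/V₀))` in µcal (V₀ in µL,
concentrations µM, ΔH kcal/mol); the displaced-complex term keeps the
running heat consistent with mass balance, which the test suite checks
against an independent bisection-based equilibrium oracle. Stoichiometry
enters as a site total n·[M]: n is injectant sites per macromolecule
monomer, so a 2:1 protein:peptide complex appears as n = 0.5 and is
reported as 1/n monomers per peptide. The first injection is excluded
from the objective by default (syringe-tip exchange artifact); heat of
dilution is an optional constant offset, default 0. Fits run
Levenberg–Marquardt (lmfit) over (K_d, n, ΔH) from a small multi-start
grid (K_d at 0.02×, 0.2×, 1×, 5× the cell concentration; ΔH from the
first usable heat under an all-bound assumption; n = 1), keeping the
lowest-χ² solution. Degenerate inputs (all-zero heats, < 5 usable
injections) raise a diagnostic error instead of returning numbers.

**Fluorescence anisotropy.** The default ("corrected") observable is
`A = A₀ + (A_max − A₀)·C/L_t`, the bound fraction of the fixed labelled
peptide, which is monotone in P_t and saturates at A_max. An
"as_printed" mode dividing by 2·P_t instead of 2·L_t is retained behind a
flag because that variant circulates in assay write-ups; it does not
saturate at A_max when P_t is titrated and is not used for fitting by
default. Fits are over (K_d, A₀, A_max) with L_t fixed at its
experimental value; flat titrations raise an unidentifiability error.

**Uncertainties.** Standard errors come from the local quadratic
approximation at the optimum. Because published "±" values rarely state
their method, a residual-resampling bootstrap (percentile intervals,
seeded, default 200 replicates, minimum 20) is available on every
converged fit, and both are reported.

## Structural analyses

**Superposition.** Kabsch's SVD solution with a determinant correction so
a reflection is never returned; degenerate (collinear/coincident) point
sets are rejected. The cross-model comparison pairs residues by author
number within chains matched by exact sequence identity and searches all
permutations within each group of sequence-identical chains — required
for homodimers, whose chain labels need not correspond between crystal
forms — returning the mapping with the lowest all-Cα RMSD and the count
of residues excluded for missing Cα atoms.

**SASA.** Shrake–Rupley with a deterministic Fibonacci-lattice point set,
960 points/atom by default (chosen so the two-sphere case agrees with the
closed-form spherical-cap solution within 1%), probe 1.4 Å, heavy-atom
radii C 1.70, N 1.55, O 1.52, S 1.80 Å (P 1.80, Se 1.90 available);
waters and hydrogens excluded by default; an unknown element is an error
naming the offending residue. Fractional burial of a residue is
1 − SASA_sc(complex)/SASA_sc(chain alone), clamped to [0, 1], with the
side chain defined as all non-backbone heavy atoms (Cβ included); glycine
is undefined (None), never 0 or 1. Note that Shrake–Rupley has no notion
of connectivity to bulk solvent: the interior of a roomy closed cavity
counts as accessible, so the burial test fixture uses a snug cage, as in
a real protein core.

**Hydrogen bonds and bridges.** Kabsch–Sander electrostatic energy with
coupling 27.888 kcal·Å/mol and cutoff −0.5 kcal/mol; a geometric
criterion (H···O < 2.5 Å, N···O < 3.5 Å, N–H···O > 120°) is available
behind a flag. Missing amide hydrogens are built at 1.0 Å from N along
the previous residue's C→O direction; the first residue of a chain,
residues after a chain break (C–N > 2.5 Å) and prolines cannot donate.
Pairs at sequence separation ≤ 1 are excluded and candidates are
pre-screened at Cα–Cα ≤ 9 Å. Bridge typing uses the original
Kabsch–Sander rules in their acceptor-first notation
(Hbond(x, y) = CO of x accepts from NH of y): (i, j) is parallel iff
{Hbond(i−1, j) and Hbond(j, i+1)} or {Hbond(j−1, i) and Hbond(i, j+1)},
antiparallel iff {Hbond(i, j) and Hbond(j, i)} or {Hbond(i−1, j+1) and
Hbond(j−1, i+1)}. The direction convention matters: read with the arrows
reversed, the parallel rule describes a geometry no rigid strand pair can
satisfy, which the ideal-geometry generator demonstrates constructively.
In a parallel ladder every interior residue pair is a bridge (the two
clauses alternate); in an antiparallel ladder narrow and wide pairs
alternate between the two clauses.

**Topology and recruitment.** Strands are maximal runs (≥ 2 residues,
single gaps filled, since ladder registers alternate) of bridge
participants; helices are maximal runs (≥ 4) of residues whose C=O
accepts an n+4→n bond. Recruitment of a designated peptide chain is
reported as bridge ladders (same chain pair, same type, positions within
2 residues) to each partner chain, with author-numbered ranges, plus
fractional burial of the peptide's Φ-class side chains; the two-sheet
flag is set iff ladders to ≥ 2 distinct partners exist — the signature of
a single strand recruited simultaneously by two sheets.

## Conservation

Pairwise Needleman–Wunsch under BLOSUM62 with affine gaps (open 10,
extend 0.5, a gap of length L costing open + (L−1)·extend) stands in for
a progressive multiple aligner: the quantities needed — percent identity
and per-column conservation classes — are reproduced by aligning each
ortholog to a common reference and projecting (star alignment). Percent
identity defaults to identical pairs over gapless columns, with
full-alignment-length and shorter-sequence denominators selectable
because reporting conventions differ. Column classes use the published
Clustal strong/weak amino-acid groups; any gap in a column forces
"none". The structure mapping assigns each chain residue the class of
sequence position (residue number − offset) and raises an error when more
than 20% of residues fall outside the classified range, which catches
systematic numbering-scheme mismatches (e.g. an off-by-12 offset).

## Synthetic data: what it emulates, and what it does not

Generators are seeded (`numpy.random.default_rng`, one isolated stream
per call) and return machine-readable truth records.

- ITC: Gaussian injection noise, default SD 2% of the first model heat —
  the order of a well-behaved instrument; baseline drift and
  first-injection artifacts are not modelled (only the first-injection
  exclusion is). Default protocol: 20 × 2 µL of 1 mM peptide into 200 µL
  of 100 µM protein at 288 K; with K_d = 19 µM and n = 0.5 this is a
  c ≈ 2.6 design, so per-seed K_d scatter of a few µM at 2% noise is
  expected and the acceptance checks are phrased accordingly (median
  within 10% at 2% noise; every seed within ±1 µM at 0.02 µcal noise).
- Anisotropy: Gaussian noise with SD 0.002 anisotropy units on a
  two-fold dilution series 0.49–500 µM protein with 0.1 µM labelled
  peptide (A₀ = 0.05, A_max = 0.20, typical for an AF488 peptide);
  photobleaching and dilution errors are not modelled.
- Motif sequences: uniform background with P+core+P motifs spliced at
  recorded non-overlapping positions, rejection-sampled until a
  proline-gated scan recovers exactly the embedded set — so round-trip
  recovery is exact by construction and tests the scanner's coordinate
  bookkeeping, not its discrimination on real proteomes.
- Ideal β-pairs: backbone-only poly-alanine strands built from ideal
  internal coordinates (bond lengths/angles of the standard restraint
  sets; φ/ψ −139/135 antiparallel, −119/113 parallel) with explicit amide
  hydrogens. The second strand's rigid placement is solved by
  deterministic least squares so the analytically enumerated ladder hits
  textbook geometry (H···O 1.9 Å, N···O 2.9 Å), and the generator
  verifies its own ladder against the detector before returning — a
  failure raises rather than yielding a silently wrong fixture. The
  recruitment fixture places one parallel and one antiparallel partner on
  the two faces of a central peptide strand, mimicking the D-box in the
  dimer groove.
- Burial cage: a valine-like side chain inside a carbon-sphere cage at
  contact range; a coverage parameter exposes part of the sphere for
  monotonicity checks.

Passing on these fixtures establishes correctness of the algorithms and
their conventions on idealised geometry and known truth. It does not
establish robustness to crystallographic disorder, alternate
conformations beyond highest-occupancy selection, non-ideal strand
twist, or real ortholog sequence diversity; the deposited-structure test
(which requires the 8VGC/8VGD coordinate files) covers the real-geometry
case when those files are obtainable.

## Sizes and determinism

Default problem sizes were chosen to keep the full suite fast while
leaving the statistics stable: 50 seeded replicates per binding assay,
100 sequences in the motif round trip, strand lengths 3–10 in the bridge
suite, 960 SASA points per atom (240–480 in inner test loops). All
randomness flows from explicit seeds; repeated runs are byte-identical.
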