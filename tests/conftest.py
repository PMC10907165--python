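import numpy as np
import pytest

from dboxkit.binding.isotherm import BindingTruth, ItcProtocol
from dboxkit.sequences import AnnotatedSequence


@pytest.fixture(scope="session")
def dbox_peptide() -> AnnotatedSequence:
    """The E. coli TonB D-box peptide, author residues 43-54."""
    return AnnotatedSequence("tonb_dbox", "QPISVTMVTPAD", numbering_offset=43)


@pytest.fixture(scope="session")
def itc_truth() -> BindingTruth:
    """Ground truth matching the wild-type calorimetry experiment:
    Kd 19 uM, one peptide per two protein monomers."""
    return BindingTruth(Kd=19.0, n=0.5, dH=-8.0)


@pytest.fixture(scope="session")
def itc_protocol() -> ItcProtocol:
    """1 mM peptide injected in 20 x 2 uL steps into 100 uM protein."""
    return ItcProtocol()


@pytest.fixture(scope="session")
def fa_truth() -> BindingTruth:
    """Anisotropy ground truth: Kd 45 uM, 100 nM labelled peptide."""
    return BindingTruth(Kd=45.0, A0=0.05, Amax=0.20)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240201)
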