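import numpy as np
import pytest

from ltrhmm.hmm_core import make_peaked_profile
from ltrhmm.model_build import train_with_noise
from ltrhmm.simulate import LTRFamilySpec, make_family


@pytest.fixture(scope="session")
def peaked_model():
    """A profile strongly peaked on a short LTR-like consensus."""
    return make_peaked_profile("TGTTACAATAAAGTGGTGTAACA", peak=0.99, match_stay=0.97)


@pytest.fixture(scope="session")
def small_family():
    """A small synthetic LTR family (60 bp core) with its motif truth."""
    spec = LTRFamilySpec(
        n_sequences=20,
        core_length=60,
        motifs=[
            ("SIR_5prime", "TGTTRNR", 0),
            ("AATAAA", "AATAAA", 28),
            ("SIR_3prime", "YNYAACA", 53),
        ],
        substitution_rate=0.05,
        indel_rate=0.01,
        seed=42,
    )
    return make_family(spec)


@pytest.fixture(scope="session")
def small_family_model(small_family):
    """A profile trained on the small synthetic family (M = core length)."""
    seqs, _ = small_family
    model, trace = train_with_noise(seqs, M=60, z=0.05, seed=42, max_iter=25, tol=1e-2)
    return model, trace
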