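import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pegtherm.pegrna import EditSpec, TargetLocus, assemble
from pegtherm.seq_io import NucleicSeq
from pegtherm.synthetic import make_toy_locus

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


@pytest.fixture
def locus() -> TargetLocus:
    """Balanced-GC toy locus, fixed seed."""
    return make_toy_locus(0.5, seed=11)


@pytest.fixture
def edit(locus) -> EditSpec:
    """+5 substitution consistent with the locus (transversion where possible)."""
    ref = locus.downstream_of_nick()[4]
    alt = "T" if ref != "T" else "A"
    return EditSpec("substitution", 5, ref=ref, alt=alt)


@pytest.fixture
def pegrna(locus, edit):
    """13-nt PBS pegRNA for the toy locus (longest PBS still auto-inhibition prone)."""
    return assemble(locus, edit, pbs_len=13, ha_len=10, name="toy13")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def random_nucleic(rng, n, alphabet="DNA") -> NucleicSeq:
    letters = "ACGT" if alphabet == "DNA" else "ACGU"
    return NucleicSeq("".join(rng.choice(list(letters), size=n)), alphabet)
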