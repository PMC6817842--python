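import numpy as np
import pytest

from cardioreg.intervals import GenomeInterval
from cardioreg.motifs import PWM
from cardioreg.peaks import SummitPeak
from cardioreg.simulate import SimConfig


def near_consensus_pwm(name: str, consensus: str, p: float = 0.99) -> PWM:
    """PWM concentrated on a consensus string."""
    mat = np.full((len(consensus), 4), (1 - p) / 3)
    for i, b in enumerate(consensus):
        mat[i, "ACGT".index(b)] = p
    return PWM(name, mat / mat.sum(axis=1, keepdims=True))


def make_summit(
    pos: int, tf: str = "TFA", chrom: str = "chr1", signal: float = 1.0
) -> SummitPeak:
    return SummitPeak(
        GenomeInterval(chrom, max(0, pos - 100), pos + 100),
        pos, signal, tf, "fetal",
    )


@pytest.fixture
def pwm_a() -> PWM:
    return near_consensus_pwm("NKX", "TTAAGTG")


@pytest.fixture
def pwm_b() -> PWM:
    return near_consensus_pwm("TEAD", "GGAATG")


@pytest.fixture
def small_cfg() -> SimConfig:
    """Toy genome small enough for per-test generator calls."""
    return SimConfig(seed=11, chrom_length=500_000, summits_per_tf=60)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
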