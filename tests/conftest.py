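import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from galaxpop.seq_io import Alignment

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def random_alignment(
    rng: np.random.Generator,
    n: int,
    L: int,
    p_missing: float = 0.0,
    p_variable: float = 0.4,
) -> Alignment:
    """Random test alignment; a fraction of columns is made variable."""
    bases = np.array(list("ACGT"))
    anc = bases[rng.integers(0, 4, size=L)]
    mat = np.tile(anc, (n, 1))
    for s in range(L):
        if rng.random() < p_variable:
            rows = rng.integers(0, n, size=rng.integers(1, max(2, n // 2)))
            mat[rows, s] = bases[rng.integers(0, 4, size=rows.size)]
    if p_missing > 0:
        miss = rng.random(size=mat.shape) < p_missing
        mat[miss] = np.where(rng.random(size=mat.shape) < 0.5, "N", "-")[miss]
    seqs = ["".join(row) for row in mat]
    return Alignment([f"s{i}" for i in range(n)], seqs)


def iid_alignment(rng: np.random.Generator, n: int, L: int) -> Alignment:
    """Every base iid uniform: sequences are almost surely all distinct,
    so permutation statistics have essentially no ties."""
    bases = np.array(list("ACGT"))
    mat = bases[rng.integers(0, 4, size=(n, L))]
    return Alignment([f"s{i}" for i in range(n)], ["".join(r) for r in mat])
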