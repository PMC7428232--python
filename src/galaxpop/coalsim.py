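"""Single-population constant-size Kingman coalescent simulator.

The engine behind the neutrality-test nulls and the coalescent-
stochasticity test.  A genealogy of ``n`` sampled lineages is grown
backwards in time: while ``k`` lineages remain, the waiting time to the
next coalescence is exponential with rate C(k, 2)/N_e generations, and
the merging pair is chosen uniformly.  Mutations are then dropped on the
branches as a Poisson process with rate ``mu`` per site per generation
over ``L`` finite sites; each mutation hits a uniformly chosen site and
replaces the current base with one of the three others, chosen uniformly
(a Jukes-Cantor-like model in which recurrent and back mutations are
possible).

Scaling
-------
``mu`` is a per-site, per-generation rate.  For a maternally inherited
haploid marker (mtDNA) the default scaling uses N_e = N, giving
``theta_locus = 2 * N * mu * L``; the ``diploid`` option uses N_e = 2N.
Time is continuous (exponential waiting times), not discrete
Wright-Fisher generations.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seq_io import Alignment, _BASES

RNGLike = np.random.Generator | int | None


def as_rng(seed: RNGLike) -> np.random.Generator:
    """Coerce a seed or Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class CoalConfig:
    """Parameters of one simulated sample.

    n: sample size (sequences); L: locus length in bp; N: population
    size in individuals; mu: mutation rate per site per generation;
    scaling: 'haploid' (N_e = N, mtDNA default) or 'diploid' (N_e = 2N).
    """

    n: int
    L: int
    N: float = 10_000.0
    mu: float = 0.0
    scaling: str = "haploid"

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need n >= 2 sampled sequences")
        if self.L < 1 or self.N < 1 or self.mu < 0:
            raise ValueError("require L >= 1, N >= 1, mu >= 0")
        if self.scaling not in ("haploid", "diploid"):
            raise ValueError("scaling must be 'haploid' or 'diploid'")

    @property
    def effective_size(self) -> float:
        return self.N if self.scaling == "haploid" else 2.0 * self.N

    @property
    def theta_locus(self) -> float:
        """Population-scaled locus mutation rate, 2 * N_e * mu * L."""
        return 2.0 * self.effective_size * self.mu * self.L

    def with_mu(self, mu: float) -> "CoalConfig":
        return dataclasses.replace(self, mu=mu)


@dataclass
class Genealogy:
    """Binary ultrametric genealogy of n tips.

    Nodes 0..n-1 are tips; internal node n+i is created at the i-th
    coalescence, so every parent index exceeds its children's and the
    root is node 2n-2.  ``parent[v]`` is -1 for the root; ``blen[v]`` is
    the branch length above v in generations; ``time[v]`` is node height.
    """

    n: int
    parent: np.ndarray
    blen: np.ndarray
    time: np.ndarray

    @property
    def root(self) -> int:
        return 2 * self.n - 2

    @property
    def tmrca(self) -> float:
        return float(self.time[self.root])

    @property
    def total_branch_length(self) -> float:
        return float(self.blen.sum())


def simulate_genealogy(cfg: CoalConfig, seed: RNGLike = None) -> Genealogy:
    """Draw one neutral constant-size coalescent genealogy."""
    rng = as_rng(seed)
    n = cfg.n
    ne = cfg.effective_size
    k_vals = np.arange(n, 1, -1)
    waits = rng.exponential(ne / (k_vals * (k_vals - 1) / 2.0))
    u = rng.random((n - 1, 2))

    nnodes = 2 * n - 1
    parent = np.full(nnodes, -1, dtype=np.int64)
    blen = np.zeros(nnodes)
    time = np.zeros(nnodes)
    active = list(range(n))
    t = 0.0
    for step in range(n - 1):
        k = n - step
        t += waits[step]
        i = int(u[step, 0] * k)
        j = int(u[step, 1] * (k - 1))
        if j >= i:
            j += 1
        a, b = active[i], active[j]
        new = n + step
        parent[a] = new
        parent[b] = new
        blen[a] = t - time[a]
        blen[b] = t - time[b]
        time[new] = t
        hi, lo = (i, j) if i > j else (j, i)
        active[hi] = active[-1]
        active.pop()
        active[lo] = new
    return Genealogy(n=n, parent=parent, blen=blen, time=time)


def _simulate_states(
    gen: Genealogy,
    cfg: CoalConfig,
    rng: np.random.Generator,
    ancestral: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Drop mutations on a genealogy; return (hit sites, tip states, ancestral).

    Returns the sorted indices of sites hit by at least one mutation, the
    (n, m) int8 matrix of tip states at those sites, and the full-length
    ancestral sequence (codes 0..3).  Only hit sites can vary, so all
    summary statistics are computable from the sparse matrix.
    """
    n, L = gen.n, cfg.L
    if ancestral is None:
        anc_full = rng.integers(0, 4, size=L, dtype=np.int8)
    else:
        anc_full = np.asarray(ancestral, dtype=np.int8)
        if anc_full.shape != (L,) or anc_full.min() < 0 or anc_full.max() > 3:
            raise ValueError("ancestral must be length-L codes in 0..3")
    tot = gen.total_branch_length
    m_mut = rng.poisson(tot * cfg.mu * L)
    if m_mut == 0:
        return (
            np.empty(0, dtype=np.int64),
            np.empty((n, 0), dtype=np.int8),
            anc_full,
        )
    branches = rng.choice(gen.blen.size, size=m_mut, p=gen.blen / tot)
    hit = rng.integers(0, L, size=m_mut)
    steps = rng.integers(1, 4, size=m_mut, dtype=np.int8)
    site_u, col = np.unique(hit, return_inverse=True)
    m = site_u.size

    muts: dict[int, list[tuple[int, int]]] = {}
    for b, c, s in zip(branches.tolist(), col.tolist(), steps.tolist()):
        muts.setdefault(b, []).append((c, s))

    states = np.empty((2 * n - 1, m), dtype=np.int8)
    states[gen.root] = anc_full[site_u]
    for node in range(2 * n - 3, -1, -1):
        states[node] = states[gen.parent[node]]
        node_muts = muts.get(node)
        if node_muts:
            # Mutations on one branch apply in draw order; with a uniform
            # choice among the three other bases the order is exchangeable.
            for c, s in node_muts:
                states[node, c] = (states[node, c] + s) % 4
    return site_u, states[:n], anc_full


def drop_mutations(
    gen: Genealogy,
    cfg: CoalConfig,
    seed: RNGLike = None,
    ancestral: str | np.ndarray | None = None,
    ids: list[str] | None = None,
) -> Alignment:
    """Mutate a genealogy into a full n x L alignment."""
    rng = as_rng(seed)
    if isinstance(ancestral, str):
        codes = {b: i for i, b in enumerate(_BASES[:4])}
        try:
            ancestral = np.array([codes[c] for c in ancestral.upper()], dtype=np.int8)
        except KeyError as exc:
            raise ValueError("ancestral sequence must be unambiguous A/C/G/T") from exc
    site_u, tips, anc_full = _simulate_states(gen, cfg, rng, ancestral)
    full = np.tile(anc_full, (gen.n, 1))
    if site_u.size:
        full[:, site_u] = tips
    lut = np.frombuffer(_BASES[:4].encode("ascii"), dtype=np.uint8)
    seqs = [bytes(lut[row]).decode("ascii") for row in full]
    if ids is None:
        ids = [f"sim{i}" for i in range(gen.n)]
    return Alignment(ids, seqs)


def summaries_from_states(n: int, tips: np.ndarray) -> tuple[int, int, float]:
    """(S, K, pi_locus) from the sparse tip-state matrix of one replicate."""
    m = tips.shape[1]
    if m == 0:
        return 0, 1, 0.0
    flat = tips.astype(np.int64) + 4 * np.arange(m, dtype=np.int64)[None, :]
    counts = np.bincount(flat.ravel(), minlength=4 * m).reshape(m, 4)
    seg = (counts > 0).sum(axis=1) > 1
    s_val = int(seg.sum())
    npairs = n * (n - 1) // 2
    same = (counts * (counts - 1) // 2).sum(axis=1)
    pi = float((npairs - same).sum() / npairs)
    k_val = len({tips[i].tobytes() for i in range(n)})
    return s_val, k_val, pi


def simulate_summaries(
    cfg: CoalConfig,
    reps: int,
    seed: RNGLike = None,
    mus: np.ndarray | None = None,
) -> pd.DataFrame:
    """Simulate `reps` independent samples; tabulate (mu, S, K, pi) each.

    If `mus` is given (length `reps`), replicate r uses mutation rate
    mus[r] instead of cfg.mu — the calibration sweep's entry point.
    Reproducible from (cfg, reps, seed).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = as_rng(seed)
    if mus is not None:
        mus = np.asarray(mus, dtype=float)
        if mus.shape != (reps,):
            raise ValueError("mus must have length reps")
    rows = np.empty((reps, 4))
    for r in range(reps):
        c = cfg if mus is None else cfg.with_mu(mus[r])
        gen = simulate_genealogy(c, rng)
        _, tips, _ = _simulate_states(gen, c, rng)
        s_val, k_val, pi = summaries_from_states(c.n, tips)
        rows[r] = (c.mu, s_val, k_val, pi)
    return pd.DataFrame(rows, columns=["mu", "S", "K", "pi"]).astype(
        {"S": int, "K": int}
    )
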