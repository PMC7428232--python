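"""Neutrality tests: Tajima's D and Fu's Fs, with coalescent-simulated nulls.

Tajima's D contrasts the pairwise estimator of theta (pi) with the
segregating-sites estimator (S/a1); sudden population expansion drives
it negative.  Fu's Fs is the log-odds of observing at least the sampled
number of haplotypes under the Ewens sampling formula at theta = pi;
an excess of rare haplotypes (expansion) makes it strongly negative.
Significance for both comes from constant-size coalescent simulation at
the observed theta, testing against the lower (expansion) tail.

Stirling numbers of the first kind, needed for the Ewens probabilities,
are computed in log space via the recurrence
|s(n+1, k)| = n |s(n, k)| + |s(n, k-1)| so Fs stays computable at
sample sizes in the hundreds without overflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .coalsim import CoalConfig, RNGLike, _simulate_states, as_rng, simulate_genealogy, summaries_from_states
from .errors import DegenerateInputError

_LOG_STIRLING_CACHE: dict[int, np.ndarray] = {}


def log_stirling_first_row(n: int) -> np.ndarray:
    """log |s(n, k)| for k = 0..n (log 0 = -inf), unsigned first kind."""
    if n < 0:
        raise ValueError("n must be >= 0")
    cached = _LOG_STIRLING_CACHE.get(n)
    if cached is not None:
        return cached
    row = np.full(1, 0.0)  # |s(0,0)| = 1
    row = np.concatenate([[-np.inf] * 0, row])
    for m in range(0, n):
        new = np.full(m + 2, -np.inf)
        with np.errstate(divide="ignore"):
            # |s(m+1,k)| = m*|s(m,k)| + |s(m,k-1)|
            grown = row + math.log(m) if m > 0 else np.full_like(row, -np.inf)
            new[: m + 1] = grown
            new[1 : m + 2] = np.logaddexp(new[1 : m + 2], row)
        row = new
    _LOG_STIRLING_CACHE[n] = row
    return row


def ewens_log_pmf(n: int, theta: float) -> np.ndarray:
    """log Pr(K = k | theta, n) for k = 1..n under the Ewens sampling formula."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if theta <= 0:
        raise DegenerateInputError("Ewens pmf needs theta > 0")
    ls = log_stirling_first_row(n)[1:]  # k = 1..n
    k = np.arange(1, n + 1)
    log_rising = np.log(theta + np.arange(n)).sum()
    return ls + k * math.log(theta) - log_rising


def ewens_expected_k(n: int, theta: float) -> float:
    """E[K] = sum_{i=0}^{n-1} theta / (theta + i)."""
    return float(np.sum(theta / (theta + np.arange(n))))


def tajima_constants(n: int) -> dict[str, float]:
    """The standard 1989 normalising constants for sample size n."""
    if n < 2:
        raise DegenerateInputError("Tajima constants need n >= 2")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": e1, "e2": e2}


def tajimas_d(S: int, pi_locus: float, n: int) -> float:
    """Tajima's D = (pi - S/a1) / sqrt(e1 S + e2 S (S-1)).

    Returns NaN (an explicit not-a-value, not zero) when S = 0, where the
    statistic is undefined.
    """
    if n < 4:
        raise DegenerateInputError("Tajima's D needs n >= 4")
    if S < 0:
        raise ValueError("S must be >= 0")
    if S == 0:
        return math.nan
    c = tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    return float((pi_locus - S / c["a1"]) / math.sqrt(var))


def fus_fs(n: int, k_obs: int, theta_hat: float) -> float:
    """Fu's Fs = ln(S' / (1 - S')) with S' = Pr(K >= k_obs | theta_hat).

    theta_hat is conventionally the observed mean number of pairwise
    differences (pi_locus).  Undefined (NaN) for monomorphic samples
    (k_obs = 1, where S' = 1).
    """
    if n < 2:
        raise DegenerateInputError("Fu's Fs needs n >= 2")
    if not 1 <= k_obs <= n:
        raise ValueError("k_obs must lie in 1..n")
    if theta_hat <= 0:
        raise DegenerateInputError("Fu's Fs needs theta_hat > 0")
    if k_obs == 1:
        return math.nan
    logp = ewens_log_pmf(n, theta_hat)
    log_sp = logsumexp(logp[k_obs - 1 :])
    log_1msp = logsumexp(logp[: k_obs - 1])
    return float(log_sp - log_1msp)


@dataclass
class NeutralityResult:
    """One statistic with its simulated-null significance."""

    statistic: str
    value: float
    p_value: float
    n_reps: int


@dataclass
class NeutralityNull:
    """Null distributions of D and Fs from constant-size coalescent samples."""

    n: int
    theta: float
    d_null: np.ndarray = field(repr=False)
    fs_null: np.ndarray = field(repr=False)
    seed: int | None = None

    def p_lower(self, statistic: str, observed: float) -> float:
        """One-sided p: fraction of defined null values <= observed."""
        null = {"D": self.d_null, "Fs": self.fs_null}[statistic]
        null = null[np.isfinite(null)]
        if null.size == 0:
            raise DegenerateInputError("null distribution entirely undefined")
        return float(np.mean(null <= observed))


def neutrality_null(
    n: int,
    theta_hat: float,
    reps: int = 1000,
    seed: RNGLike = None,
    L: int = 1000,
    N: float = 10_000.0,
) -> NeutralityNull:
    """Simulate the joint null of (D, Fs) at theta = theta_hat.

    Each replicate is a constant-size coalescent sample of n sequences
    whose locus-wide theta equals theta_hat (mu is solved from theta on
    L finite sites); D and Fs are recomputed per replicate.  Replicates
    with S = 0 or K = 1 leave the corresponding statistic undefined and
    are excluded from its tail probability.
    """
    if reps < 100:
        raise ValueError("use at least 100 null replicates")
    if theta_hat <= 0:
        raise DegenerateInputError("neutrality null needs theta_hat > 0")
    rng = as_rng(seed)
    mu = theta_hat / (2.0 * N * L)
    cfg = CoalConfig(n=n, L=L, N=N, mu=mu, scaling="haploid")
    d_null = np.empty(reps)
    fs_null = np.empty(reps)
    for r in range(reps):
        gen = simulate_genealogy(cfg, rng)
        _, tips, _ = _simulate_states(gen, cfg, rng)
        s_val, k_val, pi = summaries_from_states(n, tips)
        d_null[r] = tajimas_d(s_val, pi, n) if s_val > 0 else math.nan
        fs_null[r] = fus_fs(n, k_val, pi) if (k_val > 1 and pi > 0) else math.nan
    return NeutralityNull(n=n, theta=theta_hat, d_null=d_null, fs_null=fs_null)


def neutrality_report(
    aln, reps: int = 1000, seed: RNGLike = None
) -> list[NeutralityResult]:
    """Compute D and Fs for an alignment plus simulated lower-tail p-values."""
    from .diversity import nucleotide_diversity, segregating_sites
    from .seq_io import collapse_haplotypes

    s_val = segregating_sites(aln)
    _, pi_locus = nucleotide_diversity(aln)
    k_val = collapse_haplotypes(aln).k
    d_obs = tajimas_d(s_val, pi_locus, aln.n)
    fs_obs = fus_fs(aln.n, k_val, pi_locus) if pi_locus > 0 else math.nan
    null = neutrality_null(aln.n, max(pi_locus, 1e-9), reps=reps, seed=seed)
    out = []
    for name, obs in (("D", d_obs), ("Fs", fs_obs)):
        p = null.p_lower(name, obs) if math.isfinite(obs) else math.nan
        out.append(NeutralityResult(name, obs, p, reps))
    return out
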