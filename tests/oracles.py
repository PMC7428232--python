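"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written as plain, slow, loop-based code
(or routed through an unrelated library) so it shares no code path with
the package implementations it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_pairwise_differences(seqs: list[str]) -> list[list[float]]:
    """Per-pair difference counts over sites where both bases are in ACGT."""
    n = len(seqs)
    d = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = 0
            diff = 0
            for a, b in zip(seqs[i], seqs[j]):
                if a in "ACGT" and b in "ACGT":
                    shared += 1
                    if a != b:
                        diff += 1
            d[i][j] = diff if shared > 0 else math.nan
    return d


def brute_pi_locus(seqs: list[str], complete_sites: list[int]) -> float:
    """Mean pairwise difference count over given sites, double loop."""
    n = len(seqs)
    total = 0
    pairs = 0
    for i, j in itertools.combinations(range(n), 2):
        pairs += 1
        total += sum(1 for s in complete_sites if seqs[i][s] != seqs[j][s])
    return total / pairs


def brute_segregating_sites(seqs: list[str], complete_sites: list[int]) -> int:
    count = 0
    for s in complete_sites:
        bases = {seq[s] for seq in seqs}
        if len(bases) > 1:
            count += 1
    return count


def brute_mismatch(seqs: list[str], complete_sites: list[int]) -> dict[int, int]:
    hist: dict[int, int] = {}
    for i, j in itertools.combinations(range(len(seqs)), 2):
        d = sum(1 for s in complete_sites if seqs[i][s] != seqs[j][s])
        hist[d] = hist.get(d, 0) + 1
    return hist


def complete_sites_of(seqs: list[str]) -> list[int]:
    return [
        s for s in range(len(seqs[0]))
        if all(seq[s] in "ACGT" for seq in seqs)
    ]


def tajimas_d_reference(S: int, pi: float, n: int) -> float:
    """Second, independently coded evaluation of the 1989 statistic."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1.0))


def two_level_amova_reference(
    d: np.ndarray, pops: list[list[int]]
) -> tuple[float, float, float]:
    """(sigma_a, sigma_w, phi_st) from explicit sums, flat partition."""
    all_idx = [i for p in pops for i in p]
    n = len(all_idx)
    p_count = len(pops)

    def ssd(idx: list[int]) -> float:
        tot = 0.0
        for i in idx:
            for j in idx:
                tot += d[i][j]
        return tot / (2.0 * len(idx))

    ssd_t = ssd(all_idx)
    ssd_w = sum(ssd(p) for p in pops)
    ms_a = (ssd_t - ssd_w) / (p_count - 1)
    ms_w = ssd_w / (n - p_count)
    n_c = (n - sum(len(p) ** 2 for p in pops) / n) / (p_count - 1)
    sigma_w = ms_w
    sigma_a = (ms_a - ms_w) / n_c
    return sigma_a, sigma_w, sigma_a / (sigma_a + sigma_w)


def three_level_amova_reference(
    d: np.ndarray, groups: list[list[list[int]]]
) -> dict[str, float]:
    """Variance components from explicit nested sums of squared distances."""

    def ssd(idx: list[int]) -> float:
        tot = 0.0
        for i in idx:
            for j in idx:
                tot += d[i][j]
        return tot / (2.0 * len(idx))

    pops = [p for g in groups for p in g]
    all_idx = [i for p in pops for i in p]
    n = len(all_idx)
    n_pops = len(pops)
    n_groups = len(groups)
    ssd_t = ssd(all_idx)
    ssd_wp = sum(ssd(p) for p in pops)
    ssd_wg = sum(ssd([i for p in g for i in p]) for g in groups)

    df_ag = n_groups - 1
    df_ap = n_pops - n_groups
    df_wp = n - n_pops

    sum_np2_over_ng = 0.0
    for g in groups:
        ng = sum(len(p) for p in g)
        sum_np2_over_ng += sum(len(p) ** 2 for p in g) / ng
    sum_np2 = sum(len(p) ** 2 for p in pops)
    sum_ng2 = sum(sum(len(p) for p in g) ** 2 for g in groups)

    n_prime = (n - sum_np2_over_ng) / df_ap
    n_dprime = (sum_np2_over_ng - sum_np2 / n) / df_ag
    n_tprime = (n - sum_ng2 / n) / df_ag

    sigma_c = ssd_wp / df_wp
    sigma_b = ((ssd_wg - ssd_wp) / df_ap - sigma_c) / n_prime
    sigma_a = (
        (ssd_t - ssd_wg) / df_ag - sigma_c - n_dprime * sigma_b
    ) / n_tprime
    return {
        "among_groups": sigma_a,
        "among_pops": sigma_b,
        "within_pops": sigma_c,
    }


def watterson_expected_s(n: int, theta_locus: float) -> float:
    return theta_locus * sum(1.0 / i for i in range(1, n))


def ewens_expected_k_reference(n: int, theta: float) -> float:
    return sum(theta / (theta + i) for i in range(n))


def var_s(n: int, theta: float) -> float:
    """Variance of S under the infinite-sites neutral coalescent."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    return a1 * theta + a2 * theta**2


def var_pi(n: int, theta: float) -> float:
    """Variance of the mean pairwise difference (Tajima 1983 form)."""
    return (
        (n + 1.0) / (3.0 * (n - 1.0)) * theta
        + 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0)) * theta**2
    )
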