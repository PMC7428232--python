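"""Population structure: pairwise Phi_ST, gene flow, and hierarchical AMOVA.

"F_ST" for sequence data is implemented as the distance-based Phi_ST
obtained from an analysis of molecular variance (AMOVA) on the matrix of
pairwise site-difference counts — the standard treatment of mtDNA
haplotype data.  The three-level decomposition partitions molecular
variance among groups of populations (Phi_CT), among populations within
groups (Phi_SC), and within populations (Phi_ST for the total
population-level divergence), with significance from permutation at the
appropriate level.  Negative variance components are retained, not
truncated, so percentage decompositions can be slightly negative while
still summing to 100.

Gene flow is back-calculated from Phi_ST under a haploid island model,
Nm = (1/F - 1)/2, the convention for a maternally inherited marker.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coalsim import RNGLike, as_rng
from .errors import DegenerateInputError
from .seq_io import Alignment, SampleTable, nonmissing_mask, usable_sites


def pairwise_distance_matrix(aln: Alignment, policy: str = "complete") -> np.ndarray:
    """Symmetric matrix of pairwise site-difference counts.

    Distances are raw counts of differing usable sites (the p-distance
    numerator), matching a mismatch analysis; no substitution-model
    correction is applied.  Under pairwise deletion a pair with no
    mutually usable site gets NaN.
    """
    if aln.n < 2:
        raise DegenerateInputError("distance matrix needs >= 2 sequences")
    mat = aln.matrix
    if policy == "complete":
        sites = usable_sites(aln, "complete")
        sub = mat[:, sites]
        d = (sub[:, None, :] != sub[None, :, :]).sum(axis=2).astype(float)
        return d
    if policy == "pairwise":
        mask = nonmissing_mask(aln)
        both = mask[:, None, :] & mask[None, :, :]
        neq = (mat[:, None, :] != mat[None, :, :]) & both
        d = neq.sum(axis=2).astype(float)
        d[both.sum(axis=2) == 0] = np.nan
        np.fill_diagonal(d, 0.0)
        return d
    raise ValueError(f"unknown site policy {policy!r}")


def gene_flow_from_fst(f: float) -> float:
    """Haploid island-model migrant number Nm = (1/F - 1)/2; F <= 0 -> inf."""
    if f >= 1:
        raise ValueError("gene flow undefined for F >= 1")
    if f <= 0:
        return math.inf
    return (1.0 / f - 1.0) / 2.0


def _ssd(d: np.ndarray, idx: np.ndarray) -> float:
    """Sum of squared deviations for a set of individuals, from distances."""
    sub = d[np.ix_(idx, idx)]
    return float(sub.sum() / (2.0 * len(idx)))


def _two_level_phi(d: np.ndarray, pops: list[np.ndarray]) -> tuple[float, float, float]:
    """(phi_st, sigma_a, sigma_w) for a flat population partition."""
    sizes = np.array([len(p) for p in pops])
    n_tot = int(sizes.sum())
    n_pops = len(pops)
    ssd_t = _ssd(d, np.concatenate(pops))
    ssd_wp = sum(_ssd(d, p) for p in pops)
    ssd_ap = ssd_t - ssd_wp
    df_ap = n_pops - 1
    df_wp = n_tot - n_pops
    ms_ap = ssd_ap / df_ap
    ms_wp = ssd_wp / df_wp if df_wp > 0 else 0.0
    n_c = (n_tot - float(np.sum(sizes**2)) / n_tot) / df_ap
    sigma_w = ms_wp
    sigma_a = (ms_ap - sigma_w) / n_c
    total = sigma_a + sigma_w
    phi = sigma_a / total if total > 0 else 0.0
    return phi, sigma_a, sigma_w


@dataclass
class PairwiseStructure:
    """Phi_ST between one pair of populations, with permutation p and Nm."""

    pair: tuple[str, str]
    phi_st: float
    p_value: float
    nm: float
    n_perms: int


def phi_st_pairwise(
    aln: Alignment,
    labels: list[str] | np.ndarray,
    n_perms: int = 10_000,
    seed: RNGLike = None,
    distances: np.ndarray | None = None,
) -> PairwiseStructure:
    """Two-population Phi_ST with permutation significance.

    `labels` assigns each sequence to one of exactly two populations;
    the p-value is the proportion of random relabellings whose Phi_ST is
    at least the observed value.
    """
    labels = np.asarray(labels)
    names = sorted(pd.unique(labels).tolist())
    if len(names) != 2:
        raise ValueError("phi_st_pairwise needs exactly two populations")
    idx = [np.flatnonzero(labels == name) for name in names]
    if min(len(i) for i in idx) < 2:
        raise DegenerateInputError("each population needs >= 2 members")
    d = pairwise_distance_matrix(aln) if distances is None else distances
    phi, _, _ = _two_level_phi(d, idx)
    rng = as_rng(seed)
    sizes = [len(i) for i in idx]
    pool = np.concatenate(idx)
    count = 0
    for _ in range(n_perms):
        perm = rng.permutation(pool)
        pphi, _, _ = _two_level_phi(d, [perm[: sizes[0]], perm[sizes[0] :]])
        if pphi >= phi:
            count += 1
    p = count / n_perms if n_perms > 0 else math.nan
    return PairwiseStructure(
        pair=(names[0], names[1]),
        phi_st=float(phi),
        p_value=float(p),
        nm=gene_flow_from_fst(min(phi, 1.0 - 1e-12)),
        n_perms=n_perms,
    )


@dataclass
class AmovaResult:
    """Three-level AMOVA decomposition for one grouping hypothesis."""

    grouping: str
    sigma: dict[str, float]          # among_groups / among_pops / within_pops
    percent: dict[str, float]
    phi_ct: float
    phi_sc: float
    phi_st: float
    p_values: dict[str, float] = field(default_factory=dict)
    n_perms: int = 0
    df: dict[str, int] = field(default_factory=dict)
    degenerate: bool = False


def _amova3_components(
    d: np.ndarray, groups: list[list[np.ndarray]]
) -> tuple[dict[str, float], dict[str, int]]:
    """Variance components from sums of squared distances.

    `groups` is a nested partition: a list of groups, each a list of
    per-population index arrays.
    """
    pops = [p for g in groups for p in g]
    all_idx = np.concatenate(pops)
    n_tot = len(all_idx)
    n_pops = len(pops)
    n_groups = len(groups)
    ssd_t = _ssd(d, all_idx)
    ssd_wp = sum(_ssd(d, p) for p in pops)
    ssd_wg = sum(_ssd(d, np.concatenate(g)) for g in groups)
    ssd_ap = ssd_wg - ssd_wp
    ssd_ag = ssd_t - ssd_wg

    df_ag = n_groups - 1
    df_ap = n_pops - n_groups
    df_wp = n_tot - n_pops
    pop_sizes = np.array([len(p) for p in pops], dtype=float)
    grp_sizes = np.array([sum(len(p) for p in g) for g in groups], dtype=float)
    sum_np2_over_ng = sum(
        sum(len(p) ** 2 for p in g) / gs for g, gs in zip(groups, grp_sizes)
    )
    # Unequal-size coefficients of the nested design.
    n_prime = (n_tot - sum_np2_over_ng) / df_ap if df_ap > 0 else 0.0
    n_dprime = (
        (sum_np2_over_ng - float(np.sum(pop_sizes**2)) / n_tot) / df_ag
        if df_ag > 0
        else 0.0
    )
    n_tprime = (
        (n_tot - float(np.sum(grp_sizes**2)) / n_tot) / df_ag if df_ag > 0 else 0.0
    )

    ms_wp = ssd_wp / df_wp if df_wp > 0 else 0.0
    sigma_c = ms_wp
    if df_ap > 0 and n_prime > 0:
        sigma_b = (ssd_ap / df_ap - sigma_c) / n_prime
    else:
        sigma_b = 0.0
    if df_ag > 0 and n_tprime > 0:
        sigma_a = (ssd_ag / df_ag - sigma_c - n_dprime * sigma_b) / n_tprime
    else:
        sigma_a = 0.0
    sigma = {
        "among_groups": float(sigma_a),
        "among_pops": float(sigma_b),
        "within_pops": float(sigma_c),
    }
    df = {"among_groups": df_ag, "among_pops": df_ap, "within_pops": df_wp}
    return sigma, df


def _phis_from_sigma(sigma: dict[str, float]) -> tuple[float, float, float, bool]:
    sa, sb, sc = (
        sigma["among_groups"],
        sigma["among_pops"],
        sigma["within_pops"],
    )
    total = sa + sb + sc
    if total <= 0:
        return 0.0, 0.0, 0.0, True
    phi_ct = sa / total
    phi_sc = sb / (sb + sc) if (sb + sc) > 0 else 0.0
    phi_st = (sa + sb) / total
    return phi_ct, phi_sc, phi_st, False


def amova3(
    aln: Alignment,
    meta: SampleTable,
    grouping: list[list[str]],
    populations: str = "zone",
    n_perms: int = 10_000,
    seed: RNGLike = None,
    distances: np.ndarray | None = None,
) -> AmovaResult:
    """Three-level AMOVA over a grouping of zones (or localities).

    `grouping` partitions population labels into groups, e.g.
    ``[["Z1", "Z2"], ["Z3", "Z4"]]``.  `populations` selects which
    metadata column defines populations: "zone" or "site" (locality).
    Permutation schemes follow the level being tested: whole populations
    among groups for Phi_CT, individuals among populations within groups
    for Phi_SC, individuals among all populations for Phi_ST.
    """
    col = {"zone": "zone", "zones": "zone", "site": "locality", "sites": "locality"}[
        populations
    ]
    resolved = meta.resolve(aln.ids)
    labels = resolved[col].to_numpy()
    if col == "zone":
        pop_to_group: dict[str, int] = {}
        for gi, g in enumerate(grouping):
            for z in g:
                pop_to_group[z] = gi
    else:
        # grouping is stated in zones; localities inherit their zone's group
        zone_group = {z: gi for gi, g in enumerate(grouping) for z in g}
        pop_to_group = {}
        for loc, zone in zip(resolved["locality"], resolved["zone"]):
            pop_to_group[loc] = zone_group[zone]

    pop_names = [p for p in pd.unique(labels) if p in pop_to_group]
    present = set(labels)
    missing = [p for p in pop_to_group if p not in present and col == "zone"]
    if missing:
        warnings.warn(f"grouping lists populations with no samples: {missing}")
    groups_named: dict[int, list[str]] = {}
    for p in pop_names:
        groups_named.setdefault(pop_to_group[p], []).append(p)
    if len(groups_named) < 1 or len(pop_names) < 2:
        raise DegenerateInputError("AMOVA needs >= 2 populations")
    if len(groups_named) == 1:
        warnings.warn("single-group grouping: collapsing to a two-level AMOVA")

    d = pairwise_distance_matrix(aln) if distances is None else distances
    pop_idx = {p: np.flatnonzero(labels == p) for p in pop_names}
    nested = [
        [pop_idx[p] for p in groups_named[gi]] for gi in sorted(groups_named)
    ]

    sigma, df = _amova3_components(d, nested)
    phi_ct, phi_sc, phi_st, degen = _phis_from_sigma(sigma)
    total = sum(sigma.values())
    percent = {
        k: (100.0 * v / total if total != 0 else 0.0) for k, v in sigma.items()
    }

    rng = as_rng(seed)
    p_values: dict[str, float] = {}
    if n_perms > 0 and not degen:
        n_groups = len(nested)
        all_idx = np.concatenate([p for g in nested for p in g])
        pop_sizes = [[len(p) for p in g] for g in nested]
        flat_pops = [p for g in nested for p in g]
        pops_per_group = [len(g) for g in nested]

        c_st = c_sc = c_ct = 0
        for _ in range(n_perms):
            # Phi_ST: individuals among all populations.
            perm = rng.permutation(all_idx)
            pos = 0
            nested_st = []
            for g in range(n_groups):
                gp = []
                for sz in pop_sizes[g]:
                    gp.append(perm[pos : pos + sz])
                    pos += sz
                nested_st.append(gp)
            s_st, _ = _amova3_components(d, nested_st)
            if _phis_from_sigma(s_st)[2] >= phi_st - 1e-12:
                c_st += 1

            # Phi_SC: individuals among populations within their group.
            nested_sc = []
            for g in nested:
                gidx = rng.permutation(np.concatenate(g))
                pos = 0
                gp = []
                for p in g:
                    gp.append(gidx[pos : pos + len(p)])
                    pos += len(p)
                nested_sc.append(gp)
            s_sc, _ = _amova3_components(d, nested_sc)
            if _phis_from_sigma(s_sc)[1] >= phi_sc - 1e-12:
                c_sc += 1

            # Phi_CT: whole populations among groups.
            if n_groups > 1:
                order = rng.permutation(len(flat_pops))
                pos = 0
                nested_ct = []
                for g in range(n_groups):
                    k = pops_per_group[g]
                    nested_ct.append([flat_pops[i] for i in order[pos : pos + k]])
                    pos += k
                s_ct, _ = _amova3_components(d, nested_ct)
                if _phis_from_sigma(s_ct)[0] >= phi_ct - 1e-12:
                    c_ct += 1
        p_values = {
            "phi_st": c_st / n_perms,
            "phi_sc": c_sc / n_perms,
            "phi_ct": c_ct / n_perms if n_groups > 1 else math.nan,
        }

    label = "".join("(" + " + ".join(g) + ")" for g in grouping)
    return AmovaResult(
        grouping=label,
        sigma=sigma,
        percent=percent,
        phi_ct=phi_ct if len(nested) > 1 else math.nan,
        phi_sc=phi_sc,
        phi_st=phi_st,
        p_values=p_values,
        n_perms=n_perms,
        df=df,
        degenerate=degen,
    )


def pairwise_structure_table(
    aln: Alignment,
    meta: SampleTable,
    n_perms: int = 10_000,
    seed: RNGLike = None,
) -> pd.DataFrame:
    """Zone-by-zone matrix: Phi_ST below the diagonal, Nm above.

    Infinite gene flow (Phi_ST <= 0) is rendered as the literal "inf".
    """
    rng = as_rng(seed)
    resolved = meta.resolve(aln.ids)
    zones = [z for z in meta.zones if (resolved["zone"] == z).sum() >= 2]
    d = pairwise_distance_matrix(aln)
    out = pd.DataFrame("", index=zones, columns=zones, dtype=object)
    for i, zi in enumerate(zones):
        for j in range(i + 1, len(zones)):
            zj = zones[j]
            sel = resolved["zone"].isin([zi, zj]).to_numpy()
            idx = np.flatnonzero(sel)
            sub_d = d[np.ix_(idx, idx)]
            sub_labels = resolved.loc[sel, "zone"].to_numpy()
            res = phi_st_pairwise(
                aln.subset(resolved.loc[sel, "sample_id"]),
                sub_labels,
                n_perms=n_perms,
                seed=rng,
                distances=sub_d,
            )
            flag = "*" if res.p_value < 0.05 else ""
            out.loc[zj, zi] = f"{res.phi_st:.4f}{flag}"
            out.loc[zi, zj] = (
                "inf" if math.isinf(res.nm) else f"{res.nm:.2f}"
            )
    return out
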