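"""Diversity indexes and the mismatch distribution.

Implements the classical mtDNA summary statistics: number of segregating
sites S, haplotype count K, Nei's unbiased haplotype diversity
Hd = n/(n-1) * (1 - sum p_i^2), and nucleotide diversity pi reported both
per site (Table-style convention) and per locus (mean number of pairwise
nucleotide differences).  The mismatch distribution is the histogram of
pairwise difference counts over all C(n, 2) sequence pairs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError
from .seq_io import (
    Alignment,
    HaplotypeTable,
    SampleTable,
    collapse_haplotypes,
    nonmissing_mask,
    usable_sites,
)

log = logging.getLogger(__name__)


@dataclass
class DiversitySummary:
    """Per-population summary: n, S, K, Hd, pi (per site and per locus)."""

    n: int
    S: int
    K: int
    Hd: float
    pi_site: float
    pi_locus: float
    usable_L: int
    label: str = ""


def _column_allele_counts(sub: np.ndarray) -> np.ndarray:
    """Allele counts per column for an (n, m) matrix of codes 0..3."""
    n, m = sub.shape
    if m == 0:
        return np.zeros((0, 4), dtype=np.int64)
    flat = sub.astype(np.int64) + 4 * np.arange(m, dtype=np.int64)[None, :]
    return np.bincount(flat.ravel(), minlength=4 * m).reshape(m, 4)


def segregating_sites(aln: Alignment, policy: str = "complete") -> int:
    """Number of usable sites with two or more distinct non-missing bases."""
    if aln.n < 2:
        raise DegenerateInputError("segregating sites need >= 2 sequences")
    if policy == "complete":
        sites = usable_sites(aln, "complete")
        counts = _column_allele_counts(aln.matrix[:, sites])
    elif policy == "pairwise":
        mask = nonmissing_mask(aln)
        m = aln.L
        masked = np.where(mask, aln.matrix, 0).astype(np.int64)
        flat = masked + 4 * np.arange(m, dtype=np.int64)[None, :]
        counts = np.zeros(4 * m, dtype=np.int64)
        np.add.at(counts, flat[mask], 1)
        counts = counts.reshape(m, 4)
    else:
        raise ValueError(f"unknown site policy {policy!r}")
    return int(((counts > 0).sum(axis=1) > 1).sum())


def haplotype_diversity(
    haps: HaplotypeTable | np.ndarray | list[int], n: int | None = None
) -> float:
    """Nei's unbiased haplotype diversity Hd = n/(n-1) * (1 - sum p_i^2)."""
    counts = haps.counts if isinstance(haps, HaplotypeTable) else np.asarray(haps)
    total = int(counts.sum())
    if n is None:
        n = total
    elif n != total:
        raise ValueError(f"haplotype counts sum to {total}, not n={n}")
    if n < 2:
        raise DegenerateInputError("haplotype diversity needs n >= 2")
    p = counts / n
    return float(n / (n - 1) * (1.0 - np.square(p).sum()))


def nucleotide_diversity(
    aln: Alignment, policy: str = "complete"
) -> tuple[float, float]:
    """(pi_site, pi_locus): mean pairwise differences per site and per locus.

    Under complete deletion pi_locus = pi_site * usable_L exactly.  Under
    pairwise deletion each pair is compared over its mutually unambiguous
    sites; pi_site averages the per-pair proportions, and pairs with no
    mutually usable site are dropped with a warning.
    """
    if aln.n < 2:
        raise DegenerateInputError("nucleotide diversity needs >= 2 sequences")
    if policy == "complete":
        sites = usable_sites(aln, "complete")
        if sites.size == 0:
            raise DegenerateInputError("no usable site under complete deletion")
        sub = aln.matrix[:, sites]
        counts = _column_allele_counts(sub)
        n = aln.n
        npairs = n * (n - 1) // 2
        same = (counts * (counts - 1) // 2).sum(axis=1)
        pi_locus = float((npairs - same).sum() / npairs)
        return pi_locus / sites.size, pi_locus
    if policy == "pairwise":
        mask = nonmissing_mask(aln)
        mat = aln.matrix
        n = aln.n
        diffs, props = [], []
        dropped = 0
        for i in range(n):
            both = mask[i] & mask[i + 1 :]
            shared = both.sum(axis=1)
            neq = ((mat[i] != mat[i + 1 :]) & both).sum(axis=1)
            ok = shared > 0
            dropped += int((~ok).sum())
            diffs.extend(neq[ok].tolist())
            props.extend((neq[ok] / shared[ok]).tolist())
        if dropped:
            warnings.warn(
                f"{dropped} pair(s) with no mutually usable site excluded from pi"
            )
        if not diffs:
            raise DegenerateInputError("no pair with usable sites")
        return float(np.mean(props)), float(np.mean(diffs))
    raise ValueError(f"unknown site policy {policy!r}")


def mismatch_distribution(aln: Alignment, policy: str = "complete") -> np.ndarray:
    """Histogram of pairwise difference counts; index d holds #pairs at d.

    The histogram sums to C(n, 2) (minus pairs dropped under pairwise
    deletion for lack of mutually usable sites) and its mean equals
    pi_locus.
    """
    from .structure import pairwise_distance_matrix

    if aln.n < 2:
        raise DegenerateInputError("mismatch distribution needs >= 2 sequences")
    d = pairwise_distance_matrix(aln, policy=policy)
    iu = np.triu_indices(aln.n, k=1)
    vals = d[iu]
    vals = vals[np.isfinite(vals)].astype(np.int64)
    if vals.size == 0:
        raise DegenerateInputError("no comparable pair")
    return np.bincount(vals)


def summarize(
    aln: Alignment,
    meta: SampleTable | None = None,
    policy: str = "complete",
    label: str = "",
) -> DiversitySummary:
    """All Table-style indexes for one alignment."""
    haps = collapse_haplotypes(aln, meta, policy=policy)
    pi_site, pi_locus = nucleotide_diversity(aln, policy=policy)
    usable = usable_sites(aln, "complete")
    return DiversitySummary(
        n=aln.n,
        S=segregating_sites(aln, policy=policy),
        K=haps.k,
        Hd=haplotype_diversity(haps),
        pi_site=pi_site,
        pi_locus=pi_locus,
        usable_L=int(usable.size),
        label=label,
    )


def diversity_table(
    aln: Alignment,
    meta: SampleTable,
    policy: str = "complete",
) -> pd.DataFrame:
    """One row per species x zone plus a basin-wide row per species.

    Mirrors the layout of a per-zone genetic-diversity summary table
    (zone, n, S, K, Hd, pi).  Species-zone combinations with fewer than
    two samples yield a 'no data' row rather than an error.
    """
    rows = []
    resolved = meta.resolve(aln.ids)
    for species in pd.unique(resolved["species"]):
        sp_ids = resolved.loc[resolved["species"] == species, "sample_id"]
        for zone in list(meta.zones) + ["basin"]:
            if zone == "basin":
                ids = sp_ids
            else:
                ids = resolved.loc[
                    (resolved["species"] == species) & (resolved["zone"] == zone),
                    "sample_id",
                ]
            base = {"species": species, "zone": zone, "n": len(ids)}
            if len(ids) < 2:
                rows.append(
                    {**base, "S": None, "K": None, "Hd": None,
                     "pi_site": None, "pi_locus": None}
                )
                continue
            s = summarize(aln.subset(ids), meta, policy=policy)
            rows.append(
                {**base, "S": s.S, "K": s.K, "Hd": round(s.Hd, 4),
                 "pi_site": round(s.pi_site, 5), "pi_locus": round(s.pi_locus, 3)}
            )
    return pd.DataFrame(rows)
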