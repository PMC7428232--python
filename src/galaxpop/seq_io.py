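"""Alignment and sample-metadata I/O.

The unit every statistic in this package consumes is a rectangular DNA
alignment (equal-length sequences over ``{A, C, G, T, N, -}``) together
with a per-sample metadata table assigning each sequence to a species,
a sampling zone and a locality.  Sequences are case-folded on input and
IUPAC ambiguity codes other than ``N`` are collapsed to ``N``: control
region chromatograms commonly contain them and no downstream statistic
distinguishes the individual codes.

Missing-data policy
-------------------
Sites containing a gap or an ``N`` can be handled in two ways:

``complete``  (default)
    Sites with a gap/N in *any* sequence are excluded from every
    statistic (complete deletion, the DNASP default).
``pairwise``
    Each pair of sequences is compared over the sites where *both* are
    unambiguous (pairwise deletion, the ARLEQUIN default for distances).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    DegenerateInputError,
    EmptyInputError,
    LengthMismatchError,
    MetadataError,
)

# Integer encoding: A,C,G,T are 0..3; N (and any ambiguity code) is 4; '-' is 5.
# Codes >= MISSING_CODE are treated as missing data.
MISSING_CODE = 4
_BASES = "ACGTN-"
_IUPAC_AMBIGUOUS = set("RYSWKMBDHV")
_CODE = {b: i for i, b in enumerate(_BASES)}

DEFAULT_ZONES = ("Z1", "Z2", "Z3", "Z4")


def _clean_sequence(seq: str) -> str:
    out = []
    for ch in seq.upper():
        if ch in _CODE:
            out.append(ch)
        elif ch in _IUPAC_AMBIGUOUS or ch == "?":
            out.append("N")
        else:
            raise ValueError(f"unrecognised character {ch!r} in sequence")
    return "".join(out)


@dataclass
class Alignment:
    """Equal-length DNA sequences with unique sample ids."""

    ids: list[str]
    seqs: list[str]
    _matrix: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.ids) == 0:
            raise EmptyInputError("alignment holds no sequences")
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("sample ids are not unique")
        self.seqs = [_clean_sequence(s) for s in self.seqs]
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise LengthMismatchError(
                f"ragged alignment: sequence lengths {sorted(lengths)}"
            )

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def L(self) -> int:
        return len(self.seqs[0])

    @property
    def matrix(self) -> np.ndarray:
        """Integer-coded view, shape (n, L), dtype int8."""
        if self._matrix is None:
            lut = np.full(128, -1, dtype=np.int8)
            for b, c in _CODE.items():
                lut[ord(b)] = c
            buf = np.frombuffer(
                "".join(self.seqs).encode("ascii"), dtype=np.uint8
            ).reshape(self.n, self.L)
            self._matrix = lut[buf]
        return self._matrix

    def subset(self, ids: Iterable[str]) -> "Alignment":
        wanted = list(ids)
        index = {sid: i for i, sid in enumerate(self.ids)}
        missing = [sid for sid in wanted if sid not in index]
        if missing:
            raise MetadataError(f"ids not in alignment: {missing[:5]}")
        return Alignment(wanted, [self.seqs[index[sid]] for sid in wanted])


def read_fasta(path: str | Path) -> Alignment:
    """Read a multi-record FASTA file into an :class:`Alignment`."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")
    return Alignment([r.id for r in records], [str(r.seq) for r in records])


def write_fasta(aln: Alignment, path: str | Path, wrap: int = 70) -> None:
    records = [
        SeqRecord(Seq(s), id=i, description="") for i, s in zip(aln.ids, aln.seqs)
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(records)


@dataclass
class SampleTable:
    """Per-sample metadata: species, zone and locality for each id."""

    df: pd.DataFrame
    zones: tuple[str, ...] = DEFAULT_ZONES

    REQUIRED = ("sample_id", "species", "zone", "locality")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise MetadataError(f"metadata table lacks columns {missing}")
        if self.df["sample_id"].duplicated().any():
            raise MetadataError("duplicate sample_id in metadata")
        bad = set(self.df["zone"]) - set(self.zones)
        if bad:
            raise MetadataError(f"zones {sorted(bad)} not in declared set {self.zones}")
        self.df = self.df.reset_index(drop=True)

    def zone_of(self) -> Mapping[str, str]:
        return dict(zip(self.df["sample_id"], self.df["zone"]))

    def species_of(self) -> Mapping[str, str]:
        return dict(zip(self.df["sample_id"], self.df["species"]))

    def locality_of(self) -> Mapping[str, str]:
        return dict(zip(self.df["sample_id"], self.df["locality"]))

    def resolve(self, ids: Iterable[str]) -> pd.DataFrame:
        """Rows for `ids`, in that order; every id must resolve."""
        index = self.df.set_index("sample_id")
        wanted = list(ids)
        unknown = [sid for sid in wanted if sid not in index.index]
        if unknown:
            raise MetadataError(f"ids without metadata: {unknown[:5]}")
        return index.loc[wanted].reset_index()


def read_sample_table(
    path: str | Path, zones: tuple[str, ...] = DEFAULT_ZONES
) -> SampleTable:
    """Read the tab-separated metadata table (sample_id/species/zone/locality)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise EmptyInputError(f"no metadata rows in {path}")
    return SampleTable(df, zones=zones)


def write_sample_table(table: SampleTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


def nonmissing_mask(aln: Alignment) -> np.ndarray:
    """Boolean (n, L) mask, True where a base is unambiguous A/C/G/T."""
    return aln.matrix < MISSING_CODE


def usable_sites(aln: Alignment, policy: str = "complete") -> np.ndarray:
    """Sites usable under the given missing-data policy.

    Under ``complete`` deletion, returns the indices of sites with no
    gap/N in any sequence.  Under ``pairwise`` deletion the usable set
    is pair-specific: the returned value is the (n, L) non-missing mask,
    and the usable set for a pair (i, j) is ``mask[i] & mask[j]``.
    """
    mask = nonmissing_mask(aln)
    if policy == "complete":
        return np.flatnonzero(mask.all(axis=0))
    if policy == "pairwise":
        return mask
    raise ValueError(f"unknown site policy {policy!r}")


@dataclass
class HaplotypeTable:
    """Distinct sequences with total and per-zone counts.

    ``df`` has one row per haplotype: columns ``haplotype`` (H1, H2, ...
    in order of first appearance), ``sequence`` (representative full
    sequence), ``total`` and, when zone metadata was supplied, one count
    column per zone.  ``assignments`` maps each sample id to its
    haplotype label.
    """

    df: pd.DataFrame
    assignments: dict[str, str]

    @property
    def k(self) -> int:
        return len(self.df)

    @property
    def n(self) -> int:
        return int(self.df["total"].sum())

    @property
    def counts(self) -> np.ndarray:
        return self.df["total"].to_numpy()

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def collapse_haplotypes(
    aln: Alignment,
    meta: SampleTable | None = None,
    policy: str = "complete",
) -> HaplotypeTable:
    """Partition sequences into identity classes on the usable sites.

    Identity is judged only at sites usable under `policy` (for the
    pairwise policy, at each sequence's own unambiguous sites — two
    sequences are lumped when they agree wherever both are unambiguous
    *and* share the same missingness pattern is NOT required; we use
    the complete-deletion site set for grouping in both cases, which is
    the only transitive notion of identity).
    """
    if policy not in ("complete", "pairwise"):
        raise ValueError(f"unknown site policy {policy!r}")
    sites = usable_sites(aln, "complete")
    if sites.size == 0 and aln.L > 0:
        # No fully-usable site: fall back to whole-sequence identity so the
        # partition stays well defined.
        keymat = aln.matrix
    else:
        keymat = aln.matrix[:, sites]

    zone_of = meta.zone_of() if meta is not None else None
    zones = list(meta.zones) if meta is not None else []
    if zone_of is not None:
        unknown = [sid for sid in aln.ids if sid not in zone_of]
        if unknown:
            raise MetadataError(f"ids without metadata: {unknown[:5]}")

    order: dict[bytes, int] = {}
    members: list[list[int]] = []
    for i in range(aln.n):
        key = keymat[i].tobytes()
        if key not in order:
            order[key] = len(members)
            members.append([])
        members[order[key]].append(i)

    rows = []
    assignments: dict[str, str] = {}
    for h, idx in enumerate(members):
        label = f"H{h + 1}"
        for i in idx:
            assignments[aln.ids[i]] = label
        row: dict[str, object] = {
            "haplotype": label,
            "sequence": aln.seqs[idx[0]],
            "total": len(idx),
        }
        if zone_of is not None:
            for z in zones:
                row[z] = sum(1 for i in idx if zone_of[aln.ids[i]] == z)
        rows.append(row)
    return HaplotypeTable(pd.DataFrame(rows), assignments)
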