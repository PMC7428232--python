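"""Synthetic alignments with the statistical structure the analysis assumes.

Fixtures for every pipeline stage, generated with the package's own
coalescent engine:

* a *panmictic* dataset — one population arbitrarily split into zones,
  so between-zone Phi_ST is centred on zero (the null case);
* a *structured* dataset — deeply divergent haplogroups founded by
  sequences a fixed number of mutational steps apart, mixed into zones
  with specified weights, so zone differentiation rises with founder
  divergence (the star-like haplogroup geography of real basin data);
* a *two-species* contrast — one high-diversity structured species and
  one low-diversity near-panmictic species, written as FASTA + TSV.

Founders are built by placing the requested number of mutations at
distinct, previously unused sites of a random ancestral sequence
(infinite-sites placement), so the minimum distance between consecutive
haplogroup founders equals the requested step count exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coalsim import CoalConfig, RNGLike, as_rng, drop_mutations, simulate_genealogy
from .seq_io import Alignment, SampleTable, write_fasta, write_sample_table

DEFAULT_ZONES = ("Z1", "Z2", "Z3", "Z4")


@dataclass
class SynthSpec:
    """Recipe for one synthetic species dataset.

    zone_sizes: samples per zone; theta: within-haplogroup (or total,
    for the panmictic case) locus-wide theta = 2 N mu L; founder_steps:
    mutational separations between consecutive haplogroup founders (one
    haplogroup if empty); mixing: per-zone haplogroup weights, rows
    summing to 1.
    """

    zone_sizes: dict[str, int]
    L: int = 505
    theta: float = 5.0
    founder_steps: tuple[int, ...] = ()
    mixing: dict[str, tuple[float, ...]] | None = None
    species: str = "synthetic"
    N: float = 10_000.0

    def __post_init__(self) -> None:
        if any(v < 2 for v in self.zone_sizes.values()):
            raise ValueError("each zone needs >= 2 samples")
        if any(s < 0 for s in self.founder_steps):
            raise ValueError("founder divergences must be >= 0")
        if self.mixing is not None:
            k = len(self.founder_steps) + 1
            for z, w in self.mixing.items():
                if len(w) != k:
                    raise ValueError(f"zone {z}: expected {k} haplogroup weights")
                if abs(sum(w) - 1.0) > 1e-9:
                    raise ValueError(f"zone {z}: weights must sum to 1")

    @property
    def zones(self) -> tuple[str, ...]:
        return tuple(self.zone_sizes)

    @property
    def n_haplogroups(self) -> int:
        return len(self.founder_steps) + 1

    def config(self, n: int) -> CoalConfig:
        mu = self.theta / (2.0 * self.N * self.L)
        return CoalConfig(n=n, L=self.L, N=self.N, mu=mu)


#: Sampling localities per zone (round-robin assignment), so site-level
#: AMOVA has enough populations for group-level permutation tests.
LOCALITIES_PER_ZONE = 3


def _metadata(spec: SynthSpec, ids: list[str], zones: list[str]) -> SampleTable:
    seen: dict[str, int] = {}
    locs = []
    for z in zones:
        i = seen.get(z, 0)
        seen[z] = i + 1
        locs.append(f"{z}_loc{1 + i % LOCALITIES_PER_ZONE}")
    df = pd.DataFrame(
        {
            "sample_id": ids,
            "species": spec.species,
            "zone": zones,
            "locality": locs,
        }
    )
    return SampleTable(df, zones=tuple(spec.zone_sizes))


def make_panmictic(spec: SynthSpec, seed: RNGLike = None) -> tuple[Alignment, SampleTable]:
    """One panmictic coalescent sample split round-robin into zones."""
    rng = as_rng(seed)
    n = sum(spec.zone_sizes.values())
    cfg = spec.config(n)
    gen = simulate_genealogy(cfg, rng)
    zone_list: list[str] = []
    for z, size in spec.zone_sizes.items():
        zone_list.extend([z] * size)
    ids = [f"{spec.species}_{z}_{i}" for i, z in enumerate(zone_list)]
    aln = drop_mutations(gen, cfg, rng, ids=ids)
    return aln, _metadata(spec, ids, zone_list)


def _founders(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    """Haplogroup founder sequences (codes), consecutive pairs separated by
    exactly the requested number of mutational steps at distinct sites."""
    anc = rng.integers(0, 4, size=spec.L, dtype=np.int8)
    founders = [anc]
    used: set[int] = set()
    for steps in spec.founder_steps:
        free = np.array(sorted(set(range(spec.L)) - used), dtype=np.int64)
        if steps > free.size:
            raise ValueError("founder divergence exceeds available sites")
        sites = rng.choice(free, size=steps, replace=False)
        used.update(sites.tolist())
        nxt = founders[-1].copy()
        nxt[sites] = (nxt[sites] + rng.integers(1, 4, size=steps)) % 4
        founders.append(nxt)
    return np.stack(founders)


def make_structured(spec: SynthSpec, seed: RNGLike = None) -> tuple[Alignment, SampleTable]:
    """Zone-differentiated haplogroup mixture dataset.

    Per zone, sample counts are split across haplogroups by the mixing
    weights (multinomially); each haplogroup's members descend from its
    founder through an independent within-haplogroup coalescent at
    `spec.theta`.  With zero founder divergence and equal weights this
    reduces distributionally to several independent panmictic pools.
    """
    rng = as_rng(seed)
    if spec.mixing is None:
        k = spec.n_haplogroups
        mixing = {z: tuple([1.0 / k] * k) for z in spec.zones}
    else:
        mixing = spec.mixing
    founders = _founders(spec, rng)

    # A zero-step separation means the founders coincide: such
    # "haplogroups" are one and the same pool, so merge them (their
    # mixing weights add).  With every step zero this reduces exactly
    # to a single panmictic pool.
    eff_of = [0]
    for steps in spec.founder_steps:
        eff_of.append(eff_of[-1] + (1 if steps > 0 else 0))
    n_eff = eff_of[-1] + 1
    founders = np.stack(
        [founders[eff_of.index(e)] for e in range(n_eff)]
    )
    mixing = {
        z: tuple(
            sum(w for w, e in zip(ws, eff_of) if e == eff)
            for eff in range(n_eff)
        )
        for z, ws in mixing.items()
    }

    counts = {
        z: rng.multinomial(size, mixing[z])
        for z, size in spec.zone_sizes.items()
    }
    ids_all: list[str] = []
    zones_all: list[str] = []
    seq_chunks: list[list[str]] = []
    serial = 0
    for h in range(n_eff):
        members: list[str] = []
        for z in spec.zones:
            members.extend([z] * int(counts[z][h]))
        total = len(members)
        if total == 0:
            continue
        if total == 1:
            # A single lineage has no within-haplogroup genealogy; it
            # carries the founder sequence unchanged.
            lut = "ACGT"
            seqs = ["".join(lut[c] for c in founders[h])]
        else:
            cfg = spec.config(total)
            gen = simulate_genealogy(cfg, rng)
            aln_h = drop_mutations(gen, cfg, rng, ancestral=founders[h])
            seqs = aln_h.seqs
        for z, s in zip(members, seqs):
            ids_all.append(f"{spec.species}_{z}_{serial}")
            zones_all.append(z)
            seq_chunks.append(s)
            serial += 1
    aln = Alignment(ids_all, list(seq_chunks))
    return aln, _metadata(spec, ids_all, zones_all)


# Preset recipes: a basin-like two-species contrast, a null (panmictic)
# case, and an extreme-structure case for power checks.
PRESETS: dict[str, SynthSpec] = {
    "basin_like": SynthSpec(
        zone_sizes={"Z1": 77, "Z2": 42, "Z3": 56, "Z4": 50},
        L=505,
        theta=8.0,
        founder_steps=(25, 23),
        mixing={
            "Z1": (0.20, 0.60, 0.20),
            "Z2": (0.15, 0.65, 0.20),
            "Z3": (0.70, 0.20, 0.10),
            "Z4": (0.75, 0.15, 0.10),
        },
        species="speciesA",
    ),
    "null": SynthSpec(
        zone_sizes={z: 10 for z in DEFAULT_ZONES},
        L=505,
        theta=5.0,
        species="null_case",
    ),
    "extreme_structure": SynthSpec(
        zone_sizes={"Z1": 12, "Z2": 12, "Z3": 12, "Z4": 12},
        L=505,
        theta=0.5,
        founder_steps=(40,),
        mixing={
            "Z1": (1.0, 0.0),
            "Z2": (1.0, 0.0),
            "Z3": (0.0, 1.0),
            "Z4": (0.0, 1.0),
        },
        species="extreme",
    ),
}

#: Low-diversity, near-panmictic companion species for the two-species
#: fixture (pi_site around 0.003 on a 786 bp locus).
LOW_DIVERSITY_SPEC = SynthSpec(
    zone_sizes={"Z1": 46, "Z2": 49, "Z3": 31, "Z4": 10},
    L=786,
    theta=2.6,
    species="speciesB",
)


def make_two_species_fixture(
    seed: RNGLike = None, outdir: str | Path | None = None
) -> dict[str, tuple[Alignment, SampleTable]]:
    """High-diversity vs low-diversity species pair, optionally written out.

    Species A follows the "basin_like" structured preset (three deeply
    divergent haplogroups, zone-differentiated); species B is a
    low-theta panmictic dataset.  When `outdir` is given, writes
    ``speciesA.fasta``/``speciesA.tsv`` and likewise for B; files are
    byte-identical for identical seeds.
    """
    rng = as_rng(seed)
    aln_a, meta_a = make_structured(PRESETS["basin_like"], rng)
    aln_b, meta_b = make_panmictic(LOW_DIVERSITY_SPEC, rng)
    out = {"speciesA": (aln_a, meta_a), "speciesB": (aln_b, meta_b)}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, (aln, meta) in out.items():
            write_fasta(aln, outdir / f"{name}.fasta")
            write_sample_table(meta, outdir / f"{name}.tsv")
    return out
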