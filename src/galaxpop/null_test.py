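"""Coalescent-stochasticity null-model test.

Tests whether the genetic summaries of a high-diversity species could
plausibly arise from a single constant-size population parameterised on
its low-diversity congener: simulate many replicates of the empirical
sampling design (same n, L, N) under the calibrated mutation rate and
ask, for each of S (segregating sites), K (haplotypes) and the mean
number of pairwise nucleotide differences, what fraction of replicates
reaches or exceeds the observed value.  A small one-sided empirical
p-value means the observed contrast exceeds coalescent stochasticity.

Empirical p-values are raw proportions, count / reps, with ties counted
toward the tail; no +1 continuity correction is applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .calibration import CalibrationResult, calibrate
from .coalsim import CoalConfig, RNGLike, as_rng, simulate_summaries
from .diversity import DiversitySummary
from .errors import ConfigurationError, DegenerateInputError

DEFAULT_NULL_CFG = CoalConfig(n=217, L=505, N=10_000.0, mu=0.0)

#: Empirical summaries of the high-diversity species on the null design
#: (217 sequences of 505 bp): S, K and mean pairwise differences.
DEFAULT_EMPIRICAL = {"S": 116.0, "K": 152.0, "pi": 25.1}

_STAT_NAMES = {"S": "segregating sites", "K": "haplotypes",
               "pi": "mean pairwise differences"}


def run_null(
    mu_star: float,
    cfg: CoalConfig = DEFAULT_NULL_CFG,
    reps: int = 10_000,
    seed: RNGLike = None,
) -> pd.DataFrame:
    """Simulate the calibrated null: `reps` replicates of the sampling design."""
    if mu_star < 0:
        raise ValueError("mu_star must be non-negative")
    return simulate_summaries(cfg.with_mu(mu_star), reps, seed=seed)


def empirical_pvalue(null_values, observed: float) -> tuple[int, float]:
    """(count, p) where count = #{x : x >= observed} and p = count / reps."""
    values = np.asarray(null_values, dtype=float)
    if values.size == 0:
        raise DegenerateInputError("empty null distribution")
    count = int(np.sum(values >= observed))
    return count, count / values.size


@dataclass
class StatTest:
    """One statistic's comparison against the simulated null."""

    statistic: str
    observed: float
    null_min: float
    null_max: float
    null_mean: float
    count_ge: int
    p_value: float
    exceeds_stochasticity: bool


@dataclass
class NullTestReport:
    """Full report of the stochasticity test."""

    mu_star: float
    cfg: CoalConfig
    reps: int
    tests: dict[str, StatTest]
    alpha: float = 0.05
    seed: int | None = None
    calibration: CalibrationResult | None = field(default=None, repr=False)
    null_table: pd.DataFrame | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "package_version": __version__,
            "mu_star": self.mu_star,
            "design": {"n": self.cfg.n, "L": self.cfg.L, "N": self.cfg.N,
                       "scaling": self.cfg.scaling},
            "reps": self.reps,
            "alpha": self.alpha,
            "seed": self.seed,
            "tests": {
                k: {
                    "statistic": t.statistic,
                    "observed": t.observed,
                    "null_min": t.null_min,
                    "null_max": t.null_max,
                    "null_mean": t.null_mean,
                    "count_ge": t.count_ge,
                    "p_value": t.p_value,
                    "exceeds_stochasticity": t.exceeds_stochasticity,
                }
                for k, t in self.tests.items()
            },
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    def summary_table(self) -> pd.DataFrame:
        rows = []
        for k, t in self.tests.items():
            rows.append(
                {
                    "statistic": _STAT_NAMES.get(k, k),
                    "null_min": t.null_min,
                    "null_mean": round(t.null_mean, 2),
                    "null_max": t.null_max,
                    "observed": t.observed,
                    "count_ge": t.count_ge,
                    "p_value": t.p_value,
                    "exceeds_stochasticity": t.exceeds_stochasticity,
                }
            )
        return pd.DataFrame(rows)


def compare_species(
    empirical: Mapping[str, float] | DiversitySummary,
    null_table: pd.DataFrame,
    mu_star: float = float("nan"),
    cfg: CoalConfig = DEFAULT_NULL_CFG,
    alpha: float = 0.05,
    seed: int | None = None,
    allow_design_mismatch: bool = False,
) -> NullTestReport:
    """Compare empirical summaries against the simulated null.

    `empirical` either maps statistic keys {"S", "K", "pi"} to observed
    values, or is a :class:`DiversitySummary` computed on the same
    (n, L) design as the null (checked unless `allow_design_mismatch`).
    """
    if isinstance(empirical, DiversitySummary):
        if (empirical.n != cfg.n or empirical.usable_L != cfg.L) and (
            not allow_design_mismatch
        ):
            raise ConfigurationError(
                f"empirical design (n={empirical.n}, L={empirical.usable_L}) "
                f"differs from null design (n={cfg.n}, L={cfg.L})"
            )
        observed = {"S": float(empirical.S), "K": float(empirical.K),
                    "pi": float(empirical.pi_locus)}
    else:
        observed = {k: float(v) for k, v in empirical.items()}
        unknown = set(observed) - {"S", "K", "pi"}
        if unknown:
            raise ConfigurationError(f"unknown statistic keys {sorted(unknown)}")

    tests: dict[str, StatTest] = {}
    for key, obs in observed.items():
        null_vals = null_table[key].to_numpy(dtype=float)
        count, p = empirical_pvalue(null_vals, obs)
        tests[key] = StatTest(
            statistic=key,
            observed=obs,
            null_min=float(null_vals.min()),
            null_max=float(null_vals.max()),
            null_mean=float(null_vals.mean()),
            count_ge=count,
            p_value=p,
            exceeds_stochasticity=bool(p <= alpha),
        )
    return NullTestReport(
        mu_star=mu_star,
        cfg=cfg,
        reps=len(null_table),
        tests=tests,
        alpha=alpha,
        seed=seed,
    )


def run_stochasticity_test(
    empirical: Mapping[str, float] | DiversitySummary = None,
    sweep_reps: int = 1000,
    null_reps: int = 10_000,
    sweep_cfg: CoalConfig | None = None,
    null_cfg: CoalConfig = DEFAULT_NULL_CFG,
    mu_bounds: tuple[float, float] = (1e-8, 1e-6),
    tau: float = 0.05,
    target_s: int = 34,
    alpha: float = 0.05,
    seed: int | None = None,
    fit_kind: str = "quantile",
) -> NullTestReport:
    """End-to-end pipeline: calibrate mu*, simulate the null, compare.

    Bit-for-bit reproducible from one master `seed`: the calibration and
    null stages draw from independent child streams of the master seed.
    """
    from .calibration import DEFAULT_SWEEP_CFG

    if empirical is None:
        empirical = DEFAULT_EMPIRICAL
    if sweep_cfg is None:
        sweep_cfg = DEFAULT_SWEEP_CFG
    ss = np.random.SeedSequence(seed)
    cal_seed, null_seed = ss.spawn(2)
    cal = calibrate(
        reps=sweep_reps,
        cfg=sweep_cfg,
        mu_bounds=mu_bounds,
        tau=tau,
        target_s=target_s,
        seed=np.random.default_rng(cal_seed),
        fit_kind=fit_kind,
    )
    null_table = run_null(
        cal.mu_star, cfg=null_cfg, reps=null_reps,
        seed=np.random.default_rng(null_seed),
    )
    report = compare_species(
        empirical, null_table, mu_star=cal.mu_star, cfg=null_cfg,
        alpha=alpha, seed=seed, allow_design_mismatch=False,
    )
    report.calibration = cal
    report.null_table = null_table
    return report


def plot_null_histograms(
    null_table: pd.DataFrame,
    observed: Mapping[str, float],
    path: str | Path,
) -> None:
    """One histogram panel per statistic with the empirical value marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    keys = [k for k in ("S", "K", "pi") if k in observed]
    fig, axes = plt.subplots(1, len(keys), figsize=(4 * len(keys), 3.2))
    if len(keys) == 1:
        axes = [axes]
    for ax, key in zip(axes, keys):
        ax.hist(null_table[key], bins=40, color="C0", alpha=0.8)
        ax.axvline(observed[key], color="C3", ls="--", label="empirical")
        ax.set_xlabel(_STAT_NAMES[key])
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
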