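"""Abundance fidelity of pooled amplicon sequencing.

Given a pool design (per-specimen input volumes) and the per-species read
counts a sequencing run produced, this module computes volume-normalized
read proportions, averages them across replicate pools into a Best
Estimate of each stock's per-microlitre amplicon yield, fits the
design-vs-output regression whose slope is expected to be 1 (and intercept
0) when all inputs are equally amplifiable, and quantifies species
dropout, including the closed-form probability ``(1-p)^N`` that a species
at proportion ``p`` receives zero of ``N`` multinomially sampled reads.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PoolDesign",
    "NormalizedProfile",
    "RegressionResult",
    "normalize_by_volume",
    "read_proportions",
    "best_estimate",
    "fit_regression",
    "fit_regressions",
    "detect_dropouts",
    "dropout_probability",
    "species_recovery_simulation",
    "load_design_table",
    "load_read_table",
]


@dataclasses.dataclass(frozen=True)
class PoolDesign:
    """Per-species input volumes (µL) for one mock pool."""

    pool_id: str
    volumes: Mapping[str, float]

    def __post_init__(self) -> None:
        vols = dict(self.volumes)
        for sp, v in vols.items():
            if v <= 0:
                raise ValueError(f"volume for {sp!r} must be > 0 (got {v})")
        object.__setattr__(self, "volumes", vols)

    @property
    def species(self) -> list[str]:
        return list(self.volumes)

    def proportions(self) -> dict[str, float]:
        """Design proportions volume_i / total volume (sum to 1)."""
        total = sum(self.volumes.values())
        return {sp: v / total for sp, v in self.volumes.items()}


@dataclasses.dataclass(frozen=True)
class NormalizedProfile:
    """Volume-normalized read proportions for one pool (sum to 1)."""

    pool_id: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", dict(self.values))


@dataclasses.dataclass(frozen=True)
class RegressionResult:
    """OLS fit of output proportions against expected proportions."""

    slope: float
    intercept: float
    r_squared: float
    pearson_r: float
    p_value: float
    n: int
    m_tests: int = 1
    alpha: float = 0.05

    @property
    def alpha_adjusted(self) -> float:
        return self.alpha / self.m_tests

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha_adjusted


def normalize_by_volume(
    reads: Mapping[str, int], design: PoolDesign
) -> NormalizedProfile:
    """Per-µL read yields rescaled to proportions.

    value_i = (reads_i / volume_i) / sum_j (reads_j / volume_j), over the
    species in the design.  Species in the design with zero reads get 0
    (dropout); a species with reads but no design volume is an error, as is
    an all-zero read table.
    """
    for sp, count in reads.items():
        if count < 0:
            raise ValueError(f"negative read count for {sp!r}")
        if count > 0 and sp not in design.volumes:
            raise ValueError(
                f"species {sp!r} has reads but no volume in design {design.pool_id!r}"
            )
    rates = {
        sp: reads.get(sp, 0) / vol for sp, vol in design.volumes.items()
    }
    total = sum(rates.values())
    if total == 0:
        raise ValueError(f"pool {design.pool_id!r} has zero total reads")
    return NormalizedProfile(
        pool_id=design.pool_id, values={sp: r / total for sp, r in rates.items()}
    )


def read_proportions(reads: Mapping[str, int]) -> dict[str, float]:
    """Raw read shares ``reads_i / total``.

    This is the output side of the slope-1 check: when every input is
    equally amplifiable, a species' expected read share equals its design
    (volume) share, so OLS of read share on design share has slope 1 and
    intercept 0.  (The volume-normalized profile is flat in that case —
    normalization exists to make pools comparable to the Best Estimate,
    not to carry the design signal.)
    """
    total = sum(reads.values())
    if total <= 0:
        raise ValueError("read table sums to zero")
    return {sp: c / total for sp, c in reads.items()}


def best_estimate(profiles: Sequence[NormalizedProfile]) -> dict[str, float]:
    """Unweighted mean of normalized proportions across replicate pools.

    A species absent from a profile (dropout) contributes 0 for that pool,
    so the estimate is the mean over *all* pools, not over detections.
    """
    if len(profiles) < 2:
        raise ValueError("best_estimate needs at least two profiles")
    species: list[str] = []
    for p in profiles:
        for sp in p.values:
            if sp not in species:
                species.append(sp)
    n = len(profiles)
    return {
        sp: sum(p.values.get(sp, 0.0) for p in profiles) / n for sp in species
    }


def fit_regression(
    x: Mapping[str, float],
    y: Mapping[str, float] | NormalizedProfile,
    exclude: Iterable[str] = (),
    m_tests: int = 1,
    alpha: float = 0.05,
) -> RegressionResult:
    """OLS ``y = a + b*x`` over species shared by both profiles.

    ``x`` is typically a Best Estimate (or design proportions) and ``y`` a
    pool's normalized profile; ``exclude`` removes species (e.g. specimens
    captured sympatrically with bycatch, whose carryover contaminates the
    pool).  Pearson r and its two-sided p-value are reported alongside a
    Bonferroni-adjusted significance threshold ``alpha / m_tests``.
    """
    if isinstance(y, NormalizedProfile):
        y = y.values
    excluded = set(exclude)
    shared = [sp for sp in x if sp in y and sp not in excluded]
    if len(shared) < 3:
        raise ValueError(
            f"need >=3 shared species after exclusions (got {len(shared)})"
        )
    xv = np.array([x[sp] for sp in shared], dtype=float)
    yv = np.array([y[sp] for sp in shared], dtype=float)
    if np.allclose(xv, xv[0]):
        raise ValueError("zero variance in x; regression undefined")
    fit = stats.linregress(xv, yv)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        pearson_r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        n=len(shared),
        m_tests=m_tests,
        alpha=alpha,
    )


def fit_regressions(
    pairs: Mapping[str, tuple[Mapping[str, float], Mapping[str, float] | NormalizedProfile]],
    exclude: Iterable[str] = (),
    alpha: float = 0.05,
) -> dict[str, RegressionResult]:
    """Fit several regressions with Bonferroni m = number of fits."""
    m = len(pairs)
    return {
        name: fit_regression(x, y, exclude=exclude, m_tests=m, alpha=alpha)
        for name, (x, y) in pairs.items()
    }


def detect_dropouts(
    reads: Mapping[str, int], design: PoolDesign
) -> list[tuple[str, float]]:
    """Designed-in species with zero reads, with their design proportions."""
    props = design.proportions()
    return [
        (sp, props[sp]) for sp in design.species if reads.get(sp, 0) == 0
    ]


def dropout_probability(depth: int, proportion: float) -> float:
    """Exact probability that a species at proportion ``p`` gets zero of ``N`` reads.

    The marginal of one multinomial category is binomial, so
    P(zero reads) = (1 - p)^N.
    """
    if not 0 < proportion <= 1:
        raise ValueError("proportion must be in (0, 1]")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    return float((1.0 - proportion) ** depth)


def species_recovery_simulation(
    proportions: Sequence[float],
    depth: int,
    n_replicates: int,
    seed: int,
) -> np.ndarray:
    """Distinct species observed per replicate under multinomial sampling.

    Draws ``n_replicates`` multinomial samples of size ``depth`` from
    ``proportions`` and returns the per-replicate count of categories with
    at least one read.  Used to ask how deep a run must be to recover every
    species in a pool.
    """
    p = np.asarray(proportions, dtype=float)
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
        raise ValueError("proportions must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(depth, p, size=n_replicates)
    return (counts > 0).sum(axis=1)


def load_design_table(path: str | Path) -> dict[str, PoolDesign]:
    """Read a long-format design TSV (columns pool, species, volume_ul)."""
    df = pd.read_csv(path, sep="\t")
    designs = {}
    for pool_id, sub in df.groupby("pool", sort=False):
        designs[str(pool_id)] = PoolDesign(
            pool_id=str(pool_id),
            volumes=dict(zip(sub["species"], sub["volume_ul"].astype(float))),
        )
    return designs


def load_read_table(path: str | Path) -> dict[str, dict[str, int]]:
    """Read a long-format read-count TSV (columns pool, species, reads)."""
    df = pd.read_csv(path, sep="\t")
    tables: dict[str, dict[str, int]] = {}
    for pool_id, sub in df.groupby("pool", sort=False):
        tables[str(pool_id)] = dict(zip(sub["species"], sub["reads"].astype(int)))
    return tables
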