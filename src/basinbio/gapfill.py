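"""Completeness-based gap-filling of unevenly sampled basins.

Sampling effort differs wildly between drainage basins (up to ten-fold in
record counts among basins of comparable area), so raw presence/absence
matrices confound richness with effort. The procedure here estimates, for
each focal level-5 basin, the sample coverage — the probability that the
next record belongs to an already-recorded species — from the
singleton/doubleton structure of its unique records. A basin is acceptably
sampled when the lower 95% bootstrap bound of coverage is at least 0.75
and it holds more than 50 unique records. An under-sampled basin is
augmented by repeatedly drawing one record, uniformly with replacement,
from the pooled records of its level-4 sibling basins, re-estimating
coverage after each insertion, until the criterion is met. Because donors
are restricted to the same level-4 catchment the species pool never grows
beyond the catchment's observed fauna. Repeating the whole pass many times
(default 100) yields a set of presence/absence matrices whose spread
carries the uncertainty of the fill; basins that fail the criterion and
have no level-4 sibling are excluded outright.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import seed_stream
from .basins import BasinHierarchy

__all__ = [
    "CompletenessEstimate",
    "GapfillConfig",
    "PresenceMatrixSet",
    "coverage_point",
    "coverage",
    "is_acceptable",
    "gapfill_basin",
    "gapfill_all",
    "MustExclude",
]


class MustExclude(Exception):
    """Raised when an unacceptable basin has no neighbor pool to draw from."""


@dataclass
class CompletenessEstimate:
    """Sample coverage of one basin with its bootstrap lower bound."""

    point: float
    lower_ci: float
    n: int
    f1: int
    f2: int
    unsampled: bool = False


@dataclass
class GapfillConfig:
    threshold: float = 0.75       # lower bound the coverage must reach
    min_unique_records: int = 50  # n must be strictly greater than this
    n_matrices: int = 100
    bootstrap_B: int = 200
    max_insertions: int = 10_000  # per basin per replicate; guards termination
    criterion: str = "lower_ci"   # or "point": which estimate the test uses
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        if self.n_matrices < 1:
            raise ValueError("n_matrices must be >= 1")
        if self.criterion not in ("lower_ci", "point"):
            raise ValueError("criterion must be 'lower_ci' or 'point'")


@dataclass
class PresenceMatrixSet:
    """Replicate gap-filled binary species x basin matrices."""

    matrices: list[pd.DataFrame]
    excluded_basins: list[str]
    convergence: pd.DataFrame  # basins x replicates, True = criterion met
    insertions: pd.DataFrame   # basins x replicates, records inserted

    @property
    def n_matrices(self) -> int:
        return len(self.matrices)

    def mean_richness(self) -> pd.Series:
        return sum(m.sum(axis=0) for m in self.matrices) / len(self.matrices)

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for i, m in enumerate(self.matrices):
            m.to_csv(out / f"presence_{i:03d}.csv")
        pd.Series(self.excluded_basins, name="basin_id").to_csv(
            out / "excluded_basins.csv", index=False
        )
        self.convergence.to_csv(out / "convergence.csv")
        self.insertions.to_csv(out / "insertions.csv")


# ------------------------------------------------------------------- coverage


def coverage_point(n: int, f1: int, f2: int) -> float:
    """Closed-form sample-coverage estimate from singletons and doubletons.

    Chao-style estimator: C = 1 - (f1/n) * [(n-1) f1 / ((n-1) f1 + 2 f2)].
    With no doubletons the (f1 - 1) variant is used; the degenerate n = 1
    case returns 0, the limit of the unmodified form (a lone record says
    nothing about the fauna, so the next record is taken as surely new).
    """
    if n <= 0:
        raise ValueError("coverage undefined for n = 0")
    if f1 == 0:
        return 1.0
    if n == 1:
        return 0.0
    if f2 > 0:
        a = (n - 1) * f1 / ((n - 1) * f1 + 2.0 * f2)
    else:
        a = (n - 1) * (f1 - 1) / ((n - 1) * (f1 - 1) + 2.0)
    return 1.0 - (f1 / n) * a


def _counts_stats(counts: np.ndarray) -> tuple[int, int, int]:
    n = int(counts.sum())
    f1 = int(np.count_nonzero(counts == 1))
    f2 = int(np.count_nonzero(counts == 2))
    return n, f1, f2


def coverage(
    counts,
    bootstrap_B: int = 200,
    rng: np.random.Generator | None = None,
    alpha: float = 0.05,
) -> CompletenessEstimate:
    """Coverage of a basin from per-species record counts, with bootstrap CI.

    The lower bound is the alpha/2 percentile of coverage over
    ``bootstrap_B`` multinomial resamples of the records (nonparametric
    bootstrap over records), clipped to the point estimate so that
    lower_ci <= point always holds. ``counts`` with total 0 yields an
    estimate flagged ``unsampled``.
    """
    counts = np.asarray(counts, dtype=int)
    counts = counts[counts > 0]
    n, f1, f2 = _counts_stats(counts)
    if n == 0:
        return CompletenessEstimate(np.nan, np.nan, 0, 0, 0, unsampled=True)
    point = coverage_point(n, f1, f2)
    if bootstrap_B <= 0:
        return CompletenessEstimate(point, point, n, f1, f2)
    rng = rng if rng is not None else np.random.default_rng(0)
    p = counts / n
    boot = rng.multinomial(n, p, size=bootstrap_B)
    bf1 = (boot == 1).sum(axis=1)
    bf2 = (boot == 2).sum(axis=1)
    vals = np.array([coverage_point(n, int(a), int(b)) for a, b in zip(bf1, bf2)])
    lower = float(np.percentile(vals, 100.0 * alpha / 2.0))
    lower = min(lower, point)
    return CompletenessEstimate(point, max(lower, 0.0), n, f1, f2)


def is_acceptable(est: CompletenessEstimate, config: GapfillConfig) -> bool:
    """Joint rule: lower 95% bound >= threshold AND n strictly > 50 records."""
    if est.unsampled:
        return False
    value = est.lower_ci if config.criterion == "lower_ci" else est.point
    return bool(value >= config.threshold and est.n > config.min_unique_records)


# ------------------------------------------------------------------- filling


def gapfill_basin(
    focal_counts: pd.Series,
    neighbor_pool: np.ndarray,
    config: GapfillConfig,
    rng: np.random.Generator,
) -> tuple[pd.Series, int, bool]:
    """Augment one focal basin until the sampling-effort criterion holds.

    ``focal_counts``: unique-record count per species already in the basin.
    ``neighbor_pool``: one entry per unique record in the level-4 sibling
    basins (species name); sampling is uniform over records, with
    replacement. Returns (augmented counts, number of insertions, converged).
    Raises :class:`MustExclude` when the basin is unacceptable and the pool
    is empty.
    """
    counts: dict[str, int] = {
        str(sp): int(c) for sp, c in focal_counts.items() if c > 0
    }

    def estimate() -> CompletenessEstimate:
        arr = np.fromiter(counts.values(), dtype=int) if counts else np.zeros(0, dtype=int)
        n = int(arr.sum())
        if n == 0:
            return CompletenessEstimate(np.nan, np.nan, 0, 0, 0, unsampled=True)
        # cheap short-circuit: lower_ci <= point, so when the point estimate
        # (or the record count) already fails, skip the bootstrap entirely
        n_, f1, f2 = _counts_stats(arr)
        point = coverage_point(n_, f1, f2)
        if n_ <= config.min_unique_records or point < config.threshold:
            return CompletenessEstimate(point, 0.0, n_, f1, f2)
        if config.criterion == "point":
            return CompletenessEstimate(point, point, n_, f1, f2)
        return coverage(arr, config.bootstrap_B, rng)

    est = estimate()
    if is_acceptable(est, config):
        return pd.Series(counts, dtype=int), 0, True
    if len(neighbor_pool) == 0:
        raise MustExclude("unacceptable basin with empty neighbor pool")

    inserted = 0
    while inserted < config.max_insertions:
        sp = str(neighbor_pool[int(rng.integers(len(neighbor_pool)))])
        counts[sp] = counts.get(sp, 0) + 1
        inserted += 1
        est = estimate()
        if is_acceptable(est, config):
            return pd.Series(counts, dtype=int), inserted, True
    return pd.Series(counts, dtype=int), inserted, False


def _basin_counts(table: pd.DataFrame, basins: list[str]) -> dict[str, pd.Series]:
    grouped = table.groupby("basin_id")["species"].value_counts()
    out = {}
    for b in basins:
        out[b] = grouped[b] if b in grouped.index.get_level_values(0) else pd.Series(dtype=int)
    return out


def gapfill_all(
    table: pd.DataFrame,
    hierarchy: BasinHierarchy,
    config: GapfillConfig,
) -> PresenceMatrixSet:
    """Run the gap-filling pass ``n_matrices`` times over all basins.

    Input is the cleaned, deduplicated, basin-assigned occurrence table.
    Each replicate draws from an independent stream of the master seed.
    Basins failing the criterion with no level-4 sibling are excluded and
    listed; every returned matrix contains the observed presences as a
    subset (augmentation never removes a record).
    """
    basins = hierarchy.basin_ids
    counts0 = _basin_counts(table, basins)
    species = sorted(table["species"].unique())

    # exclusion rule is deterministic: no sibling pool and not acceptable
    pools: dict[str, np.ndarray] = {}
    for b in basins:
        sibs = hierarchy.neighbors(b)
        pool: list[str] = []
        for s in sibs:
            pool.extend([str(x) for x, c in counts0[s].items() for _ in range(int(c))])
        pools[b] = np.array(pool, dtype=object)

    screen_rng = seed_stream(config.seed, "gapfill-screen")
    excluded: list[str] = []
    active: list[str] = []
    for b in basins:
        est = coverage(counts0[b].to_numpy(), config.bootstrap_B, screen_rng) \
            if len(counts0[b]) else CompletenessEstimate(np.nan, np.nan, 0, 0, 0, True)
        if not is_acceptable(est, config) and len(pools[b]) == 0:
            excluded.append(b)
        else:
            active.append(b)

    matrices: list[pd.DataFrame] = []
    conv = pd.DataFrame(False, index=active, columns=range(config.n_matrices))
    nins = pd.DataFrame(0, index=active, columns=range(config.n_matrices))
    for rep in range(config.n_matrices):
        rng = seed_stream(config.seed, f"gapfill-rep{rep}")
        mat = pd.DataFrame(0, index=species, columns=active, dtype=np.int8)
        for b in active:
            filled, k, ok = gapfill_basin(counts0[b], pools[b], config, rng)
            conv.loc[b, rep] = ok
            nins.loc[b, rep] = k
            present = [sp for sp in filled.index if filled[sp] > 0]
            if present:
                mat.loc[present, b] = 1
        matrices.append(mat)
    return PresenceMatrixSet(matrices, excluded, conv, nins)
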