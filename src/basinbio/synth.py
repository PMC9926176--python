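"""Synthetic data with the statistical structure the pipeline assumes.

Generates (i) a nested basin hierarchy (level-5 units inside level-4
catchments inside bioregions) with lognormal surface areas and abstract
box footprints, (ii) a dated birth–death phylogeny, (iii) species ranges
evolved forward under the stratified gain/loss range model, and (iv)
effort-biased occurrence records with optional injected errors (synonyms,
exotics, bad coordinates, duplicates) plus a manifest locating every
injection, so cleaning and gap-filling can be tested against known truth.

Basin footprints are abstract axis-aligned lon/lat boxes; coordinates exist
only to exercise cleaning and assignment logic, never real geography.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from ._rng import seed_stream
from .basins import BasinHierarchy
from .ranges import BayAreaParams, RangeModel, Stratum, validate_strata
from .trees import IndexedTree, parse_newick

__all__ = [
    "SyntheticConfig",
    "default_strata",
    "simulate_basins",
    "simulate_tree",
    "simulate_ranges",
    "presence_from_ranges",
    "simulate_occurrences",
    "RangeHistory",
]


def default_strata(n_areas: int = 6) -> list[Stratum]:
    """Five geological time slices (255-33-23-10-5-0 Ma) with flat multipliers.

    The boundary ages follow the principal South American hydrogeographic
    events; the all-ones multiplier matrices are an illustrative default —
    real analyses supply their own connectivity values per stratum.
    """
    bounds = [(255.0, 33.0), (33.0, 23.0), (23.0, 10.0), (10.0, 5.0), (5.0, 0.0)]
    ones = np.ones((n_areas, n_areas))
    return [Stratum(a, b, ones.copy()) for a, b in bounds]


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic scenario; defaults emulate the study conditions.

    Six bioregions, a ten-fold maximum fold-difference in sampling effort
    between basins, and gain/loss rates of the same order as fitted values
    on continental fish data.
    """

    n_bioregions: int = 6
    n_level4_per_bioregion: int = 2
    n_level5_per_level4: int = 5
    area_lognormal_params: tuple[float, float] = (9.2, 0.6)  # log km²; median ≈ 10^4 km²
    birth_rate: float = 0.1   # 1/My
    death_rate: float = 0.05  # 1/My
    n_tips: int = 100
    true_d: float = 0.02      # expansions/My
    true_e: float = 0.01      # contractions/My
    strata: list[Stratum] | None = None
    effort_heterogeneity: float = 10.0  # max fold-difference in records between basins
    abundance_sigma: float = 1.0        # lognormal species-abundance spread per basin
    mean_records_per_basin: float = 120.0  # at unit effort
    basin_occupancy: float = 0.6  # P(level-5 basin occupied | bioregion in range)
    area_occupancy_exponent: float = 0.15  # induces a realistic species-area slope
    missing_date_rate: float = 0.1
    synonym_rate: float = 0.0
    exotic_rate: float = 0.0
    coord_error_rate: float = 0.0
    duplicate_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_bioregions, self.n_level4_per_bioregion, self.n_level5_per_level4) < 1:
            raise ValueError("basin counts must be >= 1")
        if self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        if not (self.birth_rate > self.death_rate >= 0):
            raise ValueError("require birth_rate > death_rate >= 0")
        if self.effort_heterogeneity < 1:
            raise ValueError("effort_heterogeneity must be >= 1")
        if self.strata is None:
            self.strata = default_strata(self.n_bioregions)
        validate_strata(self.strata, self.n_bioregions)

    def rng(self, label: str) -> np.random.Generator:
        return seed_stream(self.seed, label)


# -------------------------------------------------------------------- basins


def simulate_basins(config: SyntheticConfig) -> BasinHierarchy:
    """Nested hierarchy with lognormal areas and disjoint unit-box footprints."""
    rng = config.rng("basins")
    mu, sigma = config.area_lognormal_params
    rows = []
    footprints: dict[str, tuple[float, float, float, float]] = {}
    n_total = config.n_bioregions * config.n_level4_per_bioregion * config.n_level5_per_level4
    ncol = max(1, math.ceil(math.sqrt(n_total)))
    g = 0
    for r in range(config.n_bioregions):
        bid = f"R{r + 1}"
        for c in range(config.n_level4_per_bioregion):
            l4 = f"{bid}c{c + 1}"
            for s in range(config.n_level5_per_level4):
                l5 = f"{l4}s{s + 1}"
                area = float(np.exp(rng.normal(mu, sigma)))
                rows.append((l5, l4, bid, area))
                col, row = g % ncol, g // ncol
                lon0, lat0 = -80.0 + col, -40.0 + row
                footprints[l5] = (lon0, lat0, lon0 + 1.0, lat0 + 1.0)
                g += 1
    table = pd.DataFrame(rows, columns=["basin_id", "level4_id", "bioregion_id", "area_km2"])
    return BasinHierarchy(table, footprints)


# ---------------------------------------------------------------------- tree


class _Lineage:
    __slots__ = ("birth", "splits", "death", "extant")

    def __init__(self, birth: float):
        self.birth = birth
        self.splits: list[tuple[float, "_Lineage"]] = []
        self.death: float | None = None
        self.extant = False


def simulate_tree(config: SyntheticConfig, max_retries: int = 1000) -> dendropy.Tree:
    """Forward birth–death simulation conditioned on n_tips extant lineages.

    Simple-sampling scheme: grow from a crown pair until the extant count
    first reaches n_tips, place the present uniformly inside the waiting
    time to the next event (so pendant edges are positive), and retry on
    total extinction. Branch lengths are in My.
    """
    rng = config.rng("tree")
    b, d = config.birth_rate, config.death_rate
    n = config.n_tips
    for _ in range(max_retries):
        left, right = _Lineage(0.0), _Lineage(0.0)
        alive: list[_Lineage] = [left, right]
        t = 0.0
        failed = False
        while len(alive) != n:
            rate = (b + d) * len(alive)
            t += rng.exponential(1.0 / rate)
            i = rng.integers(len(alive))
            if rng.random() < b / (b + d):
                child = _Lineage(t)
                alive[i].splits.append((t, child))
                alive.append(child)
            else:
                alive[i].death = t
                alive.pop(i)
                if not alive:
                    failed = True
                    break
        if failed:
            continue
        present = t + rng.random() * rng.exponential(1.0 / ((b + d) * n))
        for lin in alive:
            lin.extant = True
        counter = [0]

        def render(lin: _Lineage):
            survivors = []
            for ts, child in lin.splits:
                sub = render(child)
                if sub is not None:
                    survivors.append((ts, sub))

            def backbone(i: int):
                if i == len(survivors):
                    if not lin.extant:
                        return None
                    counter[0] += 1
                    return (f"sp{counter[0]:04d}", present)
                ts, sub = survivors[i]
                rest = backbone(i + 1)
                if rest is None:
                    return sub
                (cs, ct), (rs, rt) = sub, rest
                return (f"({cs}:{ct - ts:.10g},{rs}:{rt - ts:.10g})", ts)

            return backbone(0)

        lsub, rsub = render(left), render(right)
        if lsub is None or rsub is None:
            # one crown lineage died out entirely; the reconstructed root is younger
            (s, st) = lsub or rsub
            newick = f"{s};"
        else:
            (ls, lt), (rs, rt) = lsub, rsub
            newick = f"({ls}:{lt:.10g},{rs}:{rt:.10g});"
        return parse_newick(newick)
    raise RuntimeError(f"no surviving tree with {n} tips after {max_retries} attempts")


# --------------------------------------------------------------------- ranges


@dataclass
class RangeHistory:
    """Forward-simulated range evolution: tip states plus the full event log.

    ``events`` has one row per gain/loss with the branch (child-node label),
    event age in Ma, kind ('gain'/'loss'), the area gained or lost, and for
    gains the source area the expansion was attributed to.
    """

    tip_ranges: dict[str, frozenset[int]]
    events: pd.DataFrame
    node_states: dict[str, frozenset[int]] = field(default_factory=dict)
    root_state: frozenset[int] = frozenset()


def _gain_rates(mask: int, m: np.ndarray, d: float, n_areas: int) -> np.ndarray:
    rates = np.zeros(n_areas)
    occ = [j for j in range(n_areas) if mask >> j & 1]
    for k in range(n_areas):
        if not mask >> k & 1:
            rates[k] = d * sum(m[j, k] for j in occ)
    return rates


def simulate_ranges(
    tree,
    model: RangeModel,
    seed: int | np.random.Generator = 0,
    root_range: frozenset[int] | None = None,
) -> RangeHistory:
    """Evolve ranges forward along the tree under the stratified gain/loss CTMC.

    The root range is drawn uniformly among non-empty area sets unless
    supplied. Loss is forbidden at range size 1, so no lineage ever loses
    its last area. Both daughters inherit the parental range at each node.
    """
    itree = tree if isinstance(tree, IndexedTree) else IndexedTree.from_dendropy(tree)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    A = model.n_areas
    d, e = model.params.d, model.params.e
    strata = validate_strata(model.strata, A)
    if root_range is None:
        mask = int(rng.integers(1, 2 ** A))
    else:
        mask = 0
        for a in root_range:
            mask |= 1 << int(a)
        if mask < 1:
            raise ValueError("root range must be non-empty")

    state = np.zeros(itree.n_nodes, dtype=int)
    state[0] = mask
    records = []
    for v in range(1, itree.n_nodes):  # preorder: parents before children
        cur = int(state[itree.parent[v]])
        age = float(itree.age[itree.parent[v]])
        child_age = float(itree.age[v])
        si = 0
        while si < len(strata) - 1 and age <= strata[si].end + 1e-12:
            si += 1
        while age > child_age + 1e-12:
            s = strata[si]
            seg_end = max(child_age, s.end)
            m = s.multipliers
            gains = _gain_rates(cur, m, d, A)
            size = bin(cur).count("1")
            loss_each = e if size > 1 else 0.0
            total = gains.sum() + loss_each * size
            if total <= 0:
                age = seg_end
            else:
                wait = rng.exponential(1.0 / total)
                if age - wait <= seg_end + 1e-12:
                    age = seg_end
                else:
                    age -= wait
                    u = rng.random() * total
                    if u < gains.sum():
                        k = int(np.searchsorted(np.cumsum(gains), u, side="right"))
                        occ = [j for j in range(A) if cur >> j & 1]
                        w = np.array([m[j, k] for j in occ], dtype=float)
                        src = int(rng.choice(occ, p=w / w.sum()))
                        cur |= 1 << k
                        records.append((itree.labels[v], age, "gain", k, src))
                    else:
                        occ = [j for j in range(A) if cur >> j & 1]
                        k = int(occ[int((u - gains.sum()) // loss_each)])
                        cur &= ~(1 << k)
                        records.append((itree.labels[v], age, "loss", k, -1))
            if age <= seg_end + 1e-12 and si < len(strata) - 1 and abs(age - s.end) < 1e-9:
                si += 1
        state[v] = cur

    def to_set(mask_: int) -> frozenset[int]:
        return frozenset(j for j in range(A) if mask_ >> j & 1)

    tips = {itree.labels[i]: to_set(int(state[i])) for i in itree.tip_indices()}
    nodes = {
        itree.labels[i]: to_set(int(state[i]))
        for i in range(itree.n_nodes)
        if not itree.is_tip[i]
    }
    events = pd.DataFrame(records, columns=["branch", "time_ma", "kind", "area", "source"])
    return RangeHistory(tips, events, nodes, to_set(mask))


def presence_from_ranges(
    tip_ranges: dict[str, frozenset[int]],
    hierarchy: BasinHierarchy,
    rng: np.random.Generator,
    occupancy: float = 0.6,
    area_exponent: float = 0.15,
) -> pd.DataFrame:
    """Downscale bioregion-level ranges to a true level-5 presence matrix.

    Within each bioregion a species occupies, every level-5 basin is occupied
    independently with probability ``occupancy`` scaled by
    (area / median area)^area_exponent (clipped to [0.02, 0.98]), so larger
    basins hold more species and the fauna shows a mild species-area slope;
    at least one basin per occupied bioregion is guaranteed.
    """
    bioregions = hierarchy.bioregion_ids
    basins = hierarchy.basin_ids
    areas = hierarchy.areas()
    med = float(areas.median())
    p_occ = np.clip(
        occupancy * (areas / med) ** area_exponent, 0.02, 0.98
    )
    presence = pd.DataFrame(0, index=sorted(tip_ranges), columns=basins, dtype=int)
    for sp in presence.index:
        for a in sorted(tip_ranges[sp]):
            members = hierarchy.basins_of_bioregion(bioregions[a])
            occupied = [b for b in members if rng.random() < p_occ[b]]
            if not occupied:
                occupied = [members[int(rng.integers(len(members)))]]
            presence.loc[sp, occupied] = 1
    return presence


# ---------------------------------------------------------------- occurrences


def effort_multipliers(hierarchy: BasinHierarchy, heterogeneity: float) -> pd.Series:
    """Deterministic log-spaced per-basin effort spanning [1, heterogeneity]."""
    basins = hierarchy.basin_ids
    B = len(basins)
    if B == 1 or heterogeneity == 1.0:
        vals = np.ones(B)
    else:
        vals = heterogeneity ** (np.arange(B) / (B - 1))
    return pd.Series(vals, index=basins)


def simulate_occurrences(
    hierarchy: BasinHierarchy,
    true_presence: pd.DataFrame,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
):
    """Effort-biased occurrence records for truly present species.

    Per-basin record counts are Poisson with mean proportional to a
    log-spaced effort multiplier spanning the configured fold-difference;
    record species are drawn from per-(species, basin) lognormal abundances,
    giving the heavy singleton/doubleton tails that coverage estimation
    feeds on. Optional injections corrupt the table at configured rates and
    are listed row-by-row in the returned manifest.

    Returns (occurrences, manifest, cleaning_tables) where cleaning_tables
    is the (synonym map, exotic list) pair that exactly undoes the
    injections.
    """
    from .occurrences import CleaningTables

    if true_presence.empty:
        raise ValueError("true_presence must be non-empty")
    rng = rng if rng is not None else config.rng("occurrences")
    efforts = effort_multipliers(hierarchy, config.effort_heterogeneity)
    rows = []
    for basin in hierarchy.basin_ids:
        present = [sp for sp in true_presence.index if true_presence.loc[sp, basin]]
        if not present:
            continue
        lam = config.mean_records_per_basin * efforts[basin]
        n_rec = int(rng.poisson(lam))
        if n_rec == 0:
            continue
        weights = np.exp(rng.normal(0.0, config.abundance_sigma, size=len(present)))
        weights /= weights.sum()
        species = rng.choice(present, size=n_rec, p=weights)
        lon0, lat0, lon1, lat1 = hierarchy.footprints[basin]
        lons = rng.uniform(lon0, lon1, size=n_rec)
        lats = rng.uniform(lat0, lat1, size=n_rec)
        years = rng.integers(1950, 2021, size=n_rec)
        months = rng.integers(1, 13, size=n_rec)
        days = rng.integers(1, 29, size=n_rec)
        for i in range(n_rec):
            date = f"{years[i]}-{months[i]:02d}-{days[i]:02d}"
            if rng.random() < config.missing_date_rate:
                date = ""
            rows.append((str(species[i]), lons[i], lats[i], date, basin, "synthetic"))
    df = pd.DataFrame(rows, columns=["species", "lon", "lat", "date", "basin_id", "source"])

    manifest_rows = []
    all_species = sorted(true_presence.index)
    synonym_map = {f"{sp}_syn": sp for sp in all_species}
    exotic_names = [f"Exoticus_sp{i + 1}" for i in range(5)]

    if config.synonym_rate > 0 and len(df):
        hit = np.flatnonzero(rng.random(len(df)) < config.synonym_rate)
        for i in hit:
            df.iat[i, 0] = f"{df.iat[i, 0]}_syn"
            manifest_rows.append((int(i), "synonym"))
    if config.coord_error_rate > 0 and len(df):
        hit = np.flatnonzero(rng.random(len(df)) < config.coord_error_rate)
        for i in hit:
            df.iat[i, 2] = 95.0 + float(rng.random())  # latitude out of range
            manifest_rows.append((int(i), "coord_error"))
    if config.exotic_rate > 0 and len(df):
        n_exo = int(round(config.exotic_rate * len(df)))
        basins = hierarchy.basin_ids
        for _ in range(n_exo):
            basin = basins[int(rng.integers(len(basins)))]
            lon0, lat0, lon1, lat1 = hierarchy.footprints[basin]
            row = (
                exotic_names[int(rng.integers(len(exotic_names)))],
                float(rng.uniform(lon0, lon1)),
                float(rng.uniform(lat0, lat1)),
                f"{int(rng.integers(1950, 2021))}-01-15",
                basin,
                "synthetic",
            )
            manifest_rows.append((len(df), "exotic"))
            df.loc[len(df)] = row
    if config.duplicate_rate > 0 and len(df):
        hit = np.flatnonzero(rng.random(len(df)) < config.duplicate_rate)
        for i in hit:
            manifest_rows.append((len(df), "duplicate"))
            df.loc[len(df)] = df.iloc[int(i)]

    manifest = pd.DataFrame(manifest_rows, columns=["row_index", "kind"])
    tables = CleaningTables(synonym_map=synonym_map, exotic_list=set(exotic_names))
    return df, manifest, tables
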