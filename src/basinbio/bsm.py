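"""Biogeographical stochastic mapping and dispersal-event accounting.

Given the fitted range model, full event histories consistent with the tip
data are sampled by backward filtering / forward sampling: joint node
states are drawn from their conditional distribution, then each branch's
path is sampled conditional on its endpoint states by uniformization under
the stratified generator. Every gain event (anagenetic range expansion) is
a dispersal event; its source area within the pre-event range is attributed
probabilistically, proportional to the dispersal multipliers into the
gained area (or uniformly over the range, by configuration).

Event counts are binned in 1-My slices and normalized by the log-number of
lineages alive in each bin, which removes the mechanical increase of
absolute event counts toward the present as the tree accumulates branches
while damping the opposite bias from the very few branches near the root.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from ._rng import seed_stream
from .ranges import BayAreaParams, LikelihoodEngine, Stratum
from .trees import IndexedTree, lineages_at

__all__ = [
    "MapHistory",
    "DispersalSummary",
    "attribute_source",
    "stochastic_map",
    "bin_events",
    "relative_dispersal",
    "summarize_flows",
    "events_to_frame",
]

_MAX_JUMPS = 2000
_RESAMPLE_CAP = 50

EVENT_COLUMNS = ["map_id", "branch", "time_ma", "kind", "area", "source"]


@dataclass
class MapHistory:
    """One sampled history: per-branch events plus the sampled node states."""

    map_id: int
    events: pd.DataFrame          # EVENT_COLUMNS
    node_states: dict[str, int]   # node label -> state index (mask - 1)


@dataclass
class DispersalSummary:
    """Source x destination dispersal accounting averaged over maps."""

    counts_mean: pd.DataFrame    # mean event counts, source rows -> destination cols
    source_percent: pd.DataFrame  # per-source rows summing to 100
    source_share: pd.Series      # share of the grand total per source, in %
    n_maps: int
    total_events_mean: float


def attribute_source(
    range_mask: int,
    gained: int,
    multipliers: np.ndarray,
    rng: np.random.Generator,
    mode: str = "multiplier",
) -> int:
    """Pick the source area j within the pre-event range for a gain of ``gained``.

    ``multiplier`` mode samples j with probability m[j, k] / sum over the
    range; ``uniform`` ignores the multipliers. The gained area must lie
    outside the range.
    """
    if range_mask >> gained & 1:
        raise ValueError("gained area already in the range")
    occupied = [j for j in range(multipliers.shape[0]) if range_mask >> j & 1]
    if not occupied:
        raise ValueError("empty range cannot be a dispersal source")
    if mode == "uniform":
        return int(occupied[int(rng.integers(len(occupied)))])
    w = np.array([multipliers[j, gained] for j in occupied], dtype=float)
    tot = w.sum()
    if tot <= 0:
        raise ValueError("all multipliers into the gained area are zero")
    if len(occupied) == 1:
        return occupied[0]
    return int(rng.choice(occupied, p=w / tot))


class _SegmentSampler:
    """Endpoint-conditioned CTMC path sampling on one stratum's generator."""

    def __init__(self, Q: np.ndarray, propagator):
        self.Q = Q
        self.P = propagator
        self.mu = float(np.max(-np.diag(Q)))
        self.S = Q.shape[0]
        if self.mu > 0:
            self.R = np.eye(self.S) + Q / self.mu
        else:
            self.R = np.eye(self.S)
        self._Rpow: list[np.ndarray] = [np.eye(self.S), self.R.copy()]

    def Rpow(self, n: int) -> np.ndarray:
        while len(self._Rpow) <= n:
            self._Rpow.append(self._Rpow[-1] @ self.R)
        return self._Rpow[n]

    def sample_path(
        self, i: int, j: int, dt: float, rng: np.random.Generator
    ) -> list[tuple[float, int]]:
        """States after each real jump: [(fraction of dt from the old end, new state)]."""
        if self.mu == 0.0 or dt <= 0.0:
            if i != j:
                raise ValueError("endpoint change with a zero generator")
            return []
        p_ij = float(self.P(dt)[i, j])
        if p_ij <= 0.0:
            raise ValueError("conditioning on a zero-probability endpoint pair")
        u = rng.random() * p_ij
        acc = 0.0
        n = 0
        while n <= _MAX_JUMPS:
            w = scipy.stats.poisson.pmf(n, self.mu * dt) * self.Rpow(n)[i, j]
            acc += w
            if acc >= u:
                break
            n += 1
        if n == 0:
            return []
        times = np.sort(rng.random(n)) * dt
        states = [i]
        for k in range(1, n):
            probs = self.R[states[-1]] * self.Rpow(n - k)[:, j]
            tot = probs.sum()
            if tot <= 0:
                raise ValueError("degenerate conditioned jump chain")
            states.append(int(rng.choice(self.S, p=probs / tot)))
        states.append(j)
        out = []
        for k in range(1, n + 1):
            if states[k] != states[k - 1]:
                out.append((float(times[k - 1]), states[k]))
        return out


def _classify(prev_state: int, new_state: int) -> tuple[str, int]:
    prev_mask, new_mask = prev_state + 1, new_state + 1
    diff = prev_mask ^ new_mask
    if bin(diff).count("1") != 1:
        raise ValueError("jump changes more than one area")
    area = diff.bit_length() - 1
    return ("gain", area) if new_mask > prev_mask else ("loss", area)


def stochastic_map(
    tree: IndexedTree,
    tip_ranges: dict,
    params: BayAreaParams,
    strata: list[Stratum],
    n_areas: int,
    n_maps: int = 20,
    seed: int | np.random.Generator = 0,
    source_mode: str = "multiplier",
    root_prior: np.ndarray | None = None,
) -> list[MapHistory]:
    """Sample full range-evolution histories consistent with the tip data.

    Default 20 maps. Every history is exactly consistent with the observed
    tip ranges and the stratified generator at the supplied parameters.
    """
    eng = LikelihoodEngine(tree, tip_ranges, strata, n_areas, root_prior)
    rng = seed if isinstance(seed, np.random.Generator) else seed_stream(int(seed), "bsm")
    props = eng.propagators(params)
    Qs = [p.Q for p in props]
    samplers = [_SegmentSampler(Q, p) for Q, p in zip(Qs, props)]
    branch_P = [
        eng.branch_matrix(v, props) if v else None for v in range(tree.n_nodes)
    ]
    partial, log_scale = eng._partials([
        P if P is not None else np.eye(eng.S) for P in branch_P
    ])
    if not np.isfinite(log_scale):
        raise ValueError("tip data have zero likelihood at these parameters")

    histories: list[MapHistory] = []
    for map_id in range(n_maps):
        states = np.zeros(tree.n_nodes, dtype=int)
        probs = eng.root_prior * partial[0]
        states[0] = int(rng.choice(eng.S, p=probs / probs.sum()))
        records: list[tuple] = []
        for v in range(1, tree.n_nodes):  # preorder: parent states known
            p_idx = tree.parent[v]
            w = branch_P[v][states[p_idx]] * partial[v]
            tot = w.sum()
            if tot <= 0:
                raise ValueError("zero-probability branch endpoint distribution")
            states[v] = int(rng.choice(eng.S, p=w / tot))
            # walk the branch old -> young through its stratum segments
            segs = eng.segments[v]
            top_age = float(tree.age[p_idx])
            cur = int(states[p_idx])
            target = int(states[v])
            # sample the states at interior segment boundaries
            boundary_states: list[int] = []
            if len(segs) > 1:
                # suffix[k] = product of segment matrices k..end (old -> young)
                suffix: list[np.ndarray] = [np.eye(eng.S)] * len(segs)
                acc = np.eye(eng.S)
                for k in range(len(segs) - 1, -1, -1):
                    idx, dt = segs[k]
                    acc = props[idx](dt) @ acc
                    suffix[k] = acc
                s_here = cur
                for k in range(len(segs) - 1):
                    idx, dt = segs[k]
                    w2 = props[idx](dt)[s_here] * suffix[k + 1][:, target]
                    t2 = w2.sum()
                    if t2 <= 0:
                        raise ValueError("zero-probability boundary state")
                    s_here = int(rng.choice(eng.S, p=w2 / t2))
                    boundary_states.append(s_here)
            ends = boundary_states + [target]
            age = top_age
            s_prev = cur
            for (idx, dt), s_end in zip(segs, ends):
                jumps = None
                for attempt in range(_RESAMPLE_CAP):
                    try:
                        jumps = samplers[idx].sample_path(s_prev, s_end, dt, rng)
                        break
                    except ValueError:
                        continue
                if jumps is None:
                    raise RuntimeError("could not sample a conditioned branch path")
                state_now = s_prev
                for frac, s_new in jumps:
                    t_ev = age - frac
                    kind, area = _classify(state_now, s_new)
                    if kind == "gain":
                        src = attribute_source(
                            state_now + 1, area, strata_mult(eng, idx), rng, source_mode
                        )
                    else:
                        src = -1
                    records.append((map_id, tree.labels[v], t_ev, kind, area, src))
                    state_now = s_new
                age -= dt
                s_prev = s_end
        events = pd.DataFrame(records, columns=EVENT_COLUMNS)
        node_states = {
            tree.labels[k]: int(states[k])
            for k in range(tree.n_nodes)
            if not tree.is_tip[k]
        }
        histories.append(MapHistory(map_id, events, node_states))
    return histories


def strata_mult(eng: LikelihoodEngine, idx: int) -> np.ndarray:
    return eng.strata[idx].multipliers


def events_to_frame(histories: list[MapHistory]) -> pd.DataFrame:
    if not histories:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    return pd.concat([h.events for h in histories], ignore_index=True)


# ------------------------------------------------------------------- binning


def bin_events(
    histories: list[MapHistory],
    tree: IndexedTree,
    bin_width: float = 1.0,
) -> pd.DataFrame:
    """Mean dispersal counts per (1-My bin, source, destination) over maps.

    Bins are half-open [t, t - width) Ma with the oldest edge at
    ceil(root age); an event at 12.3 Ma falls in bin [13, 12). The lineage
    count per bin is the number of branches alive at the bin midpoint.
    """
    if not histories:
        raise ValueError("need at least one map history")
    oldest = math.ceil(tree.root_age / bin_width) * bin_width
    starts = np.arange(oldest, 0.0, -bin_width)
    lineages = {float(t): lineages_at(tree, float(t) - bin_width / 2.0) for t in starts}
    all_events = events_to_frame(histories)
    gains = all_events[all_events["kind"] == "gain"].copy()
    n_maps = len(histories)
    if len(gains):
        gains["bin_start"] = np.ceil(gains["time_ma"] / bin_width) * bin_width
        gains.loc[gains["bin_start"] <= 0, "bin_start"] = bin_width
        grouped = (
            gains.groupby(["bin_start", "source", "area"]).size().rename("total").reset_index()
        )
    else:
        grouped = pd.DataFrame(columns=["bin_start", "source", "area", "total"])
    rows = []
    for _, r in grouped.iterrows():
        t = float(r["bin_start"])
        rows.append(
            (t, int(r["source"]), int(r["area"]), r["total"] / n_maps, lineages.get(t, 1))
        )
    out = pd.DataFrame(
        rows, columns=["bin_start", "source", "destination", "absolute", "lineages"]
    )
    out["relative"] = relative_dispersal(out["absolute"], out["lineages"])
    return out.sort_values(["bin_start", "source", "destination"], ascending=[False, True, True]).reset_index(drop=True)


def relative_dispersal(counts, lineages, log_base: str = "ln"):
    """Per-bin relative dispersal: counts / max(log(lineages), 1).

    The clamp at 1 avoids division by log(1) = 0 near the root, where the
    tree holds only one or two branches.
    """
    counts = np.asarray(counts, dtype=float)
    lineages = np.asarray(lineages, dtype=float)
    if np.any(lineages < 1):
        raise ValueError("lineage counts must be >= 1")
    log = np.log(lineages) if log_base == "ln" else np.log10(lineages)
    denom = np.maximum(log, 1.0)
    return counts / denom


def summarize_flows(
    histories: list[MapHistory], n_areas: int, area_names: list[str] | None = None
) -> DispersalSummary:
    """Source x destination mean counts, per-source percentages, total shares."""
    if not histories:
        raise ValueError("need at least one map history")
    names = area_names or [chr(ord("A") + k) for k in range(n_areas)]
    counts = np.zeros((n_areas, n_areas))
    for h in histories:
        gains = h.events[h.events["kind"] == "gain"]
        for _, r in gains.iterrows():
            counts[int(r["source"]), int(r["area"])] += 1.0
    counts /= len(histories)
    cm = pd.DataFrame(counts, index=names, columns=names)
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(row_sums > 0, 100.0 * counts / row_sums, 0.0)
    total = counts.sum()
    share = pd.Series(
        100.0 * counts.sum(axis=1) / total if total > 0 else np.zeros(n_areas),
        index=names,
    )
    return DispersalSummary(
        counts_mean=cm,
        source_percent=pd.DataFrame(pct, index=names, columns=names),
        source_share=share,
        n_maps=len(histories),
        total_events_mean=float(total),
    )
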