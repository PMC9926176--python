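"""Ancestral-range model over bioregions: anagenetic-only CTMC with time strata.

The geographic range of a lineage is a non-empty subset of ``A`` bioregions
(default six). Along a branch the range evolves by single-area gains at rate
``d`` (range expansion), weighted by a per-stratum dispersal-multiplier
matrix ``m``, and single-area losses at rate ``e`` (range contraction).
Cladogenesis copies the parental range to both daughters; there is no
founder-event (jump) process, so speciation itself never changes ranges.
The empty range is excluded from the state space: a loss from a
single-area range is forbidden, mirroring the fact that an extant species
must occupy at least one bioregion.

Geological history enters through time strata: contiguous intervals
[start Ma, end Ma] each carrying its own multiplier matrix. Branch
transition probabilities are products of matrix exponentials over the
strata a branch crosses, ordered from oldest to youngest. Lineages older
than the oldest stratum boundary evolve under the oldest stratum's matrix.

Rates d and e are fit by maximum likelihood (Felsenstein pruning with a
uniform root prior over non-empty ranges), compared by AIC/AICc, and
marginal ancestral-state probabilities are computed per internal node.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import yaml

from .trees import IndexedTree

__all__ = [
    "BayAreaParams",
    "Stratum",
    "RangeModel",
    "FitResult",
    "n_range_states",
    "state_masks",
    "state_label",
    "build_rate_matrix",
    "validate_strata",
    "branch_segments",
    "StratumPropagator",
    "LikelihoodEngine",
    "prune_likelihood",
    "fit_ml",
    "ancestral_marginals",
    "read_strata_yaml",
    "write_strata_yaml",
    "tip_ranges_from_frame",
    "tip_ranges_to_frame",
    "tip_ranges_from_presence_set",
]

_MIN_LOGLIK = -1e12


@dataclass
class BayAreaParams:
    """Anagenetic rates: d = range expansion, e = range contraction (events/My)."""

    d: float
    e: float

    def __post_init__(self) -> None:
        if self.d < 0 or self.e < 0:
            raise ValueError("rates d and e must be non-negative")


@dataclass
class Stratum:
    """One time slice [start Ma, end Ma] with its A x A dispersal multiplier matrix."""

    start: float  # older bound, Ma
    end: float    # younger bound, Ma
    multipliers: np.ndarray

    def __post_init__(self) -> None:
        self.multipliers = np.asarray(self.multipliers, dtype=float)
        if self.start <= self.end:
            raise ValueError(f"stratum start ({self.start}) must be older than end ({self.end})")
        if self.multipliers.ndim != 2 or self.multipliers.shape[0] != self.multipliers.shape[1]:
            raise ValueError("multiplier matrix must be square")
        if (self.multipliers < 0).any():
            raise ValueError("multiplier entries must be >= 0")


@dataclass
class RangeModel:
    """Areas, strata and rates bundled for forward simulation and reporting."""

    areas: list[str]
    strata: list[Stratum]
    params: BayAreaParams

    def __post_init__(self) -> None:
        validate_strata(self.strata, len(self.areas))

    @property
    def n_areas(self) -> int:
        return len(self.areas)


@dataclass
class FitResult:
    params: BayAreaParams
    loglik: float
    aic: float
    aicc: float
    converged: bool
    n_evals: int = 0
    message: str = ""
    starts: list[tuple[float, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "d": self.params.d,
            "e": self.params.e,
            "loglik": self.loglik,
            "AIC": self.aic,
            "AICc": self.aicc,
            "converged": bool(self.converged),
            "n_evals": int(self.n_evals),
            "message": self.message,
        }


# --------------------------------------------------------------------- states


def n_range_states(n_areas: int) -> int:
    return 2 ** n_areas - 1


def state_masks(n_areas: int) -> np.ndarray:
    """Bitmasks of all non-empty ranges; state index s <-> mask s + 1."""
    return np.arange(1, 2 ** n_areas, dtype=int)


def mask_to_state(mask: int) -> int:
    if mask < 1:
        raise ValueError("empty range has no state index")
    return mask - 1


def state_to_mask(state: int) -> int:
    return state + 1


def areas_of_mask(mask: int, n_areas: int) -> list[int]:
    return [k for k in range(n_areas) if mask >> k & 1]


def mask_of_areas(areas) -> int:
    mask = 0
    for a in areas:
        mask |= 1 << int(a)
    return mask


def state_label(state: int, area_names: list[str]) -> str:
    return "+".join(area_names[k] for k in areas_of_mask(state + 1, len(area_names)))


def build_rate_matrix(stratum: Stratum, params: BayAreaParams, n_areas: int) -> np.ndarray:
    """Instantaneous generator over the 2^A - 1 non-empty range states.

    rate(R -> R+{k}) = d * sum_{j in R} m[j, k]      (k not in R)
    rate(R -> R-{k}) = e                             (k in R, |R| > 1)
    Loss is not multiplier-weighted: the multipliers encode connectivity
    for dispersal, while contraction is a local process.
    """
    m = stratum.multipliers
    if m.shape[0] != n_areas:
        raise ValueError(f"multiplier matrix is {m.shape[0]}x{m.shape[0]}, expected {n_areas}")
    S = n_range_states(n_areas)
    Q = np.zeros((S, S))
    for s in range(S):
        mask = s + 1
        occupied = areas_of_mask(mask, n_areas)
        for k in range(n_areas):
            if mask >> k & 1:
                if len(occupied) > 1:
                    Q[s, mask_to_state(mask & ~(1 << k))] = params.e
            else:
                gain = params.d * sum(m[j, k] for j in occupied)
                if gain > 0:
                    Q[s, mask_to_state(mask | (1 << k))] = gain
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


# --------------------------------------------------------------------- strata


def validate_strata(strata: list[Stratum], n_areas: int) -> list[Stratum]:
    """Check strata tile [oldest, 0] without gaps; return sorted old -> young."""
    if not strata:
        raise ValueError("at least one stratum required")
    out = sorted(strata, key=lambda s: -s.start)
    for s in out:
        if s.multipliers.shape[0] != n_areas:
            raise ValueError("stratum multiplier matrix does not match number of areas")
    for older, younger in zip(out, out[1:]):
        if not math.isclose(older.end, younger.start, abs_tol=1e-9):
            raise ValueError(
                f"strata do not tile: gap between {older.end} and {younger.start} Ma"
            )
    if not math.isclose(out[-1].end, 0.0, abs_tol=1e-9):
        raise ValueError("youngest stratum must end at 0 Ma")
    return out


def branch_segments(parent_age: float, child_age: float, strata: list[Stratum]) -> list[tuple[int, float]]:
    """Split a branch into (stratum index, duration) pieces, ordered old -> young.

    Ages above the oldest stratum's start fall into the oldest stratum.
    """
    segs: list[tuple[int, float]] = []
    remaining_hi = parent_age
    for i, s in enumerate(strata):
        hi = remaining_hi if i == 0 else min(remaining_hi, s.start)
        lo = max(child_age, s.end)
        if hi - lo > 1e-12:
            segs.append((i, hi - lo))
            remaining_hi = lo
        if remaining_hi <= child_age + 1e-12:
            break
    total = sum(dt for _, dt in segs)
    expected = parent_age - child_age
    if expected > 1e-9 and abs(total - expected) > 1e-6 * max(1.0, expected):
        raise ValueError("branch segments do not cover the branch; check strata tiling")
    return segs


# ---------------------------------------------------------------- propagators


class StratumPropagator:
    """Computes P(t) = exp(Q t) for one generator, via eigendecomposition.

    The spectral route costs one decomposition per generator and two dense
    matmuls per branch, which dominates at the 63-state space of six areas.
    Accuracy is checked against scipy's expm once; if the generator is too
    ill-conditioned for the spectral route, every call falls back to expm.
    """

    def __init__(self, Q: np.ndarray):
        self.Q = Q
        self.S = Q.shape[0]
        self._cache: dict[float, np.ndarray] = {}
        self._use_eig = False
        scale = max(1.0, np.abs(Q).max())
        try:
            w, V = np.linalg.eig(Q)
            Vinv = np.linalg.inv(V)
            t_ref = 1.0 / scale
            P_eig = (V * np.exp(w * t_ref)) @ Vinv
            P_ref = scipy.linalg.expm(Q * t_ref)
            if np.abs(P_eig.real - P_ref).max() < 1e-10:
                self._w, self._V, self._Vinv = w, V, Vinv
                self._use_eig = True
        except np.linalg.LinAlgError:
            pass

    def __call__(self, t: float) -> np.ndarray:
        P = self._cache.get(t)
        if P is not None:
            return P
        if t <= 0:
            P = np.eye(self.S)
        elif self._use_eig:
            P = ((self._V * np.exp(self._w * t)) @ self._Vinv).real
            if P.min() < -1e-9 or np.abs(P.sum(axis=1) - 1.0).max() > 1e-9:
                P = scipy.linalg.expm(self.Q * t)
        else:
            P = scipy.linalg.expm(self.Q * t)
        np.clip(P, 0.0, None, out=P)
        self._cache[t] = P
        return P

    def apply(self, t: float, vec: np.ndarray) -> np.ndarray:
        """exp(Q t) @ vec without forming the full matrix (spectral matvec)."""
        if t <= 0:
            return vec
        if not self._use_eig:
            return self(t) @ vec
        u = self._Vinv @ vec
        u *= np.exp(self._w * t)
        out = (self._V @ u).real
        np.clip(out, 0.0, None, out=out)
        return out

    def batch(self, ts: np.ndarray) -> np.ndarray:
        """exp(Q t) for many durations at once (stacked BLAS matmuls)."""
        ts = np.asarray(ts, dtype=float)
        if not self._use_eig:
            return np.stack([self(float(t)) for t in ts])
        E = np.exp(np.multiply.outer(ts, self._w))        # (B, S)
        M = self._V[None, :, :] * E[:, None, :]           # (B, S, S)
        B = len(ts)
        P = (M.reshape(B * self.S, self.S) @ self._Vinv).reshape(B, self.S, self.S).real
        if P.min() < -1e-9 or np.abs(P.sum(axis=2) - 1.0).max() > 1e-9:
            return np.stack([self(float(t)) for t in ts])
        np.clip(P, 0.0, None, out=P)
        return P


# ------------------------------------------------------------------ likelihood


def _tip_state(range_spec, n_areas: int) -> int:
    """Accept a bitmask, an iterable of area indices, or a frozenset."""
    if isinstance(range_spec, (int, np.integer)):
        mask = int(range_spec)
    else:
        mask = mask_of_areas(range_spec)
    if mask < 1 or mask >= 2 ** n_areas:
        raise ValueError(f"tip range {range_spec!r} invalid for {n_areas} areas")
    return mask_to_state(mask)


class LikelihoodEngine:
    """Felsenstein pruning over the stratified range CTMC for one dataset.

    Precomputes branch/stratum segmentation once; each likelihood evaluation
    rebuilds only the per-stratum generators and branch propagators.
    """

    def __init__(
        self,
        tree: IndexedTree,
        tip_ranges: dict,
        strata: list[Stratum],
        n_areas: int,
        root_prior: np.ndarray | None = None,
    ):
        self.tree = tree
        self.n_areas = n_areas
        self.S = n_range_states(n_areas)
        self.strata = validate_strata(strata, n_areas)
        missing = [lab for lab in tree.tip_labels() if lab not in tip_ranges]
        if missing:
            raise ValueError(f"tips lacking observed ranges: {missing[:5]}...")
        self.tip_state = {
            lab: _tip_state(tip_ranges[lab], n_areas) for lab in tree.tip_labels()
        }
        if root_prior is None:
            root_prior = np.full(self.S, 1.0 / self.S)
        self.root_prior = np.asarray(root_prior, dtype=float)
        self.segments: list[list[tuple[int, float]]] = [[] for _ in range(tree.n_nodes)]
        for v in range(1, tree.n_nodes):
            p = tree.parent[v]
            self.segments[v] = branch_segments(tree.age[p], tree.age[v], self.strata)
        self._post = tree.postorder

    def propagators(self, params: BayAreaParams) -> list[StratumPropagator]:
        return [
            StratumPropagator(build_rate_matrix(s, params, self.n_areas))
            for s in self.strata
        ]

    def branch_matrix(self, v: int, props: list[StratumPropagator]) -> np.ndarray:
        """Transition matrix parent -> child for the branch above node v."""
        P = None
        for idx, dt in self.segments[v]:
            Pi = props[idx](dt)
            P = Pi if P is None else P @ Pi
        if P is None:
            P = np.eye(self.S)
        return P

    def branch_matrices(self, params: BayAreaParams) -> list[np.ndarray]:
        """Per-node parent->child transition matrices, batched per stratum."""
        props = self.propagators(params)
        n = self.tree.n_nodes
        # gather every (node, segment) duration, grouped by stratum
        per_stratum: dict[int, list[tuple[int, int, float]]] = {}
        for v in range(1, n):
            for pos, (idx, dt) in enumerate(self.segments[v]):
                per_stratum.setdefault(idx, []).append((v, pos, dt))
        seg_P: dict[tuple[int, int], np.ndarray] = {}
        for idx, entries in per_stratum.items():
            Ps = props[idx].batch(np.array([dt for _, _, dt in entries]))
            for (v, pos, _), P in zip(entries, Ps):
                seg_P[(v, pos)] = P
        out = [np.eye(self.S)]
        for v in range(1, n):
            P = None
            for pos in range(len(self.segments[v])):
                Pi = seg_P[(v, pos)]
                P = Pi if P is None else P @ Pi
            out.append(P if P is not None else np.eye(self.S))
        return out

    def _partials(self, branch_P: list[np.ndarray]) -> tuple[np.ndarray, float]:
        """Down partials L_v(s) = P(data below v | state s at v), with log scaling."""
        tree = self.tree
        partial = np.empty((tree.n_nodes, self.S))
        log_scale = 0.0
        for v in self._post:
            if tree.is_tip[v]:
                vec = np.zeros(self.S)
                vec[self.tip_state[tree.labels[v]]] = 1.0
                partial[v] = vec
                continue
            vec = np.ones(self.S)
            for c in tree.children[v]:
                vec = vec * (branch_P[c] @ partial[c])
            m = vec.max()
            if m <= 0.0:
                return partial, -np.inf
            vec /= m
            log_scale += math.log(m)
            partial[v] = vec
        return partial, log_scale

    def loglik(self, params: BayAreaParams) -> float:
        """Pruning pass with spectral matvecs: never forms full branch matrices."""
        props = self.propagators(params)
        tree = self.tree
        partial = np.empty((tree.n_nodes, self.S))
        log_scale = 0.0
        for v in self._post:
            if tree.is_tip[v]:
                vec = np.zeros(self.S)
                vec[self.tip_state[tree.labels[v]]] = 1.0
                partial[v] = vec
                continue
            vec = np.ones(self.S)
            for c in tree.children[v]:
                msg = partial[c]
                for idx, dt in reversed(self.segments[c]):
                    msg = props[idx].apply(dt, msg)
                vec = vec * msg
            m = vec.max()
            if m <= 0.0:
                return -np.inf
            vec /= m
            log_scale += math.log(m)
            partial[v] = vec
        L = float(self.root_prior @ partial[0])
        if L <= 0.0 or not np.isfinite(L):
            return -np.inf
        return math.log(L) + log_scale

    def marginals(self, params: BayAreaParams) -> tuple[np.ndarray, list[np.ndarray], np.ndarray]:
        """Per-node marginal state probabilities given tip data.

        Returns (marginals [n_nodes x S], branch matrices, down partials).
        Tip rows are point masses on the observed state.
        """
        tree = self.tree
        branch_P = self.branch_matrices(params)
        partial, log_scale = self._partials(branch_P)
        if not np.isfinite(log_scale):
            raise ValueError("data have zero probability under these parameters")
        up = np.zeros((tree.n_nodes, self.S))
        up[0] = self.root_prior
        msg = {}
        for v in range(tree.n_nodes):
            for c in tree.children[v]:
                msg[c] = branch_P[c] @ partial[c]
        for v in range(tree.n_nodes):  # preorder
            if tree.is_tip[v]:
                continue
            kids = tree.children[v]
            for c in kids:
                other = up[v].copy()
                for s in kids:
                    if s != c:
                        other *= msg[s]
                vec = branch_P[c].T @ other
                tot = vec.sum()
                if tot > 0:
                    vec /= tot
                up[c] = vec
        marg = up * partial
        sums = marg.sum(axis=1, keepdims=True)
        sums[sums == 0] = 1.0
        marg /= sums
        return marg, branch_P, partial


def prune_likelihood(
    tree: IndexedTree,
    tip_ranges: dict,
    params: BayAreaParams,
    strata: list[Stratum],
    n_areas: int,
    root_prior: np.ndarray | None = None,
) -> float:
    """Log-likelihood of observed tip ranges under the stratified range CTMC."""
    return LikelihoodEngine(tree, tip_ranges, strata, n_areas, root_prior).loglik(params)


def ancestral_marginals(
    tree: IndexedTree,
    tip_ranges: dict,
    params: BayAreaParams,
    strata: list[Stratum],
    n_areas: int,
    root_prior: np.ndarray | None = None,
) -> pd.DataFrame:
    """Marginal range probabilities per node, rows keyed by node label."""
    eng = LikelihoodEngine(tree, tip_ranges, strata, n_areas, root_prior)
    marg, _, _ = eng.marginals(params)
    cols = [state_label(s, [chr(ord("A") + k) for k in range(n_areas)]) for s in range(eng.S)]
    return pd.DataFrame(marg, index=tree.labels, columns=cols)


# ------------------------------------------------------------------------ fit


_DEFAULT_STARTS = [(0.001, 0.001), (0.01, 0.01), (0.1, 0.05)]


def fit_ml(
    tree: IndexedTree,
    tip_ranges: dict,
    strata: list[Stratum],
    n_areas: int,
    starts: list[tuple[float, float]] | None = None,
    bounds: tuple[float, float] = (1e-8, 10.0),
    root_prior: np.ndarray | None = None,
) -> FitResult:
    """Maximum-likelihood fit of (d, e) on a log scale, with multi-start.

    AIC = -2 lnL + 2k with k = 2 free rates; AICc adds the small-sample
    correction with n = number of tips.
    """
    eng = LikelihoodEngine(tree, tip_ranges, strata, n_areas, root_prior)
    starts = starts or _DEFAULT_STARTS
    lo, hi = math.log(bounds[0]), math.log(bounds[1])
    n_evals = 0

    def nll(x: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        ll = eng.loglik(BayAreaParams(math.exp(x[0]), math.exp(x[1])))
        if not np.isfinite(ll):
            return -_MIN_LOGLIK
        return -ll

    best = None
    any_converged = False
    messages = []
    for d0, e0 in starts:
        x0 = np.log(np.clip([d0, e0], bounds[0], bounds[1]))
        res = scipy.optimize.minimize(
            nll, x0, method="L-BFGS-B", bounds=[(lo, hi), (lo, hi)],
            options={"maxiter": 200},
        )
        messages.append(str(res.message))
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("likelihood not finite at any starting point")
    d_hat, e_hat = math.exp(best.x[0]), math.exp(best.x[1])
    ll = -float(best.fun)
    k = 2
    n = tree.n_tips
    aic = -2.0 * ll + 2 * k
    aicc = aic + (2.0 * k * (k + 1) / (n - k - 1)) if n > k + 1 else math.inf
    return FitResult(
        params=BayAreaParams(d_hat, e_hat),
        loglik=ll,
        aic=aic,
        aicc=aicc,
        converged=any_converged,
        n_evals=n_evals,
        message="; ".join(dict.fromkeys(messages)),
        starts=list(starts),
    )


# --------------------------------------------------------------------- config


def write_strata_yaml(path, areas: list[str], strata: list[Stratum]) -> None:
    doc = {
        "areas": list(areas),
        "strata": [
            {"start": float(s.start), "end": float(s.end), "multipliers": s.multipliers.tolist()}
            for s in strata
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_strata_yaml(path) -> tuple[list[str], list[Stratum]]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    areas = [str(a) for a in doc["areas"]]
    strata = [
        Stratum(float(s["start"]), float(s["end"]), np.asarray(s["multipliers"], dtype=float))
        for s in doc["strata"]
    ]
    validate_strata(strata, len(areas))
    return areas, strata


# ------------------------------------------------------------------ tip ranges


def tip_ranges_from_frame(df: pd.DataFrame) -> dict[str, frozenset[int]]:
    """Binary species x area table -> {species: set of area indices}."""
    out: dict[str, frozenset[int]] = {}
    for sp, row in df.iterrows():
        idx = frozenset(int(i) for i, v in enumerate(row.values) if v)
        if not idx:
            raise ValueError(f"species {sp!r} has an empty range")
        out[str(sp)] = idx
    return out


def tip_ranges_to_frame(tip_ranges: dict[str, frozenset[int]], area_names: list[str]) -> pd.DataFrame:
    data = {
        sp: [1 if k in areas else 0 for k in range(len(area_names))]
        for sp, areas in tip_ranges.items()
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=list(area_names)).sort_index()


def tip_ranges_from_presence_set(
    matrices: list[pd.DataFrame],
    basin_to_bioregion: dict[str, str],
    bioregions: list[str],
    rule: str = "majority",
) -> pd.DataFrame:
    """Collapse replicate species x basin matrices to one species x bioregion table.

    ``majority``: a species occupies a bioregion if it is present in at least
    one of its basins in >= 50% of the replicates. ``union``: in any replicate.
    A species whose majority-rule range is empty falls back to its union
    range so that every tip keeps a non-empty observed range.
    """
    if rule not in ("majority", "union"):
        raise ValueError("rule must be 'majority' or 'union'")
    frac = None
    for mat in matrices:
        cols = pd.Index([basin_to_bioregion[b] for b in mat.columns], name="bioregion")
        by_region = (mat.T.groupby(cols).any().T).astype(float)
        by_region = by_region.reindex(columns=bioregions, fill_value=0.0)
        frac = by_region if frac is None else frac.add(by_region, fill_value=0.0)
    frac = frac / len(matrices)
    union = (frac > 0).astype(int)
    if rule == "union":
        return union
    major = (frac >= 0.5).astype(int)
    empty = major.sum(axis=1) == 0
    major.loc[empty] = union.loc[empty]
    return major
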