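"""Independent oracles used by the test suite.

Everything here deliberately avoids the package's own numerical paths:
transition probabilities come straight from scipy.linalg.expm, likelihoods
from exhaustive enumeration over internal node states, and expectations
from explicit linear algebra or quadrature.
"""

from __future__ import annotations

import itertools

import numpy as np
import scipy.integrate
import scipy.linalg

from basinbio.ranges import BayAreaParams, Stratum, build_rate_matrix
from basinbio.trees import IndexedTree


def branch_matrix_direct(
    parent_age: float,
    child_age: float,
    strata: list[Stratum],
    params: BayAreaParams,
    n_areas: int,
) -> np.ndarray:
    """Piecewise transition matrix by direct expm over stratum overlaps."""
    S = 2**n_areas - 1
    P = np.eye(S)
    ordered = sorted(strata, key=lambda s: -s.start)
    for i, s in enumerate(ordered):
        hi = parent_age if i == 0 else min(parent_age, s.start)
        lo = max(child_age, s.end)
        if hi > lo:
            Q = build_rate_matrix(s, params, n_areas)
            P = P @ scipy.linalg.expm(Q * (hi - lo))
    return P


def brute_force_loglik(
    tree: IndexedTree,
    tip_states: dict[str, int],
    params: BayAreaParams,
    strata: list[Stratum],
    n_areas: int,
) -> float:
    """Exhaustive sum over internal-node state assignments (<= 4 tips)."""
    S = 2**n_areas - 1
    internals = [v for v in range(tree.n_nodes) if not tree.is_tip[v]]
    P = {}
    for v in range(1, tree.n_nodes):
        P[v] = branch_matrix_direct(
            float(tree.age[tree.parent[v]]), float(tree.age[v]), strata, params, n_areas
        )
    total = 0.0
    for combo in itertools.product(range(S), repeat=len(internals)):
        assign = dict(zip(internals, combo))
        for i in tree.tip_indices():
            assign[int(i)] = tip_states[tree.labels[i]]
        prob = 1.0 / S  # uniform root prior over non-empty states
        for v in range(1, tree.n_nodes):
            prob *= P[v][assign[tree.parent[v]], assign[v]]
            if prob == 0.0:
                break
        total += prob
    if total <= 0:
        return -np.inf
    return float(np.log(total))


def brute_force_joint(
    tree: IndexedTree,
    tip_states: dict[str, int],
    params: BayAreaParams,
    strata: list[Stratum],
    n_areas: int,
) -> dict[tuple[int, ...], float]:
    """Posterior over internal-node state assignments by enumeration."""
    S = 2**n_areas - 1
    internals = [v for v in range(tree.n_nodes) if not tree.is_tip[v]]
    P = {
        v: branch_matrix_direct(
            float(tree.age[tree.parent[v]]), float(tree.age[v]), strata, params, n_areas
        )
        for v in range(1, tree.n_nodes)
    }
    joint: dict[tuple[int, ...], float] = {}
    for combo in itertools.product(range(S), repeat=len(internals)):
        assign = dict(zip(internals, combo))
        for i in tree.tip_indices():
            assign[int(i)] = tip_states[tree.labels[i]]
        prob = 1.0 / S
        for v in range(1, tree.n_nodes):
            prob *= P[v][assign[tree.parent[v]], assign[v]]
        if prob > 0:
            joint[combo] = prob
    Z = sum(joint.values())
    return {k: v / Z for k, v in joint.items()}


def expected_events_conditioned(
    Q: np.ndarray, a: int, b: int, T: float, n_grid: int = 801
) -> float:
    """E[number of state changes | X_0 = a, X_T = b] by Simpson quadrature.

    Integrates sum_{i != j} P_aj(s)... explicitly:
    E = (1 / P_ab(T)) * int_0^T sum_{i,j != i} [e^{Qs}]_{a,i} q_ij [e^{Q(T-s)}]_{j,b} ds.
    """
    S = Q.shape[0]
    Pab = scipy.linalg.expm(Q * T)[a, b]
    if Pab <= 0:
        raise ValueError("impossible endpoint pair")
    ss = np.linspace(0.0, T, n_grid)
    vals = np.empty(n_grid)
    for k, s in enumerate(ss):
        Ps = scipy.linalg.expm(Q * s)
        Pr = scipy.linalg.expm(Q * (T - s))
        acc = 0.0
        for i in range(S):
            for j in range(S):
                if i != j and Q[i, j] > 0:
                    acc += Ps[a, i] * Q[i, j] * Pr[j, b]
        vals[k] = acc
    return float(scipy.integrate.simpson(vals, x=ss) / Pab)


def conditioned_bd_mean_span(b: float, d: float, n: int) -> float:
    """Expected simulated time span of the tree generator's stopping rule.

    The generator grows a linear birth-death chain from 2 lineages, retries
    on extinction, stops at the first passage to n lineages, then extends
    the present by U * Exp((b+d) n). The first term is the expected first
    passage time from 2 to n conditioned on hitting n before 0, computed
    from the Doob h-transformed chain; the second is the stub mean.
    """
    # hitting probabilities u_k = P(hit n before 0 | k), gambler's ruin
    states = np.arange(0, n + 1)
    if d == 0:
        u = np.ones(n + 1)
        u[0] = 0.0
    else:
        r = d / b
        if abs(r - 1.0) < 1e-12:
            u = states / n
        else:
            u = (1 - r**states) / (1 - r**n)
    # h-transformed rates from k: up b*k*u[k+1]/u[k], down d*k*u[k-1]/u[k]
    # expected hitting time of n: t_k = (1 + up_k t_{k+1}/w + down_k t_{k-1}/w)...
    # solve the linear system (L t = -1) on interior states 1..n-1
    m = n - 1
    A = np.zeros((m, m))
    rhs = -np.ones(m)
    for k in range(1, n):
        i = k - 1
        up = b * k * u[k + 1] / u[k]
        down = d * k * (u[k - 1] / u[k]) if k > 1 else 0.0  # u[0]=0: down to 0 impossible
        A[i, i] = -(up + down)
        if k + 1 <= n - 1:
            A[i, i + 1] = up
        if k - 1 >= 1:
            A[i, i - 1] = down
    t = np.linalg.solve(A, rhs)
    first_passage = t[2 - 1]  # start from 2 lineages
    stub = 0.5 / ((b + d) * n)
    return float(first_passage + stub)
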