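"""Graph analyses of the derived connectome.

Area level: community detection by minimizing a two-level map-equation
codelength for a teleported random walk on the relative-outdegree graph,
with a weighted directed modularity Q and degree-preserving surrogate
networks for significance testing.

Population level: an approximate gain matrix weights each connection by
its indegree times the synaptic efficacy (|J|, four times larger for
inhibitory sources), scaled so the maximal real part of its eigenvalues is
one (near-critical operating point).  Edge distances ``log(1/w)`` turn
strongest-path search into shortest-path search, solved with a vectorized
Bellman-Ford that tolerates negative distances and reports negative
cycles.  Shortest paths between areas are categorized by the SLN-defined
hierarchical direction and by the architectural-type difference of their
endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import Counter

import numpy as np
import pandas as pd

from cortimap.errors import (
    InvalidArgumentError,
    InvalidStateError,
    NegativeCycleError,
)
from cortimap.cortico_cortical import sln_category

# ---------------------------------------------------------------------------
# modularity


def relative_degrees(nsyn_area: pd.DataFrame, n_area: pd.Series):
    """Relative indegree and outdegree matrices of the area graph.

    ``nsyn_area`` holds synapse counts (target rows, source columns);
    ``K = nsyn / N_target`` is normalized per target row, ``Kout = nsyn /
    N_source`` per source column, yielding row- respectively
    column-stochastic relative matrices (rows/columns without weight stay
    zero).
    """
    syn = nsyn_area.to_numpy(dtype=float)
    n = n_area.reindex(nsyn_area.index).to_numpy(dtype=float)
    K = syn / n[:, None]
    Kout = syn / n[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        W_in = np.nan_to_num(K / K.sum(axis=1, keepdims=True))
        W_out = np.nan_to_num(Kout / Kout.sum(axis=0, keepdims=True))
    idx = nsyn_area.index
    return (
        pd.DataFrame(W_out, index=idx, columns=idx),
        pd.DataFrame(W_in, index=idx, columns=idx),
    )


def modularity(W_out: pd.DataFrame, W_in: pd.DataFrame, clustering: dict) -> float:
    """Weighted directed modularity of a clustering.

    ``Q = (1/m) sum_AB (Wout_AB - sum_B' Wout_AB' * sum_A' Win_A'B / m)
    delta(C_A, C_B)`` with ``m = sum_AB Wout_AB``; Q in [-1, 1].
    """
    if len(W_out) == 0:
        raise InvalidArgumentError("empty graph")
    areas = list(W_out.index)
    missing = set(areas) - set(clustering)
    if missing:
        raise InvalidArgumentError(f"clustering does not cover {sorted(missing)}")
    wo = W_out.to_numpy(dtype=float)
    wi = W_in.loc[areas, areas].to_numpy(dtype=float)
    m = wo.sum()
    if m <= 0:
        raise InvalidArgumentError("graph carries no weight")
    labels = np.array([clustering[a] for a in areas])
    same = labels[:, None] == labels[None, :]
    null = np.outer(wo.sum(axis=1), wi.sum(axis=0)) / m
    return float(((wo - null) * same).sum() / m)


# ---------------------------------------------------------------------------
# map equation


def _transition_matrix(W_out: np.ndarray, p_jump: float):
    """Row-stochastic transition matrix P[source, target] of the teleported
    walk, and the teleportation distribution (proportional to total
    out-weight; uniform if the graph carries no weight).  Dangling nodes
    teleport with probability one."""
    n = W_out.shape[0]
    out_w = W_out.sum(axis=0)  # total out-weight per source column
    tau = out_w / out_w.sum() if out_w.sum() > 0 else np.full(n, 1.0 / n)
    P = np.zeros((n, n))
    for b in range(n):
        col = W_out[:, b]
        s = col.sum()
        if s > 0:
            P[b] = (1.0 - p_jump) * col / s + p_jump * tau
        else:
            P[b] = tau
    return P, tau


def _stationary(P: np.ndarray, tol: float = 1e-12, max_iter: int = 100000) -> np.ndarray:
    n = P.shape[0]
    pi = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        nxt = pi @ P
        if np.abs(nxt - pi).sum() < tol:
            return nxt / nxt.sum()
        pi = nxt
    raise InvalidStateError("stationary distribution did not converge")


def _plogp(x):
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    nz = x > 0
    out[nz] = x[nz] * np.log2(x[nz])
    return out


def _codelength(labels: np.ndarray, F: np.ndarray, pi: np.ndarray) -> float:
    """Two-level map-equation codelength (bits) for a module assignment.

    ``F = pi[:, None] * P`` is the stationary flow matrix of the walk."""
    mods = np.unique(labels)
    k = len(mods)
    M = np.zeros((len(labels), k))
    for j, m in enumerate(mods):
        M[labels == m, j] = 1.0
    Fm = M.T @ F @ M
    q = Fm.sum(axis=1) - np.diag(Fm)  # exit flow per module
    p_mod = M.T @ pi
    q_tot = q.sum()
    # index codebook
    L = 0.0
    if q_tot > 0:
        L += q_tot * (-_plogp(q / q_tot).sum())
    # module codebooks
    for j in range(k):
        p_circ = q[j] + p_mod[j]
        if p_circ <= 0:
            continue
        inside = pi[labels == mods[j]]
        ent = -_plogp(q[j] / p_circ) - _plogp(inside / p_circ).sum()
        L += p_circ * ent
    return float(L)


def map_equation_codelength(
    W_out: pd.DataFrame, clustering: dict, p_jump: float = 0.15
) -> float:
    """Codelength (bits) of a given clustering under the teleported walk."""
    areas = list(W_out.index)
    P, _ = _transition_matrix(W_out.to_numpy(dtype=float), p_jump)
    pi = _stationary(P)
    F = pi[:, None] * P
    labels = np.array([clustering[a] for a in areas])
    _, labels = np.unique(labels, return_inverse=True)
    return _codelength(labels, F, pi)


def _plogp_s(x: float) -> float:
    return x * np.log2(x) if x > 0 else 0.0


def _module_terms(q: float, p: float) -> float:
    """Module-dependent part of the codelength: -2 q log q + (q+p) log (q+p)."""
    return -2.0 * _plogp_s(q) + _plogp_s(q + p)


def _greedy_once(F, pi, rng):
    """One greedy codelength minimization (node moves + module merges).

    Uses the aggregate form of the two-level codelength,
    ``L = plogp(q_tot) + sum_m [-2 plogp(q_m) + plogp(q_m + p_m)]
    - sum_a plogp(pi_a)``, which depends on the partition only through the
    per-module exit flows ``q_m`` and visit masses ``p_m``, so every
    candidate move costs O(1) after an O(n) per-node setup.
    """
    n = len(pi)
    labels = np.arange(n)
    row = F.sum(axis=1)
    col = F.sum(axis=0)
    dg = np.diag(F).copy()
    q = row - dg  # exit flow per (singleton) module
    p = pi.copy()
    node_term = -_plogp(pi).sum()
    tol = 1e-13

    def total_L():
        q_tot = q[np.unique(labels)].sum()
        return (
            _plogp_s(q_tot)
            + sum(_module_terms(q[m], p[m]) for m in np.unique(labels))
            + node_term
        )

    improved = True
    while improved:
        improved = False
        # node-moving pass
        for a in rng.permutation(n):
            ma = labels[a]
            wo = np.bincount(labels, weights=F[a], minlength=n)
            wi = np.bincount(labels, weights=F[:, a], minlength=n)
            q_tot = q[np.unique(labels)].sum()
            # module a without node
            q_a_new = q[ma] - (row[a] - wo[ma]) + (wi[ma] - dg[a])
            p_a_new = p[ma] - pi[a]
            if p_a_new < 1e-15:
                q_a_new, p_a_new = 0.0, 0.0
            base = _module_terms(q[ma], p[ma])
            cand_mods = set(labels[(F[a] > 0) | (F[:, a] > 0)])
            cand_mods.discard(ma)
            best_dL, best_m, best_state = -tol, None, None
            for mb in cand_mods:
                q_b_new = q[mb] + (row[a] - wo[mb] - dg[a]) - wi[mb]
                p_b_new = p[mb] + pi[a]
                q_tot_new = q_tot - q[ma] - q[mb] + q_a_new + q_b_new
                dL = (
                    _plogp_s(q_tot_new)
                    - _plogp_s(q_tot)
                    + _module_terms(q_a_new, p_a_new)
                    + _module_terms(q_b_new, p_b_new)
                    - base
                    - _module_terms(q[mb], p[mb])
                )
                if dL < best_dL:
                    best_dL, best_m = dL, mb
                    best_state = (q_a_new, p_a_new, q_b_new, p_b_new)
            if best_m is not None:
                q[ma], p[ma], q[best_m], p[best_m] = best_state
                labels[a] = best_m
                improved = True
        # module-merge pass
        merged = True
        while merged:
            mods = np.unique(labels)
            if len(mods) < 2:
                break
            merged = False
            onehot = (labels[:, None] == mods[None, :]).astype(float)
            Fm = onehot.T @ F @ onehot
            q_tot = q[mods].sum()
            best_dL, best_pair = -tol, None
            for i in range(len(mods)):
                for j in range(i + 1, len(mods)):
                    a_, b_ = mods[i], mods[j]
                    q_new = q[a_] + q[b_] - Fm[i, j] - Fm[j, i]
                    p_new = p[a_] + p[b_]
                    q_tot_new = q_tot - q[a_] - q[b_] + q_new
                    dL = (
                        _plogp_s(q_tot_new)
                        - _plogp_s(q_tot)
                        + _module_terms(q_new, p_new)
                        - _module_terms(q[a_], p[a_])
                        - _module_terms(q[b_], p[b_])
                    )
                    if dL < best_dL:
                        best_dL, best_pair = dL, (a_, b_, q_new, p_new)
            if best_pair is not None:
                a_, b_, q_new, p_new = best_pair
                labels[labels == b_] = a_
                q[a_], p[a_] = q_new, p_new
                q[b_], p[b_] = 0.0, 0.0
                merged = True
                improved = True
    return labels, total_L()


def map_equation_cluster(
    W_out: pd.DataFrame,
    p_jump: float = 0.15,
    restarts: int = 100,
    seed: int = 0,
) -> tuple[dict, float]:
    """Two-level map-equation clustering of the area graph.

    A random walker follows the relative outdegrees and teleports with
    probability ``p_jump`` to a node chosen proportionally to its total
    out-weight; stationary visit rates come from power iteration (1e-12).
    The codelength is minimized by greedy node moving with module-merge
    passes, restarted ``restarts`` times from seeded node orders; the best
    partition and its codelength are returned.
    """
    areas = list(W_out.index)
    P, _ = _transition_matrix(W_out.to_numpy(dtype=float), p_jump)
    pi = _stationary(P)
    F = pi[:, None] * P
    rng = np.random.default_rng(seed)
    best_labels, best_L = None, np.inf
    for _ in range(max(1, restarts)):
        labels, L = _greedy_once(F, pi, rng)
        if L < best_L - 1e-13:
            best_labels, best_L = labels, L
    _, canon = np.unique(best_labels, return_inverse=True)
    return {a: int(c) for a, c in zip(areas, canon)}, float(best_L)


def surrogates(
    nsyn_area: pd.DataFrame,
    n_area: pd.Series,
    n_surrogates: int,
    seed: int,
    p_jump: float = 0.15,
    restarts: int = 5,
) -> np.ndarray:
    """Modularity distribution over degree-preserving surrogate networks.

    Each surrogate permutes, for every source area, the assignment of its
    outgoing synapse counts to target areas (weights travel with the
    edges, so per-source outdegree totals are conserved exactly), then
    applies the original pipeline: relative degree matrices, map-equation
    clustering, modularity.  Returns the array of surrogate Q values.
    """
    if n_surrogates < 1:
        raise InvalidArgumentError("n_surrogates must be >= 1")
    rng = np.random.default_rng(seed)
    syn = nsyn_area.to_numpy(dtype=float)
    n = syn.shape[0]
    qs = np.empty(n_surrogates)
    off_diag = [np.array([i for i in range(n) if i != b]) for b in range(n)]
    for s in range(n_surrogates):
        shuf = np.zeros_like(syn)
        for b in range(n):
            rows = off_diag[b]
            shuf[rng.permutation(rows), b] = syn[rows, b]
        sdf = pd.DataFrame(shuf, index=nsyn_area.index, columns=nsyn_area.columns)
        W_out, W_in = relative_degrees(sdf, n_area)
        clustering, _ = map_equation_cluster(
            W_out, p_jump=p_jump, restarts=restarts, seed=int(rng.integers(2**31))
        )
        qs[s] = modularity(W_out, W_in, clustering)
    return qs


# ---------------------------------------------------------------------------
# gain graph and shortest paths


@dataclass
class GainGraph:
    """Population-level gain graph.

    ``weights[i, j]`` is the scaled gain of the edge j -> i (nonnegative;
    the sign of inhibitory sources is carried separately in ``sign``);
    ``distances[j, i]`` is ``log(1/weights[i, j])`` in source -> target
    orientation, +inf where there is no edge.
    """

    nodes: list
    weights: np.ndarray
    sign: np.ndarray
    distances: np.ndarray
    J_E: float
    J_I: float
    scale: float


def build_gain(
    K: np.ndarray, ei: np.ndarray, nodes, J_E: float = 0.15, g_ratio: float = 4.0
) -> GainGraph:
    """Gain graph from population indegrees.

    ``g_ij = K_ij * |J_j|`` with ``|J| = J_E`` for excitatory and
    ``g_ratio * J_E`` for inhibitory source populations; the matrix is
    divided by the maximal real part of its eigenvalues so the scaled
    spectrum has leading real part exactly one.  Edge distances are the
    natural log of the reciprocal weight; zero-weight edges are omitted
    (+inf distance).
    """
    K = np.asarray(K, dtype=float)
    if np.any(K < 0):
        raise InvalidArgumentError("indegrees must be nonnegative")
    ei = np.asarray(ei)
    absJ = np.where(ei == "E", J_E, g_ratio * J_E)
    G = K * absJ[None, :]
    lam = np.linalg.eigvals(G)
    lam_max = float(np.max(lam.real))
    if lam_max <= 0:
        raise InvalidStateError("maximal real eigenvalue part is not positive")
    W = G / lam_max
    with np.errstate(divide="ignore"):
        dist = np.where(W > 0, -np.log(np.where(W > 0, W, 1.0)), np.inf)
    sign = np.where(ei == "E", 1, -1)
    return GainGraph(
        nodes=list(nodes),
        weights=W,
        sign=sign,
        distances=dist.T.copy(),  # [source, target]
        J_E=J_E,
        J_I=-g_ratio * J_E,
        scale=lam_max,
    )


def bellman_ford_all_pairs(dist: np.ndarray, tol: float = 1e-12):
    """All-pairs shortest path distances and predecessors by Bellman-Ford.

    ``dist[j, k]`` is the edge distance j -> k (+inf absent); negative
    distances are allowed.  Relaxation proceeds in vectorized min-plus
    rounds with early stopping; an improving n-th round raises
    :class:`NegativeCycleError` with one offending cycle.  Tie-breaking is
    deterministic: among equal-distance alternatives the predecessor with
    the smallest node index is chosen.
    """
    n = dist.shape[0]
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    for rounds in range(n):
        cand = D[:, :, None] + dist[None, :, :]
        new = np.minimum(D, cand.min(axis=1))
        if np.all(new >= D - tol):
            D = np.minimum(D, new)
            break
        D = new
    else:
        # one extra improving round after n-1 relaxations: negative cycle
        cycle = _find_negative_cycle(dist, D, tol)
        raise NegativeCycleError(cycle)
    # verify stability (covers the early-exit path on exactly round n-1)
    cand = (D[:, :, None] + dist[None, :, :]).min(axis=1)
    if np.any(cand < D - tol):
        raise NegativeCycleError(_find_negative_cycle(dist, D, tol))
    # predecessors from the converged distances (smallest index on ties)
    pred = np.full((n, n), -1, dtype=int)
    for s in range(n):
        reach = np.isfinite(D[s])
        cand = D[s][:, None] + dist  # cand[j, k]
        with np.errstate(invalid="ignore"):
            ok = np.abs(cand - D[s][None, :]) <= tol * np.maximum(
                1.0, np.abs(D[s][None, :])
            )
        ok &= np.isfinite(cand)
        for k in np.flatnonzero(reach):
            if k == s:
                continue
            js = np.flatnonzero(ok[:, k])
            if len(js):
                pred[s, k] = js[0]
    return D, pred


def _find_negative_cycle(dist, D, tol):
    n = dist.shape[0]
    # locate a node still improving and walk predecessors until a repeat
    cand = D[:, :, None] + dist[None, :, :]
    best = cand.min(axis=1)
    with np.errstate(invalid="ignore"):
        diff = best - D
    diff[~np.isfinite(diff)] = np.inf
    s, k = np.unravel_index(np.argmin(diff), (n, n))
    # build a predecessor walk greedily on improving edges
    seen = []
    node = int(k)
    for _ in range(2 * n):
        j = int(np.argmin(D[s] + dist[:, node]))
        if j in seen:
            i = seen.index(j)
            return seen[i:] + [j]
        seen.append(node)
        node = j
    return seen[-min(len(seen), n):]


def _walk(pred_row: np.ndarray, s: int, k: int) -> list[int]:
    path = [k]
    while k != s:
        k = int(pred_row[k])
        if k < 0 or len(path) > len(pred_row):
            return []
        path.append(k)
    return path[::-1]


@dataclass
class PathSet:
    """Shortest paths between ordered area pairs on the gain graph."""

    paths: pd.DataFrame  # source_area, target_area, distance, nodes, ...
    D: np.ndarray
    nodes: list = field(default_factory=list)


def shortest_paths(
    gain: GainGraph,
    node_areas: np.ndarray,
    sources=None,
    targets=None,
) -> PathSet:
    """Shortest paths between every ordered pair of (distinct) areas.

    The path for a pair (B -> A) is the minimum-distance path over all
    start populations in B and end populations in A.  Returns a PathSet
    whose table holds, per pair, the node sequence (population labels),
    total distance, start/end populations and the intermediate areas.
    """
    D, pred = bellman_ford_all_pairs(gain.distances)
    node_areas = np.asarray(node_areas)
    areas = list(dict.fromkeys(node_areas))
    sources = areas if sources is None else list(sources)
    targets = areas if targets is None else list(targets)
    idx = {a: np.flatnonzero(node_areas == a) for a in areas}
    records = []
    for B in sources:
        for A in targets:
            if A == B:
                continue
            sub = D[np.ix_(idx[B], idx[A])]
            if not np.isfinite(sub).any():
                continue
            flat = np.argmin(sub)
            bi, ai = np.unravel_index(flat, sub.shape)
            s_node, t_node = int(idx[B][bi]), int(idx[A][ai])
            nodes_seq = _walk(pred[s_node], s_node, t_node)
            labels = [gain.nodes[x] for x in nodes_seq]
            inter_areas = []
            for x in nodes_seq:
                a = node_areas[x]
                if a not in (A, B) and (not inter_areas or inter_areas[-1] != a):
                    inter_areas.append(a)
            records.append(
                {
                    "source_area": B,
                    "target_area": A,
                    "distance": float(sub[bi, ai]),
                    "nodes": labels,
                    "start_pop": labels[0].split("-")[1],
                    "end_pop": labels[-1].split("-")[1],
                    "intermediate_areas": inter_areas,
                    "indirect": len(inter_areas) > 0,
                }
            )
    return PathSet(paths=pd.DataFrame(records), D=D, nodes=list(gain.nodes))


# ---------------------------------------------------------------------------
# path categorization


@dataclass
class PathPatternStats:
    """Frequency tables of shortest-path laminar patterns."""

    start_end_by_sln: dict  # category -> Counter of (start_pop, end_pop)
    start_end_by_type: dict  # category -> Counter of (start_pop, end_pop)
    relay_by_type: dict  # category -> Counter of relay pattern strings
    frac_indirect: float
    frac_direct_pairs_indirect: float


def categorize_and_summarize(
    pathset: PathSet,
    sln: pd.DataFrame,
    arch_types: pd.Series,
    binary: pd.DataFrame | None = None,
    sln_lo: float = 0.35,
    sln_hi: float = 0.65,
) -> PathPatternStats:
    """Summarize laminar patterns of shortest paths by category.

    Directly connected pairs are categorized feedforward / lateral /
    feedback by the SLN of the connection; all pairs are additionally
    categorized high-to-low / horizontal / low-to-high by the
    architectural-type difference between source and target.  For each
    category the table of (start population, end population) patterns and
    of within-relay-area population patterns is accumulated, along with
    the fraction of indirect shortest paths and the fraction of directly
    connected pairs whose shortest path is indirect.
    """
    paths = pathset.paths
    se_sln: dict = {}
    se_type: dict = {}
    relay: dict = {}
    n_direct_pairs = 0
    n_direct_pairs_indirect = 0
    for row in paths.itertuples():
        A, B = row.target_area, row.source_area
        t_diff = int(arch_types[B] - arch_types[A])
        tcat = "horizontal" if t_diff == 0 else ("high-to-low" if t_diff > 0 else "low-to-high")
        se_type.setdefault(tcat, Counter())[(row.start_pop, row.end_pop)] += 1
        connected = (
            binary is not None
            and bool(binary.at[A, B])
        )
        if connected:
            n_direct_pairs += 1
            if row.indirect:
                n_direct_pairs_indirect += 1
            s = sln.at[A, B] if np.isfinite(sln.at[A, B]) else np.nan
            if np.isfinite(s):
                scat = sln_category(s, sln_lo, sln_hi)
                se_sln.setdefault(scat, Counter())[(row.start_pop, row.end_pop)] += 1
        # relay patterns: consecutive populations inside intermediate areas
        if row.indirect:
            seq = row.nodes
            seq_areas = [x.split("-")[0] for x in seq]
            for inter in row.intermediate_areas:
                pops_in = [
                    x.split("-")[1] for x, a in zip(seq, seq_areas) if a == inter
                ]
                pattern = "->".join(dict.fromkeys(pops_in))
                relay.setdefault(tcat, Counter())[pattern] += 1
    frac_indirect = float(paths["indirect"].mean()) if len(paths) else 0.0
    frac_dpi = (
        n_direct_pairs_indirect / n_direct_pairs if n_direct_pairs else 0.0
    )
    return PathPatternStats(
        start_end_by_sln=se_sln,
        start_end_by_type=se_type,
        relay_by_type=relay,
        frac_indirect=frac_indirect,
        frac_direct_pairs_indirect=frac_dpi,
    )
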