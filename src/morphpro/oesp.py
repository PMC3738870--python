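"""Proteinize: snap a point sequence to the nearest protein-like sequence.

An arbitrary sequence of n points (typically a linear-interpolation
intermediate between two conformations) is corrected by dynamic programming
over per-point candidate lattices.  A corrected sequence is *protein-like*
when it is

* (a, eps)-equidistant - consecutive distances within [a - eps, a + eps],
  defaults a = 3.8 A, eps = 0.1 A (the C-alpha virtual bond length);
* (70, 120)-angle consistent - every interior C-alpha pseudo-bond angle
  within [70 deg, 120 deg];
* z-distance consistent - no two non-consecutive points closer than
  z = 2.0 A.

Scores along a lattice path:

* ``EScore`` (edge): 0 when the consecutive distance is inside the window,
  infinity otherwise; edges flagged as chain breaks are free.
* ``VScore`` (vertex): squared displacement from the lattice centre, plus a
  steric penalty ``100 * sum_m d(v, c_m)^-2`` over earlier lattice centres
  m <= j-2 when the vertex comes within z of any of them (see
  ``ScoreParams.clash_mode``).
* ``AScore`` (angle): 0 when the vertex angle is inside the window,
  infinity otherwise; angles flagged as chain breaks are free.

Three strategies solve the resulting shortest-path problem:

``proteinize_basic``
    equidistance only, O(n Q^2); exact for that objective.
``proteinize_advanced``
    equidistance + angles + steric VScore, exact via a pairwise-state
    recurrence, O(n Q^3); practical only for small lattices.
``proteinize_simplified``
    O(n Q^2) variant that checks each angle against the predecessor stored
    on the best path into the previous vertex.  Any structure it produces
    satisfies all constraints, but it may be suboptimal or fail on
    instances the advanced strategy can solve.  This is the default
    strategy of the full morph pipeline.

``brute_force_oesp`` enumerates every lattice path on tiny instances and is
used as the independent oracle in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .lattice import build_lattice

__all__ = [
    "ScoreParams",
    "ProteinizeResult",
    "escore",
    "vscore",
    "ascore",
    "vertex_angle",
    "line_angle",
    "proteinize_basic",
    "proteinize_advanced",
    "proteinize_simplified",
    "proteinize",
    "brute_force_oesp",
]

INF = float("inf")
#: numerical slack on the closed score windows (distances in A, cosines)
EPS = 1e-9


@dataclass(frozen=True)
class ScoreParams:
    """Geometric constants defining "protein-like" and the DP scores.

    target_dist / tol give the C-alpha virtual bond window [3.7, 3.9] A;
    angle_low / angle_high the pseudo-bond angle window in degrees;
    clash_dist the minimum allowed distance z between non-consecutive
    points; clash_penalty the multiplier of the inverse-square steric term.

    ``clash_mode`` selects when the steric penalty is added to VScore:
    "proximity" (default) adds it only for vertices within z of an earlier
    lattice centre; "literal" keys the branch on the distance to the
    vertex's *own* centre (which, being at most half the lattice diagonal,
    fires essentially always).
    """

    target_dist: float = 3.8
    tol: float = 0.1
    angle_low: float = 70.0
    angle_high: float = 120.0
    clash_dist: float = 2.0
    clash_penalty: float = 100.0
    clash_mode: str = "proximity"

    def __post_init__(self) -> None:
        if self.tol < 0 or self.clash_dist <= 0:
            raise ValueError("tol must be >= 0 and clash_dist > 0")
        if not self.angle_low < self.angle_high:
            raise ValueError("angle window must satisfy low < high")
        if self.clash_mode not in ("proximity", "literal"):
            raise ValueError("clash_mode must be 'proximity' or 'literal'")

    @property
    def dist_low(self) -> float:
        return self.target_dist - self.tol

    @property
    def dist_high(self) -> float:
        return self.target_dist + self.tol


@dataclass
class ProteinizeResult:
    """Outcome of one Proteinize run.

    ``points`` is the corrected sequence (None when infeasible);
    ``total_score`` the summed vertex/edge/angle score of the optimal path
    (infinite iff infeasible).
    """

    points: Optional[np.ndarray]
    total_score: float
    feasible: bool
    strategy: str = ""
    edge_length: float = 0.0

    def __post_init__(self) -> None:
        assert self.feasible == np.isfinite(self.total_score)


# ---------------------------------------------------------------------------
# scalar score primitives
# ---------------------------------------------------------------------------

def escore(u: np.ndarray, w: np.ndarray, broken: bool = False,
           params: ScoreParams = ScoreParams()) -> float:
    """Edge score: 0 iff the distance is in the bond window or the edge is a chain break."""
    if broken:
        return 0.0
    d = float(np.linalg.norm(np.asarray(u, float) - np.asarray(w, float)))
    return 0.0 if params.dist_low - EPS <= d <= params.dist_high + EPS else INF


def vertex_angle(q1: np.ndarray, q2: np.ndarray, q3: np.ndarray) -> float:
    """The pseudo-bond angle at q2 between rays q2->q1 and q2->q3, in [0, 180] deg.

    This is the quantity the (70, 120) angle window applies to.  The
    alternative reading - the minor angle between the two *lines*, which is
    confined to [0, 90] - is provided as :func:`line_angle`.
    """
    a = np.asarray(q1, float) - np.asarray(q2, float)
    b = np.asarray(q3, float) - np.asarray(q2, float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("degenerate angle: coincident points")
    cosv = float(np.clip(a @ b / (na * nb), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosv)))


def line_angle(q1: np.ndarray, q2: np.ndarray, q3: np.ndarray) -> float:
    """Minor angle between the line through q1,q2 and the line through q2,q3 (in [0, 90])."""
    theta = vertex_angle(q1, q2, q3)
    return min(theta, 180.0 - theta)


def ascore(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, broken: bool = False,
           params: ScoreParams = ScoreParams()) -> float:
    """Angle score: 0 iff the vertex angle at p2 is in the window or the angle is free."""
    if broken:
        return 0.0
    theta = vertex_angle(p1, p2, p3)
    return 0.0 if params.angle_low - EPS <= theta <= params.angle_high + EPS else INF


def _vscores(vertices: np.ndarray, center: np.ndarray, earlier_centers: np.ndarray,
             params: ScoreParams, steric: bool) -> np.ndarray:
    """Vector of VScore over all lattice vertices."""
    vertices = np.atleast_2d(np.asarray(vertices, float))
    base = np.sum((vertices - np.asarray(center, float)) ** 2, axis=1)
    if not steric or len(earlier_centers) == 0 or params.clash_penalty == 0:
        return base
    d2 = cdist(vertices, np.atleast_2d(earlier_centers), "sqeuclidean")
    with np.errstate(divide="ignore"):
        penalty = params.clash_penalty * np.where(d2 > 0, 1.0 / np.where(d2 > 0, d2, 1.0), INF).sum(axis=1)
    if params.clash_mode == "literal":
        trigger = base <= params.clash_dist ** 2 + EPS
    else:
        trigger = d2.min(axis=1) <= params.clash_dist ** 2 + EPS
    return base + np.where(trigger, penalty, 0.0)


def vscore(v: np.ndarray, own_center: np.ndarray,
           earlier_centers: Optional[Sequence[np.ndarray]] = None,
           params: ScoreParams = ScoreParams()) -> float:
    """Vertex score of one candidate point: squared displacement + steric penalty."""
    earlier = np.array(earlier_centers, dtype=float).reshape(-1, 3) if earlier_centers is not None else np.empty((0, 3))
    return float(_vscores(np.asarray(v, float)[None, :], own_center, earlier, params, steric=True)[0])


# ---------------------------------------------------------------------------
# shared DP plumbing
# ---------------------------------------------------------------------------

def _normalize_flags(n: int, broken_edge, broken_angle) -> tuple[np.ndarray, np.ndarray]:
    be = np.zeros(n - 1, bool) if broken_edge is None else np.asarray(broken_edge, bool).copy()
    ba = np.zeros(n, bool) if broken_angle is None else np.asarray(broken_angle, bool).copy()
    if be.shape != (n - 1,) or ba.shape != (n,):
        raise ValueError("flag arrays must have lengths n-1 and n")
    ba[0] = ba[-1] = True  # no angle at the termini, by convention
    return be, ba


def _setup(points, params, edge_length, density, broken_edge, broken_angle,
           steric: bool):
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3 or len(points) < 2:
        raise ValueError("points must be an (n, 3) array with n >= 2")
    n = len(points)
    be, ba = _normalize_flags(n, broken_edge, broken_angle)
    lattices = [build_lattice(p, edge_length, density) for p in points]
    vs = [
        _vscores(lat.vertices, lat.center, points[: max(j - 1, 0)], params, steric)
        for j, lat in enumerate(lattices)
    ]
    return points, n, be, ba, lattices, vs


def _edge_feasible(vtx_prev: np.ndarray, vtx_next: np.ndarray, broken: bool,
                   params: ScoreParams) -> np.ndarray:
    """(Q_prev, Q_next) boolean mask of bond-window feasibility."""
    if broken:
        return np.ones((len(vtx_prev), len(vtx_next)), bool)
    d = cdist(vtx_prev, vtx_next)
    return (d >= params.dist_low - EPS) & (d <= params.dist_high + EPS)


def _cos_window(params: ScoreParams) -> tuple[float, float]:
    # angle in [low, high]  <=>  cos(angle) in [cos(high), cos(low)]
    return (np.cos(np.radians(params.angle_high)), np.cos(np.radians(params.angle_low)))


def _angle_feasible(prev_pts: np.ndarray, mids: np.ndarray, nxt: np.ndarray,
                    params: ScoreParams) -> np.ndarray:
    """(Q_mid, Q_next) mask: angle at mids[h] between prev_pts[h] and nxt[i].

    ``prev_pts`` supplies one predecessor point per middle vertex (the
    simplified strategy's stored best-path predecessor).
    """
    u = prev_pts - mids                        # (Qh, 3)
    w = nxt[None, :, :] - mids[:, None, :]     # (Qh, Qi, 3)
    nu = np.linalg.norm(u, axis=1)
    nw = np.linalg.norm(w, axis=2)
    denom = nu[:, None] * nw
    with np.errstate(invalid="ignore", divide="ignore"):
        cosv = np.einsum("hd,hid->hi", u, w) / denom
    cosv = np.where(denom > 0, cosv, 2.0)      # degenerate arms: infeasible
    lo, hi = _cos_window(params)
    return (cosv >= lo - EPS) & (cosv <= hi + EPS)


def _infeasible(strategy: str, edge_length: float) -> ProteinizeResult:
    return ProteinizeResult(None, INF, False, strategy, edge_length)


# ---------------------------------------------------------------------------
# basic strategy: equidistance only, O(n Q^2)
# ---------------------------------------------------------------------------

def proteinize_basic(points, params: ScoreParams = ScoreParams(), edge_length: float = 1.0,
                     density: float = 6, broken_edge=None, broken_angle=None) -> ProteinizeResult:
    """Exact optimal equidistant approximation over the discretized space.

    Only the bond-length window is enforced (no angle or steric terms); the
    objective is the summed squared displacement from the interpolated
    points.
    """
    points, n, be, _ba, lattices, vs = _setup(
        points, params, edge_length, density, broken_edge, broken_angle, steric=False)
    path = vs[0].copy()
    backs: list[np.ndarray] = []
    for j in range(1, n):
        ok = _edge_feasible(lattices[j - 1].vertices, lattices[j].vertices, be[j - 1], params)
        cand = np.where(ok, path[:, None], INF)
        backs.append(np.argmin(cand, axis=0))
        path = vs[j] + cand.min(axis=0)
    i = int(np.argmin(path))
    best = float(path[i])
    if not np.isfinite(best):
        return _infeasible("basic", edge_length)
    idx = [i]
    for back in reversed(backs):
        idx.append(int(back[idx[-1]]))
    idx.reverse()
    out = np.array([lattices[j].vertices[idx[j]] for j in range(n)])
    return ProteinizeResult(out, best, True, "basic", edge_length)


# ---------------------------------------------------------------------------
# simplified strategy: greedy-history angles, O(n Q^2)
# ---------------------------------------------------------------------------

def proteinize_simplified(points, params: ScoreParams = ScoreParams(), edge_length: float = 1.0,
                          density: float = 6, broken_edge=None, broken_angle=None) -> ProteinizeResult:
    """Angle- and clash-aware DP that stores one predecessor per vertex.

    The angle at position j-1 is checked against the predecessor recorded on
    the best path into each candidate vertex there, keeping the recurrence
    O(n Q^2).  Sound (any output satisfies all constraints) but possibly
    suboptimal, and it can fail where the advanced strategy succeeds.
    """
    points, n, be, ba, lattices, vs = _setup(
        points, params, edge_length, density, broken_edge, broken_angle, steric=True)
    path = vs[0].copy()
    prev_pts: Optional[np.ndarray] = None  # best-path predecessor coords per vertex of lattice j-1
    backs: list[np.ndarray] = []
    for j in range(1, n):
        qj = lattices[j].q
        cand = np.where(
            _edge_feasible(lattices[j - 1].vertices, lattices[j].vertices, be[j - 1], params),
            path[:, None], INF)
        if prev_pts is not None and not ba[j - 1]:
            ok_a = _angle_feasible(prev_pts, lattices[j - 1].vertices, lattices[j].vertices, params)
            cand = np.where(ok_a, cand, INF)
        back = np.argmin(cand, axis=0)
        path = vs[j] + cand[back, np.arange(qj)]
        prev_pts = lattices[j - 1].vertices[back]
        backs.append(back)
    i = int(np.argmin(path))
    best = float(path[i])
    if not np.isfinite(best):
        return _infeasible("simplified", edge_length)
    idx = [i]
    for back in reversed(backs):
        idx.append(int(back[idx[-1]]))
    idx.reverse()
    out = np.array([lattices[j].vertices[idx[j]] for j in range(n)])
    return ProteinizeResult(out, best, True, "simplified", edge_length)


# ---------------------------------------------------------------------------
# advanced strategy: exact pairwise-state DP, O(n Q^3)
# ---------------------------------------------------------------------------

def proteinize_advanced(points, params: ScoreParams = ScoreParams(), edge_length: float = 1.0,
                        density: float = 6, broken_edge=None, broken_angle=None) -> ProteinizeResult:
    """Exact optimum including angle and steric terms, via pairwise states.

    The DP state is the pair (current vertex, previous vertex), so every
    feasible path is considered; cost grows as O(n Q^3), which restricts it
    in practice to small lattices or short chains.  For n = 2 there are no
    angles and the basic recurrence (with steric VScore) is used.
    """
    points, n, be, ba, lattices, vs = _setup(
        points, params, edge_length, density, broken_edge, broken_angle, steric=True)
    if n == 2:
        ok = _edge_feasible(lattices[0].vertices, lattices[1].vertices, be[0], params)
        cand = np.where(ok, vs[0][:, None], INF) + vs[1][None, :]
        h, i = np.unravel_index(int(np.argmin(cand)), cand.shape)
        best = float(cand[h, i])
        if not np.isfinite(best):
            return _infeasible("advanced", edge_length)
        out = np.array([lattices[0].vertices[h], lattices[1].vertices[i]])
        return ProteinizeResult(out, best, True, "advanced", edge_length)

    lo, hi = _cos_window(params)
    # m[i, h]: best score of a path ending at vertex i of lattice j that
    # passes through vertex h of lattice j-1.
    ok01 = _edge_feasible(lattices[0].vertices, lattices[1].vertices, be[0], params)
    m = vs[1][:, None] + np.where(ok01.T, 0.0, INF) + vs[0][None, :]
    arg_g: list[np.ndarray] = []
    for j in range(2, n):
        vtx_g, vtx_h, vtx_i = (lattices[j - 2].vertices, lattices[j - 1].vertices,
                               lattices[j].vertices)
        qg, qh, qi = len(vtx_g), len(vtx_h), len(vtx_i)
        ok_e = _edge_feasible(vtx_h, vtx_i, be[j - 1], params)  # (Qh, Qi)
        new = np.full((qi, qh), INF)
        g_ptr = np.zeros((qi, qh), dtype=np.int32)
        for h in range(qh):
            row = m[h, :]  # min over g: paths whose latest vertex is h of lattice j-1
            if not np.any(np.isfinite(row)):
                continue
            if ba[j - 1]:
                g = int(np.argmin(row))
                inner = np.full(qi, row[g])
                g_col = np.full(qi, g, dtype=np.int32)
            else:
                u = vtx_g - vtx_h[h]            # (Qg, 3)
                w = vtx_i - vtx_h[h]            # (Qi, 3)
                nu = np.linalg.norm(u, axis=1)
                nw = np.linalg.norm(w, axis=1)
                denom = nu[:, None] * nw[None, :]
                with np.errstate(invalid="ignore", divide="ignore"):
                    cosv = (u @ w.T) / denom
                cosv = np.where(denom > 0, cosv, 2.0)
                ok_a = (cosv >= lo - EPS) & (cosv <= hi + EPS)   # (Qg, Qi)
                cand = np.where(ok_a, row[:, None], INF)
                g_col = np.argmin(cand, axis=0).astype(np.int32)
                inner = cand[g_col, np.arange(qi)]
            new[:, h] = vs[j] + np.where(ok_e[h], 0.0, INF) + inner
            g_ptr[:, h] = g_col
        m = new
        arg_g.append(g_ptr)
    i, h = np.unravel_index(int(np.argmin(m)), m.shape)
    best = float(m[i, h])
    if not np.isfinite(best):
        return _infeasible("advanced", edge_length)
    idx = [int(i), int(h)]  # lattice n-1, n-2, ... built backwards
    for g_ptr in reversed(arg_g):
        idx.append(int(g_ptr[idx[-2], idx[-1]]))
    idx.reverse()
    out = np.array([lattices[j].vertices[idx[j]] for j in range(n)])
    return ProteinizeResult(out, best, True, "advanced", edge_length)


_STRATEGIES = {
    "basic": proteinize_basic,
    "advanced": proteinize_advanced,
    "simplified": proteinize_simplified,
}


def proteinize(points, strategy: str = "simplified", **kwargs) -> ProteinizeResult:
    """Dispatch to one of the three strategies by name."""
    try:
        fn = _STRATEGIES[strategy]
    except KeyError:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {sorted(_STRATEGIES)}")
    return fn(points, **kwargs)


# ---------------------------------------------------------------------------
# exhaustive oracle (test support; tiny instances only)
# ---------------------------------------------------------------------------

def brute_force_oesp(points, params: ScoreParams = ScoreParams(), edge_length: float = 1.0,
                     density: float = 6, broken_edge=None, broken_angle=None,
                     include_angles: bool = True, include_steric: bool = True,
                     max_paths: int = 10 ** 7) -> ProteinizeResult:
    """Global optimum by enumerating every lattice path (Q^n of them).

    Scores each full path with the complete objective (or, with
    ``include_angles=False, include_steric=False``, the equidistance-only
    objective of the basic strategy).  Intended as an independent
    correctness oracle; refuses instances with more than ``max_paths``
    paths.
    """
    points, n, be, ba, lattices, vs = _setup(
        points, params, edge_length, density, broken_edge, broken_angle, steric=include_steric)
    q = lattices[0].q
    if q ** n > max_paths:
        raise ValueError(f"instance too large for enumeration: Q^n = {q}^{n} > {max_paths}")
    shape = (q,) * n
    total = np.zeros(shape)
    for j in range(n):
        sh = [1] * n
        sh[j] = q
        total = total + vs[j].reshape(sh)
    for j in range(n - 1):
        if be[j]:
            continue
        d = cdist(lattices[j].vertices, lattices[j + 1].vertices)
        e = np.where((d >= params.dist_low - EPS) & (d <= params.dist_high + EPS), 0.0, INF)
        sh = [1] * n
        sh[j], sh[j + 1] = q, q
        total = total + e.reshape(sh)
    if include_angles:
        lo, hi = _cos_window(params)
        for j in range(1, n - 1):
            if ba[j]:
                continue
            u = lattices[j - 1].vertices[:, None, :] - lattices[j].vertices[None, :, :]  # (g, h, 3)
            w = lattices[j + 1].vertices[None, :, :] - lattices[j].vertices[:, None, :]  # (h, i, 3)
            nu = np.linalg.norm(u, axis=2)      # (g, h)
            nw = np.linalg.norm(w, axis=2)      # (h, i)
            denom = nu[:, :, None] * nw[None, :, :]
            with np.errstate(invalid="ignore", divide="ignore"):
                cosv = np.einsum("ghd,hid->ghi", u, w) / denom
            cosv = np.where(denom > 0, cosv, 2.0)
            a = np.where((cosv >= lo - EPS) & (cosv <= hi + EPS), 0.0, INF)
            sh = [1] * n
            sh[j - 1], sh[j], sh[j + 1] = q, q, q
            total = total + a.reshape(sh)
    flat = int(np.argmin(total))
    best = float(total.ravel()[flat])
    if not np.isfinite(best):
        return _infeasible("brute_force", edge_length)
    idx = np.unravel_index(flat, shape)
    out = np.array([lattices[j].vertices[idx[j]] for j in range(n)])
    return ProteinizeResult(out, best, True, "brute_force", edge_length)
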