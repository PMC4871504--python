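"""Reciprocal collision avoidance in 3D: the f_R operator.

The dynamics model produces a *preferred* velocity for every insect; this
module maps the set of preferred velocities to actual velocities that are
pairwise collision-free over a short time horizon.  Each neighbor induces a
half-space constraint on the agent's velocity (an ORCA plane, derived from
the truncated velocity-obstacle cone), both agents taking half of the
required avoidance effort.  Within the feasible region intersected with the
maximum-speed sphere, each agent adopts the velocity closest (2-norm) to its
preferred one, found by an incremental linear program.  When the program is
infeasible (very dense packings) the configured fallback applies: freeze the
agent for one frame, or rebuild the collision constraints with a halved
time step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog
from scipy.spatial import cKDTree

__all__ = ["AvoidanceConfig", "SphereObstacle", "resolve_velocities"]

_EPS = 1e-10


@dataclass
class SphereObstacle:
    """Static spherical obstacle (e.g. the lamp in the phototaxis scene)."""

    center: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.radius <= 0:
            raise ValueError("obstacle radius must be > 0")


@dataclass
class AvoidanceConfig:
    """Parameters of the reciprocal avoidance operator.

    ``agent_radius`` is the collision radius of one insect (half the
    separation the contract guarantees); ``time_horizon`` is how far ahead
    (seconds) mutual collisions are forbidden; ``dt`` the integration step.
    ``max_neighbors`` caps the constraint count per agent for speed.
    """

    agent_radius: float = 0.05
    time_horizon: float = 0.25
    max_speed: float = 5.0
    dt: float = 1.0 / 60.0
    infeasible_policy: str = "zero_velocity"
    max_neighbors: int = 10
    obstacles: list[SphereObstacle] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("agent_radius", "time_horizon", "max_speed", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.time_horizon < self.dt:
            raise ValueError("time_horizon must be >= dt")
        if self.infeasible_policy not in ("zero_velocity", "halve_step"):
            raise ValueError("infeasible_policy must be 'zero_velocity' or 'halve_step'")


# ---------------------------------------------------------------------------
# ORCA plane construction
# ---------------------------------------------------------------------------

def _orca_plane(rel_pos, rel_vel, combined_radius, inv_horizon, inv_dt):
    """Normal and reciprocal correction u for one agent pair.

    Returns (normal, u) such that the half-space constraint for the agent is
    (v - (v_current + share * u)) . normal >= 0.
    """
    dist_sq = float(rel_pos @ rel_pos)
    r_sq = combined_radius * combined_radius

    if dist_sq > r_sq:
        # no current overlap: truncated cone apex at rel_pos / horizon
        w = rel_vel - inv_horizon * rel_pos
        w_len_sq = float(w @ w)
        dot1 = float(w @ rel_pos)
        if dot1 < 0.0 and dot1 * dot1 > r_sq * w_len_sq:
            # project on the cut-off sphere
            w_len = math.sqrt(w_len_sq)
            unit_w = w / w_len if w_len > _EPS else _perp_unit(rel_pos)
            normal = unit_w
            u = (combined_radius * inv_horizon - w_len) * unit_w
        else:
            # project on the cone surface
            a = dist_sq
            b = float(rel_pos @ rel_vel)
            cr = np.cross(rel_pos, rel_vel)
            c = float(rel_vel @ rel_vel) - float(cr @ cr) / (dist_sq - r_sq)
            t = (b + math.sqrt(max(b * b - a * c, 0.0))) / a
            ww = rel_vel - t * rel_pos
            ww_len = float(np.linalg.norm(ww))
            # relative tolerance: rounding noise in ww gives an arbitrary
            # direction, so near-axis courses use the exact axis escape
            if ww_len > 1e-6 * (combined_radius * t + math.sqrt(float(rel_vel @ rel_vel))):
                unit_w = ww / ww_len
                normal = unit_w
                u = (combined_radius * t - ww_len) * unit_w
            else:
                normal, u = _axis_escape(rel_pos, rel_vel, dist_sq, r_sq)
    else:
        # already overlapping: push apart within one time step
        w = rel_vel - inv_dt * rel_pos
        w_len = float(np.linalg.norm(w))
        if w_len > _EPS:
            unit_w = w / w_len
        else:
            n = float(np.linalg.norm(rel_pos))
            unit_w = -rel_pos / n if n > _EPS else np.array([1.0, 0.0, 0.0])
            w_len = 0.0
        normal = unit_w
        u = (combined_radius * inv_dt - w_len) * unit_w
    return normal, u


# ---------------------------------------------------------------------------
# incremental linear program on the max-speed sphere
# ---------------------------------------------------------------------------

def _perp_unit(v):
    """Deterministic unit vector perpendicular to v."""
    a = np.abs(v)
    e = np.zeros(3)
    e[int(np.argmin(a))] = 1.0
    p = np.array(
        [
            v[1] * e[2] - v[2] * e[1],
            v[2] * e[0] - v[0] * e[2],
            v[0] * e[1] - v[1] * e[0],
        ]
    )
    n = math.sqrt(float(p @ p))
    return p / n if n > _EPS else np.array([1.0, 0.0, 0.0])


def _axis_escape(rel_pos, rel_vel, dist_sq, r_sq):
    """Exact cone projection for a relative velocity lying on the cone axis
    (dead-center collision course): escape along the cone's surface normal,
    which tilts the course sideways and slightly brakes it.  Returns
    (normal, u)."""
    p_norm = math.sqrt(dist_sq)
    phat = rel_pos / p_norm
    sin_t = math.sqrt(r_sq) / p_norm
    cos_t = math.sqrt(max(1.0 - sin_t * sin_t, 0.0))
    perp = _perp_unit(rel_pos)
    normal = cos_t * perp - sin_t * phat
    speed = math.sqrt(float(rel_vel @ rel_vel))
    return normal, (speed * sin_t) * normal


def _cross3(a, b):
    return np.array(
        [
            a[1] * b[2] - a[2] * b[1],
            a[2] * b[0] - a[0] * b[2],
            a[0] * b[1] - a[1] * b[0],
        ]
    )


def _first_violation(pts, nrms, start, stop, v):
    """Index of the first plane in [start, stop) violated by v, or -1."""
    if start >= stop:
        return -1
    slack = np.einsum("ij,ij->i", v - pts[start:stop], nrms[start:stop])
    bad = np.flatnonzero(slack < -_EPS)
    return -1 if bad.size == 0 else start + int(bad[0])


def _lp_line(pts, nrms, count, line_pt, line_dir, radius, opt_v):
    """Closest point to opt_v on a line segment inside the sphere subject to
    planes 0..count-1.  Returns None when infeasible."""
    dot = float(line_pt @ line_dir)
    disc = dot * dot + radius * radius - float(line_pt @ line_pt)
    if disc < 0.0:
        return None
    sq = math.sqrt(disc)
    t_left, t_right = -dot - sq, -dot + sq

    if count:
        denom = nrms[:count] @ line_dir
        dist = np.einsum("ij,ij->i", pts[:count] - line_pt, nrms[:count])
        par = np.abs(denom) <= _EPS
        if np.any(dist[par] > 0.0):
            return None
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(par, 0.0, dist / np.where(par, 1.0, denom))
        pos = denom > _EPS
        neg = denom < -_EPS
        if np.any(pos):
            t_left = max(t_left, float(t[pos].max()))
        if np.any(neg):
            t_right = min(t_right, float(t[neg].min()))
        if t_left > t_right:
            return None

    t_opt = float((opt_v - line_pt) @ line_dir)
    t_opt = min(max(t_opt, t_left), t_right)
    return line_pt + t_opt * line_dir


def _lp_plane(pts, nrms, count, plane_pt, plane_n, radius, opt_v):
    """Closest point to opt_v on a plane, inside the sphere, subject to
    planes 0..count-1.  Returns None when infeasible."""
    plane_dist = float(plane_pt @ plane_n)
    if plane_dist * plane_dist > radius * radius:
        return None  # the plane misses the max-speed sphere entirely

    v = opt_v - float((opt_v - plane_pt) @ plane_n) * plane_n
    if float(v @ v) > radius * radius:
        # pull back onto the circle where the plane cuts the sphere
        c0 = plane_dist * plane_n
        rc = math.sqrt(max(radius * radius - plane_dist * plane_dist, 0.0))
        d = v - c0
        dn = math.sqrt(float(d @ d))
        if dn <= _EPS:
            # pick any in-plane direction
            ref = np.array([1.0, 0.0, 0.0])
            if abs(float(ref @ plane_n)) > 0.9:
                ref = np.array([0.0, 1.0, 0.0])
            d = _cross3(plane_n, ref)
            dn = math.sqrt(float(d @ d))
        v = c0 + rc * d / dn

    k = _first_violation(pts, nrms, 0, count, v)
    while k >= 0:
        cross_d = _cross3(plane_n, nrms[k])
        cn = math.sqrt(float(cross_d @ cross_d))
        if cn <= _EPS:
            return None  # parallel conflicting planes
        line_dir = cross_d / cn
        n1n2 = float(plane_n @ nrms[k])
        d1 = float(plane_pt @ plane_n)
        d2 = float(pts[k] @ nrms[k])
        det = 1.0 - n1n2 * n1n2
        a = (d1 - d2 * n1n2) / det
        b = (d2 - d1 * n1n2) / det
        line_pt = a * plane_n + b * nrms[k]
        v = _lp_line(pts, nrms, k, line_pt, line_dir, radius, opt_v)
        if v is None:
            return None
        k = _first_violation(pts, nrms, k + 1, count, v)
    return v


def _lp_solve(pts, nrms, radius, opt_v):
    """Minimize ||v - opt_v|| subject to all planes and |v| <= radius.

    Returns (v, feasible).  On infeasibility v holds the best velocity found
    before the failing constraint.
    """
    pts = np.asarray(pts, dtype=float).reshape(-1, 3)
    nrms = np.asarray(nrms, dtype=float).reshape(-1, 3)
    n_opt = math.sqrt(float(opt_v @ opt_v))
    v = opt_v if n_opt <= radius else opt_v * (radius / n_opt)
    i = _first_violation(pts, nrms, 0, len(pts), v)
    while i >= 0:
        v_new = _lp_plane(pts, nrms, i, pts[i], nrms[i], radius, opt_v)
        if v_new is None:
            return v, False
        v = v_new
        i = _first_violation(pts, nrms, i + 1, len(pts), v)
    return v, True


# ---------------------------------------------------------------------------
# vectorized plane construction
# ---------------------------------------------------------------------------

def _orca_planes_batch(rel_pos, rel_vel, combined_radius, inv_horizon, inv_dt):
    """Vectorized :func:`_orca_plane` for (m, 3) pair arrays.

    ``combined_radius`` may be scalar or an (m,) array (obstacles).
    Returns (normals (m, 3), u (m, 3)).
    """
    m = len(rel_pos)
    r = np.broadcast_to(np.asarray(combined_radius, dtype=float), (m,))
    dist_sq = np.einsum("ij,ij->i", rel_pos, rel_pos)
    r_sq = r * r
    no_col = dist_sq > r_sq

    normals = np.empty((m, 3))
    u = np.empty((m, 3))

    # --- separated agents: truncated-cone obstacle ---
    w = rel_vel - inv_horizon * rel_pos
    w_len_sq = np.einsum("ij,ij->i", w, w)
    dot1 = np.einsum("ij,ij->i", w, rel_pos)
    sphere = no_col & (dot1 < 0.0) & (dot1 * dot1 > r_sq * w_len_sq)
    if np.any(sphere):
        w_len = np.sqrt(w_len_sq[sphere])
        safe = np.where(w_len > _EPS, w_len, 1.0)
        unit_w = w[sphere] / safe[:, None]
        for idx in np.flatnonzero(w_len <= _EPS):
            unit_w[idx] = _perp_unit(rel_pos[sphere][idx])
        normals[sphere] = unit_w
        u[sphere] = (r[sphere] * inv_horizon - w_len)[:, None] * unit_w

    cone = no_col & ~sphere
    if np.any(cone):
        rp, rv = rel_pos[cone], rel_vel[cone]
        a = dist_sq[cone]
        b = np.einsum("ij,ij->i", rp, rv)
        cr = np.cross(rp, rv)
        denom = a - r_sq[cone]
        c = np.einsum("ij,ij->i", rv, rv) - np.einsum("ij,ij->i", cr, cr) / denom
        t = (b + np.sqrt(np.maximum(b * b - a * c, 0.0))) / a
        ww = rv - t[:, None] * rp
        ww_len = np.sqrt(np.einsum("ij,ij->i", ww, ww))
        speed = np.sqrt(np.einsum("ij,ij->i", rv, rv))
        tol = 1e-6 * (r[cone] * t + speed)
        safe = np.where(ww_len > tol, ww_len, 1.0)
        unit_w = ww / safe[:, None]
        nrm_c = unit_w.copy()
        u_c = (r[cone] * t - ww_len)[:, None] * unit_w
        for idx in np.flatnonzero(ww_len <= tol):
            nrm_c[idx], u_c[idx] = _axis_escape(
                rp[idx], rv[idx], dist_sq[cone][idx], r_sq[cone][idx]
            )
        normals[cone] = nrm_c
        u[cone] = u_c

    # --- overlapping agents: push apart within one step ---
    col = ~no_col
    if np.any(col):
        wc = rel_vel[col] - inv_dt * rel_pos[col]
        w_len = np.sqrt(np.einsum("ij,ij->i", wc, wc))
        safe = np.where(w_len > _EPS, w_len, 1.0)
        unit_w = wc / safe[:, None]
        degen = w_len <= _EPS
        if np.any(degen):
            rp = rel_pos[col][degen]
            d = np.sqrt(np.einsum("ij,ij->i", rp, rp))
            fallback = np.where(
                d[:, None] > _EPS, -rp / np.where(d > _EPS, d, 1.0)[:, None],
                np.array([1.0, 0.0, 0.0]),
            )
            unit_w[degen] = fallback
            w_len = np.where(degen, 0.0, w_len)
        normals[col] = unit_w
        u[col] = (r[col] * inv_dt - w_len)[:, None] * unit_w
    return normals, u


# ---------------------------------------------------------------------------
# public operator
# ---------------------------------------------------------------------------

def resolve_velocities(
    positions: np.ndarray,
    velocities: np.ndarray,
    preferred: np.ndarray,
    cfg: AvoidanceConfig,
    obstacles: list[SphereObstacle] | None = None,
) -> np.ndarray:
    """Map preferred velocities to reciprocally collision-free velocities.

    Every returned velocity satisfies ``|v| <= max_speed`` and, jointly with
    all the others, keeps pairwise separations >= 2 * agent_radius over the
    time horizon.  Agents with no feasible velocity follow
    ``cfg.infeasible_policy``.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    velocities = np.atleast_2d(np.asarray(velocities, dtype=float))
    preferred = np.atleast_2d(np.asarray(preferred, dtype=float))
    n = len(positions)
    if not (len(velocities) == len(preferred) == n):
        raise ValueError("positions, velocities and preferred must have equal length")
    if obstacles is None:
        obstacles = cfg.obstacles

    # clip preferred speeds first; a single agent then passes through
    out = preferred.copy()
    speeds = np.linalg.norm(out, axis=1)
    fast = speeds > cfg.max_speed
    if np.any(fast):
        out[fast] *= (cfg.max_speed / speeds[fast])[:, None]

    # neighbor pairs that could interact within the horizon
    cutoff = 2.0 * cfg.agent_radius + 2.0 * cfg.max_speed * cfg.time_horizon
    pair_list: list[tuple[int, int]] = []
    if n > 1:
        tree = cKDTree(positions)
        prs = tree.query_pairs(cutoff, output_type="ndarray")
        if len(prs):
            d = np.linalg.norm(positions[prs[:, 0]] - positions[prs[:, 1]], axis=1)
            # pairs that can reach contact within one integration step are
            # always constrained; the capacity cap only thins the rest
            must = 2.0 * cfg.agent_radius + 2.0 * cfg.max_speed * cfg.dt
            order = np.argsort(d, kind="stable")
            counts = np.zeros(n, dtype=int)
            for idx in order:
                i, j = int(prs[idx, 0]), int(prs[idx, 1])
                # keep the pair relation symmetric: reciprocity assumes both
                # agents constrain against each other, so a pair is included
                # for both or neither (closest pairs claim capacity first)
                if (
                    d[idx] <= must
                    or counts[i] < cfg.max_neighbors
                    or counts[j] < cfg.max_neighbors
                ):
                    pair_list.append((i, j))
                    counts[i] += 1
                    counts[j] += 1

    inv_h = 1.0 / cfg.time_horizon
    inv_dt = 1.0 / cfg.dt
    combined = 2.0 * cfg.agent_radius

    # directed pairs a -> b (constraint on a induced by b)
    plane_owner: np.ndarray
    if pair_list:
        und = np.array(pair_list, dtype=int)
        a = np.concatenate([und[:, 0], und[:, 1]])
        b = np.concatenate([und[:, 1], und[:, 0]])
        normals, u = _orca_planes_batch(
            positions[b] - positions[a],
            velocities[a] - velocities[b],
            combined, inv_h, inv_dt,
        )
        pts = velocities[a] + 0.5 * u
        plane_owner = a
    else:
        plane_owner = np.empty(0, dtype=int)
        normals = np.empty((0, 3))
        pts = np.empty((0, 3))

    # obstacle planes (no reciprocity: the agent takes the full correction)
    if obstacles:
        oa, orel, orad = [], [], []
        for obs in obstacles:
            rel = obs.center - positions
            close = np.einsum("ij,ij->i", rel, rel) <= (cutoff + obs.radius) ** 2
            for i in np.flatnonzero(close):
                oa.append(i)
                orel.append(rel[i])
                orad.append(obs.radius + cfg.agent_radius)
        if oa:
            oa = np.array(oa, dtype=int)
            on, ou = _orca_planes_batch(
                np.array(orel), velocities[oa], np.array(orad), inv_h, inv_dt
            )
            # obstacle planes first: they keep priority in the incremental LP
            plane_owner = np.concatenate([oa, plane_owner])
            normals = np.concatenate([on, normals])
            pts = np.concatenate([velocities[oa] + ou, pts])

    if len(plane_owner) == 0:
        return out

    # group planes per agent, obstacle planes leading
    order = np.argsort(plane_owner, kind="stable")
    owner_sorted = plane_owner[order]
    pts_sorted = pts[order]
    nrm_sorted = normals[order]
    starts = np.searchsorted(owner_sorted, np.arange(n))
    ends = np.searchsorted(owner_sorted, np.arange(n), side="right")

    # fast path: agents whose clipped preferred velocity already satisfies
    # every constraint keep it
    slack = np.einsum("ij,ij->i", out[owner_sorted] - pts_sorted, nrm_sorted)
    viol_owners = np.unique(owner_sorted[slack < -_EPS])

    for i in viol_owners:
        p_i = pts_sorted[starts[i]:ends[i]]
        n_i = nrm_sorted[starts[i]:ends[i]]
        v, ok = _lp_solve(p_i, n_i, cfg.max_speed, out[i])
        if ok:
            out[i] = v
            continue
        # no velocity satisfies every constraint: take the least-penetrating
        # one (maximize the minimum constraint slack), so the agent still
        # backs away from its neighbors as hard as it can
        v = _least_penetration(p_i, n_i, cfg.max_speed)
        if v is not None:
            out[i] = v
            continue
        out[i] = _infeasible_fallback(
            positions, velocities, i, p_i, n_i, out[i],
            combined, inv_h, inv_dt, cfg, obstacles,
        )
    return out


def _least_penetration(pts, nrms, radius):
    """Velocity maximizing the minimum slack over all half-space
    constraints (the standard completion of the avoidance operator when the
    constraint set is empty).  Solved as a small linear program with box
    bounds, then clipped to the speed sphere."""
    k = len(pts)
    # maximize s  s.t.  (v - p_j) . n_j >= s  ->  -n_j . v + s <= -p_j . n_j
    a_ub = np.empty((k, 4))
    a_ub[:, :3] = -nrms
    a_ub[:, 3] = 1.0
    b_ub = -np.einsum("ij,ij->i", pts, nrms)
    res = linprog(
        c=[0.0, 0.0, 0.0, -1.0],
        A_ub=a_ub,
        b_ub=b_ub,
        bounds=[(-radius, radius)] * 3 + [(None, None)],
        method="highs",
    )
    if not res.success:  # pragma: no cover - tiny LPs essentially always solve
        return None
    v = res.x[:3]
    speed = math.sqrt(float(v @ v))
    if speed > radius:
        v = v * (radius / speed)
    return v


def _infeasible_fallback(positions, velocities, i, pts, nrms, opt_v,
                         combined, inv_h, inv_dt, cfg, obstacles):
    if cfg.infeasible_policy == "halve_step":
        # rebuild this agent's constraints for a halved time step and retry
        scale = 1.0
        rel_sel = [k for k in range(len(positions)) if k != i]
        for _ in range(3):
            scale *= 2.0
            # only the within-step (collision) constraints depend on dt;
            # rebuild every plane for simplicity
            neigh = [
                k for k in rel_sel
                if np.linalg.norm(positions[k] - positions[i])
                <= 2 * cfg.agent_radius + 2 * cfg.max_speed * cfg.time_horizon
            ]
            if not neigh:
                break
            nrm2, u2 = _orca_planes_batch(
                positions[neigh] - positions[i],
                velocities[i] - velocities[neigh],
                combined, inv_h, inv_dt * scale,
            )
            p2 = velocities[i] + 0.5 * u2
            v, ok = _lp_solve(p2, nrm2, cfg.max_speed, opt_v)
            if ok:
                return v
    return np.zeros(3)
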