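"""Independent reference implementations used as test oracles.

These deliberately avoid the package's own code paths: plain double loops
and closed-form geometry, slow but transparently correct.
"""

from __future__ import annotations

import numpy as np


def brute_force_interaction(i, positions, velocities, params):
    """Term-by-term zonal interaction force via an explicit double loop."""
    ri = positions[i]
    sums = {"rep": np.zeros(3), "ali": np.zeros(3), "att": np.zeros(3)}
    counts = {"rep": 0, "ali": 0, "att": 0}
    for j in range(len(positions)):
        if j == i:
            continue
        dr = positions[j] - ri
        dist = np.sqrt((dr**2).sum())
        if dist > params.r_att:
            continue
        if dist < params.r_rep:
            zone, g = "rep", -1
        elif dist < params.r_ali:
            zone, g = "ali", 0
        else:
            zone, g = "att", 1
        rhat = dr / dist
        term = g * rhat
        if g == 0:
            dv = velocities[j] - velocities[i]
            nv = np.sqrt((dv**2).sum())
            if nv >= 1e-12:
                term = term + dv / nv
        sums[zone] += term
        counts[zone] += 1
    chi = {"rep": params.chi_rep, "ali": params.chi_ali, "att": params.chi_att}
    force = np.zeros(3)
    for zone in ("rep", "ali", "att"):
        if counts[zone]:
            force += chi[zone] / counts[zone] * sums[zone]
    return force


def min_future_distance(p0, v0, p1, v1, tau):
    """Closest approach of two linearly-moving points over [0, tau]."""
    dp = np.asarray(p1, float) - np.asarray(p0, float)
    dv = np.asarray(v1, float) - np.asarray(v0, float)
    a = float(dv @ dv)
    if a < 1e-14:
        return float(np.linalg.norm(dp))
    t = min(max(-float(dp @ dv) / a, 0.0), tau)
    cands = [np.linalg.norm(dp), np.linalg.norm(dp + dv * tau), np.linalg.norm(dp + dv * t)]
    return float(min(cands))


def grid_best_velocity(i, positions, other_velocities, pref, cfg, step=0.05,
                       slack=0.99):
    """Dense velocity-grid search: the feasible velocity (pairwise clearance
    >= slack * 2 * agent_radius over the horizon, against the other agents'
    velocities) closest to the preferred one.  Returns (velocity, objective)
    or (None, inf)."""
    ax = np.arange(-cfg.max_speed, cfg.max_speed + 1e-9, step)
    grid = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), -1).reshape(-1, 3)
    grid = grid[np.linalg.norm(grid, axis=1) <= cfg.max_speed]
    limit = slack * 2.0 * cfg.agent_radius
    others = [j for j in range(len(positions)) if j != i]

    # vectorized closest-approach for all grid candidates against agent j
    feasible = np.ones(len(grid), dtype=bool)
    for j in others:
        dp = positions[j] - positions[i]
        dv = other_velocities[j] - grid  # (g, 3)
        a = np.einsum("ij,ij->i", dv, dv)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.clip(-((dv @ dp) / np.where(a > 1e-14, a, 1.0)), 0.0, cfg.time_horizon)
        t = np.where(a > 1e-14, t, 0.0)
        d0 = np.linalg.norm(dp)
        d_tau = np.linalg.norm(dp + dv * cfg.time_horizon, axis=1)
        d_t = np.linalg.norm(dp + dv * t[:, None], axis=1)
        dmin = np.minimum(np.minimum(d_tau, d_t), d0)
        feasible &= dmin >= limit
    if not feasible.any():
        return None, np.inf
    objs = np.linalg.norm(grid - pref, axis=1)
    objs[~feasible] = np.inf
    k = int(np.argmin(objs))
    return grid[k], float(objs[k])
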