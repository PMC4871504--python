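"""Domain types and deterministic force laws for the insect swarm model.

The model treats each insect as a unit-mass self-propelled agent.  Social
(interaction) forces follow a concentric zonal scheme: neighbors inside the
innermost sphere repel, neighbors in the middle shell induce velocity
alignment, and neighbors in the outer shell attract.  Self-propulsion covers
friction drag and the response to environmental stimuli (pursuit of a target,
escape from a predator-like object).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "InsectState",
    "SwarmParams",
    "Stimulus",
    "DegenerateGeometryError",
    "zone_indicator",
    "neighbor_indices",
    "interaction_force",
    "interaction_forces",
    "friction_force",
    "friction_forces",
    "response_force",
    "rotation_about_y",
]

#: below this separation two agents are treated as coincident and the
#: repulsion direction is drawn at random (symmetry breaking)
COINCIDENT_EPS = 1e-9
#: below this relative-velocity magnitude the alignment unit vector is
#: undefined and the alignment contribution is dropped
ALIGN_EPS = 1e-12


class DegenerateGeometryError(ValueError):
    """Raised when a direction is geometrically undefined (e.g. an insect
    exactly coincident with a stimulus)."""


@dataclass
class InsectState:
    """Kinematic state of a single insect (world length units, unit mass)."""

    position: np.ndarray
    velocity: np.ndarray
    preferred_velocity: np.ndarray = field(default=None)  # type: ignore[assignment]
    acceleration: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.preferred_velocity is None:
            self.preferred_velocity = self.velocity.copy()
        else:
            self.preferred_velocity = np.asarray(self.preferred_velocity, dtype=float)
        if self.acceleration is None:
            self.acceleration = np.zeros(3)
        else:
            self.acceleration = np.asarray(self.acceleration, dtype=float)
        for name in ("position", "velocity", "preferred_velocity", "acceleration"):
            v = getattr(self, name)
            if v.shape != (3,):
                raise ValueError(f"{name} must be a 3-vector, got shape {v.shape}")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{name} contains non-finite components: {v}")


@dataclass
class SwarmParams:
    """The 11 parameters of the dynamics model.

    ``gamma`` is the friction coefficient; ``scale`` and ``gain`` shape the
    inherent-noise force (spatial smoothness and magnitude); ``chi_*`` are
    non-negative force weights and ``r_*`` the corresponding zone radii with
    the ordering ``r_att >= r_ali >= r_rep >= 0``.  ``r_res`` is the visual
    range inside which an insect perceives a stimulus.
    """

    gamma: float = 11.16
    scale: float = 2.20
    gain: float = 2.51
    chi_rep: float = 5.61
    r_rep: float = 0.17
    chi_ali: float = 0.0
    r_ali: float = 0.17
    chi_att: float = 14.29
    r_att: float = 5.29
    chi_res: float = 0.0
    r_res: float = 0.0

    KEYS = (
        "gamma", "scale", "gain",
        "chi_rep", "r_rep", "chi_ali", "r_ali",
        "chi_att", "r_att", "chi_res", "r_res",
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        if self.gain < 0:
            raise ValueError("gain must be >= 0")
        for k in ("chi_rep", "chi_ali", "chi_att", "chi_res", "r_res"):
            if getattr(self, k) < 0:
                raise ValueError(f"{k} must be >= 0")
        if not (self.r_att >= self.r_ali >= self.r_rep >= 0):
            raise ValueError(
                "zone radii must satisfy r_att >= r_ali >= r_rep >= 0, got "
                f"r_att={self.r_att}, r_ali={self.r_ali}, r_rep={self.r_rep}"
            )

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {k: float(getattr(self, k)) for k in self.KEYS}

    @classmethod
    def from_dict(cls, d: dict, radius_convention: str = "absolute") -> "SwarmParams":
        """Build from a flat mapping.

        With ``radius_convention="differences"`` the values under ``r_ali``
        and ``r_att`` are interpreted as the shell widths
        ``rali* = r_ali - r_rep`` and ``ratt* = r_att - r_ali`` (the
        convention used to print compact parameter tables) and converted to
        absolute radii.
        """
        d = {k: float(d[k]) for k in cls.KEYS if k in d}
        if radius_convention == "differences":
            r_rep = d.get("r_rep", 0.0)
            r_ali = r_rep + d.get("r_ali", 0.0)
            d["r_ali"] = r_ali
            d["r_att"] = r_ali + d.get("r_att", 0.0)
        elif radius_convention != "absolute":
            raise ValueError(f"unknown radius convention {radius_convention!r}")
        return cls(**d)

    def with_(self, **kwargs) -> "SwarmParams":
        return replace(self, **kwargs)


@dataclass
class Stimulus:
    """An environmental stimulus: a predator-like object (``kind=1``,
    triggers escape) or a target such as food, a female or a lamp
    (``kind=0``, triggers pursuit)."""

    position: np.ndarray
    kind: int = 0
    active: bool = True
    #: frame window in which the stimulus is switched on (end exclusive;
    #: ``None`` = unbounded)
    start_frame: int = 0
    end_frame: int | None = None

    def __post_init__(self) -> None:
        if not callable(self.position):
            self.position = np.asarray(self.position, dtype=float)
        if self.kind not in (0, 1):
            raise ValueError("stimulus kind must be 0 (target) or 1 (predator)")

    def active_at(self, frame: int) -> bool:
        if not self.active:
            return False
        if frame < self.start_frame:
            return False
        return self.end_frame is None or frame < self.end_frame

    def position_at(self, frame: int) -> np.ndarray:
        if callable(self.position):
            return np.asarray(self.position(frame), dtype=float)
        return self.position


# ---------------------------------------------------------------------------
# zonal interaction
# ---------------------------------------------------------------------------

def zone_indicator(x: float, params: SwarmParams) -> int:
    """Piecewise zone function g(x): -1 in the repulsion zone [0, r_rep),
    0 in the alignment shell [r_rep, r_ali), +1 in the attraction shell
    [r_ali, r_att]."""
    if x < 0:
        raise ValueError(f"distance must be non-negative, got {x}")
    if x > params.r_att:
        raise ValueError(
            f"distance {x} exceeds the neighborhood radius r_att={params.r_att}; "
            "neighbors must be pre-filtered"
        )
    if x < params.r_rep:
        return -1
    if x < params.r_ali:
        return 0
    return 1


def neighbor_indices(positions: np.ndarray, i: int, r_att: float) -> np.ndarray:
    """Indices j != i with ||r_j - r_i|| <= r_att."""
    positions = np.asarray(positions, dtype=float)
    if not 0 <= i < len(positions):
        raise IndexError(f"agent index {i} out of range for {len(positions)} agents")
    if r_att < 0:
        raise ValueError("r_att must be >= 0")
    d = np.linalg.norm(positions - positions[i], axis=1)
    mask = d <= r_att
    mask[i] = False
    return np.flatnonzero(mask)


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:  # pragma: no cover - essentially impossible
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def interaction_force(
    i: int,
    positions: np.ndarray,
    velocities: np.ndarray,
    params: SwarmParams,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Zonal interaction force on agent ``i``.

    Each zone k in {rep, ali, att} contributes the zone-average
    ``(chi_k / N_k) * sum_j [ g(r_ji) rhat_ji + (1 - |g|) vhat_ji ]`` over its
    N_k occupants; empty zones contribute nothing.  Coincident neighbors
    (``r_ji ~ 0``) get a random repulsion direction from ``rng``; an
    undefined alignment direction (identical velocities) contributes zero.
    """
    positions = np.asarray(positions, dtype=float)
    velocities = np.asarray(velocities, dtype=float)
    neigh = neighbor_indices(positions, i, params.r_att)
    if neigh.size == 0:
        return np.zeros(3)

    zone_sums = {-1: np.zeros(3), 0: np.zeros(3), 1: np.zeros(3)}
    zone_counts = {-1: 0, 0: 0, 1: 0}
    for j in neigh:
        dr = positions[j] - positions[i]
        r_ji = float(np.linalg.norm(dr))
        g = zone_indicator(r_ji, params)
        if r_ji < COINCIDENT_EPS:
            if rng is None:
                raise DegenerateGeometryError(
                    f"agents {i} and {j} coincide and no rng was supplied "
                    "for symmetry breaking"
                )
            rhat = _random_unit_vector(rng)
        else:
            rhat = dr / r_ji
        term = g * rhat
        if g == 0:
            dv = velocities[j] - velocities[i]
            nv = float(np.linalg.norm(dv))
            if nv >= ALIGN_EPS:
                term = term + dv / nv
        zone_sums[g] += term
        zone_counts[g] += 1

    chi = {-1: params.chi_rep, 0: params.chi_ali, 1: params.chi_att}
    force = np.zeros(3)
    for g in (-1, 0, 1):
        if zone_counts[g] > 0:
            force += chi[g] / zone_counts[g] * zone_sums[g]
    if not np.all(np.isfinite(force)):  # pragma: no cover - guarded above
        raise FloatingPointError(f"non-finite interaction force for agent {i}")
    return force


def interaction_forces(
    positions: np.ndarray,
    velocities: np.ndarray,
    params: SwarmParams,
    rng: np.random.Generator | None = None,
    pairs: np.ndarray | None = None,
) -> np.ndarray:
    """Vectorized zonal interaction forces for all agents at once.

    ``pairs`` may carry precomputed undirected index pairs (m, 2) with
    pairwise distance <= r_att (e.g. from a KD-tree); otherwise all pairs are
    formed densely.  Numerically identical to calling
    :func:`interaction_force` per agent (up to float summation order).
    """
    positions = np.asarray(positions, dtype=float)
    velocities = np.asarray(velocities, dtype=float)
    n = len(positions)
    forces = np.zeros((n, 3))
    if n < 2:
        return forces

    if pairs is None:
        iu, ju = np.triu_indices(n, k=1)
        d = np.linalg.norm(positions[iu] - positions[ju], axis=1)
        keep = d <= params.r_att
        iu, ju = iu[keep], ju[keep]
    else:
        pairs = np.asarray(pairs)
        if pairs.size == 0:
            return forces
        iu, ju = pairs[:, 0], pairs[:, 1]

    # directed pairs: force on a from b
    a = np.concatenate([iu, ju])
    b = np.concatenate([ju, iu])
    dr = positions[b] - positions[a]
    dist = np.linalg.norm(dr, axis=1)

    rhat = np.zeros_like(dr)
    ok = dist >= COINCIDENT_EPS
    rhat[ok] = dr[ok] / dist[ok, None]
    if not np.all(ok):
        if rng is None:
            raise DegenerateGeometryError(
                "coincident agents present and no rng supplied"
            )
        m = int(np.count_nonzero(~ok))
        v = rng.normal(size=(m, 3))
        rhat[~ok] = v / np.linalg.norm(v, axis=1, keepdims=True)

    # zone classification (half-open inner bounds, closed outer bound)
    g = np.where(dist < params.r_rep, -1, np.where(dist < params.r_ali, 0, 1))

    term = g[:, None] * rhat
    ali = g == 0
    if np.any(ali):
        dv = velocities[b[ali]] - velocities[a[ali]]
        nv = np.linalg.norm(dv, axis=1)
        vhat = np.zeros_like(dv)
        nz = nv >= ALIGN_EPS
        vhat[nz] = dv[nz] / nv[nz, None]
        term[ali] += vhat

    chi_by_zone = np.array([params.chi_rep, params.chi_ali, params.chi_att])
    for zi, gval in enumerate((-1, 0, 1)):
        sel = g == gval
        if not np.any(sel):
            continue
        zone_sum = np.zeros((n, 3))
        np.add.at(zone_sum, a[sel], term[sel])
        counts = np.bincount(a[sel], minlength=n).astype(float)
        nzc = counts > 0
        zone_sum[nzc] *= (chi_by_zone[zi] / counts[nzc])[:, None]
        forces += zone_sum
    return forces


# ---------------------------------------------------------------------------
# self-propulsion
# ---------------------------------------------------------------------------

def friction_force(v: np.ndarray, gamma: float, form: str = "quadratic") -> np.ndarray:
    """Drag force opposing the current velocity.

    The default is quadratic drag ``-gamma * ||v|| * v`` (speed-scaled);
    ``form="linear"`` gives Stokes-like drag ``-gamma * v``.  Either way the
    dissipated power ``F . v`` is non-positive.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    v = np.asarray(v, dtype=float)
    if form == "quadratic":
        return -gamma * np.linalg.norm(v) * v
    if form == "linear":
        return -gamma * v
    raise ValueError(f"unknown drag form {form!r}")


def friction_forces(v: np.ndarray, gamma: float, form: str = "quadratic") -> np.ndarray:
    """Vectorized :func:`friction_force` for an (n, 3) velocity array."""
    v = np.asarray(v, dtype=float)
    if form == "quadratic":
        return -gamma * np.linalg.norm(v, axis=1, keepdims=True) * v
    if form == "linear":
        return -gamma * v
    raise ValueError(f"unknown drag form {form!r}")


def rotation_about_y(theta: float) -> np.ndarray:
    """Rotation matrix about the world up axis n = (0, 1, 0)."""
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def response_force(
    r_i: np.ndarray,
    stimulus: Stimulus,
    params: SwarmParams,
    rng: np.random.Generator,
    frame: int = 0,
) -> np.ndarray:
    """Response to an environmental stimulus, gated by the visual range.

    Pursuit (``kind=0``): unit force toward the stimulus, scaled by chi_res.
    Escape (``kind=1``): the away-from-threat direction rotated about the
    world up axis by a random angle theta ~ U[-pi/2, 0], so the force always
    lies in the 90-180 degree sector relative to the insect->threat
    direction (escape with maximal unpredictability).
    """
    if not stimulus.active_at(frame) or params.chi_res == 0.0:
        return np.zeros(3)
    r_i = np.asarray(r_i, dtype=float)
    d = r_i - stimulus.position_at(frame)  # stimulus -> insect
    dist = float(np.linalg.norm(d))
    if dist > params.r_res:  # Heaviside gate: can the insect see it?
        return np.zeros(3)
    if dist < COINCIDENT_EPS:
        raise DegenerateGeometryError(
            "insect coincides with the stimulus; response direction undefined"
        )
    rhat_ie = d / dist
    if stimulus.kind == 0:
        return -params.chi_res * rhat_ie
    theta = rng.uniform(-math.pi / 2.0, 0.0)
    return params.chi_res * (rotation_about_y(theta) @ rhat_ie)
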