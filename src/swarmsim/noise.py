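"""Inherent-noise force fields: white, Gaussian white, Perlin and Curl.

Insects make seemingly random movements even in isolation; at the collective
level this "inherent noise" is constructive, helping a swarm hold together.
The model treats it as a stochastic force term and offers four candidate
generators.  White and Gaussian white noise are uncorrelated per agent and
per step; Perlin and Curl noise are smooth deterministic functions of the
agent's *position*, so nearby insects feel similar perturbations and a single
insect traces a continuous noisy path.  Curl noise is the curl of a Perlin
vector potential and is therefore divergence-free (swirling, never
compressing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NoiseSpec",
    "GradientNoise3D",
    "white_noise",
    "gaussian_white_noise",
    "perlin_field",
    "perlin_jacobian",
    "curl_field",
]

# fixed large offsets separating the three vector-potential channels drawn
# from one gradient-noise instance (kept away from integer lattice alignment)
CHANNEL_OFFSETS = np.array(
    [
        [0.0, 0.0, 0.0],
        [123.45, 567.89, 912.35],
        [-654.32, 210.98, -87.65],
    ]
)

# the 12 edge gradients of the improved gradient-noise construction, with 4
# repeats to make the hash modulus a power of two
_GRADS = np.array(
    [
        [1, 1, 0], [-1, 1, 0], [1, -1, 0], [-1, -1, 0],
        [1, 0, 1], [-1, 0, 1], [1, 0, -1], [-1, 0, -1],
        [0, 1, 1], [0, -1, 1], [0, 1, -1], [0, -1, -1],
        [1, 1, 0], [-1, 1, 0], [0, -1, 1], [0, -1, -1],
    ],
    dtype=float,
)


class GradientNoise3D:
    """Classic improved 3D gradient (Perlin) noise with analytic derivatives.

    Zero at every integer lattice point, C2-continuous via the quintic fade,
    deterministic in (point, seed).  ``value_and_gradient`` evaluates the
    scalar field and its exact spatial gradient in one pass, which lets the
    curl of a noise-built vector potential be formed without finite
    differences.
    """

    def __init__(self, seed: int = 0):
        self.seed = int(seed)
        p = np.random.default_rng(self.seed).permutation(256)
        self._perm = np.concatenate([p, p]).astype(np.intp)

    def _hash(self, xi: np.ndarray, yi: np.ndarray, zi: np.ndarray) -> np.ndarray:
        p = self._perm
        return p[p[p[xi] + yi] + zi] & 15

    def value_and_gradient(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Evaluate at an (n, 3) array; returns (values (n,), gradients (n, 3))."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        cell = np.floor(pts)
        xi = cell.astype(np.intp) & 255
        f = pts - cell  # fractional position in the cell, in [0, 1)

        # quintic fade and its derivative
        u = f * f * f * (f * (f * 6.0 - 15.0) + 10.0)
        du = 30.0 * f * f * (f * (f - 2.0) + 1.0)

        n_pts = len(pts)
        value = np.zeros(n_pts)
        grad = np.zeros((n_pts, 3))
        for cx in (0, 1):
            wx = u[:, 0] if cx else 1.0 - u[:, 0]
            dwx = du[:, 0] if cx else -du[:, 0]
            for cy in (0, 1):
                wy = u[:, 1] if cy else 1.0 - u[:, 1]
                dwy = du[:, 1] if cy else -du[:, 1]
                for cz in (0, 1):
                    wz = u[:, 2] if cz else 1.0 - u[:, 2]
                    dwz = du[:, 2] if cz else -du[:, 2]
                    h = self._hash(xi[:, 0] + cx, xi[:, 1] + cy, xi[:, 2] + cz)
                    g = _GRADS[h]
                    off = f - np.array([cx, cy, cz], dtype=float)
                    dot = np.einsum("ij,ij->i", g, off)
                    w = wx * wy * wz
                    value += w * dot
                    # product rule: d(w * dot)/dx_k
                    grad[:, 0] += dwx * wy * wz * dot + w * g[:, 0]
                    grad[:, 1] += wx * dwy * wz * dot + w * g[:, 1]
                    grad[:, 2] += wx * wy * dwz * dot + w * g[:, 2]
        return value, grad

    def value(self, points: np.ndarray) -> np.ndarray:
        return self.value_and_gradient(points)[0]


@dataclass
class NoiseSpec:
    """Configuration of the inherent-noise force generator.

    ``kind`` selects the generator; ``scale`` (> 0) divides positions before
    sampling the gradient noise, so larger values give smoother fields;
    ``gain`` multiplies the output magnitude.  ``lam`` is the strength
    coefficient of the Gaussian white generator (defaults to ``gain`` when
    unset).  ``seed`` fixes the gradient-noise lattice.
    """

    kind: str = "curl"
    scale: float = 2.2
    gain: float = 2.51
    lam: float | None = None
    seed: int = 0

    KINDS = ("white", "gaussian", "perlin", "curl")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"noise kind must be one of {self.KINDS}, got {self.kind!r}")
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        if self.gain < 0:
            raise ValueError("gain must be >= 0")
        if self.lam is not None and self.lam < 0:
            raise ValueError("lambda must be >= 0")
        self._noise = GradientNoise3D(self.seed)

    @property
    def strength(self) -> float:
        return self.gain if self.lam is None else self.lam

    def sample(self, positions: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Noise force for each of n agents at ``positions`` ((n, 3))."""
        positions = np.atleast_2d(np.asarray(positions, dtype=float))
        n = len(positions)
        if self.kind == "white":
            return np.stack([white_noise(rng, self.strength) for _ in range(n)])
        if self.kind == "gaussian":
            return np.stack([gaussian_white_noise(self.strength, rng) for _ in range(n)])
        if self.kind == "perlin":
            return perlin_field(positions, self)
        return curl_field(positions, self)


# ---------------------------------------------------------------------------
# per-draw stochastic generators
# ---------------------------------------------------------------------------

def white_noise(rng: np.random.Generator, gain: float = 1.0) -> np.ndarray:
    """Three independent uniform deviates on [-1, 1], scaled by ``gain``.

    Symmetric support keeps the force zero-mean per component.
    """
    return gain * rng.uniform(-1.0, 1.0, size=3)


def gaussian_white_noise(lam: float, rng: np.random.Generator) -> np.ndarray:
    """Single-branch Box-Muller approximation of Gaussian white noise.

    Per component ``G = lam * sqrt(-2 log W1) * sin(2 pi W2)`` with
    ``W1 ~ U(0, 1]`` (never zero, so the log is finite) and ``W2 ~ U[0, 1)``.
    The single sine branch of the Box-Muller transform is itself exactly
    standard normal, so Var(G) = lam^2.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    w1 = 1.0 - rng.random(3)  # in (0, 1]
    w2 = rng.random(3)
    return lam * np.sqrt(-2.0 * np.log(w1)) * np.sin(2.0 * np.pi * w2)


# ---------------------------------------------------------------------------
# position-correlated fields
# ---------------------------------------------------------------------------

def perlin_field(r: np.ndarray, spec: NoiseSpec) -> np.ndarray:
    """Three-channel gradient-noise vector field P(r).

    Channels are one noise instance sampled at large fixed coordinate
    offsets (``CHANNEL_OFFSETS``); each is evaluated at ``r / scale`` and
    multiplied by ``gain``.
    """
    pts = np.atleast_2d(np.asarray(r, dtype=float))
    single = np.asarray(r).ndim == 1
    scaled = pts / spec.scale
    out = np.empty((len(pts), 3))
    for k in range(3):
        out[:, k] = spec._noise.value(scaled + CHANNEL_OFFSETS[k])
    out *= spec.gain
    return out[0] if single else out


def perlin_jacobian(r: np.ndarray, spec: NoiseSpec) -> tuple[np.ndarray, np.ndarray]:
    """Field values (n, 3) and exact Jacobians dP_k/dr_l (n, 3, 3)."""
    pts = np.atleast_2d(np.asarray(r, dtype=float))
    scaled = pts / spec.scale
    vals = np.empty((len(pts), 3))
    jac = np.empty((len(pts), 3, 3))
    for k in range(3):
        v, g = spec._noise.value_and_gradient(scaled + CHANNEL_OFFSETS[k])
        vals[:, k] = v
        jac[:, k, :] = g / spec.scale  # chain rule for the position scaling
    return spec.gain * vals, spec.gain * jac


def curl_field(
    r: np.ndarray,
    spec: NoiseSpec,
    method: str = "analytic",
    h: float | None = None,
) -> np.ndarray:
    """Curl of the Perlin vector potential, C(r) = curl P(r).

    Divergence-free by construction, producing swirling perturbations.  The
    default uses the exact analytic derivatives of the gradient noise;
    ``method="fd"`` uses central finite differences with step ``h``
    (default ``1e-4 * scale``).
    """
    pts = np.atleast_2d(np.asarray(r, dtype=float))
    single = np.asarray(r).ndim == 1
    if method == "analytic":
        _, jac = perlin_jacobian(pts, spec)
        out = np.empty((len(pts), 3))
        out[:, 0] = jac[:, 2, 1] - jac[:, 1, 2]  # dPz/dy - dPy/dz
        out[:, 1] = jac[:, 0, 2] - jac[:, 2, 0]  # dPx/dz - dPz/dx
        out[:, 2] = jac[:, 1, 0] - jac[:, 0, 1]  # dPy/dx - dPx/dy
    elif method == "fd":
        if h is None:
            h = 1e-4 * spec.scale
        d = np.zeros((3, len(pts), 3))
        for axis in range(3):
            e = np.zeros(3)
            e[axis] = h
            d[axis] = (perlin_field(pts + e, spec) - perlin_field(pts - e, spec)) / (2 * h)
        out = np.empty((len(pts), 3))
        out[:, 0] = d[1][:, 2] - d[2][:, 1]
        out[:, 1] = d[2][:, 0] - d[0][:, 2]
        out[:, 2] = d[0][:, 1] - d[1][:, 0]
    else:
        raise ValueError(f"unknown curl method {method!r}")
    return out[0] if single else out


def divergence(
    field,
    points: np.ndarray,
    h: float,
) -> np.ndarray:
    """Central finite-difference divergence of a vector field at ``points``.

    ``field`` maps an (n, 3) array to an (n, 3) array.  Used to verify the
    incompressibility of the curl field.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    div = np.zeros(len(pts))
    for axis in range(3):
        e = np.zeros(3)
        e[axis] = h
        div += (field(pts + e)[:, axis] - field(pts - e)[:, axis]) / (2 * h)
    return div
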