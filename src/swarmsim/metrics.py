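"""Statistical evaluation of swarm trajectories.

Two noisy swarms can be behaviorally alike while their raw positions differ
everywhere, so trajectories are compared through the *distributions* of
seven time-varying kinematic metrics rather than pointwise: speed v,
acceleration magnitude a, angular velocity omega, angular acceleration
alpha, Cartesian jerk mu (trajectory roughness), nearest-neighbor distance d
(a density proxy) and the distance-weighted nearest-neighbor speed
difference eta (separates weakly-aligned swarms from flocks).  Each metric
is z-scored, binned into a discrete probability density, and the L1
difference between the real and simulated densities forms an energy term;
the weighted sum of energies gives the evaluation score E (higher = more
similar, identical data scores 1).  When several models are compared, each
energy term's weight comes from the entropy of its column in the
model-by-term energy matrix: terms that discriminate between models carry
more weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .simulator import Trajectory

__all__ = [
    "METRICS",
    "MetricSamples",
    "DiscretePDF",
    "EvaluationResult",
    "compute_metric",
    "compute_all_metrics",
    "zscore",
    "discrete_pdf",
    "energy_term",
    "evaluation_score",
    "entropy_weights",
    "evaluate",
    "compare_models",
]

METRICS = ("v", "a", "omega", "alpha", "mu", "d", "eta")


@dataclass
class MetricSamples:
    """Scalar samples of one metric (one value per insect per eligible frame)."""

    metric: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}; known: {METRICS}")
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"metric {self.metric} contains non-finite samples")


@dataclass
class DiscretePDF:
    """Discrete probability density over [u1, u2] with M equal bins."""

    u1: float
    u2: float
    densities: np.ndarray

    def __post_init__(self) -> None:
        self.densities = np.asarray(self.densities, dtype=float)
        if self.u2 <= self.u1:
            raise ValueError("u2 must exceed u1")
        if np.any(self.densities < 0):
            raise ValueError("densities must be non-negative")

    @property
    def m(self) -> int:
        return len(self.densities)

    def integral(self) -> float:
        return float(self.densities.sum() * (self.u2 - self.u1) / self.m)


@dataclass
class EvaluationResult:
    """Per-metric energies/weights/normalizers and the final score E."""

    energies: dict
    weights: dict
    p1: dict
    p2: dict
    score: float
    raw_energies: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# the seven time-varying metrics
# ---------------------------------------------------------------------------

def _velocities(traj: Trajectory) -> np.ndarray:
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames for velocity")
    return traj.velocities()  # (F-1, N, 3)


def compute_metric(metric: str, traj: Trajectory) -> MetricSamples:
    """Sample one metric for all insects over all eligible frames.

    Angular quantities skip samples where a velocity has zero magnitude
    (direction undefined); the arccos argument is clamped to [-1, 1].
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    dt = traj.dt

    if metric == "d" or metric == "eta":
        if traj.n_insects < 2:
            raise ValueError(f"metric {metric!r} needs at least 2 insects")
        # nearest neighbor per insect per frame
        frames = traj.n_frames if metric == "d" else traj.n_frames - 1
        if frames < 1:
            raise ValueError("not enough frames")
        dvals = np.empty((frames, traj.n_insects))
        nn_idx = np.empty((frames, traj.n_insects), dtype=int)
        for f in range(frames):
            tree = cKDTree(traj.positions[f])
            dist, idx = tree.query(traj.positions[f], k=2)
            dvals[f] = dist[:, 1]
            nn_idx[f] = idx[:, 1]
        if metric == "d":
            return MetricSamples("d", dvals.ravel())
        speeds = np.linalg.norm(_velocities(traj), axis=2)  # (F-1, N)
        own = speeds
        nei = np.take_along_axis(speeds, nn_idx, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            eta = (nei - own) / dvals
        if not np.all(np.isfinite(eta)):
            raise FloatingPointError("coincident insects give undefined eta")
        return MetricSamples("eta", eta.ravel())

    vel = _velocities(traj)  # (F-1, N, 3)
    if metric == "v":
        return MetricSamples("v", np.linalg.norm(vel, axis=2).ravel())

    if metric == "a":
        if traj.n_frames < 3:
            raise ValueError("metric 'a' needs at least 3 frames")
        acc = np.diff(vel, axis=0) / dt
        return MetricSamples("a", np.linalg.norm(acc, axis=2).ravel())

    if metric == "mu":
        if traj.n_frames < 4:
            raise ValueError("metric 'mu' needs at least 4 frames")
        dv = np.diff(vel, axis=0)  # velocity increments
        jerk = np.linalg.norm(np.diff(dv, axis=0), axis=2) / dt**2
        return MetricSamples("mu", jerk.ravel())

    # angular velocity / acceleration from direction changes
    if traj.n_frames < 3:
        raise ValueError(f"metric {metric!r} needs at least 3 frames")
    n1 = np.linalg.norm(vel[:-1], axis=2)
    n2 = np.linalg.norm(vel[1:], axis=2)
    ok = (n1 > 1e-12) & (n2 > 1e-12)
    dot = np.einsum("fij,fij->fi", vel[:-1], vel[1:])
    with np.errstate(divide="ignore", invalid="ignore"):
        cosang = np.clip(dot / (n1 * n2), -1.0, 1.0)
    omega = np.where(ok, np.arccos(np.where(ok, cosang, 1.0)) / dt, np.nan)
    if metric == "omega":
        return MetricSamples("omega", omega[np.isfinite(omega)])
    # alpha: rate of change of omega; both omegas must be defined
    if traj.n_frames < 4:
        raise ValueError("metric 'alpha' needs at least 4 frames")
    alpha = np.diff(omega, axis=0) / dt
    return MetricSamples("alpha", alpha[np.isfinite(alpha)])


def compute_all_metrics(traj: Trajectory) -> dict:
    return {m: compute_metric(m, traj) for m in METRICS}


# ---------------------------------------------------------------------------
# normalization, binning, energies
# ---------------------------------------------------------------------------

def zscore(samples: np.ndarray, ddof: int = 0) -> np.ndarray:
    """Mean shift followed by standard-deviation scaling (population SD)."""
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 samples to z-score")
    sd = x.std(ddof=ddof)
    if sd == 0.0:
        raise ValueError("zero variance: metric is degenerate, cannot z-score")
    return (x - x.mean()) / sd


def discrete_pdf(samples: np.ndarray, m: int, interval: tuple[float, float]) -> DiscretePDF:
    """Bin samples into M equal sub-intervals of [u1, u2].

    Density in bin i is S_i * M / (S * (u2 - u1)) so the PDF integrates to
    one.  Samples outside the interval are clipped into the boundary bins
    (cannot occur with a pooled min/max interval, but guards the API).
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("no samples to bin")
    if m < 1:
        raise ValueError("M must be >= 1")
    u1, u2 = float(interval[0]), float(interval[1])
    if u2 <= u1:
        raise ValueError("u2 must exceed u1")
    x = np.clip(x, u1, u2)
    counts, _ = np.histogram(x, bins=m, range=(u1, u2))
    densities = counts * m / (x.size * (u2 - u1))
    return DiscretePDF(u1=u1, u2=u2, densities=densities)


def energy_term(q_real: DiscretePDF, q_sim: DiscretePDF,
                p1: float = 0.0, p2: float = 1.0,
                on: str = "densities") -> float:
    """Normalized L1 difference of two discrete PDFs:
    E = (sum_i |Q_real,i - Q_sim,i| - p1) / p2.

    By default the L1 sum runs over the probability *densities* Q_i; with
    ``on="probabilities"`` it runs over the per-bin probability masses
    Q_i * (u2 - u1) / M instead (the two differ by the constant bin width,
    which matters once energies are compared across different intervals).
    """
    if q_real.m != q_sim.m or q_real.u1 != q_sim.u1 or q_real.u2 != q_sim.u2:
        raise ValueError("PDFs must share bin count and interval")
    if p2 <= 0:
        raise ValueError("p2 must be > 0")
    raw = float(np.abs(q_real.densities - q_sim.densities).sum())
    if on == "probabilities":
        raw *= (q_real.u2 - q_real.u1) / q_real.m
    elif on != "densities":
        raise ValueError("on must be 'densities' or 'probabilities'")
    return (raw - p1) / p2


def evaluation_score(energies: dict, weights: dict) -> float:
    """E = 1 - sum_phi w_phi E_phi; higher is better, identity scores 1."""
    if set(energies) != set(weights):
        raise ValueError(
            f"metric keys differ: {sorted(energies)} vs {sorted(weights)}"
        )
    return 1.0 - sum(weights[k] * energies[k] for k in energies)


# ---------------------------------------------------------------------------
# entropy weighting
# ---------------------------------------------------------------------------

def entropy_weights(x: np.ndarray):
    """Entropy-based objective weights for an (m models x n terms) energy
    matrix.

    Each column is min-max normalized (the normalizers p1 = column min and
    p2 = column range are returned for reuse in the score), flipped to
    r = 1 - x, turned into a distribution g over models, and scored by its
    Shannon entropy e_j; the weight of term j is (1 - e_j) / sum(1 - e_k).
    A constant column gets entropy 1 and hence zero weight (it cannot
    discriminate between the models).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need an (m >= 2) x n energy matrix")
    m, n = x.shape
    p1 = x.min(axis=0)
    p2 = x.max(axis=0) - p1
    e = np.empty(n)
    for j in range(n):
        if p2[j] == 0.0:
            e[j] = 1.0  # non-discriminating term
            continue
        xn = (x[:, j] - p1[j]) / p2[j]
        r = 1.0 - xn
        tot = r.sum()
        if tot == 0.0:
            e[j] = 1.0
            continue
        g = r / tot
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(g > 0, g * np.log(np.where(g > 0, g, 1.0)), 0.0)
        e[j] = -terms.sum() / math.log(m)
    one_minus = 1.0 - e
    total = one_minus.sum()
    if total <= 0.0:
        raise ValueError("all energy terms are non-discriminating (e_j = 1)")
    w = one_minus / total
    return w, p1, p2


# ---------------------------------------------------------------------------
# pairwise evaluation and model comparison
# ---------------------------------------------------------------------------

def raw_energies(
    reference: Trajectory,
    simulated: Trajectory,
    m_bins: int = 50,
    pooled_zscore: bool = False,
    eta_abs: bool = False,
    l1_on: str = "densities",
) -> dict:
    """Raw (un-normalized) L1 energies for the seven metrics.

    Each dataset is z-scored with its own mean/SD by default (the two
    sources live on different quantity scales); the binning interval is the
    pooled min/max of both z-scored sample sets.
    """
    out = {}
    for metric in METRICS:
        a = compute_metric(metric, reference).values
        b = compute_metric(metric, simulated).values
        if eta_abs and metric == "eta":
            a, b = np.abs(a), np.abs(b)
        if pooled_zscore:
            pool = np.concatenate([a, b])
            mu, sd = pool.mean(), pool.std()
            if sd == 0.0:
                raise ValueError(f"metric {metric} degenerate in pooled data")
            za, zb = (a - mu) / sd, (b - mu) / sd
        else:
            za, zb = zscore(a), zscore(b)
        u1 = min(za.min(), zb.min())
        u2 = max(za.max(), zb.max())
        if u2 <= u1:  # pragma: no cover - z-scored data always has spread
            u1, u2 = u1 - 0.5, u2 + 0.5
        qa = discrete_pdf(za, m_bins, (u1, u2))
        qb = discrete_pdf(zb, m_bins, (u1, u2))
        out[metric] = energy_term(qa, qb, on=l1_on)
    return out


def evaluate(
    reference: Trajectory,
    simulated: Trajectory,
    m_bins: int = 50,
    weights: dict | None = None,
    p1: dict | None = None,
    p2: dict | None = None,
    pooled_zscore: bool = False,
    eta_abs: bool = False,
) -> EvaluationResult:
    """Score a simulated trajectory against a reference one.

    Defaults: equal weights 1/7, p1 = 0, p2 = 1 (the bare procedure);
    normalizers and weights from an entropy-weight comparison can be
    supplied to reproduce a full model-comparison score.
    """
    raw = raw_energies(reference, simulated, m_bins, pooled_zscore, eta_abs)
    weights = weights or {k: 1.0 / len(METRICS) for k in METRICS}
    p1 = p1 or {k: 0.0 for k in METRICS}
    p2 = p2 or {k: 1.0 for k in METRICS}
    energies = {k: (raw[k] - p1[k]) / p2[k] for k in METRICS}
    return EvaluationResult(
        energies=energies,
        weights=dict(weights),
        p1=dict(p1),
        p2=dict(p2),
        score=evaluation_score(energies, weights),
        raw_energies=raw,
    )


def compare_models(
    model_fits,
    reference: Trajectory,
    m_bins: int = 50,
    max_iter: int = 10,
    tol: float = 1e-3,
):
    """Iterative entropy-weighted comparison of >= 2 simulation models.

    ``model_fits`` maps a model name to a callable
    ``fit(weights, p1, p2) -> raw energy dict`` that re-optimizes the model
    under the current evaluation weighting (the Par-Est step) and returns
    the seven raw energies of its best fit.  The loop alternates fitting and
    entropy re-weighting until the weights move less than ``tol``
    (max-norm) or ``max_iter`` is reached; it returns
    ``(results, weights, history)`` with one :class:`EvaluationResult` per
    model.
    """
    names = list(model_fits)
    if len(names) < 2:
        raise ValueError("need at least two models to compare")
    weights = {k: 1.0 / len(METRICS) for k in METRICS}
    p1 = {k: 0.0 for k in METRICS}
    p2 = {k: 1.0 for k in METRICS}
    history = []
    raw_mat = None
    for _ in range(max(max_iter, 1)):
        raw_mat = {name: model_fits[name](weights, p1, p2) for name in names}
        x = np.array([[raw_mat[name][k] for k in METRICS] for name in names])
        w_vec, p1_vec, p2_vec = entropy_weights(x)
        new_weights = dict(zip(METRICS, w_vec))
        # guard the score's division: a constant column has zero range
        p1 = dict(zip(METRICS, p1_vec))
        p2 = {k: (v if v > 0 else 1.0) for k, v in zip(METRICS, p2_vec)}
        history.append(dict(new_weights))
        delta = max(abs(new_weights[k] - weights[k]) for k in METRICS)
        weights = new_weights
        if delta < tol:
            break
    results = {}
    for name in names:
        energies = {k: (raw_mat[name][k] - p1[k]) / p2[k] for k in METRICS}
        results[name] = EvaluationResult(
            energies=energies,
            weights=dict(weights),
            p1=dict(p1),
            p2=dict(p2),
            score=evaluation_score(energies, weights),
            raw_energies=raw_mat[name],
        )
    return results, weights, history
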