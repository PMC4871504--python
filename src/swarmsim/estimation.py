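"""Parameter estimation (Par-Est) and synthetic trajectory fixtures.

Par-Est wraps the simulator in a genetic algorithm: each candidate parameter
vector is simulated (fixed seed and run length, so fitness noise comes only
from the candidate itself), scored against the reference trajectory with
the entropy-weighted evaluation, and evolved by tournament selection,
uniform crossover and Gaussian mutation with one elite.  Seven of the
model's eleven parameters can be estimated from trajectory data; alignment
and stimulus-response parameters cannot (real swarm datasets show no strong
alignment tendency and contain no controlled stimulus), so they stay at
their configured base values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .metrics import compare_models, evaluate
from .simulator import SimConfig, Trajectory, build_scenario, run

__all__ = [
    "GAConfig",
    "ParEstResult",
    "par_est",
    "default_bounds",
    "generate_fixture",
    "compare_simulators",
]

#: the parameters estimable from trajectory data
DATA_ESTIMABLE = ("gamma", "chi_rep", "r_rep", "chi_att", "r_att", "scale", "gain")


@dataclass
class GAConfig:
    """Genetic-algorithm settings for Par-Est."""

    population: int = 30
    generations: int = 40
    crossover_rate: float = 0.8
    mutation_rate: float = 0.1
    mutation_sigma_frac: float = 0.1  # per-gene sigma as a fraction of range
    tournament: int = 3
    elites: int = 1
    bounds: dict = field(default_factory=dict)  # key -> (lo, hi)
    estimated_keys: tuple = DATA_ESTIMABLE
    seed: int = 0
    #: frames simulated per fitness evaluation (after burn-in)
    eval_frames: int = 300
    #: equilibration frames discarded before metrics are sampled, so the
    #: compared distributions reflect the established swarm
    burn_in: int = 300
    #: simulation seed shared by all fitness evaluations
    sim_seed: int = 12345
    m_bins: int = 50

    def __post_init__(self) -> None:
        if self.population < 4:
            raise ValueError("population must be >= 4")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        for name in ("crossover_rate", "mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for k, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"bounds for {k} must satisfy lo < hi")


@dataclass
class ParEstResult:
    best_params: "object"
    best_score: float
    trace: np.ndarray  # best fitness per generation (including generation 0)
    best_energies: dict
    evaluated: int


def default_bounds(params, keys=DATA_ESTIMABLE, factor: float = 4.0) -> dict:
    """Per-parameter search boxes [0, factor * base] (base 0 widens to a
    small positive range; ``scale`` keeps a positive floor)."""
    bounds = {}
    for k in keys:
        base = getattr(params, k)
        hi = factor * base if base > 0 else 1.0
        lo = 0.01 if k == "scale" else 0.0
        bounds[k] = (lo, hi)
    return bounds


def _apply_genes(base_cfg: SimConfig, keys, genes) -> SimConfig:
    """Candidate config with ``genes`` substituted into the parameter set.

    Zone-radius ordering is repaired rather than rejected: r_rep is capped
    at r_att and r_ali is clipped into [r_rep, r_att], so every candidate is
    a valid model.
    """
    over = dict(zip(keys, (float(g) for g in genes)))
    p = base_cfg.params.to_dict()
    p.update(over)
    if p["r_rep"] > p["r_att"]:
        p["r_rep"] = p["r_att"]
    p["r_ali"] = min(max(p["r_ali"], p["r_rep"]), p["r_att"])
    from .core import SwarmParams

    params = SwarmParams(**p)
    noise = base_cfg.noise
    if "scale" in over or "gain" in over:
        noise = replace(noise, scale=params.scale, gain=params.gain)
    cfg = replace(base_cfg, params=params, noise=noise)
    return cfg


def par_est(
    reference: Trajectory,
    base_config: SimConfig,
    ga: GAConfig,
    weights: dict | None = None,
    p1: dict | None = None,
    p2: dict | None = None,
) -> ParEstResult:
    """Genetic-algorithm search maximizing the evaluation score of the
    simulated swarm against ``reference``.

    Only ``ga.estimated_keys`` vary; the rest of the parameter set stays at
    ``base_config`` values.  Fitness uses a fixed simulation seed and run
    length per candidate.  Returns the best parameter set, its score, the
    per-generation best-fitness trace (non-decreasing thanks to elitism) and
    the energies of the best fit.
    """
    keys = tuple(ga.estimated_keys)
    bounds = dict(ga.bounds) if ga.bounds else default_bounds(base_config.params, keys)
    missing = [k for k in keys if k not in bounds]
    if missing:
        bounds.update(default_bounds(base_config.params, missing))
    lo = np.array([bounds[k][0] for k in keys])
    hi = np.array([bounds[k][1] for k in keys])

    rng = np.random.default_rng(ga.seed)
    n_genes = len(keys)
    pop = rng.uniform(lo, hi, size=(ga.population, n_genes))

    evaluated = 0
    cache: dict = {}

    def fitness(genes) -> tuple[float, dict]:
        nonlocal evaluated
        key = tuple(np.round(genes, 12))
        if key in cache:
            return cache[key]
        cfg = _apply_genes(base_config, keys, genes)
        cfg = replace(cfg, n_frames=ga.eval_frames + ga.burn_in, seed=ga.sim_seed)
        sim = run(cfg)
        if ga.burn_in:
            sim = Trajectory(sim.positions[ga.burn_in:], sim.dt, sim.metadata)
        res = evaluate(reference, sim, m_bins=ga.m_bins,
                       weights=weights, p1=p1, p2=p2)
        evaluated += 1
        cache[key] = (res.score, res.raw_energies)
        return cache[key]

    scored = [fitness(ind) for ind in pop]
    fits = np.array([s[0] for s in scored])
    trace = [float(fits.max())]

    for _ in range(ga.generations):
        order = np.argsort(fits)[::-1]
        new_pop = [pop[order[e]].copy() for e in range(ga.elites)]
        while len(new_pop) < ga.population:
            # tournament selection
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, ga.population, size=ga.tournament)
                parents.append(pop[contenders[np.argmax(fits[contenders])]])
            child = parents[0].copy()
            if rng.random() < ga.crossover_rate:
                take = rng.random(n_genes) < 0.5
                child[take] = parents[1][take]
            mutate = rng.random(n_genes) < ga.mutation_rate
            if np.any(mutate):
                sigma = ga.mutation_sigma_frac * (hi - lo)
                child[mutate] += rng.normal(0.0, sigma[mutate])
            np.clip(child, lo, hi, out=child)
            new_pop.append(child)
        pop = np.array(new_pop)
        scored = [fitness(ind) for ind in pop]
        fits = np.array([s[0] for s in scored])
        trace.append(max(trace[-1], float(fits.max())))

    best_idx = int(np.argmax(fits))
    # the elite guarantees the final population holds the best-ever individual
    best_genes = pop[best_idx]
    best_score, best_raw = fitness(best_genes)
    best_cfg = _apply_genes(base_config, keys, best_genes)
    return ParEstResult(
        best_params=best_cfg.params,
        best_score=float(best_score),
        trace=np.array(trace),
        best_energies=best_raw,
        evaluated=evaluated,
    )


def compare_simulators(
    configs: dict,
    reference: Trajectory,
    ga: GAConfig,
    m_bins: int = 50,
    max_iter: int = 10,
    tol: float = 1e-3,
):
    """Entropy-weighted comparison of named simulator configurations.

    Each model is re-fit by Par-Est under the current weights in every
    iteration of the evaluation loop (``compare_models``); GA seeds are
    derived per model from ``ga.seed`` so models do not share random
    streams.  Returns ``(results, weights, history)``.
    """
    names = list(configs)

    def make_fit(name, offset):
        def fit(weights, p1, p2):
            ga_m = replace(ga, seed=(ga.seed + offset) % (2**31 - 1))
            res = par_est(reference, configs[name], ga_m,
                          weights=weights, p1=p1, p2=p2)
            return res.best_energies
        return fit

    fits = {name: make_fit(name, k) for k, name in enumerate(names)}
    return compare_models(fits, reference, m_bins=m_bins,
                          max_iter=max_iter, tol=tol)


# ---------------------------------------------------------------------------
# synthetic fixtures
# ---------------------------------------------------------------------------

def generate_fixture(
    kind: str,
    n_insects: int = 50,
    n_frames: int = 500,
    dt: float = 1.0 / 60.0,
    seed: int = 0,
    separation: float = 2.0,
    speeds: tuple[float, float] = (3.0, 1.0),
    burn_in: int = 300,
) -> Trajectory:
    """Synthetic trajectories standing in for motion-capture recordings.

    ``swarmlike`` runs the full dynamics + Curl-noise model with the midge
    box defaults (noisy, bounded, weakly aligned kinematics emulating an
    indoor midge swarm); ``burn_in`` equilibration frames are simulated and
    discarded so the fixture records an established swarm, as a motion
    capture session would.  The others are analytic with closed-form metric
    values: ``lattice`` (static cubic grid), ``straightline`` (constant
    distinct velocities) and ``two_body`` (two insects co-rotating at a
    fixed separation with distinct constant speeds).
    """
    if n_insects < 1:
        raise ValueError("n_insects must be >= 1")
    t = np.arange(n_frames)[:, None] * dt

    if kind == "swarmlike":
        cfg = build_scenario(
            "midge_box", n_insects=n_insects, n_frames=n_frames + burn_in,
            dt=dt, seed=seed,
        )
        traj = run(cfg)
        positions = traj.positions[burn_in:]
        meta = dict(traj.metadata, kind="swarmlike", burn_in=burn_in)
        return Trajectory(positions, dt, meta)

    if kind == "lattice":
        side = int(np.ceil(n_insects ** (1 / 3)))
        grid = np.stack(
            np.meshgrid(*[np.arange(side)] * 3, indexing="ij"), axis=-1
        ).reshape(-1, 3)[:n_insects]
        pos = np.repeat(grid[None, :, :].astype(float), n_frames, axis=0)
        return Trajectory(pos, dt, {"kind": "lattice"})

    if kind == "straightline":
        rng = np.random.default_rng(seed)
        starts = rng.uniform(0, 10, size=(n_insects, 3))
        vels = rng.uniform(0.5, 2.0, size=(n_insects, 3))
        pos = starts[None, :, :] + t[:, :, None] * vels[None, :, :]
        return Trajectory(pos, dt, {"kind": "straightline"})

    if kind == "two_body":
        # co-rotating circles about a common center: separation and the two
        # speeds are constant in closed form
        w = 1.0  # angular rate (rad/s)
        r0, r1 = speeds[0] / w, speeds[1] / w
        if abs((r0 - r1) - separation) > 1e-12:
            # adjust the angular rate so the radial gap equals `separation`
            w = (speeds[0] - speeds[1]) / separation
            if w <= 0:
                raise ValueError("speeds must differ to hold a fixed separation")
            r0, r1 = speeds[0] / w, speeds[1] / w
        ang = w * t[:, 0]
        pos = np.zeros((n_frames, 2, 3))
        pos[:, 0, 0] = r0 * np.cos(ang)
        pos[:, 0, 1] = r0 * np.sin(ang)
        pos[:, 1, 0] = r1 * np.cos(ang)
        pos[:, 1, 1] = r1 * np.sin(ang)
        return Trajectory(pos, dt, {"kind": "two_body", "separation": separation})

    raise ValueError(f"unknown fixture kind {kind!r}")
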