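"""Gain optimization: seeded evolutionary minimization of the gait cost.

The ten reflex gains are optimized with a real-coded evolutionary algorithm
(scipy's differential evolution, deterministic under a fixed seed) against
the multi-objective cost.  The published optimized gain column can be
injected into the initial population, which together with elitist updating
guarantees the best cost never increases over generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import differential_evolution

from .cost import cost_function
from .params import GAIN_NAMES, CostWeights, ReflexGains, SimConfig
from .simulate import simulate


@dataclass
class GASettings:
    """Evolutionary-run settings (scaled-down defaults for desk use)."""

    popsize: int = 20
    generations: int = 5
    seed: int = 0
    bounds_rel: float = 0.3  # +-30% box around the seed gains
    mutation: tuple = (0.3, 0.9)
    recombination: float = 0.7


@dataclass
class OptimizationResult:
    gains: ReflexGains
    cost: float
    log: list = field(default_factory=list)
    nfev: int = 0


def default_bounds(seed_gains: ReflexGains, rel: float = 0.3):
    """A +-rel box around a seed gain set (gains are kept non-negative)."""
    x0 = seed_gains.as_array()
    lo = np.maximum(x0 * (1.0 - rel), 0.0)
    hi = x0 * (1.0 + rel)
    hi = np.where(hi <= lo, lo + 1e-6, hi)
    return list(zip(lo, hi))


def optimize_gains(
    kind: str,
    weights: CostWeights | None = None,
    settings: GASettings | None = None,
    config: SimConfig | None = None,
    seed_gains: ReflexGains | None = None,
    bounds=None,
) -> OptimizationResult:
    """Minimize the gait cost over the ten reflex gains for one variant.

    Deterministic under ``settings.seed``.  Each cost evaluation is a full
    forward simulation; falls terminate early and are penalized by the
    cost's fall term, so infeasible individuals are cheap.
    """
    settings = settings or GASettings()
    weights = weights or CostWeights()
    config = config or SimConfig()
    seed_gains = seed_gains or ReflexGains.table(kind)
    bounds = bounds or default_bounds(seed_gains, settings.bounds_rel)

    log: list[dict] = []
    nfev = 0

    def objective(x):
        nonlocal nfev
        nfev += 1
        tr = simulate(kind, gains=ReflexGains.from_array(x), config=config)
        return cost_function(tr, weights, t_sim_des=config.duration).total

    rng = np.random.default_rng(settings.seed)
    npar = len(GAIN_NAMES)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    init = lo + (hi - lo) * rng.random((max(settings.popsize, 5), npar))
    init[0] = np.clip(seed_gains.as_array(), lo, hi)  # elitist seeding

    def callback(xk, convergence=0.0):
        log.append({"best_x": np.asarray(xk).tolist(),
                    "convergence": float(convergence)})

    res = differential_evolution(
        objective,
        bounds=bounds,
        init=init,
        maxiter=settings.generations,
        mutation=settings.mutation,
        recombination=settings.recombination,
        seed=settings.seed,
        polish=False,
        tol=0.0,
        updating="immediate",
        callback=callback,
    )
    return OptimizationResult(
        gains=ReflexGains.from_array(res.x),
        cost=float(res.fun),
        log=log,
        nfev=nfev,
    )
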