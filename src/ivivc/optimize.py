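"""Hybrid differential-evolution / particle-swarm (DEPS) global optimizer.

A from-scratch box-bounded stochastic minimizer in the spirit of the DEPS
solver found in spreadsheet nonlinear solvers: every generation each agent
takes, with probability ``de_probability``, a DE/rand/1/bin step (greedy
selection) and otherwise a standard inertial PSO velocity step. The two
heuristics share one population, one personal-best memory and one global
best, which is returned as the best-ever point.

Fully deterministic for a fixed seed. Bound handling is by clamping.
Convergence is declared on objective stagnation; fits using this module
report ``converged=False`` rather than raising, so pipelines always
complete.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DEPSConfig", "OptResult", "minimize"]


@dataclass(frozen=True)
class DEPSConfig:
    """Tuning knobs of the hybrid optimizer (conventional DE/PSO values)."""

    bounds: tuple[tuple[float, float], ...] = ()
    population_size: int = 40
    max_generations: int = 2000
    de_weight: float = 0.8  # DE differential weight F
    crossover_rate: float = 0.9  # DE binomial crossover CR
    inertia: float = 0.72  # PSO w
    cognitive: float = 1.49  # PSO c1
    social: float = 1.49  # PSO c2
    de_probability: float = 0.5  # chance of a DE step vs a PSO step
    seed: int = 0
    tolerance: float = 1e-10  # objective stagnation threshold
    stagnation_window: int = 50  # generations without improvement to stop

    def __post_init__(self) -> None:
        bounds = tuple((float(lo), float(hi)) for lo, hi in self.bounds)
        object.__setattr__(self, "bounds", bounds)
        if any(lo >= hi for lo, hi in bounds):
            raise ValueError("each bound must satisfy low < high")
        if self.population_size < 8:
            raise ValueError("population_size must be at least 8")
        if not 0.0 < self.de_weight < 2.0:
            raise ValueError("de_weight must lie in (0, 2)")
        if not 0.0 < self.crossover_rate < 1.0:
            raise ValueError("crossover_rate must lie in (0, 1)")
        if not 0.0 <= self.de_probability <= 1.0:
            raise ValueError("de_probability must lie in [0, 1]")


@dataclass
class OptResult:
    best_params: np.ndarray
    best_objective: float
    generations_used: int
    converged: bool
    trace: np.ndarray = field(repr=False)


def _safe(objective, x: np.ndarray) -> float:
    val = objective(x)
    return float(val) if np.isfinite(val) else np.inf


def minimize(objective, config: DEPSConfig) -> OptResult:
    """Minimize ``objective`` over the box in ``config.bounds``.

    Non-finite objective values are treated as +inf penalties. The
    per-generation best-ever objective trace is nonincreasing by
    construction (greedy elitism on the global best).
    """
    if not config.bounds:
        raise ValueError("config.bounds must define at least one parameter")
    rng = np.random.default_rng(config.seed)
    lo = np.array([b[0] for b in config.bounds])
    hi = np.array([b[1] for b in config.bounds])
    dim = lo.size
    npop = config.population_size

    pos = lo + rng.random((npop, dim)) * (hi - lo)
    vel = np.zeros((npop, dim))
    fit = np.array([_safe(objective, pos[i]) for i in range(npop)])
    pbest = pos.copy()
    pbest_fit = fit.copy()

    g_idx = int(np.argmin(fit))
    gbest = pos[g_idx].copy()
    gbest_fit = float(fit[g_idx])

    trace = []
    last_improved = 0
    last_best = gbest_fit
    gen = 0
    for gen in range(1, config.max_generations + 1):
        for i in range(npop):
            if rng.random() < config.de_probability:
                # DE/rand/1/bin with greedy selection
                choices = rng.choice(npop - 1, size=3, replace=False)
                choices[choices >= i] += 1
                r1, r2, r3 = pos[choices]
                mutant = np.clip(
                    r1 + config.de_weight * (r2 - r3), lo, hi
                )
                cross = rng.random(dim) < config.crossover_rate
                cross[rng.integers(dim)] = True
                trial = np.where(cross, mutant, pos[i])
                f_trial = _safe(objective, trial)
                if f_trial <= fit[i]:
                    pos[i] = trial
                    fit[i] = f_trial
            else:
                # inertial PSO step (position accepted regardless)
                r1 = rng.random(dim)
                r2 = rng.random(dim)
                vel[i] = (
                    config.inertia * vel[i]
                    + config.cognitive * r1 * (pbest[i] - pos[i])
                    + config.social * r2 * (gbest - pos[i])
                )
                pos[i] = np.clip(pos[i] + vel[i], lo, hi)
                fit[i] = _safe(objective, pos[i])

            if fit[i] < pbest_fit[i]:
                pbest[i] = pos[i].copy()
                pbest_fit[i] = fit[i]
            if fit[i] < gbest_fit:
                gbest = pos[i].copy()
                gbest_fit = fit[i]

        trace.append(gbest_fit)
        if last_best - gbest_fit > config.tolerance:
            last_improved = gen
            last_best = gbest_fit
        elif gen - last_improved >= config.stagnation_window:
            return OptResult(gbest, gbest_fit, gen, True, np.asarray(trace))

    return OptResult(gbest, gbest_fit, gen, False, np.asarray(trace))
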