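"""Proportional-hazards covariate effects and random covariate paths.

Individual hazards are built multiplicatively from a discretized baseline:
``h_i(t) = h0(t) * m^{x_i(t)}``, where the per-unit multiplier ``m`` is
either ``exp(beta)`` (``beta`` a log-hazard ratio, the usual Cox convention)
or ``beta`` itself (``beta`` a hazard ratio).  Covariates are piecewise
constant within each interval, evaluated at its left endpoint — the same
convention as the piecewise-constant hazard itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import HazardGrid, pmf_from_hazards
from .sampling import ProbabilityMatrix

__all__ = [
    "CovariatePath",
    "RandomWalkSpec",
    "EffectSpec",
    "ph_constant_covariate",
    "ph_time_dependent",
    "gaussian_random_walk",
    "probability_matrix_from_paths",
]


@dataclass(frozen=True)
class CovariatePath:
    """Time-indexed covariate values for one individual.

    ``values[t]`` applies on the interval ``[t*delta_t, (t+1)*delta_t)``; the
    length must match the hazard grid it modifies.
    """

    delta_t: float
    values: np.ndarray
    id: str | int | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 1:
            raise ValueError("covariate path must be a nonempty 1-d sequence")
        if not np.all(np.isfinite(v)):
            raise ValueError("covariate path contains non-finite values")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "delta_t", float(self.delta_t))

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class RandomWalkSpec:
    """Gaussian random walk ``y(t) = y(t-1) + eps``, ``eps ~ Normal(0, sigma)``."""

    sigma: float
    n_paths: int
    horizon: int
    init: float = 0.0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.horizon < 1:
            raise ValueError("horizon must be at least one step")
        if self.n_paths < 1:
            raise ValueError("n_paths must be at least 1")


@dataclass(frozen=True)
class EffectSpec:
    """A proportional-hazards covariate effect.

    ``interpretation='log_hazard_ratio'``: multiplier ``exp(beta * x)``.
    ``interpretation='hazard_ratio'``: per-unit multiplier ``beta ** x``
    (requires ``beta > 0``).
    """

    beta: float
    interpretation: str = "log_hazard_ratio"

    def __post_init__(self):
        if self.interpretation not in ("log_hazard_ratio", "hazard_ratio"):
            raise ValueError(f"unknown interpretation {self.interpretation!r}")
        if self.interpretation == "hazard_ratio" and self.beta <= 0:
            raise ValueError("a hazard ratio must be positive")

    def multiplier(self, x) -> np.ndarray:
        """Hazard multiplier ``m^x`` for covariate value(s) ``x``."""
        x = np.asarray(x, dtype=float)
        if self.interpretation == "log_hazard_ratio":
            return np.exp(self.beta * x)
        return np.power(self.beta, x)

    @property
    def log_multiplier(self) -> float:
        """``ln m``: the log hazard ratio per covariate unit."""
        if self.interpretation == "log_hazard_ratio":
            return self.beta
        return float(np.log(self.beta))


def _apply_multiplier(h0: HazardGrid, mult) -> HazardGrid:
    hazards = h0.hazards * mult
    if not np.all(np.isfinite(hazards)):
        raise ValueError("covariate effect produced non-finite hazards "
                         "(overflowing multiplier?)")
    return HazardGrid(delta_t=h0.delta_t, hazards=hazards, origin=h0.origin)


def ph_constant_covariate(h0: HazardGrid, x: float, effect: EffectSpec) -> HazardGrid:
    """Scale a baseline hazard grid by ``m^x`` for a time-independent covariate."""
    return _apply_multiplier(h0, float(effect.multiplier(x)))


def ph_time_dependent(h0: HazardGrid, path: CovariatePath,
                      effect: EffectSpec) -> HazardGrid:
    """Per-interval scaling ``h_t = h0_t * m^{x(t)}`` for a covariate path."""
    if len(path) != len(h0):
        raise ValueError(
            f"covariate path length {len(path)} != hazard grid length {len(h0)}")
    return _apply_multiplier(h0, effect.multiplier(path.values))


def gaussian_random_walk(spec: RandomWalkSpec, seed=None) -> list[CovariatePath]:
    """Simulate independent Gaussian random-walk covariate paths.

    Each path has ``horizon`` values (one per interval): ``values[0] = init``
    and ``horizon - 1`` Normal(0, sigma) increments.  ``delta_t`` of the
    returned paths is 1 (one walk step per interval).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    steps = rng.normal(0.0, spec.sigma, size=(spec.n_paths, spec.horizon - 1))
    walks = np.concatenate(
        [np.full((spec.n_paths, 1), spec.init), spec.init + np.cumsum(steps, axis=1)],
        axis=1)
    return [CovariatePath(delta_t=1.0, values=walks[i], id=i)
            for i in range(spec.n_paths)]


def probability_matrix_from_paths(h0: HazardGrid, paths,
                                  effect: EffectSpec) -> ProbabilityMatrix:
    """One pmf row per covariate path, ready for the multivariate sampler.

    Vectorized across individuals: builds the K x (Z+1) matrix of per-interval
    hazards ``h0_t * m^{x_k(t)}``, accumulates, and differences the CDF rows.
    """
    paths = list(paths)
    if not paths:
        raise ValueError("need at least one covariate path")
    x = np.vstack([p.values for p in paths])
    if x.shape[1] != len(h0):
        raise ValueError(
            f"covariate path length {x.shape[1]} != hazard grid length {len(h0)}")
    hazards = h0.hazards[None, :] * effect.multiplier(x)
    if not np.all(np.isfinite(hazards)):
        raise ValueError("covariate effect produced non-finite hazards")
    H = np.cumsum(hazards * h0.delta_t, axis=1)
    F = -np.expm1(-H)
    probs = np.diff(F, axis=1, prepend=0.0)
    residual = np.maximum(1.0 - probs.sum(axis=1), 0.0)
    return ProbabilityMatrix(delta_t=h0.delta_t, probs=probs, residual=residual)
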