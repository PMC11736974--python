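"""Discretized hazards and their conversions down to interval probabilities.

The native representation is a :class:`HazardGrid`: a uniform time grid of
piecewise-constant hazards ``h_t`` on half-open intervals
``[t*delta_t, (t+1)*delta_t)`` for ``t = 0..Z``.  From it the chain

    h_t  ->  H_t = sum_{x<t} h_x * delta_t   (cumulative hazard)
         ->  F_t = 1 - exp(-H_t)             (CDF)
         ->  p_t = F_{t+1} - F_t             (interval probabilities)

produces the parameters of a categorical distribution over time intervals,
plus the residual mass ``1 - F_{Z+1}`` of never observing the event within
the grid's horizon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import integrate

__all__ = [
    "HazardGrid",
    "CumulativeHazardGrid",
    "CdfGrid",
    "EventPmf",
    "cumulative_from_interval_hazards",
    "cdf_from_cumulative",
    "interval_hazards_from_continuous_cumulative",
    "continuous_cumulative_from_hazard_function",
    "pmf_from_cdf",
    "pmf_from_hazards",
    "rescale_hazards",
    "refine",
]

#: tolerance below which small negative numerical noise is clipped to zero
_NEG_TOL = 1e-12


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if arr.size < 1:
        raise ValueError(f"{name} must have at least one entry")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def _check_delta_t(delta_t: float) -> float:
    delta_t = float(delta_t)
    if not np.isfinite(delta_t) or delta_t <= 0:
        raise ValueError(f"delta_t must be a positive finite number, got {delta_t}")
    return delta_t


@dataclass(frozen=True)
class HazardGrid:
    """Per-interval hazards ``h_t`` on a uniform grid of width ``delta_t``.

    Parameters
    ----------
    delta_t : float
        Interval width in time units.
    hazards : array-like
        Nonnegative hazard within each interval ``[t*delta_t, (t+1)*delta_t)``.
    origin : float
        Time of the left edge of interval 0 (default 0).
    """

    delta_t: float
    hazards: np.ndarray
    origin: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "delta_t", _check_delta_t(self.delta_t))
        h = _as_float_array(self.hazards, "hazards")
        if np.any(h < 0):
            raise ValueError("hazards must be nonnegative")
        object.__setattr__(self, "hazards", h)
        object.__setattr__(self, "origin", float(self.origin))

    def __len__(self) -> int:
        return self.hazards.size

    @property
    def interval_starts(self) -> np.ndarray:
        """Left edges of the intervals, in time units."""
        return self.origin + self.delta_t * np.arange(len(self))

    @classmethod
    def from_function(cls, h: Callable[[np.ndarray], np.ndarray], delta_t: float,
                      horizon: float, origin: float = 0.0) -> "HazardGrid":
        """Discretize a continuous hazard by evaluating it at interval starts.

        This is the piecewise-constant-from-the-left convention: within each
        interval the hazard is frozen at its value at the left edge.  For a
        hazard increasing in time this slightly understates the cumulative
        hazard (and overstates mean event times) relative to the exact
        finite-difference route
        :func:`interval_hazards_from_continuous_cumulative`; the gap shrinks
        with ``delta_t``.
        """
        delta_t = _check_delta_t(delta_t)
        n = int(np.ceil(round(horizon / delta_t, 9)))
        if n < 1:
            raise ValueError("horizon must cover at least one interval")
        t = origin + delta_t * np.arange(n)
        vals = np.asarray(h(t), dtype=float)
        return cls(delta_t=delta_t, hazards=vals, origin=origin)

    def to_csv(self, path) -> None:
        """Write the grid as CSV with columns ``t_start, delta_t, hazard``."""
        pd.DataFrame({
            "t_start": self.interval_starts,
            "delta_t": self.delta_t,
            "hazard": self.hazards,
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "HazardGrid":
        """Read a grid written by :meth:`to_csv` (header required)."""
        df = pd.read_csv(path)
        required = {"t_start", "delta_t", "hazard"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"hazard CSV missing columns: {sorted(missing)}")
        delta_t = df["delta_t"].to_numpy(dtype=float)
        if not np.allclose(delta_t, delta_t[0], rtol=0, atol=1e-12):
            raise ValueError("hazard CSV must have a single uniform delta_t")
        starts = df["t_start"].to_numpy(dtype=float)
        expected = starts[0] + delta_t[0] * np.arange(len(df))
        if not np.allclose(starts, expected, rtol=0, atol=1e-9 * max(1.0, delta_t[0])):
            raise ValueError("t_start column is not a uniform grid")
        return cls(delta_t=float(delta_t[0]),
                   hazards=df["hazard"].to_numpy(dtype=float),
                   origin=float(starts[0]))


@dataclass(frozen=True)
class CumulativeHazardGrid:
    """Cumulative hazard ``H_t`` at interval starts ``t = 0..Z+1``; ``H_0 = 0``."""

    delta_t: float
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "delta_t", _check_delta_t(self.delta_t))
        v = _as_float_array(self.values, "values")
        if v[0] != 0.0:
            raise ValueError(f"cumulative hazard must start at 0, got {v[0]}")
        if np.any(np.diff(v) < -_NEG_TOL):
            raise ValueError("cumulative hazard must be nondecreasing")
        v = np.maximum.accumulate(v)  # clip numerical noise
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class CdfGrid:
    """Event-time CDF ``F_t`` at interval starts."""

    delta_t: float
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "delta_t", _check_delta_t(self.delta_t))
        v = _as_float_array(self.values, "values")
        if np.any(v < -_NEG_TOL) or np.any(v > 1 + _NEG_TOL):
            raise ValueError("CDF values must lie in [0, 1]")
        if np.any(np.diff(v) < -_NEG_TOL):
            raise ValueError("CDF must be nondecreasing")
        v = np.clip(np.maximum.accumulate(v), 0.0, 1.0)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class EventPmf:
    """Interval probabilities ``p_t`` plus the beyond-horizon residual mass.

    ``probs[t]`` is the probability of the event occurring in interval
    ``[t*delta_t, (t+1)*delta_t)``; ``residual`` is the probability of no
    event by the horizon, so ``sum(probs) + residual == 1``.
    """

    delta_t: float
    probs: np.ndarray
    residual: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "delta_t", _check_delta_t(self.delta_t))
        p = _as_float_array(self.probs, "probs")
        if np.any(p < 0):
            raise ValueError("probabilities must be nonnegative")
        r = float(self.residual)
        if r < -_NEG_TOL:
            raise ValueError("residual must be nonnegative")
        r = max(r, 0.0)
        total = p.sum() + r
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probs + residual must sum to 1, got {total!r}")
        object.__setattr__(self, "probs", p)
        object.__setattr__(self, "residual", r)

    def __len__(self) -> int:
        return self.probs.size

    def renormalized(self) -> "EventPmf":
        """Condition on the event occurring by the horizon (residual -> 0).

        Opt-in: silently renormalizing a truncated distribution biases
        expected values, so the residual is carried explicitly by default.
        """
        total = self.probs.sum()
        if total <= 0:
            raise ValueError("cannot renormalize a pmf with zero event mass")
        return EventPmf(self.delta_t, self.probs / total, 0.0)


def cumulative_from_interval_hazards(grid: HazardGrid) -> CumulativeHazardGrid:
    """Accumulate interval hazards: ``H_t = sum_{x<t} h_x * delta_t``.

    The output has one more entry than the input and starts at 0, so
    ``values[t]`` is the cumulative hazard at the *start* of interval ``t``.
    """
    values = np.concatenate([[0.0], np.cumsum(grid.hazards * grid.delta_t)])
    return CumulativeHazardGrid(delta_t=grid.delta_t, values=values)


def cdf_from_cumulative(cum: CumulativeHazardGrid) -> CdfGrid:
    """Map cumulative hazard to the CDF: ``F = 1 - exp(-H)``."""
    return CdfGrid(delta_t=cum.delta_t, values=-np.expm1(-cum.values))


def interval_hazards_from_continuous_cumulative(
    H: Callable[[np.ndarray], np.ndarray], delta_t: float, horizon: float,
    origin: float = 0.0,
) -> HazardGrid:
    """Discretize a continuous cumulative hazard by finite differences.

    ``h_t = (H((t+1)*delta_t) - H(t*delta_t)) / delta_t``, so re-accumulating
    with :func:`cumulative_from_interval_hazards` reproduces ``H`` at the grid
    points exactly.  Differences more negative than ``-1e-12`` raise; smaller
    negative noise is clipped to zero.
    """
    delta_t = _check_delta_t(delta_t)
    n = int(np.ceil(round(horizon / delta_t, 9)))
    if n < 1:
        raise ValueError("horizon must cover at least one interval")
    edges = origin + delta_t * np.arange(n + 1)
    Hv = np.asarray(H(edges), dtype=float)
    diffs = np.diff(Hv)
    if np.any(diffs < -_NEG_TOL):
        raise ValueError("cumulative hazard function is decreasing on the grid")
    return HazardGrid(delta_t=delta_t, hazards=np.maximum(diffs, 0.0) / delta_t,
                      origin=origin)


def continuous_cumulative_from_hazard_function(
    h: Callable[[float], float], delta_t: float, horizon: float,
    tol: float = 1e-10, origin: float = 0.0,
) -> CumulativeHazardGrid:
    """Integrate a continuous hazard onto a grid: ``H(t) = int_0^t h(x) dx``.

    Adaptive quadrature per interval (``scipy.integrate.quad``), accumulated so
    ``values[t]`` is the integral from ``origin`` to the start of interval ``t``
    within the stated tolerance.  Raises if ``h`` is negative at any
    quadrature-check point.
    """
    delta_t = _check_delta_t(delta_t)
    n = int(np.ceil(round(horizon / delta_t, 9)))
    edges = origin + delta_t * np.arange(n + 1)
    probes = np.concatenate([edges, edges[:-1] + delta_t / 2])
    vals = np.asarray(h(probes), dtype=float)
    if np.any(vals < 0):
        t_bad = probes[np.argmin(vals)]
        raise ValueError(f"hazard function is negative at t={t_bad}")
    pieces = np.empty(n)
    for i in range(n):
        pieces[i], _ = integrate.quad(h, edges[i], edges[i + 1],
                                      epsabs=tol, epsrel=tol)
    values = np.concatenate([[0.0], np.cumsum(pieces)])
    return CumulativeHazardGrid(delta_t=delta_t, values=values)


def pmf_from_cdf(cdf: CdfGrid) -> EventPmf:
    """Interval probabilities ``p_t = F_{t+1} - F_t``; residual ``1 - F_{Z+1}``."""
    diffs = np.diff(cdf.values)
    if np.any(diffs < -_NEG_TOL):
        raise ValueError("CDF differences are negative beyond tolerance")
    probs = np.maximum(diffs, 0.0)
    # residual defined so probs + residual sum to 1 exactly in float
    residual = max(1.0 - cdf.values[0] - probs.sum(), 0.0)
    return EventPmf(delta_t=cdf.delta_t, probs=probs, residual=residual)


def pmf_from_hazards(grid: HazardGrid, renormalize: bool = False) -> EventPmf:
    """Full chain ``h_t -> H_t -> F_t -> p_t`` in one call."""
    pmf = pmf_from_cdf(cdf_from_cumulative(cumulative_from_interval_hazards(grid)))
    return pmf.renormalized() if renormalize else pmf


def rescale_hazards(grid: HazardGrid, scale_ratio: float) -> HazardGrid:
    """Change the time unit of a hazard grid.

    ``scale_ratio`` is the ratio of the given scale to the desired scale
    (e.g. 1/12 to express yearly hazards per month).  Hazard values are
    multiplied by the ratio and ``delta_t`` divided by it, so the cumulative
    hazard over the same physical span is unchanged and a round trip with the
    inverse ratio is exact.  Use :func:`refine` afterwards to subdivide
    intervals when sampling on the finer scale.
    """
    scale_ratio = float(scale_ratio)
    if not np.isfinite(scale_ratio) or scale_ratio <= 0:
        raise ValueError(f"scale_ratio must be positive, got {scale_ratio}")
    return HazardGrid(delta_t=grid.delta_t / scale_ratio,
                      hazards=grid.hazards * scale_ratio,
                      origin=grid.origin / scale_ratio)


def refine(grid: HazardGrid, k: int) -> HazardGrid:
    """Subdivide each interval into ``k`` equal pieces with the same hazard."""
    k = int(k)
    if k < 1:
        raise ValueError("k must be a positive integer")
    return HazardGrid(delta_t=grid.delta_t / k,
                      hazards=np.repeat(grid.hazards, k),
                      origin=grid.origin)
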