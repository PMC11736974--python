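"""Categorical sampling of event-time intervals and the continuous-time correction.

Draws are interval indices (categories).  A draw landing in the residual
beyond-horizon mass is flagged with the sentinel :data:`BEYOND_HORIZON` and
carries no finite time.  The continuous-time correction adds an independent
``U[0, delta_t)`` offset to each category's left edge, which raises the mean
by exactly ``delta_t / 2`` in expectation — the sampling analogue of a
half-cycle correction, but preserving within-interval spread.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .grids import EventPmf, _check_delta_t

__all__ = [
    "BEYOND_HORIZON",
    "ProbabilityMatrix",
    "EventTimes",
    "sample_univariate",
    "sample_multivariate",
    "continuous_time_correction",
    "expected_time",
]

logger = logging.getLogger(__name__)

#: category sentinel for draws falling beyond the grid horizon
BEYOND_HORIZON = -1

_ROW_TOL = 1e-12


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class ProbabilityMatrix:
    """K individual-specific probability rows over a shared interval grid.

    ``probs[k, t]`` is individual ``k``'s probability of the event in interval
    ``t``; ``residual[k]`` the probability of no event by the horizon.  Every
    row must sum to 1 (probs + residual) within 1e-12.
    """

    delta_t: float
    probs: np.ndarray
    residual: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "delta_t", _check_delta_t(self.delta_t))
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[0] < 1 or p.shape[1] < 1:
            raise ValueError(f"probs must be a K x (Z+1) matrix, got shape {p.shape}")
        r = np.asarray(self.residual, dtype=float)
        if r.shape != (p.shape[0],):
            raise ValueError("residual must have one entry per row")
        if not (np.all(np.isfinite(p)) and np.all(np.isfinite(r))):
            raise ValueError("probabilities must be finite")
        if np.any(p < 0) or np.any(r < -_ROW_TOL):
            raise ValueError("probabilities must be nonnegative")
        row_sums = p.sum(axis=1) + r
        bad = np.abs(row_sums - 1.0) > 1e-9
        if np.any(bad):
            k = int(np.argmax(bad))
            raise ValueError(f"row {k} sums to {row_sums[k]!r}, expected 1")
        object.__setattr__(self, "probs", p)
        object.__setattr__(self, "residual", np.maximum(r, 0.0))

    @property
    def n_rows(self) -> int:
        return self.probs.shape[0]

    @property
    def n_intervals(self) -> int:
        return self.probs.shape[1]

    @classmethod
    def from_pmfs(cls, pmfs) -> "ProbabilityMatrix":
        """Stack per-individual :class:`EventPmf` objects (equal grids) into rows."""
        pmfs = list(pmfs)
        if not pmfs:
            raise ValueError("need at least one pmf")
        delta_t = pmfs[0].delta_t
        z = len(pmfs[0])
        for pmf in pmfs:
            if pmf.delta_t != delta_t or len(pmf) != z:
                raise ValueError("all pmfs must share delta_t and grid length")
        return cls(delta_t=delta_t,
                   probs=np.vstack([pmf.probs for pmf in pmfs]),
                   residual=np.array([pmf.residual for pmf in pmfs]))

    def row(self, k: int) -> EventPmf:
        return EventPmf(self.delta_t, self.probs[k], self.residual[k])


@dataclass(frozen=True)
class EventTimes:
    """Sampled event-time categories, optionally corrected to continuous time.

    ``categories`` holds interval indices (or :data:`BEYOND_HORIZON`);
    ``times`` holds ``category * delta_t + Y`` with ``Y ~ U[0, delta_t)``
    once corrected, NaN for beyond-horizon draws.
    """

    delta_t: float
    categories: np.ndarray
    times: np.ndarray | None = None
    corrected: bool = False

    def __post_init__(self):
        object.__setattr__(self, "delta_t", _check_delta_t(self.delta_t))
        cats = np.asarray(self.categories)
        if not np.issubdtype(cats.dtype, np.integer):
            raise ValueError("categories must be integers")
        object.__setattr__(self, "categories", cats)

    def __len__(self) -> int:
        return self.categories.size

    @property
    def is_event(self) -> np.ndarray:
        """Boolean mask of draws with an event inside the horizon."""
        return self.categories != BEYOND_HORIZON

    @property
    def n_beyond_horizon(self) -> int:
        return int(np.sum(~self.is_event))

    def mean(self) -> float:
        """Mean event time over draws with an event inside the horizon.

        Uses corrected continuous times if present, otherwise the interval
        left edges ``category * delta_t``.  Beyond-horizon draws are excluded
        (their count is logged).
        """
        mask = self.is_event
        n_out = self.categories.size - int(mask.sum())
        if n_out:
            logger.info("excluding %d beyond-horizon draws from mean", n_out)
        if not np.any(mask):
            return float("nan")
        if self.corrected and self.times is not None:
            return float(np.mean(self.times[mask]))
        return float(np.mean(self.categories[mask]) * self.delta_t)


def _inverse_cdf_draw(probs: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Map uniforms to category indices by inverse CDF on cumulative sums.

    ``probs`` may omit the residual; uniforms beyond the total mass map to
    index ``Z+1`` (caller converts to the sentinel).
    """
    cum = np.cumsum(probs)
    return np.searchsorted(cum, u, side="right")


def sample_univariate(pmf: EventPmf, n: int, seed=None) -> EventTimes:
    """Draw ``n`` i.i.d. event-time categories from one interval pmf.

    Inverse-CDF sampling: one uniform per draw; mass beyond the horizon maps
    to :data:`BEYOND_HORIZON`.  Reproducible under a fixed seed.
    """
    n = int(n)
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    idx = _inverse_cdf_draw(pmf.probs, rng.random(n))
    cats = np.where(idx >= len(pmf), BEYOND_HORIZON, idx).astype(np.int64)
    return EventTimes(delta_t=pmf.delta_t, categories=cats)


def sample_multivariate(pm: ProbabilityMatrix, seed=None) -> EventTimes:
    """Draw one event-time category per row of a probability matrix.

    Vectorized multivariate categorical draw: exactly one uniform variate is
    consumed per row and mapped through that row's cumulative sums (row-wise
    inverse CDF), so rows are independent and the draw is reproducible under
    a fixed seed.
    """
    rng = _rng(seed)
    cum = np.cumsum(pm.probs, axis=1)
    u = rng.random(pm.n_rows)
    idx = (u[:, None] >= cum).sum(axis=1)
    cats = np.where(idx >= pm.n_intervals, BEYOND_HORIZON, idx).astype(np.int64)
    return EventTimes(delta_t=pm.delta_t, categories=cats)


def continuous_time_correction(draws: EventTimes, seed=None) -> EventTimes:
    """Add ``Y ~ U[0, delta_t)`` to each sampled category's left edge.

    Returns a corrected copy with ``times = category * delta_t + Y``; raises
    if the draws are already corrected.  Beyond-horizon draws get NaN times.
    The correction consumes its own random stream, so corrected and
    uncorrected results from the same sampling seed are pairable.
    """
    if draws.corrected:
        raise ValueError("draws are already corrected")
    rng = _rng(seed)
    y = rng.random(len(draws)) * draws.delta_t
    times = draws.categories * draws.delta_t + y
    times[~draws.is_event] = np.nan
    return replace(draws, times=times, corrected=True)


def expected_time(pmf: EventPmf, corrected: bool = True,
                  conditional: bool = False) -> float:
    """Exact expectation of the sampled event time for a given pmf.

    ``sum_t (t * delta_t) * p_t``, plus ``delta_t / 2`` when ``corrected`` —
    the deterministic value Monte-Carlo means converge to.  With residual
    mass the unconditional expectation is undefined (the event may never
    occur); pass ``conditional=True`` to condition on the event occurring
    within the horizon.
    """
    if pmf.residual > 0 and not conditional:
        raise ValueError(
            f"pmf has residual mass {pmf.residual:g}; expected time is only "
            "defined conditional on the event (pass conditional=True)")
    p = pmf.probs
    total = p.sum()
    if total <= 0:
        raise ValueError("pmf has no event mass")
    t = np.arange(len(pmf))
    mean = float((t * pmf.delta_t * p).sum() / (total if conditional else 1.0))
    return mean + (pmf.delta_t / 2 if corrected else 0.0)
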