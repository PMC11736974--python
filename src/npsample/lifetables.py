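"""Life-table input, conversion to hazard grids, and synthetic mortality schedules.

A life table gives, per single year of age, either the conditional death
probability ``q_x`` or the central death rate ``m_x``.  Under the
within-interval constant-hazard assumption the two map exactly onto a
per-age hazard: ``h_x = -ln(1 - q_x)`` (or ``h_x = m_x`` directly), which
drops straight into the interval-probability chain for age-to-death sampling.

Synthetic tables follow a Gompertz–Makeham law ``h(x) = c + a * exp(b*x)``
(background hazard plus exponential senescence), the standard two-component
description of adult human mortality, so tests and examples need no external
mortality data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import HazardGrid
from .parametric import DistSpec, cumulative_hazard_function

__all__ = [
    "LifeTable",
    "GompertzMakeham",
    "read_life_table",
    "hazards_from_life_table",
    "synthetic_life_table",
]


@dataclass(frozen=True)
class LifeTable:
    """Age-indexed mortality: contiguous integer ages from 0 with qx or mx.

    Exactly one of ``qx`` (conditional death probabilities, in [0,1]) or
    ``mx`` (central death rates, >= 0) is given.  The final row is treated as
    an open age interval.
    """

    ages: np.ndarray
    qx: np.ndarray | None = None
    mx: np.ndarray | None = None
    group: str | None = None

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=int)
        if ages.size < 1:
            raise ValueError("life table must have at least one row")
        if ages[0] != 0 or np.any(np.diff(ages) != 1):
            raise ValueError("ages must be contiguous integers starting at 0")
        object.__setattr__(self, "ages", ages)
        if (self.qx is None) == (self.mx is None):
            raise ValueError("exactly one of qx or mx is required")
        for name in ("qx", "mx"):
            col = getattr(self, name)
            if col is None:
                continue
            col = np.asarray(col, dtype=float)
            if col.shape != ages.shape:
                raise ValueError(f"{name} must have one value per age")
            if not np.all(np.isfinite(col)):
                raise ValueError(f"{name} contains non-finite values")
            if name == "qx" and (np.any(col < 0) or np.any(col > 1)):
                bad = int(ages[np.argmax((col < 0) | (col > 1))])
                raise ValueError(f"qx out of [0, 1] at age {bad}")
            if name == "mx" and np.any(col < 0):
                bad = int(ages[np.argmax(col < 0)])
                raise ValueError(f"mx negative at age {bad}")
            object.__setattr__(self, name, col)

    def __len__(self) -> int:
        return self.ages.size


@dataclass(frozen=True)
class GompertzMakeham:
    """Mortality law ``h(x) = c + a * exp(b * x)``: Makeham background ``c``
    plus Gompertz senescence with level ``a`` and log-slope ``b``."""

    a: float
    b: float
    c: float = 0.0

    def __post_init__(self):
        if self.a < 0 or self.b <= 0 or self.c < 0:
            raise ValueError("require a >= 0, b > 0, c >= 0")

    def hazard(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.c + self.a * np.exp(self.b * x)

    def cumulative_hazard(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.c * x + (self.a / self.b) * np.expm1(self.b * x)


def read_life_table(source):
    """Read life table(s) from CSV.

    The header must contain ``age`` plus ``qx`` or ``mx``; an optional
    ``group`` column yields one table per group (returned as a dict keyed by
    group label).  Validation errors name the offending row's age.
    """
    df = pd.read_csv(source)
    cols = {c.lower(): c for c in df.columns}
    if "age" not in cols:
        raise ValueError("life table CSV must have an 'age' column")
    has_q, has_m = "qx" in cols, "mx" in cols
    if not (has_q or has_m):
        raise ValueError("life table CSV must have a 'qx' or 'mx' column")
    rate_col = cols["qx"] if has_q else cols["mx"]

    def build(sub: pd.DataFrame, group=None) -> LifeTable:
        sub = sub.sort_values(cols["age"])
        kwargs = {"qx" if has_q else "mx": sub[rate_col].to_numpy(dtype=float)}
        return LifeTable(ages=sub[cols["age"]].to_numpy(), group=group, **kwargs)

    if "group" in cols:
        return {str(g): build(sub, group=str(g))
                for g, sub in df.groupby(cols["group"], sort=True)}
    return build(df)


def hazards_from_life_table(lt: LifeTable, terminal_cap_age: int = 110) -> HazardGrid:
    """Convert a life table to a yearly hazard grid, extended to a cap age.

    Per-age hazard ``h_x = -ln(1 - q_x)`` (exact under within-interval
    constant hazard), or ``h_x = m_x`` when central rates are given.  The
    final tabulated row is an open interval: its hazard (or, if its
    ``q_x = 1``, the preceding age's) is repeated up to ``terminal_cap_age``
    so the beyond-horizon residual is negligible.  ``q_x = 1`` before the
    final row is an error (an infinite hazard inside the grid).
    """
    if lt.mx is not None:
        h = lt.mx.copy()
    else:
        q = lt.qx
        saturated = q >= 1.0
        if np.any(saturated[:-1]):
            bad = int(lt.ages[np.argmax(saturated[:-1])])
            raise ValueError(f"qx = 1 at age {bad}, before the terminal row "
                             "(infinite hazard)")
        h = np.empty_like(q)
        h[~saturated] = -np.log1p(-q[~saturated])
        if saturated[-1]:
            if len(lt) < 2:
                raise ValueError("cannot infer a terminal hazard from a "
                                 "single all-dying row")
            h[-1] = h[-2]
    terminal_cap_age = int(terminal_cap_age)
    n_extra = terminal_cap_age - len(lt)
    if n_extra > 0:
        h = np.concatenate([h, np.full(n_extra, h[-1])])
    grid = HazardGrid(delta_t=1.0, hazards=h)
    residual = float(np.exp(-np.sum(h)))
    if residual >= 1e-6:
        warnings.warn(
            f"residual survival beyond age {len(h)} is {residual:.2e}; "
            "consider a higher terminal_cap_age", stacklevel=2)
    return grid


def synthetic_life_table(law: GompertzMakeham | DistSpec, max_age: int = 100,
                         group: str | None = None) -> LifeTable:
    """Deterministic synthetic life table from a continuous mortality law.

    ``q_x = 1 - exp(-int_x^{x+1} h(u) du)`` exactly, for ages 0..max_age.
    ``law`` may be a :class:`GompertzMakeham` or any :class:`DistSpec` with a
    closed-form cumulative hazard.
    """
    ages = np.arange(int(max_age) + 1)
    if isinstance(law, GompertzMakeham):
        H = law.cumulative_hazard
    elif isinstance(law, DistSpec):
        H = cumulative_hazard_function(law)
    else:
        raise TypeError(f"unsupported mortality law: {type(law).__name__}")
    edges = np.asarray(H(np.arange(int(max_age) + 2, dtype=float)), dtype=float)
    qx = -np.expm1(-np.diff(edges))
    return LifeTable(ages=ages, qx=qx, group=group)
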