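"""Otolith daily-increment growth analysis.

Lengths-at-age are back-calculated from daily otolith increments with the
biological-intercept method, anchoring the fish-length/otolith-radius
relation at hatch (length 4.5 mm, otolith radius 9 um). For a fish of
capture length ``L_c`` and otolith radius ``O_c``,

    L_a = L_c + (O_a - O_c) (L_c - L_i) / (O_c - O_i)

so each daily increment of width ``w_t`` contributes a daily growth

    dL_t = (L_c - L_i) / (O_c - O_i) * w_t

and the increments telescope: ``sum dL = L_c - L_i``. Age in days is the
increment count (plus a configurable onset offset), and hatch date follows
by subtracting age from the capture date.

The module also provides the additive two-factor ANOVA used to compare
ages/growth between ecotypes and sampling locations, and two-predictor
hierarchical partitioning of length variance into age and growth-rate
contributions.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "OtolithSeries",
    "back_calc_length",
    "daily_growth",
    "hatch_date",
    "two_way_anova",
    "hier_part2",
]

L_INTERCEPT_MM = 4.5  # fish length at hatch
O_INTERCEPT_UM = 9.0  # otolith radius at hatch


@dataclass(frozen=True)
class OtolithSeries:
    """One fish's daily increment record.

    ``increments_um`` is ordered from hatch; the otolith radius at capture is
    the biological-intercept radius plus the summed widths.
    """

    fish_id: str
    increments_um: np.ndarray
    length_capture_mm: float
    capture_date: dt.date | None = None
    o_intercept_um: float = O_INTERCEPT_UM
    l_intercept_mm: float = L_INTERCEPT_MM
    o_capture_um: float = field(default=None)

    def __post_init__(self):
        inc = np.asarray(self.increments_um, dtype=float)
        object.__setattr__(self, "increments_um", inc)
        if inc.size and (inc <= 0).any():
            raise ValueError("increment widths must all be positive")
        oc = self.o_intercept_um + float(inc.sum())
        if self.o_capture_um is None:
            object.__setattr__(self, "o_capture_um", oc)
        elif abs(self.o_capture_um - oc) > 1e-6:
            raise ValueError(
                f"capture radius {self.o_capture_um} inconsistent with "
                f"intercept + increments = {oc}"
            )
        if self.length_capture_mm <= self.l_intercept_mm:
            raise ValueError("capture length must exceed the biological intercept")

    @property
    def n_days(self) -> int:
        return int(self.increments_um.size)


def back_calc_length(series: OtolithSeries, o_a: float) -> float:
    """Biological-intercept back-calculated fish length at otolith radius ``o_a``.

    ``o_a`` must lie within [intercept radius, capture radius]; the map is
    affine and returns the capture length at ``o_a = O_c`` and the intercept
    length at ``o_a = O_i``.
    """
    o_i, o_c = series.o_intercept_um, series.o_capture_um
    if not (o_i <= o_a <= o_c):
        raise ValueError(f"radius {o_a} outside the observed range [{o_i}, {o_c}]")
    l_c, l_i = series.length_capture_mm, series.l_intercept_mm
    return l_c + (o_a - o_c) * (l_c - l_i) / (o_c - o_i)


def daily_growth(series: OtolithSeries) -> tuple[np.ndarray, float]:
    """Per-day growth (mm/day) from increment widths, and its mean.

    ``dL_t = (L_c - L_i)/(O_c - O_i) * w_t``; the vector telescopes to
    ``L_c - L_i``. The mean daily rate equals ``(L_c - L_i) / age`` when all
    days carry one increment.
    """
    if series.n_days < 1:
        raise ValueError("need at least one increment")
    scale = series.o_capture_um - series.o_intercept_um
    if scale <= 0:
        raise ValueError("degenerate otolith: capture radius at the intercept")
    k = (series.length_capture_mm - series.l_intercept_mm) / scale
    dl = k * series.increments_um
    return dl, float(dl.mean())


def hatch_date(series: OtolithSeries, first_increment_offset: int = 0) -> tuple[dt.date, int]:
    """Hatch date and age in days from the increment count.

    Age = number of increments + offset (offset > 0 models a lag between
    hatching and increment onset, shifting hatch earlier); hatch date is the
    capture date minus the age.
    """
    if series.capture_date is None:
        raise ValueError("capture date not set on this series")
    age = series.n_days + int(first_increment_offset)
    return series.capture_date - dt.timedelta(days=age), age


def two_way_anova(values, factor_a, factor_b) -> dict:
    """Additive two-factor ANOVA omnibus test.

    Fits ``value ~ a + b`` with two 2-level factors by least squares and
    tests both factors jointly against the residual:
    ``F = ((SS_null - SS_full)/2) / (SS_full/(n-3))`` on (2, n-3) df.
    Per-factor partial F tests are reported alongside.
    """
    y = np.asarray(values, dtype=float)
    a = np.asarray(factor_a)
    b = np.asarray(factor_b)
    n = y.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    if len(np.unique(a)) != 2 or len(np.unique(b)) != 2:
        raise ValueError("both factors must have exactly 2 levels")
    ia = (a == np.unique(a)[1]).astype(float)
    ib = (b == np.unique(b)[1]).astype(float)
    if np.array_equal(ia, ib) or np.array_equal(ia, 1 - ib):
        raise ValueError("factors are aliased (confounded)")

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    one = np.ones(n)
    ss_full = rss(np.column_stack([one, ia, ib]))
    ss_null = rss(one[:, None])
    df1, df2 = 2, n - 3
    # a response with no variation: F = 0 by convention (avoid 0/0 noise)
    tiny = 1e-12 * max(1.0, float(y @ y))
    if ss_null <= tiny:
        f_val, p = 0.0, 1.0
    elif ss_full <= tiny:
        f_val, p = np.inf, 0.0
    else:
        f_val = ((ss_null - ss_full) / df1) / (ss_full / df2)
        p = float(sps.f.sf(f_val, df1, df2))

    def partial(ss_reduced):
        if ss_full <= tiny:
            return (0.0, 1.0) if ss_reduced <= tiny else (np.inf, 0.0)
        f = (ss_reduced - ss_full) / (ss_full / df2)
        return float(f), float(sps.f.sf(f, 1, df2))

    f_a, p_a = partial(rss(np.column_stack([one, ib])))
    f_b, p_b = partial(rss(np.column_stack([one, ia])))
    return {
        "F": float(f_val), "df": (df1, df2), "p": p,
        "F_a": f_a, "p_a": p_a, "F_b": f_b, "p_b": p_b,
    }


def _r2(y: np.ndarray, X: np.ndarray) -> float:
    X1 = np.column_stack([np.ones(y.size), X])
    beta, *_ = np.linalg.lstsq(X1, y, rcond=None)
    resid = y - X1 @ beta
    tss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - float(resid @ resid) / tss


def hier_part2(length, age, growth) -> dict:
    """Two-predictor hierarchical partitioning of explained length variance.

    With R² from the single-predictor and joint least-squares fits, the
    independent contribution of each predictor averages its gain over the
    two orderings:

        I_age    = (R²(age) + R²(joint) - R²(growth)) / 2
        I_growth = (R²(growth) + R²(joint) - R²(age)) / 2

    ``I_age + I_growth = R²(joint)`` exactly; percentages are shares of the
    joint R².
    """
    y = np.asarray(length, dtype=float)
    a = np.asarray(age, dtype=float)
    g = np.asarray(growth, dtype=float)
    if y.size < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(a) == 0 or np.ptp(g) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance variable: partitioning undefined")
    r2_a = _r2(y, a[:, None])
    r2_g = _r2(y, g[:, None])
    r2_joint = _r2(y, np.column_stack([a, g]))
    i_a = 0.5 * (r2_a + r2_joint - r2_g)
    i_g = 0.5 * (r2_g + r2_joint - r2_a)
    return {
        "r2_joint": r2_joint,
        "indep_age": i_a,
        "indep_growth": i_g,
        "pct_age": 100.0 * i_a / r2_joint,
        "pct_growth": 100.0 * i_g / r2_joint,
    }
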