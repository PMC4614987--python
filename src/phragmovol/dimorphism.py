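"""Group-comparison statistics for growth trajectories (ARSS tests).

The analysis of the residual sum of squares (ARSS) compares regressions
fitted separately to two groups — here, male and female conchs:

* :func:`compare_linear` is the classical two-slope comparison: ordinary
  least-squares lines per group, and a t statistic for the slope
  difference using the pooled residual mean square with
  n_a + n_b - 4 degrees of freedom.
* :func:`compare_nonlinear` is the extra-sum-of-squares F test for
  nonlinear (logistic) growth curves: one curve fitted to the pooled
  data versus separate curves per group,

      F = ((RSS_pooled - (RSS_a + RSS_b)) / p) /
          ((RSS_a + RSS_b) / (N - 2 p)),

  with p = 3 parameters per logistic curve, df1 = p, df2 = N - 2 p.

Significance is reported both as a two-sided p-value and as the tiered
text labels used in the source tables ("s (P < 0.05)", "s (P < 0.1)",
"ns").  No multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .fixtures import ChamberSeries
from .trajectories import fit_logistic_points

__all__ = [
    "RegressionComparison",
    "FComparison",
    "compare_linear",
    "compare_nonlinear",
    "arss_f_statistic",
    "group_sd",
    "significance_label",
]

_N_LOGISTIC_PARAMS = 3


@dataclass(frozen=True)
class RegressionComparison:
    """Two-group linear-slope comparison (ARSS t test)."""

    slope_a: float
    slope_b: float
    rss_a: float
    rss_b: float
    n_a: int
    n_b: int
    t: float
    p: float
    label: str

    @property
    def df_a(self) -> int:
        return self.n_a - 2

    @property
    def df_b(self) -> int:
        return self.n_b - 2

    @property
    def df_t(self) -> int:
        return self.n_a + self.n_b - 4


@dataclass(frozen=True)
class FComparison:
    """Pooled-versus-separate logistic fit comparison (extra-SS F test)."""

    rss_pooled: float
    rss_a: float
    rss_b: float
    n_a: int
    n_b: int
    F: float
    df1: int
    df2: int
    p: float
    label: str


def _xy(points) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(points, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 2:
        return arr[:, 0], arr[:, 1]
    if isinstance(points, tuple) and len(points) == 2:
        return np.asarray(points[0], float), np.asarray(points[1], float)
    raise ValueError("points must be an (n, 2) array or an (x, y) tuple")


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Slope, intercept, RSS and centred x sum of squares of an OLS line."""
    xbar, ybar = x.mean(), y.mean()
    sxx = float(((x - xbar) ** 2).sum())
    if sxx == 0.0:
        raise ValueError("degenerate regressor: x has zero variance")
    slope = float(((x - xbar) * (y - ybar)).sum() / sxx)
    intercept = float(ybar - slope * xbar)
    resid = y - (intercept + slope * x)
    return slope, intercept, float(resid @ resid), sxx


def compare_linear(points_a, points_b) -> RegressionComparison:
    """ARSS comparison of two linear regressions via their slopes.

    Fits an OLS line to each group and tests slope equality with the
    pooled residual mean square; the t statistic has
    n_a + n_b - 4 degrees of freedom.  Per-group RSS and df mirror the
    columns of the source summary tables.  With both groups noiseless
    and slopes different, the statistic is reported as +/- infinity with
    p = 0.
    """
    xa, ya = _xy(points_a)
    xb, yb = _xy(points_b)
    if len(xa) < 3 or len(xb) < 3:
        raise ValueError("need at least 3 points per group")
    slope_a, _, rss_a, sxx_a = _ols_line(xa, ya)
    slope_b, _, rss_b, sxx_b = _ols_line(xb, yb)
    df = len(xa) + len(xb) - 4
    s2 = (rss_a + rss_b) / df
    diff = slope_a - slope_b
    if s2 == 0.0:
        t = 0.0 if diff == 0.0 else float(np.copysign(np.inf, diff))
        p = 1.0 if diff == 0.0 else 0.0
    else:
        t = diff / np.sqrt(s2 * (1.0 / sxx_a + 1.0 / sxx_b))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return RegressionComparison(
        slope_a=slope_a,
        slope_b=slope_b,
        rss_a=rss_a,
        rss_b=rss_b,
        n_a=len(xa),
        n_b=len(xb),
        t=float(t),
        p=p,
        label=significance_label(p),
    )


def _pool_points(
    group: Iterable[ChamberSeries], fit_from_chamber: int | None
) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for series in group:
        mask = series.volume_mask
        if fit_from_chamber is not None:
            mask = mask & (series.chambers >= fit_from_chamber)
        xs.append(series.chambers[mask].astype(float))
        ys.append(series.volumes[mask])
    return np.concatenate(xs), np.concatenate(ys)


def arss_f_statistic(
    rss_pooled: float, rss_a: float, rss_b: float, n_total: int,
    n_params: int = _N_LOGISTIC_PARAMS,
) -> tuple[float, int, int, float]:
    """Extra-sum-of-squares F from an RSS decomposition.

    Returns (F, df1, df2, p) with df1 = n_params and
    df2 = n_total - 2 * n_params.  Usable directly on a printed RSS
    decomposition as well as on freshly fitted values.
    """
    df1 = n_params
    df2 = n_total - 2 * n_params
    if df2 < 1:
        raise ValueError(f"not enough points: df2 = {df2}")
    rss_sep = rss_a + rss_b
    F = max(0.0, (rss_pooled - rss_sep)) / df1 / (rss_sep / df2)
    p = float(stats.f.sf(F, df1, df2))
    return float(F), df1, df2, p


def compare_nonlinear(
    series_a: Sequence[ChamberSeries],
    series_b: Sequence[ChamberSeries],
    fit_from_chamber: int | None = 6,
    scale: str = "raw",
) -> FComparison:
    """ARSS F test comparing logistic growth curves of two groups.

    Pools (chamber, volume) points per group from ``fit_from_chamber``
    on, fits one logistic to each group and one to the combined data
    (sharing the multi-start fitting engine of the per-specimen fits),
    and applies the extra-sum-of-squares F test with df1 = 3 and
    df2 = N - 6.
    """
    xa, ya = _pool_points(series_a, fit_from_chamber)
    xb, yb = _pool_points(series_b, fit_from_chamber)
    _, rss_a = fit_logistic_points(xa, ya, scale=scale)
    _, rss_b = fit_logistic_points(xb, yb, scale=scale)
    _, rss_pooled = fit_logistic_points(
        np.concatenate([xa, xb]), np.concatenate([ya, yb]), scale=scale
    )
    F, df1, df2, p = arss_f_statistic(rss_pooled, rss_a, rss_b, len(xa) + len(xb))
    return FComparison(
        rss_pooled=rss_pooled,
        rss_a=rss_a,
        rss_b=rss_b,
        n_a=len(xa),
        n_b=len(xb),
        F=F,
        df1=df1,
        df2=df2,
        p=p,
        label=significance_label(p),
    )


def group_sd(totals_by_group: Mapping[str, Sequence[float]]) -> dict[str, float]:
    """Sample standard deviation (n-1 denominator) per group and combined.

    ``totals_by_group`` maps a group name (e.g. "male") to the
    per-specimen total phragmocone volumes.  The result adds a
    "combined" entry over all groups.  Singleton groups are an error.
    """
    out = {}
    all_vals: list[float] = []
    for name, vals in totals_by_group.items():
        vals = list(map(float, vals))
        if len(vals) < 2:
            raise ValueError(f"group {name!r} needs >= 2 specimens, got {len(vals)}")
        out[name] = float(np.std(vals, ddof=1))
        all_vals.extend(vals)
    out["combined"] = float(np.std(all_vals, ddof=1))
    return out


def significance_label(
    p: float,
    strict_alpha: float = 0.05,
    weak_alpha: float = 0.1,
    ns_annotation_threshold: float = 0.5,
) -> str:
    """Map a p-value to the tiered text labels of the summary tables."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    if p < strict_alpha:
        return f"s (P < {strict_alpha:g})"
    if p < weak_alpha:
        return f"s (P < {weak_alpha:g})"
    if p > ns_annotation_threshold:
        return f"ns (P > {ns_annotation_threshold:g})"
    return "ns"
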