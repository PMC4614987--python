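"""Per-specimen growth analytics for chamber-volume series.

Implements the descriptive statistics of volumetric ontogeny: cumulative
phragmocone volume, detection of the growth-stage breakpoint (a change
of log-slope, e.g. at the end of the embryonic or neanic stage), the
terminal countdown (declining chamber volumes before maturity), the
largest anomalous volume drop, three-parameter logistic fits, and the
covariation of chamber widths with volumes.

Conventions
-----------
* All detectors operate on present (non-missing) measurements only.
* The two-segment breakpoint model is continuous piecewise-linear in
  (chamber, log volume): an exhaustive search over hinge positions at
  every admissible measured chamber.  The reported ``breakpoint`` is the
  first chamber governed by the second slope; the hinge chamber itself
  (last chamber of the first regime) is reported as ``knot``.
* The countdown onset is the centre chamber of the maximal 3-point
  moving average of volumes (earliest centre on ties); the countdown is
  only declared if the last volume lies below the onset volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

from .fixtures import ChamberSeries

__all__ = [
    "GrowthFit",
    "BreakpointResult",
    "CountdownResult",
    "DropResult",
    "cumulative",
    "find_breakpoint",
    "detect_countdown",
    "largest_drop",
    "fit_logistic",
    "fit_logistic_points",
    "covariation_index",
    "analyze_specimen",
]


@dataclass(frozen=True)
class GrowthFit:
    """A fitted three-parameter logistic growth curve."""

    model: str  # "logistic3"
    K: float
    r: float
    m: float
    rss: float
    n: int
    fit_range: tuple[int, int]
    scale: str  # "raw" | "log"

    @property
    def params(self) -> tuple[float, float, float]:
        return (self.K, self.r, self.m)

    @property
    def df(self) -> int:
        return self.n - 3

    def predict(self, chambers) -> np.ndarray:
        i = np.asarray(chambers, dtype=float)
        return self.K / (1.0 + np.exp(-self.r * (i - self.m)))


@dataclass(frozen=True)
class BreakpointResult:
    """Outcome of the exhaustive two-segment hinge search."""

    breakpoint: int  # first chamber of the second slope regime
    knot: int  # hinge chamber = last chamber of the first regime
    rss_two_segment: float
    rss_one_segment: float
    improvement: float  # 1 - rss_two/rss_one
    found: bool


@dataclass(frozen=True)
class CountdownResult:
    """Terminal-countdown detection outcome."""

    onset: int  # centre chamber of the maximal 3-point moving average
    length: int  # chambers from onset through the last measured, 0 if absent
    found: bool


@dataclass(frozen=True)
class DropResult:
    """Largest single-step proportional volume decrease."""

    chamber: int  # chamber whose volume dropped relative to its predecessor
    fraction: float  # (V_prev - V) / V_prev


def _present(series: ChamberSeries) -> tuple[np.ndarray, np.ndarray]:
    mask = series.volume_mask
    return series.chambers[mask].astype(float), series.volumes[mask]


def cumulative(series: ChamberSeries):
    """Running total of chamber volumes per measured chamber.

    Missing chambers are skipped with a warning; the final total equals
    the sum of present volumes.  Returns a pandas Series indexed by
    chamber number, in the series volume unit.
    """
    import pandas as pd

    ch, v = _present(series)
    if not len(ch):
        raise ValueError(f"{series.specimen_id}: no measured volumes to accumulate")
    n_missing = len(series) - len(ch)
    if n_missing:
        warnings.warn(
            f"{series.specimen_id}: skipping {n_missing} missing volume(s) "
            "in cumulative totals",
            stacklevel=2,
        )
    return pd.Series(np.cumsum(v), index=ch.astype(int), name=series.specimen_id)


def _hinge_rss(x: np.ndarray, y: np.ndarray, c: float) -> float:
    """RSS of the continuous two-segment least-squares fit with hinge at c."""
    X = np.column_stack([np.ones_like(x), x, np.maximum(0.0, x - c)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def find_breakpoint(
    series: ChamberSeries,
    fit_range: tuple[int, int] | None = None,
    transform: str = "log",
    improvement_threshold: float = 0.8,
    min_points_per_segment: int = 3,
) -> BreakpointResult:
    """Exhaustive two-segment (hinge) breakpoint search on log volumes.

    Every measured chamber with at least ``min_points_per_segment``
    points on each side is tried as the hinge; the global-RSS-minimum
    hinge wins.  ``found`` is True when the two-segment fit reduces the
    single-line RSS to at most ``improvement_threshold`` of its value
    (and the single line does not already fit perfectly).
    """
    ch, v = _present(series)
    if fit_range is not None:
        lo, hi = fit_range
        keep = (ch >= lo) & (ch <= hi)
        ch, v = ch[keep], v[keep]
    if len(ch) < 2 * min_points_per_segment:
        raise ValueError(
            f"need at least {2 * min_points_per_segment} measured points "
            f"for a two-segment fit, got {len(ch)}"
        )
    if transform == "log":
        y = np.log(v)
    elif transform == "raw":
        y = v.copy()
    else:
        raise ValueError(f"unknown transform {transform!r}")

    best_rss = np.inf
    best_idx = -1
    for idx in range(len(ch)):
        c = ch[idx]
        n_left = int((ch <= c).sum())
        n_right = int((ch > c).sum())
        if n_left < min_points_per_segment or n_right < min_points_per_segment:
            continue
        rss = _hinge_rss(ch, y, c)
        if rss < best_rss - 0.0:
            best_rss = rss
            best_idx = idx
    rss_one = _hinge_rss(ch, y, ch[-1] + 1.0)  # hinge beyond the data = single line
    # a perfect single line leaves nothing to improve on
    degenerate = rss_one <= 1e-10 * len(ch)
    improvement = 0.0 if degenerate else 1.0 - best_rss / rss_one
    found = (not degenerate) and best_rss <= improvement_threshold * rss_one
    return BreakpointResult(
        breakpoint=int(ch[best_idx + 1]),
        knot=int(ch[best_idx]),
        rss_two_segment=best_rss,
        rss_one_segment=rss_one,
        improvement=float(improvement),
        found=bool(found),
    )


def detect_countdown(series: ChamberSeries) -> CountdownResult:
    """Detect the terminal countdown (declining volumes before maturity).

    The onset is the centre chamber of the maximal 3-point moving
    average over successive measured volumes (earliest centre on ties);
    the countdown is declared only when the last measured volume lies
    below the onset-chamber volume.  The length counts chambers from the
    onset through the last measured chamber.
    """
    ch, v = _present(series)
    if len(ch) < 5:
        raise ValueError(f"need at least 5 measured chambers, got {len(ch)}")
    ma = (v[:-2] + v[1:-1] + v[2:]) / 3.0
    centre = int(np.argmax(ma)) + 1  # argmax takes the earliest maximum
    onset = int(ch[centre])
    found = bool(v[-1] < v[centre])
    length = int(ch[-1]) - onset + 1 if found else 0
    return CountdownResult(onset=onset, length=length, found=found)


def largest_drop(series: ChamberSeries) -> DropResult | None:
    """Largest proportional volume decrease between consecutive chambers.

    Only pairs of chambers i, i+1 that are both measured are considered;
    returns None when no decrease exists.  Scale-invariant.
    """
    ch, v = _present(series)
    if len(ch) < 2:
        raise ValueError("need at least 2 measured chambers")
    best: DropResult | None = None
    for j in range(1, len(ch)):
        if ch[j] - ch[j - 1] != 1 or v[j] >= v[j - 1]:
            continue
        frac = (v[j - 1] - v[j]) / v[j - 1]
        if best is None or frac > best.fraction:
            best = DropResult(chamber=int(ch[j]), fraction=float(frac))
    return best


# ---------------------------------------------------------------------------
# logistic fitting

def _logistic(i, K, r, m):
    return K / (1.0 + np.exp(-r * (i - m)))


def fit_logistic_points(
    x: np.ndarray, y: np.ndarray, scale: str = "raw"
) -> tuple[tuple[float, float, float], float]:
    """Fit V = K / (1 + exp(-r (x - m))) by multi-start least squares.

    Returns ((K, r, m), rss) with rss on the requested scale ("raw"
    residuals on volumes, "log" residuals on log volumes).  Raises
    RuntimeError with diagnostics if no start converges.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4:
        raise ValueError(f"need >= 4 points for a 3-parameter fit, got {len(x)}")
    if np.any(y <= 0):
        raise ValueError("volumes must be positive")
    if scale not in ("raw", "log"):
        raise ValueError(f"unknown scale {scale!r}")

    if scale == "log":
        target = np.log(y)

        def residuals(p):
            return np.log(_logistic(x, p[0], p[1], p[2])) - target
    else:
        target = y

        def residuals(p):
            return _logistic(x, p[0], p[1], p[2]) - target

    ymax = float(y.max())
    # slope of log y against x seeds the rate
    slope = float(np.polyfit(x, np.log(y), 1)[0]) if len(np.unique(x)) > 1 else 0.2
    r0 = min(max(abs(slope), 1e-3), 5.0)
    half_idx = int(np.argmin(np.abs(y - ymax / 2.0)))
    starts = []
    for K0 in (1.05 * ymax, 2.0 * ymax, 5.0 * ymax):
        for m0 in (float(x[half_idx]), float(np.median(x))):
            starts.append((K0, r0, m0))
    starts.append((1.5 * ymax, 0.5 * r0, float(x[-1])))

    lower = [1e-12 * ymax, 1e-6, -1e6]
    upper = [1e6 * ymax, 1e3, 1e6]
    best = None
    failures = []
    for p0 in starts:
        try:
            sol = optimize.least_squares(
                residuals,
                p0,
                bounds=(lower, upper),
                method="trf",
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
                max_nfev=2000,
            )
        except Exception as exc:  # pragma: no cover - defensive
            failures.append(f"start {p0}: {exc}")
            continue
        if not sol.success and sol.status <= 0:
            failures.append(f"start {p0}: {sol.message}")
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError(
            "logistic fit failed to converge from all starts:\n" + "\n".join(failures)
        )
    K, r, m = (float(t) for t in best.x)
    rss = float(2.0 * best.cost)
    return (K, r, m), rss


def fit_logistic(
    series: ChamberSeries,
    fit_range: tuple[int, int] | None = None,
    scale: str = "raw",
) -> GrowthFit:
    """Three-parameter logistic fit of a chamber-volume series.

    By default the residuals are on the raw volume scale; ``scale="log"``
    fits on log volumes instead (useful when volumes span several orders
    of magnitude).
    """
    ch, v = _present(series)
    if fit_range is not None:
        lo, hi = fit_range
        keep = (ch >= lo) & (ch <= hi)
        ch, v = ch[keep], v[keep]
    else:
        fit_range = (int(ch[0]), int(ch[-1])) if len(ch) else (0, 0)
    (K, r, m), rss = fit_logistic_points(ch, v, scale=scale)
    return GrowthFit(
        model="logistic3",
        K=K,
        r=r,
        m=m,
        rss=rss,
        n=len(ch),
        fit_range=(int(fit_range[0]), int(fit_range[1])),
        scale=scale,
    )


def covariation_index(series: ChamberSeries) -> float | None:
    """Pearson correlation of per-chamber log-increments of width and volume.

    Measures whether chamber widths and volumes change in step through
    ontogeny: r close to 1 means the conch changes shape and volume
    together (as in the ammonites); r near 0 means width expands at a
    constant pace irrespective of volume (as in *Nautilus*).  Only
    consecutive chamber pairs with both quantities present contribute.
    Returns None (undefined) when either increment series is constant.
    """
    both = series.volume_mask & ~np.isnan(series.widths_mm)
    if int(both.sum()) < 5:
        raise ValueError(
            "need at least 5 chambers with both width and volume, "
            f"got {int(both.sum())}"
        )
    ch = series.chambers
    dv, dw = [], []
    idx = {int(c): j for j, c in enumerate(ch)}
    for c in ch[both]:
        j, c = idx[int(c)], int(c)
        if c + 1 in idx and both[idx[c + 1]]:
            k = idx[c + 1]
            dv.append(np.log(series.volumes[k]) - np.log(series.volumes[j]))
            dw.append(np.log(series.widths_mm[k]) - np.log(series.widths_mm[j]))
    dv, dw = np.asarray(dv), np.asarray(dw)
    if len(dv) < 2 or np.ptp(dv) == 0 or np.ptp(dw) == 0:
        return None
    return float(np.corrcoef(dw, dv)[0, 1])


def analyze_specimen(
    series: ChamberSeries,
    breakpoint_range: tuple[int, int] | None = None,
    exclude_countdown_from_fit: bool = True,
    fit_scale: str = "raw",
) -> dict:
    """Full per-specimen analysis record (JSON-serializable).

    Countdown chambers are excluded from the logistic fit range by
    default, since the terminal decline departs from the logistic trend.
    """
    ch, _ = _present(series)
    record: dict = {"specimen_id": series.specimen_id, "volume_unit": series.volume_unit}
    cum = cumulative(series)
    record["total_volume"] = float(cum.iloc[-1])

    cd = detect_countdown(series) if len(ch) >= 5 else None
    record["countdown"] = (
        {"onset": cd.onset, "length": cd.length, "found": cd.found} if cd else None
    )

    drop = largest_drop(series)
    record["largest_drop"] = (
        {"chamber": drop.chamber, "fraction": drop.fraction} if drop else None
    )

    try:
        bp = find_breakpoint(series, fit_range=breakpoint_range)
        record["breakpoint"] = {
            "breakpoint": bp.breakpoint,
            "knot": bp.knot,
            "found": bp.found,
            "improvement": bp.improvement,
        }
    except ValueError:
        record["breakpoint"] = None

    fit_hi = int(ch[-1])
    if exclude_countdown_from_fit and cd and cd.found:
        fit_hi = cd.onset - 1
    try:
        fit = fit_logistic(series, fit_range=(int(ch[0]), fit_hi), scale=fit_scale)
        record["logistic_fit"] = {
            "K": fit.K,
            "r": fit.r,
            "m": fit.m,
            "rss": fit.rss,
            "n": fit.n,
            "fit_range": list(fit.fit_range),
            "scale": fit.scale,
        }
    except (ValueError, RuntimeError) as exc:
        record["logistic_fit"] = {"error": str(exc)}

    try:
        record["covariation"] = covariation_index(series)
    except ValueError:
        record["covariation"] = None
    return record
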