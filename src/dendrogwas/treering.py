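"""Ring-width standardization and site chronologies.

The detrending follows the standard dendrochronological recipe: a cubic
smoothing spline whose frequency response is 50% at a wavelength equal to a
fixed fraction (default 67%) of the series length is fitted to each raw
series, and dimensionless indices are the ratios raw/fitted.  Optional
autoregressive prewhitening removes the persistence component, and site
chronologies are built by a robust (Tukey biweight) mean across trees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse, stats
from scipy.sparse.linalg import spsolve

from dendrogwas.core import Chronology, IndexSeries, RingSeries

_FIT_FLOOR = 1e-6


def _spline_lambda(cutoff: float) -> float:
    """Penalty giving a 50% frequency response at wavelength `cutoff` years.

    The discrete cubic smoothing spline minimizes ||y-f||^2 + lam*||D2 f||^2;
    its frequency response is 1/(1 + lam*(2 - 2 cos w)^2), so the 50% point
    at w = 2*pi/cutoff fixes lam.
    """
    w = 2.0 * np.pi / cutoff
    return 1.0 / (2.0 - 2.0 * np.cos(w)) ** 2


def _smooth(y: np.ndarray, lam: float) -> np.ndarray:
    n = len(y)
    if n < 3:
        return y.astype(float)
    e = np.ones(n)
    D = sparse.diags([e[:-2], -2 * e[:-2], e[:-2]], [0, 1, 2], shape=(n - 2, n))
    A = sparse.eye(n) + lam * (D.T @ D)
    return spsolve(A.tocsc(), y.astype(float))


def detrend_spline(series: RingSeries, spline_fraction: float = 0.67) -> IndexSeries:
    """Remove the age trend with a smoothing spline; return ratio indices.

    The spline's 50% frequency cutoff sits at ``spline_fraction`` times the
    series length, so variation slower than ~2/3 of the record (the age/size
    trend) is absorbed into the fitted curve while interannual variability
    survives in the indices.
    """
    n = len(series)
    if n < 10:
        raise ValueError(f"series {series.tree_id}: length {n} < 10")
    if not np.any(series.widths > 0):
        raise ValueError(f"series {series.tree_id}: all widths are zero")
    lam = _spline_lambda(spline_fraction * n)
    fitted = np.maximum(_smooth(series.widths, lam), _FIT_FLOOR)
    return IndexSeries(series.tree_id, series.years.copy(), series.widths / fitted)


def select_ar(y: np.ndarray, max_order: int = 3) -> tuple[int, np.ndarray]:
    """AR order by AICc (conditional least squares on a common sample).

    Returns the selected order p and its coefficients (phi_1..phi_p),
    refitted on the maximal sample for that order.  Following the usual
    parsimony convention, the smallest order within 2 AICc units of the
    minimum is chosen, which keeps white noise at order 0.
    """
    y = np.asarray(y, float)
    n = len(y)
    yc = y - y.mean()
    m = max_order
    target = yc[m:]
    n_eff = len(target)
    aiccs = []
    for p in range(0, m + 1):
        if p == 0:
            resid = target
            k = 1
        else:
            X = np.column_stack([yc[m - j : n - j] for j in range(1, p + 1)])
            coef, *_ = np.linalg.lstsq(X, target, rcond=None)
            resid = target - X @ coef
            k = p + 1
        sig2 = float(np.mean(resid**2))
        aic = n_eff * np.log(max(sig2, 1e-300)) + 2 * k
        aiccs.append(aic + 2 * k * (k + 1) / max(n_eff - k - 1, 1))
    best_p = int(np.argmin(aiccs))
    for p in range(best_p):  # smallest order within 2 units of the minimum
        if aiccs[p] <= aiccs[best_p] + 2.0:
            best_p = p
            break
    if best_p == 0:
        return 0, np.empty(0)
    X = np.column_stack([yc[best_p - j : n - j] for j in range(1, best_p + 1)])
    coef, *_ = np.linalg.lstsq(X, yc[best_p:], rcond=None)
    return best_p, coef


def prewhiten(series: IndexSeries, max_order: int = 3) -> IndexSeries:
    """Remove the autoregressive component from an index series.

    Fits AR(p) for p = 0..max_order by conditional least squares on a common
    sample, selects p by AICc, and returns the residuals re-centered on the
    series mean.  The output starts max(1, p) years later than the input
    only when p > 0.
    """
    y = np.asarray(series.indices, float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in index series")
    n = len(y)
    if n < 30:
        raise ValueError("prewhitening needs at least 30 years")
    if np.std(y) == 0:
        raise ValueError("constant series has zero variance")
    mu = y.mean()
    yc = y - mu
    p_sel, coef = select_ar(y, max_order)
    if p_sel == 0:
        return IndexSeries(series.tree_id, series.years.copy(), y.copy())
    X = np.column_stack([yc[p_sel - j : n - j] for j in range(1, p_sel + 1)])
    resid = yc[p_sel:] - X @ coef
    return IndexSeries(series.tree_id, series.years[p_sel:].copy(), resid + mu)


def estimate_ar1(series: IndexSeries) -> float:
    """Lag-1 autocorrelation (diagnostic for prewhitening)."""
    y = series.indices - series.indices.mean()
    denom = float(np.sum(y**2))
    if denom == 0:
        return 0.0
    return float(np.sum(y[1:] * y[:-1]) / denom)


def tukey_biweight_mean(x: np.ndarray, c: float = 9.0, n_iter: int = 10) -> float:
    """Tukey's biweight robust mean (median start, MAD scale)."""
    x = np.asarray(x, float)
    if len(x) == 1:
        return float(x[0])
    m = float(np.median(x))
    for _ in range(n_iter):
        s = float(np.median(np.abs(x - m)))
        if s == 0:
            return m
        u = (x - m) / (c * s)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        if w.sum() == 0:
            return m
        m_new = float(np.sum(w * x) / np.sum(w))
        if abs(m_new - m) < 1e-12:
            return m_new
        m = m_new
    return m


def build_chronology(
    indexed: list[IndexSeries], method: str = "biweight"
) -> Chronology:
    """Average index series into a site chronology with sample depth.

    method "biweight" uses the Tukey biweight robust mean per year (falls
    back to the plain mean where fewer than 3 series overlap); "mean" is the
    arithmetic mean.
    """
    if method not in ("mean", "biweight"):
        raise ValueError("method must be 'mean' or 'biweight'")
    if not indexed:
        raise ValueError("no series supplied")
    y0 = min(s.first_year for s in indexed)
    y1 = max(s.last_year for s in indexed)
    years = np.arange(y0, y1 + 1)
    values = np.full(len(years), np.nan)
    depth = np.zeros(len(years), dtype=int)
    per_year: list[list[float]] = [[] for _ in years]
    for s in indexed:
        off = s.first_year - y0
        for i, v in enumerate(s.indices):
            per_year[off + i].append(float(v))
    for i, vals in enumerate(per_year):
        depth[i] = len(vals)
        if not vals:
            continue
        arr = np.asarray(vals)
        if method == "mean" or len(arr) < 3:
            values[i] = arr.mean()
        else:
            values[i] = tukey_biweight_mean(arr)
    keep = depth > 0
    if not keep.any():
        raise ValueError("empty overlap: no year has any series")
    return Chronology(years[keep], values[keep], depth[keep])


@dataclass
class TrendResult:
    """OLS growth trend over a recent window with its significance class."""

    tree_id: str
    slope: float
    p_value: float
    trend_class: str  # positive | negative | nonsignificant

    def __post_init__(self) -> None:
        assert self.trend_class in ("positive", "negative", "nonsignificant")


def classify_trend(
    series: IndexSeries, window: int = 30, alpha: float = 0.05
) -> TrendResult:
    """OLS slope of the last `window` years with a two-sided t-test.

    Classified positive/negative when p < alpha, nonsignificant otherwise.
    """
    if len(series) < window:
        raise ValueError(
            f"series {series.tree_id}: window {window} longer than series {len(series)}"
        )
    y = series.indices[-window:]
    t = series.years[-window:].astype(float)
    if np.allclose(y, y[0]):
        return TrendResult(series.tree_id, 0.0, 1.0, "nonsignificant")
    res = stats.linregress(t, y)
    cls = "nonsignificant"
    if res.pvalue < alpha:
        cls = "positive" if res.slope > 0 else "negative"
    return TrendResult(series.tree_id, float(res.slope), float(res.pvalue), cls)
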