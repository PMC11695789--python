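"""Post-calibration analyses.

Fit statistics of observed-versus-modelled streams, relative
sensitivity coefficients (local elasticities) of model outputs to
environmental inputs, leaf-specific production, cambial phenology
metrics, outlier-screened correlations, and the running-maximum growth
baseline used by dendrometer practitioners.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class FitMetrics:
    """OLS fit of observed on modelled values plus RMSE."""

    fs: float           # fitted slope
    intercept: float    # in output units
    r2: float
    rmse: float         # root-mean-square of (obs - mod), output units
    n: int


def fit_metrics(obs, mod) -> FitMetrics:
    """Linear regression of observed on modelled values and the RMSE.

    RMSE is computed on the raw residuals obs - mod (not the regression
    residuals), matching how model performance tables are usually
    reported.  Pairs with missing values are dropped; at least three
    finite pairs and non-degenerate variance are required.
    """
    obs = np.asarray(obs, dtype=float)
    mod = np.asarray(mod, dtype=float)
    m = np.isfinite(obs) & np.isfinite(mod)
    if m.sum() < 3:
        raise ValueError("need at least 3 paired finite points")
    x, y = mod[m], obs[m]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate variance in paired series")
    res = stats.linregress(x, y)
    rmse = float(np.sqrt(np.mean((y - x) ** 2)))
    return FitMetrics(fs=float(res.slope), intercept=float(res.intercept),
                      r2=float(res.rvalue ** 2), rmse=rmse, n=int(m.sum()))


@dataclass
class RSCCurve:
    """Relative sensitivity along a grid of one input, other inputs fixed."""

    x_name: str
    x_grid: np.ndarray
    rsc: np.ndarray     # NaN where undefined (y <= 0)
    y: np.ndarray


def rsc_curve(model_fn, x_grid, x_name: str = "x", h_rel: float = 1e-3) -> RSCCurve:
    """Relative sensitivity coefficient RSC = (dy/y) / (dx/x) on a grid.

    Central finite differences with relative step ``h_rel``:
    RSC(x) = [y(x(1+h)) - y(x(1-h))] / y(x) / (2h).  Dimensionless; a
    pure power law y = x^n gives RSC = n everywhere.  Undefined (NaN)
    where x <= 0 or y(x) <= 0.
    """
    x_grid = np.asarray(x_grid, dtype=float)
    y0 = np.array([float(model_fn(x)) for x in x_grid])
    rsc = np.full(x_grid.size, np.nan)
    for i, x in enumerate(x_grid):
        if x <= 0 or y0[i] <= 0:
            continue
        y_hi = float(model_fn(x * (1.0 + h_rel)))
        y_lo = float(model_fn(x * (1.0 - h_rel)))
        if y_hi <= 0.0 or y_lo <= 0.0:
            continue  # stencil straddles a threshold: derivative undefined
        rsc[i] = (y_hi - y_lo) / y0[i] / (2.0 * h_rel)
    return RSCCurve(x_name=x_name, x_grid=x_grid, rsc=rsc, y=y0)


def production(a_series, dt_seconds: float = 1800.0) -> float:
    """Leaf-specific production P = sum(A dt), mol C m-2 leaf.

    Rectangle-rule accumulation over the given window; additive over
    window splits.
    """
    a = np.asarray(a_series, dtype=float)
    if a.size == 0:
        raise ValueError("empty accumulation window")
    return float(np.sum(a) * dt_seconds)


@dataclass
class PhenologyResult:
    """Seasonal growth timing and magnitude metrics for one tree-year."""

    t_onset: pd.Timestamp | None        # first step reaching onset quantile
    t_cessation: pd.Timestamp | None
    onset_doy: int | None
    duration_days: float | None         # onset-to-cessation quantile window
    annual_increment_mm: float          # radial growth over the season
    cambial_area_mm2: float | None      # annulus between start and end radii


def phenology_metrics(d_gro: pd.Series, onset_q: float = 0.01, cess_q: float = 0.99,
                      dbh_cm: float | None = None) -> PhenologyResult:
    """Onset/cessation quantile crossings of cumulative growth.

    Onset is the first timestamp at which cumulative growth reaches
    ``onset_q`` (1% by convention) of the annual total; duration runs to
    the ``cess_q`` crossing.  The annual cambial area increment is the
    annulus pi[(r0 + dr)^2 - r0^2] with r0 = DBH/2 at season start
    (inside-bark radius taken as given).  Zero annual growth yields a
    sentinel result with None timings.
    """
    if not isinstance(d_gro, pd.Series):
        d_gro = pd.Series(np.asarray(d_gro, dtype=float))
    g = d_gro.to_numpy(dtype=float)
    if np.any(np.diff(g) < -1e-12):
        raise ValueError("cumulative growth must be non-decreasing")
    total = g[-1] - g[0]
    area = None
    if total <= 0:
        return PhenologyResult(None, None, None, None, 0.0, area)
    rel = (g - g[0]) / total
    i_on = int(np.argmax(rel >= onset_q))
    i_off = int(np.argmax(rel >= cess_q))
    t_on, t_off = d_gro.index[i_on], d_gro.index[i_off]
    if isinstance(d_gro.index, pd.DatetimeIndex):
        duration = (t_off - t_on).total_seconds() / 86400.0
        onset_doy = int(pd.Timestamp(t_on).dayofyear)
    else:
        duration = float(i_off - i_on)
        onset_doy = None
    if dbh_cm is not None:
        r0 = dbh_cm * 10.0 / 2.0           # mm
        area = float(np.pi * ((r0 + total) ** 2 - r0 ** 2))
    return PhenologyResult(t_onset=t_on, t_cessation=t_off, onset_doy=onset_doy,
                           duration_days=float(duration),
                           annual_increment_mm=float(total), cambial_area_mm2=area)


@dataclass
class CorrelationResult:
    """Pearson correlation with Cook's-distance outlier screening."""

    r: float
    p: float
    cooks_d: np.ndarray
    outliers: np.ndarray        # boolean flags, D > threshold
    r_screened: float | None    # recomputed without flagged points
    p_screened: float | None


def pearson_cooks(x, y, threshold: float = 1.0) -> CorrelationResult:
    """Pearson r with outlier flags from the simple linear regression.

    Cook's distance of each point is computed from the OLS fit of y on
    x; points with D above ``threshold`` (default 1) are flagged and the
    correlation is recomputed without them.  Order-invariant.
    """
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need n >= 3 paired points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance")
    r, p = stats.pearsonr(x, y)
    ols = sm.OLS(y, sm.add_constant(x)).fit()
    cooks = ols.get_influence().cooks_distance[0]
    flags = cooks > threshold
    r_s = p_s = None
    if flags.any() and (~flags).sum() >= 3 and np.ptp(x[~flags]) > 0 and np.ptp(y[~flags]) > 0:
        r_s, p_s = stats.pearsonr(x[~flags], y[~flags])
        r_s, p_s = float(r_s), float(p_s)
    return CorrelationResult(r=float(r), p=float(p), cooks_d=cooks,
                             outliers=flags, r_screened=r_s, p_screened=p_s)


def zweifel_growth(d_series) -> np.ndarray:
    """Running-maximum growth extraction from a dendrometer series.

    Growth is the cumulated increment between successive temporal maxima
    of stem radial dimension — shrinkage phases contribute nothing:
    growth(t) = max_{s<=t} d(s) - d(0).  Non-decreasing; equals the
    total rise for monotone input.
    """
    d = np.asarray(d_series, dtype=float)
    if d.size == 0:
        return d.copy()
    return np.maximum.accumulate(d) - d[0]
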