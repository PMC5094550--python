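"""Dynamic, iRT-dependent extraction-window width estimation.

For targeted extraction of DIA data, each precursor's ion chromatogram is
only scored inside an RT window centered on its predicted elution.  The
window must be wide enough to contain the true apex despite calibration
residuals, yet narrow enough to exclude interfering peak groups.  Both
quantities vary along the gradient, so the width is modeled as a function
of iRT:

* anchors are sorted by iRT and grouped into bins of ``n / log2(n)``
  points sliding by one index;
* each bin contributes a reference point with x = mean iRT and
  y = (w + q) / 2, where w is the bin's median chromatographic peak width
  and q the 75th percentile of the absolute RT prediction residuals;
* the reference points are fed into the segmented Theil-Sen regression
  (bin size m/10) and the emitted window width is twice its prediction.

With fewer than 30 anchors a fixed width is used instead.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .regression import (
    DegenerateInputError,
    SegmentedTheilSenRegressor,
    TooFewAnchorsError,
    _round_half_up,
)

__all__ = [
    "MIN_WINDOW_ANCHORS",
    "summarize_window_bins",
    "ExtractionWindowEstimator",
    "fit_window_model",
    "window_at",
]

#: Below this anchor count a fixed window is applied.
MIN_WINDOW_ANCHORS = 30

_OBS_COLUMNS = ("irt", "rt_measured", "rt_predicted", "peak_width")


def _validate_observations(obs: pd.DataFrame) -> pd.DataFrame:
    missing = set(_OBS_COLUMNS) - set(obs.columns)
    if missing:
        raise ValueError(f"window observations missing columns: {sorted(missing)}")
    vals = obs[list(_OBS_COLUMNS)].to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("non-finite values in window observations")
    if (obs["peak_width"].to_numpy(dtype=float) <= 0).any():
        raise ValueError("peak widths must be positive")
    return obs


def summarize_window_bins(obs: pd.DataFrame) -> pd.DataFrame:
    """Reduce anchor observations to per-bin window reference points.

    ``obs`` needs columns ``irt``, ``rt_measured``, ``rt_predicted`` and
    ``peak_width`` (minutes).  Observations are sorted by iRT and grouped
    into bins of ``max(2, round(n / log2(n)))`` points sliding by one index
    (n - s + 1 bins).  Returns a frame with columns ``x_ref`` (mean iRT),
    ``w`` (median peak width), ``q`` (75th percentile of |measured -
    predicted| RT, linear interpolation between order statistics) and
    ``y_ref`` = (w + q) / 2.

    Raises
    ------
    TooFewAnchorsError
        With fewer than 30 observations; apply the fixed window instead.
    """
    obs = _validate_observations(obs)
    n = len(obs)
    if n < MIN_WINDOW_ANCHORS:
        raise TooFewAnchorsError(
            f"{n} anchors < {MIN_WINDOW_ANCHORS}; fixed window required"
        )
    srt = obs.sort_values("irt", kind="stable")
    irt = srt["irt"].to_numpy(dtype=float)
    resid = np.abs(srt["rt_measured"].to_numpy(dtype=float)
                   - srt["rt_predicted"].to_numpy(dtype=float))
    width = srt["peak_width"].to_numpy(dtype=float)

    s = max(2, _round_half_up(n / math.log2(n)))
    win = np.lib.stride_tricks.sliding_window_view
    x_ref = win(irt, s).mean(axis=1)
    w = np.median(win(width, s), axis=1)
    q = np.percentile(win(resid, s), 75, axis=1)
    y_ref = (w + q) * 0.5
    return pd.DataFrame({"x_ref": x_ref, "w": w, "q": q, "y_ref": y_ref})


class ExtractionWindowEstimator(BaseEstimator):
    """iRT-indexed extraction-window width model.

    Fits the sliding-bin summaries of anchor residuals and peak widths with
    a segmented Theil-Sen regression (bin size m/10 over the m reference
    points) and predicts the full window width as ``scale`` times the
    regression value.  Falls back to a fixed width when fewer than
    ``min_anchors`` observations are available.

    Parameters
    ----------
    scale : float, default 2.0
        Multiplier on the inner regression prediction (the window spans the
        predicted RT +/- half this width).
    min_anchors : int, default 30
        Below this anchor count the fixed width is used.
    fixed_width : float or None
        Fallback full width in minutes; None derives it at fit time as 5%
        of the observed measured-RT span.

    Attributes
    ----------
    inner_ : SegmentedTheilSenRegressor or None
        Regression over the (x_ref, y_ref) reference points.
    fixed_width_ : float
        Resolved fallback width (minutes).
    m_ : int
        Number of reference points fed to the inner regression (0 when the
        fixed width is in force).
    summaries_ : DataFrame or None
        The per-bin reference points used for the fit.
    """

    def __init__(self, scale: float = 2.0, min_anchors: int = MIN_WINDOW_ANCHORS,
                 fixed_width: float | None = None):
        self.scale = scale
        self.min_anchors = min_anchors
        self.fixed_width = fixed_width

    def fit(self, X: pd.DataFrame, y=None):
        if self.scale <= 0:
            raise ValueError(f"scale must be positive, got {self.scale}")
        obs = _validate_observations(X)
        rt = obs["rt_measured"].to_numpy(dtype=float)
        span = float(rt.max() - rt.min()) if len(rt) else 0.0
        self.fixed_width_ = (self.fixed_width if self.fixed_width is not None
                             else max(0.05 * span, 1e-6))
        self.inner_ = None
        self.summaries_ = None
        self.m_ = 0
        if len(obs) >= self.min_anchors:
            summaries = summarize_window_bins(obs)
            try:
                self._fit_inner(summaries)
            except DegenerateInputError:
                # e.g. all anchors at one iRT; keep the fixed width
                pass
        return self

    def _fit_inner(self, summaries: pd.DataFrame):
        m = len(summaries)
        inner = SegmentedTheilSenRegressor(
            mode="irt_to_rt",  # x is iRT, y a width in minutes
            min_anchors=2,
            bin_size=max(2, _round_half_up(m / 10)),
        )
        inner.fit(summaries["x_ref"].to_numpy(), summaries["y_ref"].to_numpy())
        self.inner_ = inner
        self.summaries_ = summaries
        self.m_ = m

    def predict(self, irt):
        """Full extraction-window width (minutes) at the given iRT value(s)."""
        check_is_fitted(self, "fixed_width_")
        x = np.asarray(irt, dtype=float)
        scalar = x.ndim == 0
        x = np.atleast_1d(x)
        if not np.isfinite(x).all():
            raise ValueError("non-finite iRT input")
        if self.inner_ is None:
            out = np.full(x.shape, self.fixed_width_)
        else:
            out = self.scale * np.asarray(self.inner_.predict(x), dtype=float)
        return float(out[0]) if scalar else out

    def to_dict(self) -> dict:
        check_is_fitted(self, "fixed_width_")
        return {
            "scale": self.scale,
            "fixed_width": self.fixed_width_,
            "m": self.m_,
            "inner": None if self.inner_ is None else self.inner_.to_dict(),
        }

    @classmethod
    def from_summaries(cls, summaries: pd.DataFrame, fixed_width: float = 1.0,
                       **params) -> "ExtractionWindowEstimator":
        """Build a model directly from precomputed bin reference points."""
        est = cls(fixed_width=fixed_width, **params)
        if est.scale <= 0:
            raise ValueError(f"scale must be positive, got {est.scale}")
        est.fixed_width_ = fixed_width
        est.inner_ = None
        est.summaries_ = None
        est.m_ = 0
        est._fit_inner(summaries.reset_index(drop=True))
        return est

    @classmethod
    def from_dict(cls, d: dict) -> "ExtractionWindowEstimator":
        est = cls(scale=float(d["scale"]))
        est.fixed_width_ = float(d["fixed_width"])
        est.m_ = int(d.get("m", 0))
        inner = d.get("inner")
        est.inner_ = (None if inner is None
                      else SegmentedTheilSenRegressor.from_dict(inner))
        est.summaries_ = None
        return est


def fit_window_model(obs: pd.DataFrame, **params) -> ExtractionWindowEstimator:
    """Fit an :class:`ExtractionWindowEstimator` on window observations."""
    return ExtractionWindowEstimator(**params).fit(obs)


def window_at(model: ExtractionWindowEstimator, irt):
    """Full extraction-window width (minutes) at ``irt``."""
    return model.predict(irt)
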