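"""FRAP recovery quantitation with the ROI-subtraction scheme.

Half of an inclusion is photobleached and its fluorescence monitored once per
minute. ROIs are fixed from the first post-bleach frame and reused across the
series (inclusions are assumed stationary over the 21-minute window):

* whole inclusion — automatic threshold of the fusion-protein channel;
* unbleached half — automatic threshold of the FlAsH channel (the covalently
  bound dye does not recover, so its signal marks the unbleached pixels);
* bleached half — whole inclusion minus unbleached pixels;
* background — a circle of fixed radius (default 25 px) at a user-supplied
  position, or the darkest corner circle.

Relative recovery at each post-bleach frame is the background-corrected
bleached mean over the background-corrected unbleached mean,

    r(t) = (bleached(t) - background(t)) / (unbleached(t) - background(t)),

which is invariant under affine gain/offset rescaling of the whole image.
No additional pre-bleach normalisation is applied (the stated formula is
implemented literally; the pre-bleach frame is retained for reporting).
Mobility is summarised by the end-minus-start recovery and by a
single-exponential fit r(t) - r(t0) = A * (1 - 2**(-t/h)), from which the
mobile fraction estimate is A / (1 - r(t0)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import EmptyROIError, GeometryError
from .image import MultiChannelImage
from .roi import (Centroid, PixelROI, auto_threshold, circular_roi,
                  largest_component, mean_intensity, subtract)


@dataclass(frozen=True)
class FrapRois:
    whole_inclusion: PixelROI
    unbleached: PixelROI
    bleached: PixelROI
    background: PixelROI

    def __post_init__(self) -> None:
        if self.bleached.coordinates & self.unbleached.coordinates:
            raise GeometryError("bleached and unbleached ROIs overlap")
        if self.background.coordinates & self.whole_inclusion.coordinates:
            raise GeometryError("background circle overlaps the inclusion")


@dataclass(frozen=True)
class FrapTrace:
    """Per-frame mean intensities of the three ROIs.

    ``times`` are minutes; the first ``n_prebleach`` frames precede the
    bleach, the remainder run t0, t1, ... at the acquisition interval.
    """

    times: np.ndarray
    bleached: np.ndarray
    unbleached: np.ndarray
    background: np.ndarray
    n_prebleach: int = 1

    def __post_init__(self) -> None:
        for name in ("times", "bleached", "unbleached", "background"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.times.size < 2:
            raise ValueError("a trace needs at least 2 frames")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        n = self.times.size
        for name in ("bleached", "unbleached", "background"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} length does not match times")


@dataclass(frozen=True)
class RecoveryCurve:
    times: np.ndarray  # post-bleach times, minutes
    relative_recovery: np.ndarray
    normalization: str = "bleached/unbleached, background-corrected"

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "relative_recovery",
                           np.asarray(self.relative_recovery, dtype=float))
        if not np.all(np.isfinite(self.relative_recovery)):
            raise ValueError("relative recovery must be finite")


def darkest_corner_circle(channel: np.ndarray, radius: float = 25.0) -> PixelROI:
    """The darkest of the four corner circles — the automatic background ROI."""
    h, w = channel.shape
    r = radius
    candidates = [circular_roi((r, r), radius, channel.shape),
                  circular_roi((r, w - 1 - r), radius, channel.shape),
                  circular_roi((h - 1 - r, r), radius, channel.shape),
                  circular_roi((h - 1 - r, w - 1 - r), radius, channel.shape)]
    return min(candidates, key=lambda roi: mean_intensity(channel, roi))


def assign_frap_rois(
    fusion_channel: np.ndarray,
    flash_channel: np.ndarray,
    background_center=None,
    background_radius: float = 25.0,
    method: str = "otsu",
    fusion_method: str = "multiotsu_low",
) -> FrapRois:
    """Fix the FRAP ROIs from the first post-bleach frame.

    Whole inclusion from the fusion channel, unbleached half from the FlAsH
    channel, bleached half by set subtraction; an empty bleached ROI means the
    bleach failed and raises. ``background_center`` is (row, col) or None for
    the darkest corner circle.

    The fusion channel of the first post-bleach frame is trimodal
    (background, dimmed bleached half, unbleached half), so its default
    threshold is the lower threshold of a three-class Otsu, which keeps the
    dimmed half inside the whole-inclusion ROI; the bimodal FlAsH channel
    uses the ordinary two-class method.
    """
    whole = largest_component(auto_threshold(fusion_channel, fusion_method))
    unbleached = largest_component(auto_threshold(flash_channel, method))
    bleached = subtract(whole, unbleached)
    if bleached.is_empty:
        raise EmptyROIError("bleach failed: FlAsH threshold covers the whole inclusion")
    if background_center is None:
        background = darkest_corner_circle(fusion_channel, background_radius)
    else:
        background = circular_roi(background_center, background_radius,
                                  fusion_channel.shape)
    return FrapRois(whole, unbleached, bleached, background)


def extract_trace(
    frames: list,
    rois: FrapRois,
    times,
    channel: str = "mcherry",
    n_prebleach: int = 1,
) -> FrapTrace:
    """Mean ROI intensities of one channel across an image time series.

    ``frames`` may be :class:`MultiChannelImage` objects or bare 2D arrays.
    """
    def _chan(frame):
        return frame[channel] if isinstance(frame, MultiChannelImage) else frame

    bleached = [mean_intensity(_chan(f), rois.bleached) for f in frames]
    unbleached = [mean_intensity(_chan(f), rois.unbleached) for f in frames]
    background = [mean_intensity(_chan(f), rois.background) for f in frames]
    return FrapTrace(np.asarray(times, dtype=float), bleached, unbleached,
                     background, n_prebleach=n_prebleach)


def relative_recovery(trace: FrapTrace) -> RecoveryCurve:
    """r(t) = (bleached - background) / (unbleached - background), post-bleach."""
    sl = slice(trace.n_prebleach, None)
    num = trace.bleached[sl] - trace.background[sl]
    den = trace.unbleached[sl] - trace.background[sl]
    if np.any(den <= 0):
        raise ValueError("non-positive background-corrected unbleached mean")
    return RecoveryCurve(times=trace.times[sl], relative_recovery=num / den)


def mobility_summary(curve: RecoveryCurve) -> dict:
    """End recovery, recovery change, and a single-exponential mobility fit.

    Returns ``end_recovery``, ``delta_recovery`` (r(t_end) - r(t0)),
    ``mobile_fraction_estimate``, ``halftime_estimate`` (minutes), ``fit_rmse``
    and ``fit_ok``. On fit failure only the deltas are reported (flagged).
    """
    r = curve.relative_recovery
    t = curve.times - curve.times[0]
    if r.size < 3:
        raise ValueError("mobility summary needs >= 3 post-bleach frames")
    r0 = r[0]
    out = {
        "end_recovery": float(r[-1]),
        "delta_recovery": float(r[-1] - r0),
        "mobile_fraction_estimate": None,
        "halftime_estimate": None,
        "fit_rmse": None,
        "fit_ok": False,
    }
    bleach_depth = 1.0 - r0
    try:
        def model(tt, amp, half):
            return amp * (1.0 - 2.0 ** (-tt / half))

        # amplitude start: observed plateau change; halftime start: mid-series
        p0 = (max(r[-1] - r0, 1e-3), max(t[-1] / 4.0, 1e-3))
        popt, _ = curve_fit(model, t, r - r0, p0=p0,
                            bounds=([0.0, 1e-6], [2.0, 1e4]), maxfev=10000)
        amp, half = popt
        resid = (r - r0) - model(t, *popt)
        out["fit_rmse"] = float(np.sqrt(np.mean(resid ** 2)))
        out["halftime_estimate"] = float(half)
        if bleach_depth > 1e-6:
            out["mobile_fraction_estimate"] = float(amp / bleach_depth)
        else:
            out["mobile_fraction_estimate"] = 0.0
        out["fit_ok"] = True
    except (RuntimeError, ValueError):
        pass
    return out
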