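"""Antibody-penetration depth: a porosity measurement for inclusions.

Fixed, permeabilised cells are stained with an anti-GFP antibody that can
enter an inclusion only as far as its meshwork allows. Penetration depth is
measured from two boundaries:

* **external** — the inclusion segmented from the cerulean channel, scaled by
  110% about its centroid (the outer edge of cerulean fluorescence);
* **internal** — the boundary of the unstained core, found by automatically
  thresholding the *inverted* antibody intensities within the inclusion's
  bounding region.

Penetration is the mean centroid-to-external-boundary distance minus the mean
centroid-to-internal-boundary distance, in pixels. When the antibody stains
the whole inclusion the unstained core is empty and, by convention,
penetration equals the external mean distance (the limit of the formula as
the core shrinks onto the centroid).

Note the 110% scaling imposes a geometric floor: even a zero-depth surface
coat measures a penetration of about 10% of the inclusion radius. The raw
internal and external mean distances are always reported so users can
subtract that floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyROIError, ThresholdError
from .roi import (Boundary, Centroid, PixelROI, auto_threshold,
                  largest_component, scale_roi)


@dataclass(frozen=True)
class PenetrationMeasurement:
    external_mean_distance: float  # pixels
    internal_mean_distance: float  # pixels; 0 when the core is empty
    penetration: float  # pixels, external - internal
    inclusion_id: str | int | None = None
    ratio: float | None = None  # FlAsH:Cerulean maturity ratio, for pairing
    full_penetration: bool = False

    def __post_init__(self) -> None:
        if self.external_mean_distance <= 0:
            raise ValueError("external mean distance must be > 0")


def external_boundary(
    cerulean_channel: np.ndarray,
    scale_factor: float = 1.10,
    method: str = "otsu",
) -> tuple[Boundary, Centroid, PixelROI]:
    """Outer boundary and centroid of the 110%-scaled segmented inclusion.

    Returns ``(boundary, centroid_of_scaled_roi, inclusion_roi)``; the
    unscaled inclusion ROI is needed by :func:`internal_boundary`.
    """
    inclusion = largest_component(auto_threshold(cerulean_channel, method))
    scaled = scale_roi(inclusion, scale_factor)
    return scaled.boundary(), scaled.centroid(), inclusion


def internal_boundary(
    antibody_channel: np.ndarray,
    inclusion: PixelROI,
    method: str = "otsu",
    pad: int = 2,
) -> Boundary | None:
    """Boundary of the antibody-unstained core of an inclusion.

    Antibody intensities within the inclusion's (padded) bounding region are
    inverted and automatically thresholded; the thresholded pixels restricted
    to the inclusion form the unstained core. Returns None when the core is
    empty (full penetration). A constant antibody signal in the region means
    no staining at all, so the core is the entire inclusion.
    """
    if inclusion.is_empty:
        raise EmptyROIError("internal_boundary of empty inclusion")
    arr = inclusion.coord_array
    h, w = inclusion.image_shape
    r0, r1 = max(arr[:, 0].min() - pad, 0), min(arr[:, 0].max() + pad + 1, h)
    c0, c1 = max(arr[:, 1].min() - pad, 0), min(arr[:, 1].max() + pad + 1, w)
    region = np.asarray(antibody_channel, dtype=float)[r0:r1, c0:c1]
    try:
        sub_roi = auto_threshold(region.max() - region, method)
    except ThresholdError:
        return inclusion.boundary()  # no antibody signal anywhere: core == inclusion
    core_coords = frozenset(
        (r + r0, c + c0) for r, c in sub_roi.coordinates
    ) & inclusion.coordinates
    if not core_coords:
        return None
    core = largest_component(PixelROI(core_coords, inclusion.image_shape))
    return core.boundary()


def penetration(
    outer: Boundary,
    centroid: Centroid,
    internal: Boundary | None,
    inclusion_id=None,
    ratio: float | None = None,
) -> PenetrationMeasurement:
    """Mean centroid-to-boundary distance difference, in pixels.

    ``internal=None`` (empty unstained core) applies the full-penetration
    convention: penetration equals the external mean distance.
    """
    if outer.is_empty:
        raise EmptyROIError("empty external boundary")
    ext = float(centroid.distance_to(outer.coord_array).mean())
    if internal is None or internal.is_empty:
        return PenetrationMeasurement(ext, 0.0, ext, inclusion_id, ratio,
                                      full_penetration=True)
    internal_mean = float(centroid.distance_to(internal.coord_array).mean())
    return PenetrationMeasurement(ext, internal_mean, ext - internal_mean,
                                  inclusion_id, ratio)


def measure_penetration(
    cerulean_channel: np.ndarray,
    antibody_channel: np.ndarray,
    scale_factor: float = 1.10,
    method: str = "otsu",
    inclusion_id=None,
    ratio: float | None = None,
) -> PenetrationMeasurement:
    """Full pipeline: segment, scale, find both boundaries, measure depth."""
    outer, centroid, inclusion = external_boundary(cerulean_channel,
                                                  scale_factor, method)
    internal = internal_boundary(antibody_channel, inclusion, method)
    return penetration(outer, centroid, internal, inclusion_id, ratio)
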