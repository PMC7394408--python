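"""Pixel-set (ROI) primitives shared by every image analysis.

An ROI is an explicit set of integer ``(row, col)`` pixel positions inside an
image — 0-based, origin top-left, pixel-center semantics. Representing ROIs
as sets (rather than contours) makes the set algebra the downstream analyses
rely on (subtraction of the unbleached half from the whole inclusion, outer
rings from scaled boundaries) exact.

Conventions:

* connected components use 8-connectivity;
* the boundary of an ROI is the subset of its pixels having at least one
  4-neighbour outside the ROI (pixels on the image edge count as boundary);
* geometric scaling of an ROI is about its centroid, with the scaled set
  clipped to the image.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage
from skimage import filters

from .errors import EmptyROIError, GeometryError, ThresholdError

#: 4-connectivity structuring element (cross) used for boundary extraction.
_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)

#: Automatic threshold methods by name. Otsu is the default throughout: the
#: study's processing names only "automatic thresholding", and Otsu is the
#: de-facto default of the imaging tools it used; the method is recorded in
#: ROI metadata so a run is auditable.
THRESHOLD_METHODS = {
    "otsu": filters.threshold_otsu,
    "li": filters.threshold_li,
    "yen": filters.threshold_yen,
    "mean": filters.threshold_mean,
    "triangle": filters.threshold_triangle,
}


def _multiotsu_low(img: np.ndarray) -> float:
    """Lower threshold of a three-class Otsu: separates background from all
    signal in trimodal images (e.g. a half-bleached inclusion over
    background). Falls back to two-class Otsu when the image holds fewer
    than three distinct values."""
    if np.unique(img).size < 3:
        return filters.threshold_otsu(img)
    return filters.threshold_multiotsu(img, classes=3)[0]


THRESHOLD_METHODS["multiotsu_low"] = _multiotsu_low


@dataclass(frozen=True)
class Centroid:
    """Fractional pixel coordinates (arithmetic mean of ROI coordinates)."""

    row: float
    col: float

    def distance_to(self, coords: np.ndarray) -> np.ndarray:
        coords = np.atleast_2d(coords)
        return np.hypot(coords[:, 0] - self.row, coords[:, 1] - self.col)


@dataclass(frozen=True)
class PixelROI:
    """A set of integer pixel coordinates within an image of known shape."""

    coordinates: frozenset
    image_shape: tuple
    metadata: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self) -> None:
        coords = frozenset((int(r), int(c)) for r, c in self.coordinates)
        object.__setattr__(self, "coordinates", coords)
        object.__setattr__(self, "image_shape", tuple(int(s) for s in self.image_shape))
        h, w = self.image_shape
        for r, c in coords:
            if not (0 <= r < h and 0 <= c < w):
                raise GeometryError(f"pixel {(r, c)} outside image {self.image_shape}")

    # -- construction -----------------------------------------------------
    @classmethod
    def from_mask(cls, mask: np.ndarray, metadata: dict | None = None) -> "PixelROI":
        mask = np.asarray(mask, dtype=bool)
        rows, cols = np.nonzero(mask)
        return cls(
            frozenset(zip(rows.tolist(), cols.tolist())),
            mask.shape,
            metadata or {},
        )

    # -- basic views ------------------------------------------------------
    @cached_property
    def coord_array(self) -> np.ndarray:
        """Coordinates as an (n, 2) int array in lexicographic (row, col) order."""
        if not self.coordinates:
            return np.empty((0, 2), dtype=int)
        return np.array(sorted(self.coordinates), dtype=int)

    def to_mask(self) -> np.ndarray:
        mask = np.zeros(self.image_shape, dtype=bool)
        if self.coordinates:
            arr = self.coord_array
            mask[arr[:, 0], arr[:, 1]] = True
        return mask

    @property
    def area(self) -> int:
        return len(self.coordinates)

    @property
    def is_empty(self) -> bool:
        return not self.coordinates

    # -- geometry ---------------------------------------------------------
    def centroid(self) -> Centroid:
        if self.is_empty:
            raise EmptyROIError("centroid of empty ROI")
        arr = self.coord_array
        return Centroid(float(arr[:, 0].mean()), float(arr[:, 1].mean()))

    def boundary(self) -> "Boundary":
        """Pixels of the ROI with at least one 4-neighbour outside the ROI."""
        if self.is_empty:
            raise EmptyROIError("boundary of empty ROI")
        mask = self.to_mask()
        interior = ndimage.binary_erosion(mask, structure=_CROSS, border_value=0)
        return Boundary.from_mask(mask & ~interior)

    # -- set algebra ------------------------------------------------------
    def _check_shape(self, other: "PixelROI") -> None:
        if self.image_shape != other.image_shape:
            raise GeometryError(
                f"image shapes differ: {self.image_shape} vs {other.image_shape}"
            )

    def union(self, other: "PixelROI") -> "PixelROI":
        self._check_shape(other)
        return PixelROI(self.coordinates | other.coordinates, self.image_shape)

    def intersection(self, other: "PixelROI") -> "PixelROI":
        self._check_shape(other)
        return PixelROI(self.coordinates & other.coordinates, self.image_shape)

    __or__ = union
    __and__ = intersection

    # -- serialization ----------------------------------------------------
    def to_rle(self) -> dict:
        """Run-length encoding: list of [row, col_start, run_length] triples."""
        runs = []
        arr = self.coord_array
        i = 0
        n = len(arr)
        while i < n:
            r, c = int(arr[i, 0]), int(arr[i, 1])
            j = i
            while j + 1 < n and arr[j + 1, 0] == r and arr[j + 1, 1] == arr[j, 1] + 1:
                j += 1
            runs.append([r, c, j - i + 1])
            i = j + 1
        return {"image_shape": list(self.image_shape), "runs": runs,
                "metadata": self.metadata}

    @classmethod
    def from_rle(cls, data: dict) -> "PixelROI":
        coords = set()
        for r, c0, length in data["runs"]:
            coords.update((r, c0 + k) for k in range(length))
        return cls(frozenset(coords), tuple(data["image_shape"]),
                   dict(data.get("metadata", {})))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_rle()))

    @classmethod
    def from_json(cls, path: str | Path) -> "PixelROI":
        return cls.from_rle(json.loads(Path(path).read_text()))

    @classmethod
    def from_label_tiff(cls, path: str | Path, label: int = 1) -> "PixelROI":
        """Import an ROI from a label-mask TIFF (pixels equal to ``label``)."""
        mask = tifffile.imread(path) == label
        return cls.from_mask(mask, {"source": str(path), "label": int(label)})


class Boundary(PixelROI):
    """A boundary pixel set; structurally a :class:`PixelROI`."""

    @property
    def pixels(self) -> frozenset:
        return self.coordinates


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def auto_threshold(channel: np.ndarray, method: str = "otsu") -> PixelROI:
    """Segment the pixels above an automatically computed intensity threshold.

    The threshold method name and value are recorded in the ROI metadata.
    Raises :class:`ThresholdError` for a constant (degenerate) image.
    """
    channel = np.asarray(channel, dtype=float)
    if method not in THRESHOLD_METHODS:
        raise ValueError(f"unknown threshold method {method!r}; "
                         f"choose from {sorted(THRESHOLD_METHODS)}")
    if np.ptp(channel) == 0:
        raise ThresholdError("constant image: no threshold exists")
    thr = float(THRESHOLD_METHODS[method](channel))
    return PixelROI.from_mask(channel > thr, {"method": method, "threshold": thr})


def largest_component(roi: PixelROI) -> PixelROI:
    """Largest 8-connected component; ties broken by the component containing
    the lexicographically smallest (row, col) pixel."""
    if roi.is_empty:
        raise EmptyROIError("largest_component of empty ROI")
    labels, n = ndimage.label(roi.to_mask(), structure=np.ones((3, 3), dtype=bool))
    if n == 1:
        return PixelROI(roi.coordinates, roi.image_shape, dict(roi.metadata))
    sizes = np.bincount(labels.ravel())[1:]
    best = None
    for lab in (np.nonzero(sizes == sizes.max())[0] + 1):
        rows, cols = np.nonzero(labels == lab)
        first = (int(rows[0]), int(cols[0]))  # row-major scan => lexicographic min
        if best is None or first < best[0]:
            best = (first, lab)
    return PixelROI.from_mask(labels == best[1], dict(roi.metadata))


def scale_roi(roi: PixelROI, factor: float) -> PixelROI:
    """Scale an ROI geometrically about its centroid.

    A pixel belongs to the scaled ROI iff its position, inverse-mapped through
    the scaling (centroid + (p - centroid)/factor) and rounded to the nearest
    pixel, lies in the source ROI. Inverse mapping leaves no rasterization
    gaps for any factor. The result is clipped to the image bounds.
    """
    if factor <= 0:
        raise ValueError("scale factor must be > 0")
    if roi.is_empty:
        raise EmptyROIError("scale_roi of empty ROI")
    if factor == 1.0:
        return PixelROI(roi.coordinates, roi.image_shape, dict(roi.metadata))
    h, w = roi.image_shape
    c = roi.centroid()
    mask = roi.to_mask()
    rows, cols = np.indices((h, w))
    src_r = np.rint(c.row + (rows - c.row) / factor).astype(int)
    src_c = np.rint(c.col + (cols - c.col) / factor).astype(int)
    valid = (src_r >= 0) & (src_r < h) & (src_c >= 0) & (src_c < w)
    out = np.zeros((h, w), dtype=bool)
    out[valid] = mask[src_r[valid], src_c[valid]]
    if not out.any():
        # extreme shrink: collapse to the pixel nearest the centroid
        pr, pc = int(round(c.row)), int(round(c.col))
        if 0 <= pr < h and 0 <= pc < w and mask[pr, pc]:
            out[pr, pc] = True
        else:
            raise GeometryError("scaled ROI entirely outside image")
    meta = dict(roi.metadata)
    meta["scaled_by"] = float(factor)
    return PixelROI.from_mask(out, meta)


def subtract(a: PixelROI, b: PixelROI) -> PixelROI:
    """Set difference a \\ b (may be empty)."""
    a._check_shape(b)
    return PixelROI(a.coordinates - b.coordinates, a.image_shape, dict(a.metadata))


def mean_intensity(channel: np.ndarray, roi: PixelROI) -> float:
    """Arithmetic mean of the channel values over the ROI coordinates."""
    if roi.is_empty:
        raise EmptyROIError("mean_intensity of empty ROI")
    channel = np.asarray(channel, dtype=float)
    if channel.shape != roi.image_shape:
        raise GeometryError(
            f"channel shape {channel.shape} != ROI image shape {roi.image_shape}"
        )
    arr = roi.coord_array
    return float(channel[arr[:, 0], arr[:, 1]].mean())


def circular_roi(center, radius: float, image_shape) -> PixelROI:
    """All pixels within Euclidean distance ``radius`` of ``center``, clipped
    to the image. ``center`` may be a :class:`Centroid` or (row, col) pair."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if isinstance(center, Centroid):
        cr, cc = center.row, center.col
    else:
        cr, cc = float(center[0]), float(center[1])
    h, w = int(image_shape[0]), int(image_shape[1])
    rr, cc_idx = np.ogrid[:h, :w]
    mask = (rr - cr) ** 2 + (cc_idx - cc) ** 2 <= radius ** 2
    if not mask.any():
        raise GeometryError("circular ROI entirely outside image")
    return PixelROI.from_mask(mask, {"center": (cr, cc), "radius": float(radius)})
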