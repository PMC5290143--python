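"""Bead segmentation and geometry from equatorial epifluorescence images.

Each bead is imaged at its own equatorial focal plane before and after the
pressure step.  The cross-sectional area is segmented with the iterative
intermeans (IsoData) threshold computed on a region of interest around the
bead; assuming the bead stays spherical, area converts to volume via
V = (4/(3*sqrt(pi))) * A^(3/2) and the volumetric strain is |V-V0|/V0.
Bead positions combine image (x, y) centroids with the stage z coordinate;
the spheroid equatorial contour sets the centre and radius R0 used to
normalize radial positions.

Conventions: 0-based pixel indices, x = column and y = row, pixel centres
at integer coordinates; physical outputs in micrometres via ``pixel_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.measure import label, regionprops

from .errors import ConstantRegionError, NoObjectError

__all__ = [
    "Rect",
    "BeadObservation",
    "SpheroidGeometry",
    "isodata_threshold",
    "segment_bead",
    "bead_strain_from_areas",
    "spheroid_geometry",
    "bead_radial_position",
    "qc_filter",
    "auto_roi",
]

QC_PASS = "pass"
QC_SURFACE = "surface"
QC_ELLIPTICAL = "elliptical"
QC_SEGMENTATION = "segmentation_failed"

_N_BINS = 256  # IsoData histogram granularity (8-bit style, ImageJ-compatible)


@dataclass(frozen=True)
class Rect:
    """Axis-aligned ROI, half-open pixel ranges: x in [x0, x1), y in [y0, y1)."""

    x0: int
    y0: int
    x1: int
    y1: int

    def clip(self, shape: tuple[int, int]) -> "Rect":
        h, w = shape
        return Rect(
            max(self.x0, 0), max(self.y0, 0), min(self.x1, w), min(self.y1, h)
        )

    def slices(self) -> tuple[slice, slice]:
        return slice(self.y0, self.y1), slice(self.x0, self.x1)


@dataclass
class BeadObservation:
    """One bead's before/after geometry and derived strain.

    Areas in um^2, volumes in um^3, center in um (image frame, z from the
    stage).  ``ellipticity`` is the major/minor axis ratio of the
    before-compression mask; ``r_norm`` is the 3D distance to the spheroid
    centre over R0 (may exceed 1 before QC).
    """

    spheroid_id: str
    bead_id: str
    area_before: float
    area_after: float
    volume_before: float
    volume_after: float
    strain: float
    center: tuple[float, float, float]
    ellipticity: float
    r_norm: float = np.nan
    qc: str = QC_PASS


@dataclass(frozen=True)
class SpheroidGeometry:
    """Spheroid centre (um) and equivalent radius from the equatorial contour."""

    center: tuple[float, float, float]
    radius: float
    contour_area: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("spheroid radius must be positive")


def isodata_threshold(image: np.ndarray, roi: Rect | None = None) -> float:
    """Iterative intermeans (IsoData) threshold on an ROI histogram.

    Starting from the ROI mean, iterate T <- (mean below T + mean above
    T)/2 until the change falls under half a histogram bin (256 equal-width
    bins over the ROI min-max).  Pixels equal to T count as background.
    """
    img = np.asarray(image, dtype=float)
    if roi is not None:
        img = img[roi.clip(img.shape).slices()]
    pix = img.ravel()
    if pix.size == 0:
        raise ValueError("empty ROI")
    lo, hi = float(pix.min()), float(pix.max())
    if lo == hi:
        raise ConstantRegionError(f"ROI is constant (value {lo:g}); no threshold exists")
    tol = (hi - lo) / _N_BINS / 2.0
    t = float(pix.mean())
    for _ in range(1000):
        below = pix[pix <= t]
        above = pix[pix > t]
        if below.size == 0 or above.size == 0:
            # threshold drifted past the data; pull back to the midpoint
            t_new = (lo + hi) / 2.0
        else:
            t_new = (below.mean() + above.mean()) / 2.0
        if abs(t_new - t) < tol:
            return float(t_new)
        t = t_new
    raise RuntimeError("IsoData did not converge within 1000 iterations")


def segment_bead(
    image: np.ndarray, roi: Rect | None, threshold: float
) -> tuple[float, tuple[float, float], float]:
    """Largest bright connected component above a threshold.

    Returns (area in px^2, centroid (x, y) in full-image px, ellipticity =
    major/minor axis of the second-moment ellipse).  8-connectivity.
    """
    img = np.asarray(image, dtype=float)
    r = roi.clip(img.shape) if roi is not None else Rect(0, 0, img.shape[1], img.shape[0])
    fg = img[r.slices()] > threshold
    if not fg.any():
        raise NoObjectError("no pixels above threshold in ROI")
    labels = label(fg, connectivity=2)
    props = max(regionprops(labels), key=lambda p: p.area)
    cy, cx = props.centroid
    minor = props.axis_minor_length
    ellipticity = props.axis_major_length / minor if minor > 0 else np.inf
    return float(props.area), (cx + r.x0, cy + r.y0), float(ellipticity)


def bead_strain_from_areas(area_before: float, area_after: float) -> tuple[float, float, float]:
    """Volumes and volumetric strain from equatorial areas of a spherical bead.

    V = (4/(3*sqrt(pi))) * A^(3/2); strain = |V - V0| / V0 (equivalently
    |1 - (A/A0)^(3/2)|).  Areas in um^2, volumes in um^3.
    """
    if area_before <= 0 or area_after <= 0:
        raise ValueError("areas must be positive")
    factor = 4.0 / (3.0 * np.sqrt(np.pi))
    v0 = factor * area_before**1.5
    v = factor * area_after**1.5
    return v0, v, abs(v - v0) / v0


def spheroid_geometry(
    mask: np.ndarray, pixel_size: float, z: float = 0.0
) -> SpheroidGeometry:
    """Centre and radius from an equatorial contour mask.

    Uses the largest connected component of ``mask > 0``; the radius is the
    equivalent-disk radius R0 = sqrt(area/pi).  z comes from stage metadata.
    """
    fg = np.asarray(mask) > 0
    if not fg.any():
        raise NoObjectError("empty spheroid mask")
    labels = label(fg, connectivity=2)
    props = max(regionprops(labels), key=lambda p: p.area)
    cy, cx = props.centroid
    area_um2 = float(props.area) * pixel_size**2
    return SpheroidGeometry(
        center=(cx * pixel_size, cy * pixel_size, z),
        radius=float(np.sqrt(area_um2 / np.pi)),
        contour_area=area_um2,
    )


def bead_radial_position(
    center: tuple[float, float, float], geom: SpheroidGeometry
) -> float:
    """Normalized 3D radial position |bead - centre| / R0."""
    d = np.asarray(center, dtype=float) - np.asarray(geom.center, dtype=float)
    return float(np.linalg.norm(d) / geom.radius)


def qc_filter(
    observations: list[BeadObservation],
    geom: SpheroidGeometry,
    margin: float = 10.0,
    ellipticity_max: float = 1.15,
) -> tuple[list[BeadObservation], list[BeadObservation]]:
    """Apply the bead exclusion rules.

    A bead is rejected when it sits within ``margin`` um of the spheroid
    surface (possibly only partially embedded) or when its before-image is
    elliptical beyond ``ellipticity_max`` (rare pre-deformed beads).  Each
    rejected observation carries a machine-readable reason in ``qc``.
    """
    if margin < 0:
        raise ValueError("margin must be non-negative")
    kept: list[BeadObservation] = []
    rejected: list[BeadObservation] = []
    for obs in observations:
        if obs.r_norm * geom.radius > geom.radius - margin:
            rejected.append(replace(obs, qc=QC_SURFACE))
        elif obs.ellipticity > ellipticity_max:
            rejected.append(replace(obs, qc=QC_ELLIPTICAL))
        else:
            kept.append(replace(obs, qc=QC_PASS))
    return kept, rejected


def auto_roi(image: np.ndarray, dilate: float = 0.5) -> Rect:
    """Bounding box of the brightest blob, dilated by ``dilate`` per side.

    The blob is the largest connected component above the min/max midpoint
    intensity; a stand-in for the manually drawn ROI of the original
    acquisition workflow.
    """
    img = np.asarray(image, dtype=float)
    lo, hi = img.min(), img.max()
    if lo == hi:
        raise ConstantRegionError("constant image; no blob to frame")
    fg = img > (lo + hi) / 2.0
    # weight candidate blobs by total intensity so noise specks never win
    labels, n = ndimage.label(fg)
    if n == 0:
        raise NoObjectError("no bright blob found")
    sums = ndimage.sum_labels(img, labels, index=np.arange(1, n + 1))
    best = int(np.argmax(sums)) + 1
    ys, xs = np.nonzero(labels == best)
    h, w = ys.max() - ys.min() + 1, xs.max() - xs.min() + 1
    pad_y, pad_x = int(np.ceil(h * dilate)), int(np.ceil(w * dilate))
    return Rect(
        int(xs.min() - pad_x),
        int(ys.min() - pad_y),
        int(xs.max() + 1 + pad_x),
        int(ys.max() + 1 + pad_y),
    ).clip(img.shape)
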