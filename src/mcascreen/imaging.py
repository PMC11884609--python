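"""Bright-field image analysis of multicellular aggregates.

Implements the on-the-fly screening pipeline: background normalisation,
intensity-threshold segmentation, partition of the binary mask into Center /
Inner / Border regions, morphometric feature extraction (area, perimeter,
equivalent diameter, ellipse fit, eccentricity), lumen-based phenotype
classification, and the two Beer-Lambert calibration fits (attenuation length
from spheroids, monolayer-thickness scaling from cysts).

All geometric measurements use the binary mask; intensities are relative to
the local background, so a normalised frame has background level ~1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from skimage import measure as _skmeasure
from skimage import morphology as _skmorph

from .errors import ConfigurationError, DegenerateObjectError, FitError, InputError

__all__ = [
    "Frame",
    "SegmentationParams",
    "Regions",
    "FeatureVector",
    "GateConfig",
    "CalibrationFit",
    "ClassificationReport",
    "normalize_frame",
    "segment",
    "partition_regions",
    "measure",
    "classify_phenotype",
    "estimate_thickness",
    "fit_attenuation_length",
    "fit_cyst_scaling",
    "evaluate_classifier",
    "analyze_frame",
]


@dataclass
class Frame:
    """A single grayscale image with its physical pixel scale.

    Parameters
    ----------
    pixels : ndarray
        2-D array of intensities (arbitrary units, or background-relative
        after :func:`normalize_frame`).
    pixel_scale : float
        Physical size of one pixel in µm.
    """

    pixels: np.ndarray
    pixel_scale: float = 3.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise InputError("Frame.pixels must be a 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise InputError("Frame.pixels must be finite")
        if self.pixel_scale <= 0:
            raise ConfigurationError("pixel_scale must be positive")

    @property
    def shape(self) -> tuple:
        return self.pixels.shape


@dataclass
class SegmentationParams:
    """Parameters of the threshold/morphology segmentation stage.

    threshold is a fraction of the (normalised) background intensity: pixels
    below it form the object mask.  min_area_px discards frames whose largest
    object is too small.  erosion_px sets the Border thickness; the Center
    region is a small disk (odd diameter, in px) about the mask centroid.
    """

    threshold: float = 0.90
    min_area_px: int = 200
    erosion_px: int = 6
    center_disk_diameter_px: int = 11

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ConfigurationError("threshold must be in (0, 1)")
        if self.min_area_px < 1:
            raise ConfigurationError("min_area_px must be >= 1")
        if self.erosion_px < 1:
            raise ConfigurationError("erosion_px must be >= 1")
        if self.center_disk_diameter_px < 1 or self.center_disk_diameter_px % 2 == 0:
            raise ConfigurationError("center_disk_diameter_px must be odd and >= 1")


@dataclass
class Regions:
    """The object mask and its Center / Inner / Border partition.

    inner and border tile the mask exactly; center is a small disk about the
    mask centroid and may partially fall outside the mask (flagged).
    """

    mask: np.ndarray
    inner: np.ndarray
    border: np.ndarray
    center: np.ndarray
    centroid_px: tuple
    multi_object: bool = False
    center_outside_mask: bool = False


@dataclass
class FeatureVector:
    """Per-object measurements extracted from one frame.

    Notes
    -----
    ``P`` is the pixel count of the (erosion-thick) Border region, matching
    the screening pipeline's perimeter definition; ``circ`` uses an
    independent single-pixel contour perimeter ``P_geom`` so that the
    isoperimetric ratio 4πA/P_geom² is ≈1 for disks.
    """

    A: float  # area, px
    P: float  # border-region pixel count
    D: float  # equivalent diameter, µm
    a: float  # semi-major axis, µm
    b: float  # semi-minor axis, µm
    e: float  # eccentricity
    theta: float  # orientation, rad
    mean_inner: float
    center_int: float
    I0_local: float
    circ: float  # 4*pi*A / P_geom**2
    P_geom: float
    h: float = float("nan")  # Beer-Lambert thickness, µm (if h0 supplied)
    multi_object: bool = False


@dataclass
class GateConfig:
    """Size gate: an object is a target iff Dmin <= D <= Dmax (µm)."""

    Dmin: float = 320.0
    Dmax: float = 336.0
    phenotype_rule: str = "none"  # "cyst" | "spheroid" | "none"
    inclusive: bool = True

    def __post_init__(self) -> None:
        if self.Dmin > self.Dmax:
            raise ConfigurationError("Dmin must be <= Dmax")
        if self.phenotype_rule not in ("cyst", "spheroid", "none"):
            raise ConfigurationError("phenotype_rule must be cyst|spheroid|none")


@dataclass
class CalibrationFit:
    """Result of a through-origin linear calibration fit."""

    h0_hat: float  # attenuation length (µm) or NaN for the cyst-scaling fit
    slope: float
    n: int
    rms_residual: float
    k: float = float("nan")  # D/h constant for the cyst-scaling fit
    nonlinear: bool = False


@dataclass
class ClassificationReport:
    """Confusion counts and precision/recall, with 'cyst' the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int
    precision: Optional[float] = field(default=None)
    recall: Optional[float] = field(default=None)


def normalize_frame(raw: Frame, background: Frame, eps: float = 1e-6) -> Frame:
    """Divide a raw frame pixelwise by a background (object-free) frame.

    Background pixels below ``eps`` are raised to ``eps`` so the ratio stays
    finite.  A raw frame equal to its background maps to all-ones.
    """
    if raw.pixels.shape != background.pixels.shape:
        raise InputError("raw and background frames must have the same shape")
    bg = np.maximum(background.pixels, eps)
    return Frame(raw.pixels / bg, raw.pixel_scale)


def segment(frame: Frame, params: SegmentationParams | None = None) -> Optional[Regions]:
    """Threshold a normalised frame and keep the largest connected object.

    Returns ``None`` ("discard") when no pixel is below threshold or the
    largest component is smaller than ``min_area_px``.  When more than one
    component passes the area cutoff a ``multi_object`` flag is raised on the
    returned :class:`Regions` (this feeds the sorter's co-detection logic).
    """
    params = params or SegmentationParams()
    below = frame.pixels < params.threshold
    if not below.any():
        return None
    labels, n_labels = _skmeasure.label(below, return_num=True, connectivity=2)
    areas = np.bincount(labels.ravel())[1:]
    biggest = int(np.argmax(areas)) + 1
    if areas[biggest - 1] < params.min_area_px:
        return None
    mask = labels == biggest
    multi = int(np.sum(areas >= params.min_area_px)) > 1
    regions = partition_regions(mask, params)
    regions.multi_object = multi
    return regions


def _disk_footprint(radius: int) -> np.ndarray:
    return _skmorph.disk(radius)


def partition_regions(mask: np.ndarray, params: SegmentationParams | None = None) -> Regions:
    """Split a binary mask into Inner / Border and place the Center disk.

    Inner is the mask eroded by ``erosion_px`` with a Euclidean disk
    structuring element; Border is the set difference.  Center is a disk of
    ``center_disk_diameter_px`` about the mask centroid rounded to the
    nearest pixel.
    """
    params = params or SegmentationParams()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise InputError("cannot partition an empty mask")
    inner = _skmorph.erosion(mask, _disk_footprint(params.erosion_px))
    if not inner.any():
        raise DegenerateObjectError(
            f"object vanished under {params.erosion_px}-px erosion (too small/thin)"
        )
    border = mask & ~inner
    rows, cols = np.nonzero(mask)
    cr, cc = int(round(rows.mean())), int(round(cols.mean()))
    radius = (params.center_disk_diameter_px - 1) / 2.0
    rr, cc_grid = np.ogrid[: mask.shape[0], : mask.shape[1]]
    center = (rr - cr) ** 2 + (cc_grid - cc) ** 2 <= radius**2
    outside = bool(np.any(center & ~mask))
    return Regions(
        mask=mask,
        inner=inner,
        border=border,
        center=center,
        centroid_px=(cr, cc),
        center_outside_mask=outside,
    )


def _background_level(frame: Frame, regions: Regions, pad_px: int) -> float:
    """Mean intensity outside the (dilated) mask; 1.0 if nothing is left."""
    dilated = _skmorph.dilation(regions.mask, _disk_footprint(pad_px))
    outside = ~dilated
    if not outside.any():
        return 1.0
    return float(frame.pixels[outside].mean())


def measure(
    frame: Frame,
    regions: Regions,
    params: SegmentationParams | None = None,
    h0: Optional[float] = None,
) -> FeatureVector:
    """Extract the morphometric/intensity feature vector from one object.

    The ellipse fit (semi-axes, orientation, eccentricity) comes from the
    normalised second central moments of the binary mask.  When ``h0`` is
    given, the Beer-Lambert thickness at the center is appended.
    """
    params = params or SegmentationParams()
    scale = frame.pixel_scale
    props = _skmeasure.regionprops(regions.mask.astype(np.uint8))[0]
    A = float(props.area)
    P = float(np.count_nonzero(regions.border))
    D = 2.0 * scale * math.sqrt(A / math.pi)
    a = scale * props.axis_major_length / 2.0
    b = scale * props.axis_minor_length / 2.0
    e = float(props.eccentricity)
    theta = float(props.orientation)
    p_geom = float(props.perimeter_crofton)  # 4-direction Crofton: unbiased for disks
    circ = 4.0 * math.pi * A / p_geom**2 if p_geom > 0 else float("nan")
    mean_inner = float(frame.pixels[regions.inner].mean())
    center_int = float(frame.pixels[regions.center].mean())
    i0_local = _background_level(frame, regions, params.erosion_px)
    h = float("nan")
    if h0 is not None:
        h = estimate_thickness(center_int, i0_local, h0)
    return FeatureVector(
        A=A,
        P=P,
        D=D,
        a=a,
        b=b,
        e=e,
        theta=theta,
        mean_inner=mean_inner,
        center_int=center_int,
        I0_local=i0_local,
        circ=circ,
        P_geom=p_geom,
        h=h,
        multi_object=regions.multi_object,
    )


def classify_phenotype(fv: FeatureVector) -> str:
    """Classify an object as ``"cyst"`` or ``"spheroid"``.

    A lumen transmits light, so a cyst shows a bright center spot: it is
    called a cyst iff the Center intensity strictly exceeds the Inner-region
    mean intensity (ties break to spheroid).
    """
    return "cyst" if fv.center_int > fv.mean_inner else "spheroid"


def estimate_thickness(center_int: float, I0_local: float, h0: float) -> float:
    """Invert the Beer-Lambert law: h = h0 * ln(I0 / I) (µm, >= 0).

    ``center_int`` above the local background means no absorber on the path;
    the thickness is clamped to 0 with a warning in that case.
    """
    if h0 <= 0:
        raise InputError("h0 must be positive")
    if center_int <= 0:
        raise InputError("center intensity must be positive")
    if center_int > I0_local:
        warnings.warn("center intensity above background; thickness clamped to 0")
        return 0.0
    return h0 * math.log(I0_local / center_int)


def _through_origin_fit(x: np.ndarray, y: np.ndarray) -> tuple:
    """Least-squares slope of y = s*x through the origin, plus residual RMS."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sxx = float(np.dot(x, x))
    if sxx <= 0 or np.ptp(x) == 0:
        raise FitError("singular design: predictor has no spread")
    slope = float(np.dot(x, y)) / sxx
    rms = float(np.sqrt(np.mean((y - slope * x) ** 2)))
    return slope, rms


def fit_attenuation_length(features: Sequence[FeatureVector]) -> CalibrationFit:
    """Estimate the attenuation length h0 from a spheroid series.

    Fits y = -ln(center_int / I0_local) against the equivalent diameter D
    through the origin; for a plain aggregate the center chord is ~D, so the
    slope is 1/h0.
    """
    if len(features) < 2:
        raise FitError("need at least two spheroids to fit the attenuation length")
    D = np.array([f.D for f in features])
    y = np.array([-math.log(f.center_int / f.I0_local) for f in features])
    slope, rms = _through_origin_fit(D, y)
    if slope <= 0:
        raise FitError("non-positive attenuation slope")
    return CalibrationFit(h0_hat=1.0 / slope, slope=slope, n=len(features), rms_residual=rms)


def fit_cyst_scaling(features: Sequence[FeatureVector], h0: float) -> CalibrationFit:
    """Fit the monolayer-thickness scaling h = D / k over a cyst series.

    The center thickness h of each cyst is obtained by Beer-Lambert inversion
    with the (spheroid-calibrated) attenuation length ``h0``; h is regressed
    on D through the origin and k = 1/slope is reported.  If an affine fit
    reduces the residual by more than half, the linear-through-origin model is
    flagged as a poor description (``nonlinear=True``), e.g. for cysts whose
    monolayer thickness does not grow with diameter.
    """
    if len(features) < 2:
        raise FitError("need at least two cysts to fit the thickness scaling")
    D = np.array([f.D for f in features])
    h = np.array([estimate_thickness(f.center_int, f.I0_local, h0) for f in features])
    slope, rms = _through_origin_fit(D, h)
    if slope <= 0:
        raise FitError("non-positive thickness slope")
    # affine comparison fit to flag misfit of the through-origin model; small
    # systematic residuals (a few % of h) are expected and not flagged
    coeffs = np.polyfit(D, h, 1)
    rms_affine = float(np.sqrt(np.mean((h - np.polyval(coeffs, D)) ** 2)))
    nonlinear = rms_affine < 0.5 * rms and rms > 0.05 * float(np.mean(np.abs(h)))
    return CalibrationFit(
        h0_hat=float("nan"),
        slope=slope,
        n=len(features),
        rms_residual=rms,
        k=1.0 / slope,
        nonlinear=nonlinear,
    )


def evaluate_classifier(
    predicted: Sequence[str], truth: Sequence[str], positive: str = "cyst"
) -> ClassificationReport:
    """Confusion counts, precision and recall for a label sequence pair.

    Precision (recall) is reported as ``None`` when no positives are
    predicted (present).
    """
    if len(predicted) != len(truth):
        raise InputError("predicted and truth label sequences differ in length")
    pred = np.asarray(predicted) == positive
    true = np.asarray(truth) == positive
    tp = int(np.sum(pred & true))
    fp = int(np.sum(pred & ~true))
    fn = int(np.sum(~pred & true))
    tn = int(np.sum(~pred & ~true))
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    recall = tp / (tp + fn) if (tp + fn) > 0 else None
    return ClassificationReport(tp=tp, fp=fp, fn=fn, tn=tn, precision=precision, recall=recall)


def analyze_frame(
    frame: Frame,
    background: Optional[Frame] = None,
    params: SegmentationParams | None = None,
    h0: Optional[float] = None,
) -> Optional[FeatureVector]:
    """Full single-frame pipeline: normalise, segment, measure.

    Returns ``None`` when the frame is discarded (no object above the area
    cutoff).
    """
    params = params or SegmentationParams()
    if background is not None:
        frame = normalize_frame(frame, background)
    regions = segment(frame, params)
    if regions is None:
        return None
    return measure(frame, regions, params, h0=h0)
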