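"""Fluorescence reporter quantification for enhancer assays in the limb.

The workflow mirrors how mosaic reporter electroporations are scored: each
embryo contributes a light (morphology) image, an RFP transfection-control
channel and a GFP reporter channel. Channels are converted to grayscale and
bilateral-denoised; the limb is segmented from the light image by Otsu
thresholding plus a manually annotated limb/body-wall boundary; nested
anatomical masks (Limb >= Posterior >= ZPA) restrict measurement to tissue
that can express; the transfected region is the Otsu foreground of the
masked RFP channel and the active region the Otsu foreground of GFP within
it. Relative enhancer activity is total GFP intensity normalized to total
RFP intensity, which controls for transfection efficiency differences
between embryos.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from skimage import draw as skdraw
from skimage import measure as skmeasure
from skimage.restoration import denoise_bilateral

__all__ = [
    "ImageBundle",
    "MaskSet",
    "Orientation",
    "BoundaryAnnotation",
    "RegionMeasurement",
    "ActivityRecord",
    "QuantParams",
    "to_grayscale",
    "bilateral_denoise",
    "otsu_threshold",
    "segment_limb",
    "build_posterior_mask",
    "build_zpa_mask",
    "transfection_region",
    "activity_region",
    "measure_region",
    "relative_activity",
    "quantify_bundle",
    "load_bundle",
    "load_annotation",
]

log = logging.getLogger(__name__)

GRAY_WEIGHTS = np.array([0.2125, 0.7154, 0.0721])


class ImagingError(ValueError):
    """Invalid input to an image-quantification stage."""


class DegenerateInputError(ImagingError):
    """Input without the contrast needed for thresholding (all values equal)."""


class AnnotationError(ImagingError):
    """Manual boundary annotation does not usably split the tissue."""


class NoTransfectionError(DegenerateInputError):
    """No transfected tissue detectable in the RFP channel."""


class UndefinedActivityError(ImagingError):
    """Relative activity undefined because total RFP intensity is zero."""


class StageError(ImagingError):
    """Failure inside quantify_bundle, tagged with the stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ImageBundle:
    """Aligned light/RFP/GFP rasters for one embryo limb."""

    light: np.ndarray
    rfp: np.ndarray
    gfp: np.ndarray
    embryo_id: str = ""
    group: str = ""
    saturation_level: float | None = None  # max representable intensity

    def __post_init__(self) -> None:
        self.light = np.asarray(self.light, dtype=float)
        self.rfp = np.asarray(self.rfp, dtype=float)
        self.gfp = np.asarray(self.gfp, dtype=float)
        if not (self.light.shape == self.rfp.shape == self.gfp.shape):
            raise ImagingError(
                f"channel shapes differ: light {self.light.shape}, "
                f"rfp {self.rfp.shape}, gfp {self.gfp.shape}")
        for name, arr in (("light", self.light), ("rfp", self.rfp),
                          ("gfp", self.gfp)):
            if arr.ndim != 2:
                raise ImagingError(f"{name} channel must be 2-D")
            if np.any(arr < 0):
                raise ImagingError(f"{name} channel has negative intensities")


@dataclass
class MaskSet:
    """Nested anatomical masks: zpa <= posterior <= limb (pixelwise)."""

    limb: np.ndarray
    posterior: np.ndarray
    zpa: np.ndarray

    def __post_init__(self) -> None:
        if not (self.limb.shape == self.posterior.shape == self.zpa.shape):
            raise ImagingError("mask shapes differ")
        if np.any(self.posterior & ~self.limb):
            raise ImagingError("posterior mask not contained in limb mask")
        if np.any(self.zpa & ~self.posterior):
            raise ImagingError("ZPA mask not contained in posterior mask")

    def get(self, choice: str) -> np.ndarray:
        try:
            return {"limb": self.limb, "posterior": self.posterior,
                    "zpa": self.zpa}[choice]
        except KeyError:
            raise ImagingError(f"unknown mask choice {choice!r}") from None


_EDGES = ("top", "bottom", "left", "right")
_OPPOSITE = {"top": "bottom", "bottom": "top", "left": "right", "right": "left"}


@dataclass(frozen=True)
class Orientation:
    """Which image edges are anatomically anterior and distal.

    Default matches the standard dorsal-view mounting: top = anterior,
    right = distal (so bottom = posterior, left = proximal).
    """

    anterior: str = "top"
    distal: str = "right"

    def __post_init__(self) -> None:
        if self.anterior not in _EDGES or self.distal not in _EDGES:
            raise ImagingError(f"orientation edges must be one of {_EDGES}")
        vertical = {"top", "bottom"}
        if (self.anterior in vertical) == (self.distal in vertical):
            raise ImagingError("anterior and distal must be perpendicular axes")

    @property
    def posterior(self) -> str:
        return _OPPOSITE[self.anterior]


@dataclass
class BoundaryAnnotation:
    """Sidecar annotation: manual limb/body-wall boundary for one embryo.

    ``boundary_polyline`` is a list of (row, col) vertices; ``limb_side_point``
    is any (row, col) pixel inside the limb, flagging which side of the
    boundary is limb tissue.
    """

    embryo_id: str
    group: str
    boundary_polyline: list[tuple[float, float]]
    orientation: Orientation = field(default_factory=Orientation)
    limb_side_point: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if len(self.boundary_polyline) < 2:
            raise AnnotationError("boundary polyline needs >= 2 vertices")


@dataclass(frozen=True)
class RegionMeasurement:
    """Pixel count and total (summed) intensity over a region."""

    pixel_count: int
    total_intensity: float

    def __post_init__(self) -> None:
        if self.pixel_count == 0 and self.total_intensity != 0.0:
            raise ImagingError("empty region cannot carry intensity")


@dataclass
class ActivityRecord:
    """Per-embryo quantification result.

    ``relative_activity`` is gfp_total / rfp_total; NaN with ``excluded``
    set when the embryo could not be scored (e.g. no transfection).
    ``metadata`` records every threshold and mask fraction used, enough to
    re-derive the numbers by hand.
    """

    embryo_id: str
    group: str
    rfp_pixels: int = 0
    rfp_total: float = 0.0
    gfp_pixels: int = 0
    gfp_total: float = 0.0
    relative_activity: float = math.nan
    mask_choice: str = "posterior"
    excluded: bool = False
    flags: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        return {
            "embryo_id": self.embryo_id, "group": self.group,
            "mask_choice": self.mask_choice,
            "rfp_pixels": self.rfp_pixels, "rfp_total": self.rfp_total,
            "gfp_pixels": self.gfp_pixels, "gfp_total": self.gfp_total,
            "relative_activity": self.relative_activity,
            "excluded": self.excluded, "flags": ";".join(self.flags),
        }


@dataclass
class QuantParams:
    """Tunable parameters of the quantification pipeline.

    sigma_spatial: bilateral filter spatial sigma, pixels.
    sigma_range_frac: bilateral range sigma as a fraction of each channel's
        dynamic range.
    posterior_ap_fraction: posterior share of the limb bounding box retained
        by the Posterior mask along the anterior-posterior axis.
    zpa_pd_fraction / zpa_ap_fraction: distal and posterior shares defining
        the ZPA mask.
    intensity_over: 'foreground' sums intensity over the Otsu-foreground
        pixels only (transfected region for RFP, active region for GFP);
        'mask' sums over every pixel of the relevant mask.
    rfp_threshold / gfp_threshold: optional fixed thresholds overriding Otsu.
    saturation_flag_fraction: flag the record when more than this fraction
        of pixels sit at the saturation level.
    """

    sigma_spatial: float = 3.0
    sigma_range_frac: float = 0.10
    posterior_ap_fraction: float = 0.5
    zpa_pd_fraction: float = 0.4
    zpa_ap_fraction: float = 0.35
    intensity_over: Literal["foreground", "mask"] = "foreground"
    rfp_threshold: float | None = None
    gfp_threshold: float | None = None
    saturation_flag_fraction: float = 0.01


# ---------------------------------------------------------------------------
# Pixel-level operations
# ---------------------------------------------------------------------------

def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Luminance grayscale conversion preserving the input intensity range.

    Single-channel input is returned unchanged (as float); 3-channel RGB is
    combined with weights (0.2125, 0.7154, 0.0721), which sum to 1 so a gray
    RGB pixel (v, v, v) maps to v.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        return image.copy()
    if image.ndim == 3 and image.shape[-1] == 1:
        return image[..., 0].copy()
    if image.ndim == 3 and image.shape[-1] == 3:
        return image @ GRAY_WEIGHTS
    raise ImagingError(f"unsupported channel count for shape {image.shape}")


def bilateral_denoise(image: np.ndarray, sigma_spatial: float = 3.0,
                      sigma_range: float | None = None) -> np.ndarray:
    """Edge-preserving bilateral smoothing in original intensity units.

    ``sigma_range`` defaults to 10% of the image's dynamic range. The image
    is normalized to [0, 1] for filtering and rescaled back, so output units
    match input units; a constant image passes through unchanged.
    """
    image = np.asarray(image, dtype=float)
    if sigma_spatial <= 0:
        raise ImagingError(f"sigma_spatial must be > 0, got {sigma_spatial}")
    lo, hi = float(image.min()), float(image.max())
    span = hi - lo
    if span == 0:
        return image.copy()
    if sigma_range is None:
        sigma_range = 0.10 * span
    if sigma_range <= 0:
        raise ImagingError(f"sigma_range must be > 0, got {sigma_range}")
    norm = (image - lo) / span
    out = denoise_bilateral(norm, sigma_color=sigma_range / span,
                            sigma_spatial=sigma_spatial, channel_axis=None)
    return out * span + lo


def otsu_threshold(values) -> float:
    """Otsu's threshold over the exact observed intensity values.

    Candidate cuts are the distinct observed values; the returned threshold
    maximizes the between-class variance w0*w1*(mu0 - mu1)^2, with the
    foreground defined as values strictly greater than the threshold. Ties
    are broken toward the smallest threshold. Working on exact values rather
    than a fixed histogram binning keeps the result identical to exhaustive
    search for any input.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise DegenerateInputError("no values to threshold")
    uniq, counts = np.unique(values, return_counts=True)
    if uniq.size < 2:
        raise DegenerateInputError(
            "all values identical; no threshold separates two classes")
    n = counts.sum()
    cum_n = np.cumsum(counts)            # pixels <= uniq[i]
    cum_s = np.cumsum(uniq * counts)     # intensity sum <= uniq[i]
    w0 = cum_n[:-1]
    w1 = n - w0
    mu0 = cum_s[:-1] / w0
    mu1 = (cum_s[-1] - cum_s[:-1]) / w1
    between = w0 * w1 * (mu0 - mu1) ** 2
    return float(uniq[int(np.argmax(between))])  # argmax takes first maximum


def segment_limb(light: np.ndarray, boundary: Sequence[tuple[float, float]],
                 limb_side_point: tuple[int, int] | None = None) -> np.ndarray:
    """Segment the limb from a light image using Otsu plus a manual boundary.

    The Otsu foreground of the light image contains both limb and body-wall
    tissue; burning the annotated boundary polyline into it severs the two,
    after which the limb is the connected component containing
    ``limb_side_point`` (or the largest component when no point is given).
    Raises AnnotationError when the boundary leaves the foreground in a
    single component.
    """
    light = np.asarray(light, dtype=float)
    if len(boundary) < 2:
        raise AnnotationError("boundary polyline needs >= 2 vertices")
    t = otsu_threshold(light)
    fg = light > t
    cut = fg.copy()
    for (r0, c0), (r1, c1) in zip(boundary[:-1], boundary[1:]):
        rr, cc = skdraw.line(int(round(r0)), int(round(c0)),
                             int(round(r1)), int(round(c1)))
        inside = (rr >= 0) & (rr < cut.shape[0]) & (cc >= 0) & (cc < cut.shape[1])
        cut[rr[inside], cc[inside]] = False
    # 4-connectivity so the 8-connected drawn line cannot be leaked across
    labels, n_comp = skmeasure.label(cut, connectivity=1, return_num=True)
    if n_comp < 2:
        raise AnnotationError(
            "boundary does not split the tissue foreground into >= 2 "
            "components")
    if limb_side_point is not None:
        r, c = int(limb_side_point[0]), int(limb_side_point[1])
        if not (0 <= r < labels.shape[0] and 0 <= c < labels.shape[1]):
            raise AnnotationError("limb_side_point outside the image")
        lbl = labels[r, c]
        if lbl == 0:
            raise AnnotationError("limb_side_point is not on tissue foreground")
    else:
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        lbl = int(np.argmax(sizes))
    return labels == lbl


def _axis_keep(mask: np.ndarray, fraction: float, edge: str) -> np.ndarray:
    """Keep the ``fraction`` of the mask's bounding box nearest ``edge``."""
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    keep = np.zeros_like(mask)
    if edge in ("top", "bottom"):
        lo, hi = rows[0], rows[-1]
        n = math.ceil(fraction * (hi - lo + 1))
        if edge == "bottom":
            keep[hi - n + 1: hi + 1, :] = True
        else:
            keep[lo: lo + n, :] = True
    else:
        lo, hi = cols[0], cols[-1]
        n = math.ceil(fraction * (hi - lo + 1))
        if edge == "right":
            keep[:, hi - n + 1: hi + 1] = True
        else:
            keep[:, lo: lo + n] = True
    return mask & keep


def build_posterior_mask(limb: np.ndarray, ap_fraction: float = 0.5,
                         orientation: Orientation = Orientation()) -> np.ndarray:
    """Posterior-most ``ap_fraction`` of the limb along the AP axis.

    The crop is an axis-aligned fraction of the limb bounding box, which
    excludes anterior tissue that may be transfected but would not express
    wild-type enhancer activity. Always a subset of the limb mask.
    """
    if not 0 < ap_fraction <= 1:
        raise ImagingError(f"ap_fraction must be in (0, 1], got {ap_fraction}")
    if not limb.any():
        raise ImagingError("empty limb mask")
    return _axis_keep(limb, ap_fraction, orientation.posterior)


def build_zpa_mask(limb: np.ndarray, posterior: np.ndarray,
                   pd_fraction: float = 0.4, ap_fraction: float = 0.35,
                   orientation: Orientation = Orientation()) -> np.ndarray:
    """Distal-posterior corner of the limb approximating the ZPA.

    Intersection of the distal-most ``pd_fraction`` and posterior-most
    ``ap_fraction`` of the limb bounding box, clipped to the posterior mask
    so the nesting zpa <= posterior <= limb always holds.
    """
    for name, f in (("pd_fraction", pd_fraction), ("ap_fraction", ap_fraction)):
        if not 0 < f <= 1:
            raise ImagingError(f"{name} must be in (0, 1], got {f}")
    if not posterior.any():
        raise ImagingError("empty posterior mask")
    if np.any(posterior & ~limb):
        raise ImagingError("posterior mask not contained in limb mask")
    zpa = _axis_keep(limb, ap_fraction, orientation.posterior)
    zpa &= _axis_keep(limb, pd_fraction, orientation.distal)
    return zpa & posterior


def transfection_region(rfp: np.ndarray, analysis_mask: np.ndarray,
                        threshold: float | None = None
                        ) -> tuple[np.ndarray, float]:
    """Transfected pixels: Otsu foreground of RFP within the analysis mask.

    The threshold is computed from RFP values inside the mask only (or taken
    fixed when given). Returns ``(mask, threshold)``. Constant RFP within
    the mask means no transfection is detectable and raises
    NoTransfectionError.
    """
    if not analysis_mask.any():
        raise ImagingError("empty analysis mask")
    vals = rfp[analysis_mask]
    if threshold is None:
        try:
            threshold = otsu_threshold(vals)
        except DegenerateInputError:
            raise NoTransfectionError("no transfection detected "
                                      "(constant RFP within mask)") from None
    region = (rfp > threshold) & analysis_mask
    return region, float(threshold)


def activity_region(gfp: np.ndarray, transfection_mask: np.ndarray,
                    threshold: float | None = None
                    ) -> tuple[np.ndarray, float]:
    """Active pixels: Otsu foreground of GFP within the transfected region.

    A silent enhancer (constant GFP within the region) is a valid outcome:
    an empty region is returned with a logged warning, not an error.
    """
    if not transfection_mask.any():
        raise ImagingError("empty transfection mask")
    vals = gfp[transfection_mask]
    if threshold is None:
        try:
            threshold = otsu_threshold(vals)
        except DegenerateInputError:
            log.warning("constant GFP within transfection mask; "
                        "silent enhancer, empty activity region")
            return np.zeros_like(transfection_mask), math.inf
    region = (gfp > threshold) & transfection_mask
    return region, float(threshold)


def measure_region(image: np.ndarray, region: np.ndarray) -> RegionMeasurement:
    """Pixel count and summed intensity of ``image`` over ``region``."""
    image = np.asarray(image, dtype=float)
    if image.shape != region.shape:
        raise ImagingError(f"image shape {image.shape} != region shape "
                           f"{region.shape}")
    count = int(region.sum())
    total = float(image[region].sum()) if count else 0.0
    return RegionMeasurement(count, total)


def relative_activity(gfp_total: float, rfp_total: float) -> float:
    """Total GFP over total RFP; scale-free measure of enhancer activity."""
    if gfp_total < 0 or rfp_total < 0:
        raise ImagingError("intensity totals must be non-negative")
    if rfp_total == 0:
        raise UndefinedActivityError(
            "relative activity undefined: total RFP intensity is zero")
    return gfp_total / rfp_total


# ---------------------------------------------------------------------------
# End-to-end quantification
# ---------------------------------------------------------------------------

def _saturation_flags(bundle: ImageBundle, frac: float) -> list[str]:
    if bundle.saturation_level is None:
        return []
    flags = []
    for name, arr in (("light", bundle.light), ("rfp", bundle.rfp),
                      ("gfp", bundle.gfp)):
        if np.mean(arr >= bundle.saturation_level) > frac:
            flags.append(f"saturated_{name}")
    return flags


def build_masks(bundle: ImageBundle, annotation: BoundaryAnnotation,
                params: QuantParams = QuantParams()) -> MaskSet:
    """Denoise the light image and construct the nested anatomical masks."""
    light = bilateral_denoise(to_grayscale(bundle.light),
                              params.sigma_spatial)
    limb = segment_limb(light, annotation.boundary_polyline,
                        annotation.limb_side_point)
    posterior = build_posterior_mask(limb, params.posterior_ap_fraction,
                                     annotation.orientation)
    zpa = build_zpa_mask(limb, posterior, params.zpa_pd_fraction,
                         params.zpa_ap_fraction, annotation.orientation)
    return MaskSet(limb, posterior, zpa)


def quantify_bundle(bundle: ImageBundle, annotation: BoundaryAnnotation,
                    mask_choice: str = "posterior",
                    params: QuantParams = QuantParams()) -> ActivityRecord:
    """Run the full quantification workflow on one embryo.

    denoise -> segment limb -> build masks -> transfection region (within
    the chosen mask) -> activity region -> measure -> normalize. An embryo
    without detectable transfection is returned as an excluded record
    flagged "no transfection detected" rather than an error; any other stage
    failure raises StageError tagged with the stage name.
    """
    record = ActivityRecord(bundle.embryo_id, bundle.group,
                            mask_choice=mask_choice)
    record.flags.extend(_saturation_flags(bundle,
                                          params.saturation_flag_fraction))

    def run(stage, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except NoTransfectionError:
            raise
        except Exception as exc:
            raise StageError(stage, exc) from exc

    masks = run("masks", build_masks, bundle, annotation, params)
    analysis = masks.get(mask_choice)
    span = lambda a: float(a.max() - a.min())
    rfp = run("denoise", bilateral_denoise, to_grayscale(bundle.rfp),
              params.sigma_spatial, params.sigma_range_frac * span(bundle.rfp)
              if span(bundle.rfp) > 0 else None)
    gfp = run("denoise", bilateral_denoise, to_grayscale(bundle.gfp),
              params.sigma_spatial, params.sigma_range_frac * span(bundle.gfp)
              if span(bundle.gfp) > 0 else None)

    try:
        tmask, t_rfp = run("transfection_region", transfection_region,
                           rfp, analysis, params.rfp_threshold)
    except NoTransfectionError as exc:
        record.excluded = True
        record.flags.append("no transfection detected")
        record.metadata["exclusion_reason"] = str(exc)
        log.warning("%s: %s", bundle.embryo_id, exc)
        return record

    amask, t_gfp = run("activity_region", activity_region,
                       gfp, tmask, params.gfp_threshold)

    if params.intensity_over == "foreground":
        rfp_meas = run("measure", measure_region, rfp, tmask)
        gfp_meas = run("measure", measure_region, gfp, amask)
    elif params.intensity_over == "mask":
        rfp_meas = run("measure", measure_region, rfp, analysis)
        gfp_meas = run("measure", measure_region, gfp, tmask)
    else:
        raise StageError("measure", ImagingError(
            f"unknown intensity_over {params.intensity_over!r}"))

    record.rfp_pixels, record.rfp_total = (rfp_meas.pixel_count,
                                           rfp_meas.total_intensity)
    record.gfp_pixels, record.gfp_total = (gfp_meas.pixel_count,
                                           gfp_meas.total_intensity)
    try:
        record.relative_activity = relative_activity(record.gfp_total,
                                                     record.rfp_total)
    except UndefinedActivityError as exc:
        record.excluded = True
        record.flags.append("undefined activity")
        record.metadata["exclusion_reason"] = str(exc)
        log.warning("%s: %s", bundle.embryo_id, exc)

    record.metadata.update({
        "rfp_threshold": t_rfp, "gfp_threshold": t_gfp,
        "sigma_spatial": params.sigma_spatial,
        "sigma_range_frac": params.sigma_range_frac,
        "posterior_ap_fraction": params.posterior_ap_fraction,
        "zpa_pd_fraction": params.zpa_pd_fraction,
        "zpa_ap_fraction": params.zpa_ap_fraction,
        "intensity_over": params.intensity_over,
        "limb_pixels": int(masks.limb.sum()),
        "analysis_pixels": int(analysis.sum()),
    })
    return record


# ---------------------------------------------------------------------------
# Input loading
# ---------------------------------------------------------------------------

def load_annotation(path: str | Path) -> BoundaryAnnotation:
    """Load a sidecar JSON annotation for one embryo."""
    with Path(path).open() as fh:
        data = json.load(fh)
    orientation = Orientation(**data.get("orientation",
                                         {"anterior": "top", "distal": "right"}))
    point = data.get("limb_side_point")
    return BoundaryAnnotation(
        embryo_id=data["embryo_id"],
        group=data.get("group", ""),
        boundary_polyline=[tuple(v) for v in data["boundary_polyline"]],
        orientation=orientation,
        limb_side_point=tuple(point) if point is not None else None,
    )


def load_bundle(path: str | Path, embryo_id: str = "", group: str = "",
                saturation_level: float | None = None) -> ImageBundle:
    """Load an embryo bundle from a multi-page TIFF (light, RFP, GFP pages)
    or a directory of light.png / rfp.png / gfp.png."""
    path = Path(path)
    if path.is_dir():
        from imageio.v3 import imread
        pages = [to_grayscale(imread(path / f"{name}.png"))
                 for name in ("light", "rfp", "gfp")]
    else:
        import tifffile
        stack = tifffile.imread(path)
        if stack.ndim != 3 or stack.shape[0] != 3:
            raise ImagingError(
                f"expected a 3-page TIFF (light, RFP, GFP); got {stack.shape}")
        pages = [np.asarray(p, dtype=float) for p in stack]
    return ImageBundle(*pages, embryo_id=embryo_id or path.stem, group=group,
                       saturation_level=saturation_level)
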