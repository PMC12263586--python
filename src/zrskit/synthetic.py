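"""Synthetic embryo-limb reporter images and PBM tables with known truth.

The image simulator emulates the mosaic reporter assay: a limb bud (an
ellipse of tissue) next to a strip of body-wall tissue, patchy transfection
from electroporation (RFP), and an enhancer-activity focus in the
posterior-distal limb (GFP) whose brightness in each active pixel is
proportional to the local RFP dose, mirroring co-electroporation of
reporter and control plasmids. Every bundle carries a ground truth (masks,
manual-boundary polyline, expected measurable activity) so the downstream
quantification pipeline can be validated end to end.

The PBM simulator produces a complete 8-mer intensity landscape with a known
optimal 8-mer and geometric decay per mismatch, reverse-complement
symmetric, optionally with multiplicative lognormal noise.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .imaging import BoundaryAnnotation, ImageBundle, Orientation, _axis_keep
from .pbm import FULL_TABLE_SIZE, PBMTable

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_limb_bundle",
    "simulate_cohort",
    "simulate_pbm_table",
    "annotation_from_truth",
    "write_bundle",
    "write_truth",
    "write_pbm_table",
]


class ConfigurationError(ValueError):
    """Invalid simulation configuration; message names the offending field."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated embryo-limb bundle.

    Geometry is in pixels; the activity focus is positioned in
    limb-normalized coordinates (ap, pd) where ap runs 0 (anterior) -> 1
    (posterior) and pd runs 0 (proximal) -> 1 (distal) across the limb
    bounding box. ``activity_level`` is the expected GFP:RFP intensity ratio
    (above background) in active cells. Channels are stored as floats but
    clipped to the bit-depth range after noise, so saturation behaves like a
    real camera.
    """

    image_width: int = 160
    image_height: int = 128
    bit_depth: int = 8
    limb_center: tuple[float, float] = (64.0, 96.0)   # (row, col)
    limb_semiaxes: tuple[float, float] = (48.0, 52.0)  # (row, col)
    limb_rotation: float = 0.0                         # radians
    body_wall_fraction: float = 0.18
    transfection_fraction: float = 0.6
    transfection_patchiness: float = 6.0
    activity_level: float = 0.5
    activity_center: tuple[float, float] = (0.7, 0.7)  # (ap, pd) in [0,1]
    activity_radius: float = 0.35
    background_level: float = 4.0
    noise_sd: float = 2.0
    seed: int = 0

    # internal contrast constants (above background, before clipping)
    light_tissue_level: float = 120.0
    rfp_amplitude: float = 150.0

    def __post_init__(self) -> None:
        if self.bit_depth not in (8, 16):
            raise ConfigurationError("bit_depth must be 8 or 16")
        if not 0 <= self.transfection_fraction <= 1:
            raise ConfigurationError(
                f"transfection_fraction must be in [0, 1], got "
                f"{self.transfection_fraction}")
        if self.activity_level < 0:
            raise ConfigurationError("activity_level must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.transfection_patchiness <= 0:
            raise ConfigurationError("transfection_patchiness must be > 0")
        if not 0 <= self.body_wall_fraction < 0.5:
            raise ConfigurationError("body_wall_fraction must be in [0, 0.5)")
        if self.background_level < 0:
            raise ConfigurationError("background_level must be >= 0")
        r, c = self.limb_center
        ar, ac = self.limb_semiaxes
        if ar <= 0 or ac <= 0:
            raise ConfigurationError("limb_semiaxes must be positive")
        ext = max(ar, ac) if self.limb_rotation else 0.0
        rr, cc = (ar, ac) if not self.limb_rotation else (ext, ext)
        if (r - rr < 0 or r + rr > self.image_height
                or c - cc < 0 or c + cc > self.image_width):
            raise ConfigurationError("limb_center/limb_semiaxes: ellipse does "
                                     "not fit within the frame")
        wall_edge = self.body_wall_fraction * self.image_width
        if c - cc <= wall_edge:
            raise ConfigurationError("limb_center: ellipse overlaps the "
                                     "body-wall strip")

    @property
    def max_intensity(self) -> float:
        return float(2 ** self.bit_depth - 1)

    @classmethod
    def default(cls, width: int = 160, height: int = 128,
                **overrides) -> "SimulationConfig":
        """A config with geometry scaled proportionally to the frame size."""
        width = overrides.pop("image_width", width)
        height = overrides.pop("image_height", height)
        wall = overrides.get("body_wall_fraction", 0.18)
        col0 = wall * width
        # center the ellipse in the space right of the wall, small margins
        c = (col0 + width) / 2 + 0.02 * width
        r = height / 2
        semi_r = 0.375 * height
        semi_c = min(0.325 * width, (width - c) - 2, (c - col0) - 4)
        geometry = {
            "image_width": width, "image_height": height,
            "limb_center": (r, c), "limb_semiaxes": (semi_r, semi_c),
        }
        geometry.update(overrides)
        return cls(**geometry)


@dataclass
class GroundTruth:
    """Known truth for one simulated bundle.

    ``true_activity`` is the noise-free relative activity the assay measures
    under the standard posterior-mask convention: summed clean GFP over the
    active region divided by summed clean RFP over the transfected region,
    both restricted to the posterior half of the true limb. It therefore
    reflects both the per-cell activity level and the active fraction of the
    transfected signal. ``cell_activity_level`` echoes the per-cell GFP:RFP
    ratio from the config.
    """

    limb_mask: np.ndarray
    transfected_mask: np.ndarray
    active_mask: np.ndarray
    true_activity: float
    boundary_polyline: list[tuple[float, float]]
    cell_activity_level: float = 0.0

    def __post_init__(self) -> None:
        if np.any(self.active_mask & ~self.transfected_mask):
            raise ConfigurationError("active_mask must be within "
                                     "transfected_mask")
        if np.any(self.transfected_mask & ~self.limb_mask):
            raise ConfigurationError("transfected_mask must be within "
                                     "limb_mask")
        if len(self.boundary_polyline) < 2:
            raise ConfigurationError("boundary_polyline needs >= 2 vertices")


def _ellipse_mask(config: SimulationConfig) -> np.ndarray:
    h, w = config.image_height, config.image_width
    rows, cols = np.mgrid[0:h, 0:w]
    r0, c0 = config.limb_center
    ar, ac = config.limb_semiaxes
    theta = config.limb_rotation
    dr, dc = rows - r0, cols - c0
    u = dr * math.cos(theta) + dc * math.sin(theta)
    v = -dr * math.sin(theta) + dc * math.cos(theta)
    return (u / ar) ** 2 + (v / ac) ** 2 <= 1.0


def simulate_limb_bundle(config: SimulationConfig
                         ) -> tuple[ImageBundle, GroundTruth]:
    """Simulate one embryo limb bundle; deterministic given config.seed.

    Light: limb ellipse plus a body-wall strip, both brighter than
    background. RFP: transfected pixels only (patchy mosaic from a
    thresholded smoothed noise field, with a smoothly varying dose). GFP:
    within the activity focus, proportional to the local RFP signal with
    factor ``activity_level``. Additive Gaussian noise everywhere; channels
    clipped to the bit-depth range.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.image_height, config.image_width
    bg = config.background_level
    limb = _ellipse_mask(config)

    wall_cols = int(round(config.body_wall_fraction * w))
    body_wall = np.zeros((h, w), dtype=bool)
    body_wall[:, :wall_cols] = True

    # manual boundary: vertical polyline midway between wall and limb
    limb_cols = np.flatnonzero(limb.any(axis=0))
    boundary_col = (wall_cols + limb_cols[0]) / 2 if wall_cols else \
        max(limb_cols[0] / 2, 1)
    boundary = [(0.0, float(boundary_col)), (float(h - 1), float(boundary_col))]

    # mosaic transfection: smoothed white noise thresholded at quantile
    noise_field = gaussian_filter(rng.standard_normal((h, w)),
                                  config.transfection_patchiness)
    f = config.transfection_fraction
    if f <= 0:
        transfected = np.zeros((h, w), dtype=bool)
    elif f >= 1:
        transfected = limb.copy()
    else:
        q = np.quantile(noise_field[limb], 1 - f)
        transfected = (noise_field > q) & limb

    # per-pixel dose in [0.6, 1.0], shared by RFP and GFP (co-electroporation)
    dose = np.zeros((h, w))
    if transfected.any():
        vals = noise_field[transfected]
        span = vals.max() - vals.min()
        u = (noise_field - vals.min()) / span if span > 0 else \
            np.ones_like(noise_field)
        dose[transfected] = 0.6 + 0.4 * np.clip(u[transfected], 0, 1)

    # activity focus in limb-normalized (ap, pd) coordinates
    rows_idx = np.flatnonzero(limb.any(axis=1))
    cols_idx = np.flatnonzero(limb.any(axis=0))
    rows, cols = np.mgrid[0:h, 0:w]
    ap = (rows - rows_idx[0]) / max(rows_idx[-1] - rows_idx[0], 1)
    pd = (cols - cols_idx[0]) / max(cols_idx[-1] - cols_idx[0], 1)
    ca, cp = config.activity_center
    focus = (ap - ca) ** 2 + (pd - cp) ** 2 <= config.activity_radius ** 2
    active = focus & transfected
    if config.activity_level == 0:
        active = np.zeros((h, w), dtype=bool)

    light_clean = np.full((h, w), bg)
    light_clean[limb | body_wall] += config.light_tissue_level
    rfp_clean = np.full((h, w), bg)
    rfp_clean[transfected] += config.rfp_amplitude * dose[transfected]
    gfp_clean = np.full((h, w), bg)
    gfp_clean[active] += config.activity_level * (rfp_clean[active] - bg)

    def finish(clean: np.ndarray) -> np.ndarray:
        out = clean
        if config.noise_sd > 0:
            out = clean + rng.normal(0.0, config.noise_sd, clean.shape)
        return np.clip(out, 0.0, config.max_intensity)

    bundle = ImageBundle(finish(light_clean), finish(rfp_clean),
                         finish(gfp_clean),
                         saturation_level=config.max_intensity)

    # measurable truth: posterior half of the true limb, noise-free signals
    posterior_half = _axis_keep(limb, 0.5, Orientation().posterior)
    rfp_sig = float(rfp_clean[transfected & posterior_half].sum())
    gfp_sig = float(gfp_clean[active & posterior_half].sum())
    true_activity = gfp_sig / rfp_sig if rfp_sig > 0 else math.nan

    truth = GroundTruth(limb, transfected, active, true_activity, boundary,
                        cell_activity_level=config.activity_level)
    return bundle, truth


def annotation_from_truth(truth: GroundTruth, embryo_id: str = "",
                          group: str = "") -> BoundaryAnnotation:
    """Build the sidecar annotation the quantifier needs from ground truth."""
    rows = np.flatnonzero(truth.limb_mask.any(axis=1))
    cols = np.flatnonzero(truth.limb_mask.any(axis=0))
    center = (int((rows[0] + rows[-1]) // 2), int((cols[0] + cols[-1]) // 2))
    return BoundaryAnnotation(embryo_id=embryo_id, group=group,
                              boundary_polyline=list(truth.boundary_polyline),
                              limb_side_point=center)


def simulate_cohort(group_specs: list[tuple[str, SimulationConfig, int]],
                    seed: int) -> list[tuple[ImageBundle, GroundTruth, str]]:
    """Simulate labelled groups of embryos, reproducibly.

    Per-bundle seeds are the master seed plus a running bundle index, so the
    same master seed always yields bitwise-identical cohorts and individual
    bundles can be regenerated in isolation.
    """
    labels = [label for label, _, _ in group_specs]
    if len(set(labels)) != len(labels):
        raise ConfigurationError("duplicate group labels in cohort spec")
    out = []
    index = 0
    for label, config, n in group_specs:
        if n < 1:
            raise ConfigurationError(f"group {label!r}: n must be >= 1")
        for i in range(n):
            cfg = dataclasses.replace(config, seed=seed + index)
            bundle, truth = simulate_limb_bundle(cfg)
            bundle.embryo_id = f"{label}_{i:03d}"
            bundle.group = label
            out.append((bundle, truth, label))
            index += 1
    return out


# ---------------------------------------------------------------------------
# Synthetic PBM tables
# ---------------------------------------------------------------------------

_POWERS = 4 ** np.arange(7, -1, -1)
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _kmer_digits(n_kmers: int = FULL_TABLE_SIZE) -> np.ndarray:
    return (np.arange(n_kmers)[:, None] // _POWERS) % 4


def simulate_pbm_table(consensus: str, optimal_intensity: float = 40_000.0,
                       decay_per_mismatch: float = 0.5,
                       noise_cv: float = 0.0, seed: int = 0,
                       factor_name: str = "synthetic_tf") -> PBMTable:
    """Synthetic complete PBM table with geometric mismatch decay.

    The expected intensity of an 8-mer with m mismatches to the consensus
    (or to its reverse complement, whichever is fewer) is
    ``optimal_intensity * decay_per_mismatch ** m``. Multiplicative
    lognormal noise with coefficient of variation ``noise_cv`` is shared
    between an 8-mer and its reverse complement, so tables stay
    RC-symmetric. Covers all 65,536 8-mers.
    """
    consensus = consensus.upper()
    if len(consensus) != 8 or not set(consensus) <= set("ACGT"):
        raise ConfigurationError(
            f"consensus must be an 8-mer over ACGT, got {consensus!r}")
    if optimal_intensity <= 0:
        raise ConfigurationError("optimal_intensity must be > 0")
    if not 0 < decay_per_mismatch < 1:
        raise ConfigurationError("decay_per_mismatch must be in (0, 1)")
    if noise_cv < 0:
        raise ConfigurationError("noise_cv must be >= 0")

    digits = _kmer_digits()
    cons = np.array(["ACGT".index(b) for b in consensus])
    rc_cons = (3 - cons)[::-1]
    mism = np.minimum((digits != cons).sum(axis=1),
                      (digits != rc_cons).sum(axis=1))
    expected = optimal_intensity * decay_per_mismatch ** mism

    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = math.sqrt(math.log1p(noise_cv ** 2))
        raw = np.exp(rng.normal(-sigma ** 2 / 2, sigma, FULL_TABLE_SIZE))
        rc_idx = ((3 - digits)[:, ::-1] * _POWERS).sum(axis=1)
        canonical = np.minimum(np.arange(FULL_TABLE_SIZE), rc_idx)
        expected = expected * raw[canonical]

    kmers = _BASES[digits].tobytes().decode()
    intensities = {kmers[8 * i: 8 * i + 8]: float(expected[i])
                   for i in range(FULL_TABLE_SIZE)}
    return PBMTable(factor_name, intensities)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_bundle(bundle: ImageBundle, path: str | Path,
                 bit_depth: int = 8) -> Path:
    """Write a bundle as a 3-page TIFF (light, RFP, GFP page order)."""
    import tifffile
    path = Path(path)
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    stack = np.stack([np.round(a).astype(dtype)
                      for a in (bundle.light, bundle.rfp, bundle.gfp)])
    tifffile.imwrite(path, stack, photometric="minisblack")
    return path


def write_truth(truth: GroundTruth, prefix: str | Path) -> tuple[Path, Path]:
    """Write ground truth: compressed raster sidecar (.npz) + JSON."""
    prefix = Path(prefix)
    raster_path = prefix.with_suffix(".npz")
    json_path = prefix.with_suffix(".json")
    np.savez_compressed(raster_path, limb=truth.limb_mask,
                        transfected=truth.transfected_mask,
                        active=truth.active_mask)
    with json_path.open("w") as fh:
        json.dump({"true_activity": truth.true_activity,
                   "cell_activity_level": truth.cell_activity_level,
                   "boundary_polyline": [list(v)
                                         for v in truth.boundary_polyline]},
                  fh, indent=2)
    return raster_path, json_path


def write_pbm_table(table: PBMTable, path: str | Path) -> Path:
    """Write a PBM table as a 2-column TSV with a factor-naming header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"kmer\t{table.factor_name}\n")
        for kmer in sorted(table.intensities):
            fh.write(f"{kmer}\t{table.intensities[kmer]:.6g}\n")
    return path
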