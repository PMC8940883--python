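"""Synthetic OCT B-scan generator with class-conditional tissue signatures.

Renders single-scattering Beer-Lambert phantoms so that the three tissue
classes carry the morphological signatures the classifier must learn:

* **NOR** (normal brain) — laterally homogeneous, uniformly attenuating.
* **GBM** (glioblastoma) — laterally nonuniform attenuation (piecewise-constant
  regions with smoothed borders, i.e. "attenuation cliffs") plus irregular
  low-reflectivity elliptical inclusions standing in for microcysts, necrosis
  and hemorrhage.
* **PCNSL** (CNS lymphoma) — homogeneous texture but a low attenuation
  coefficient drawn from a range strictly below the normal range, with only a
  low-amplitude smooth lateral modulation.

The detected intensity at depth row z, lateral column x is modeled as

    I(z, x) = R(z, x) * exp(-2 * sum_{z' <= z} mu(z', x) * dz) * G + F

with reflectivity R, attenuation mu (mm^-1, round-trip factor 2), axial pitch
dz (mm), unit-mean gamma speckle G (shape k; k = inf disables speckle) and an
additive exponential noise floor of mean F. No confocal/sensitivity roll-off,
multiple scattering or polarization effects are modeled.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .core import (
    BScanFrame,
    GeometryError,
    InvalidParameterError,
    OCTVolume,
    TissueClass,
    VolumeMetadata,
    logger,
)

# Saturation level for float-valued frames, in linear intensity units where
# the tissue surface reflectivity is ~1. Chosen far above any speckle tail.
SATURATION_LEVEL = 8.0

# Full-scale linear intensity mapped to the top of the 16-bit range when
# volumes are digitized to disk.
DIGITIZER_FULL_SCALE = 8.0

# Class-conditional attenuation ranges (mm^-1). The PCNSL range sits strictly
# below the NOR range (its low, slowly-attenuating signature); GBM overlaps
# NOR but adds strong lateral nonuniformity and inclusions.
CLASS_MU_RANGES: dict[TissueClass, tuple[float, float]] = {
    TissueClass.NOR: (1.5, 2.5),
    TissueClass.PCNSL: (0.6, 1.2),
    TissueClass.GBM: (1.5, 3.5),
}

GBM_LATERAL_VARIATION = 0.4    # relative amplitude of piecewise lateral mu field
PCNSL_LATERAL_VARIATION = 0.1  # low-amplitude smooth modulation
INCLUSION_MU_FACTOR = 0.3      # attenuation inside inclusions relative to local mu
INCLUSION_REFLECTIVITY = 0.1   # reflectivity inside inclusions (holes are dark)


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one class-conditional tissue phantom.

    mu_base is the mean attenuation coefficient (mm^-1);
    mu_lateral_variation the relative amplitude of the lateral mu field;
    lateral_correlation_length (mm) the smoothing scale of region borders.
    """

    label: TissueClass
    mu_base: float
    mu_lateral_variation: float = 0.0
    lateral_correlation_length: float = 0.2
    n_inclusions: int = 0
    inclusion_radius_range: tuple[float, float] = (0.05, 0.25)
    surface_depth: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu_base <= 0:
            raise InvalidParameterError("mu_base must be > 0")
        if not (0.0 <= self.mu_lateral_variation <= 1.0):
            raise InvalidParameterError("mu_lateral_variation must be in [0, 1]")
        lo, hi = self.inclusion_radius_range
        if lo > hi or lo <= 0:
            raise InvalidParameterError("inclusion_radius_range must satisfy 0 < min <= max")
        if self.n_inclusions < 0:
            raise InvalidParameterError("n_inclusions must be >= 0")
        if self.label != TissueClass.GBM and self.n_inclusions > 0:
            raise InvalidParameterError(
                f"{self.label.value} phantoms are structureless; n_inclusions must be 0"
            )


@dataclass(frozen=True)
class AcquisitionSpec:
    """Scan geometry and noise model of the (simulated) OCT system.

    Defaults are desk-scale: 256 depth x 512 lateral pixels spanning the
    instrument's 2.5 mm x 5 mm B-scan footprint (the full system acquires
    1000 x 1000 A-scans over 5 mm x 5 mm).
    """

    n_depth_pixels: int = 256
    n_lateral_pixels: int = 512
    scan_width: float = 5.0      # mm
    scan_depth: float = 2.5      # mm
    center_wavelength: float = 1.31  # um
    fwhm_bandwidth: float = 100.0    # nm
    speckle_shape: float = 1.0       # gamma shape; inf disables speckle
    noise_floor: float = 1e-4        # mean additive noise, linear units
    saturation_probability: float = 0.0
    max_jitter: int = 3              # max |inter-frame shift| in px, both axes

    def __post_init__(self) -> None:
        if self.n_depth_pixels <= 0 or self.n_lateral_pixels <= 0:
            raise InvalidParameterError("pixel counts must be > 0")
        if self.scan_width <= 0 or self.scan_depth <= 0:
            raise InvalidParameterError("scan dimensions must be > 0")
        if not (0.0 <= self.saturation_probability <= 1.0):
            raise InvalidParameterError("saturation_probability must be in [0, 1]")
        if self.speckle_shape <= 0:
            raise InvalidParameterError("speckle_shape must be > 0 (use inf to disable)")

    @property
    def pixel_pitch_axial(self) -> float:
        return self.scan_depth / self.n_depth_pixels

    @property
    def pixel_pitch_lateral(self) -> float:
        return self.scan_width / self.n_lateral_pixels


@dataclass
class TissuePhantom:
    """Attenuation / reflectivity maps plus ground-truth inclusion mask."""

    mu_map: np.ndarray           # (depth, lateral), mm^-1
    reflectivity_map: np.ndarray  # (depth, lateral), linear units >= 0
    inclusion_mask: np.ndarray   # (depth, lateral), bool
    label: TissueClass
    pixel_pitch_axial: float
    pixel_pitch_lateral: float

    def __post_init__(self) -> None:
        shapes = {self.mu_map.shape, self.reflectivity_map.shape, self.inclusion_mask.shape}
        if len(shapes) != 1:
            raise GeometryError(f"phantom rasters disagree in shape: {shapes}")
        if np.any(self.mu_map < 0):
            raise InvalidParameterError("mu_map must be >= 0 everywhere")
        if self.label != TissueClass.GBM and self.inclusion_mask.any():
            raise InvalidParameterError("inclusion_mask may be non-empty only for GBM")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mu_map.shape


# ---------------------------------------------------------------------------
# Analytic helpers
# ---------------------------------------------------------------------------

def axial_resolution(center_wavelength: float, fwhm_bandwidth: float) -> float:
    """Theoretical axial resolution (um) of a Gaussian-spectrum source.

    Coherence length (2 ln 2 / pi) * lambda_c**2 / delta_lambda, with the
    center wavelength in um and the FWHM bandwidth in nm. For the simulated
    system (1.31 um, 100 nm) this evaluates to 7.57 um, i.e. 8 um rounded.
    """
    if center_wavelength <= 0 or fwhm_bandwidth <= 0:
        raise InvalidParameterError("wavelength and bandwidth must be > 0")
    return (2.0 * math.log(2.0) / math.pi) * center_wavelength**2 / (fwhm_bandwidth * 1e-3)


# ---------------------------------------------------------------------------
# Phantom construction
# ---------------------------------------------------------------------------

def _smooth_lateral_noise(rng: np.random.Generator, n: int, sigma_px: float) -> np.ndarray:
    """Unit-amplitude smooth lateral field in [-1, 1]."""
    f = ndimage.gaussian_filter1d(rng.standard_normal(n), max(sigma_px, 1.0), mode="wrap")
    peak = np.max(np.abs(f))
    return f / peak if peak > 0 else f


def _piecewise_lateral_field(rng: np.random.Generator, n: int, amplitude: float,
                             sigma_px: float) -> np.ndarray:
    """Piecewise-constant relative mu field (2-4 regions), smoothed at borders.

    Construction guarantees the realized lateral variation: every region is at
    least 4 smoothing sigmas wide (so border smoothing cannot erase it) and
    region levels alternate in sign with magnitude in [0.6, 1] x amplitude,
    so adjacent regions always differ by more than the requested amplitude
    even after normalizing by the realized mean —
    every phantom carries a genuine attenuation cliff.
    """
    sigma_px = max(sigma_px, 1.0)
    n_regions = int(rng.integers(2, 5))
    min_w = max(int(4 * sigma_px), n // (2 * n_regions), 2)
    for _ in range(200):
        cuts = np.sort(rng.choice(np.arange(min_w, n - min_w),
                                  size=n_regions - 1, replace=False))
        if n_regions == 2 or np.all(np.diff(cuts) >= min_w):
            break
    else:
        cuts = np.linspace(0, n, n_regions + 1)[1:-1].astype(int)
    sign = 1.0 if rng.random() < 0.5 else -1.0
    levels = np.empty(n_regions)
    for i in range(n_regions):
        levels[i] = sign * rng.uniform(0.6, 1.0) * amplitude
        sign = -sign
    field = np.empty(n)
    start = 0
    for i, end in enumerate(list(cuts) + [n]):
        field[start:end] = levels[i]
        start = end
    return ndimage.gaussian_filter1d(field, sigma_px, mode="nearest")


def build_phantom(spec: PhantomSpec, shape: tuple[int, int],
                  pixel_pitch_axial: float | None = None,
                  pixel_pitch_lateral: float | None = None) -> TissuePhantom:
    """Build a class-conditional phantom of the given (depth, lateral) shape.

    Deterministic given ``spec`` (including its seed). Pitches default to the
    standard acquisition geometry (2.5 mm depth, 5 mm width).
    """
    rows, cols = shape
    dz = pixel_pitch_axial if pixel_pitch_axial is not None else 2.5 / rows
    dx = pixel_pitch_lateral if pixel_pitch_lateral is not None else 5.0 / cols
    rng = np.random.default_rng(spec.seed)
    sigma_px = spec.lateral_correlation_length / dx

    if spec.label == TissueClass.NOR:
        lateral = np.zeros(cols)
    elif spec.label == TissueClass.GBM:
        lateral = _piecewise_lateral_field(rng, cols, spec.mu_lateral_variation, sigma_px)
        if spec.n_inclusions == 0:
            logger.info("GBM phantom requested with n_inclusions=0")
    else:  # PCNSL: low-amplitude smooth modulation
        lateral = spec.mu_lateral_variation * _smooth_lateral_noise(rng, cols, sigma_px)

    mu = np.clip(spec.mu_base * (1.0 + lateral), 0.05, None)
    mu_map = np.tile(mu, (rows, 1))
    reflectivity = np.ones((rows, cols))
    mask = np.zeros((rows, cols), dtype=bool)

    surface_row = int(round(spec.surface_depth / dz))
    if spec.label == TissueClass.GBM and spec.n_inclusions > 0:
        mask = _place_inclusions(rng, spec, (rows, cols), dz, dx, surface_row)
        mu_map = np.where(mask, mu_map * INCLUSION_MU_FACTOR, mu_map)
        reflectivity = np.where(mask, INCLUSION_REFLECTIVITY, reflectivity)

    # air above the tissue surface: nothing backscatters, nothing attenuates
    mu_map[:surface_row, :] = 0.0
    reflectivity[:surface_row, :] = 0.0
    mask[:surface_row, :] = False

    return TissuePhantom(mu_map, reflectivity, mask, spec.label, dz, dx)


def _place_inclusions(rng: np.random.Generator, spec: PhantomSpec, shape: tuple[int, int],
                      dz: float, dx: float, surface_row: int) -> np.ndarray:
    """Rejection-sample axis-aligned elliptical inclusions (non-overlapping)."""
    rows, cols = shape
    mask = np.zeros(shape, dtype=bool)
    zz = np.arange(rows)[:, None]
    xx = np.arange(cols)[None, :]
    placed: list[tuple[float, float, float, float]] = []
    lo, hi = spec.inclusion_radius_range
    for _ in range(spec.n_inclusions):
        for _attempt in range(200):
            rz = rng.uniform(lo, hi) / dz  # semi-axes in px
            rx = rng.uniform(lo, hi) / dx
            cz = rng.uniform(surface_row + rz + 2, rows * 0.75 - rz - 2)
            cx = rng.uniform(rx + 2, cols - rx - 2)
            # pad by 2 px so smoothed components stay disjoint
            ok = all(
                ((cz - pz) / (rz + prz + 2)) ** 2 + ((cx - px) / (rx + prx + 2)) ** 2 > 1.0
                for pz, px, prz, prx in placed
            )
            if ok:
                placed.append((cz, cx, rz, rx))
                mask |= ((zz - cz) / rz) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
                break
        else:
            logger.warning("could not place inclusion %d without overlap", len(placed) + 1)
    return mask


def default_phantom_spec(label: TissueClass, seed: int,
                         mu_base: float | None = None) -> PhantomSpec:
    """Class-conditional PhantomSpec from the default parameter ranges.

    ``mu_base`` overrides the seeded uniform draw — used by the dataset
    generator, which stratifies attenuation coefficients across the volumes
    of a class (see :func:`stratified_mu_bases`).
    """
    rng = np.random.default_rng(seed)
    lo, hi = CLASS_MU_RANGES[label]
    drawn = float(rng.uniform(lo, hi))
    mu = drawn if mu_base is None else float(mu_base)
    if label == TissueClass.NOR:
        return PhantomSpec(label, mu, 0.0, seed=seed)
    if label == TissueClass.PCNSL:
        return PhantomSpec(label, mu, PCNSL_LATERAL_VARIATION, seed=seed)
    n_inc = int(rng.integers(5, 12))
    return PhantomSpec(
        label, mu, GBM_LATERAL_VARIATION, n_inclusions=n_inc, seed=seed,
    )


def stratified_mu_bases(label: TissueClass, k: int,
                        rng: np.random.Generator) -> np.ndarray:
    """``k`` attenuation coefficients covering the class range by stratified
    (jittered Latin) sampling, in random order.

    A cohort of a few volumes drawn i.i.d. from overlapping class ranges can,
    by chance, end up with non-overlapping per-class attenuation values; a
    classifier trained on such a draw learns the decay rate as a spurious
    class cue instead of the intended morphological signatures. Stratifying
    the draws across each class's volumes is the usual experimental-design
    remedy at small cohort sizes.
    """
    lo, hi = CLASS_MU_RANGES[label]
    if k <= 0:
        return np.empty(0)
    positions = (np.arange(k) + rng.uniform(0.0, 1.0, size=k)) / k
    rng.shuffle(positions)
    return lo + (hi - lo) * positions


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def expected_intensity(phantom: TissuePhantom, acq: AcquisitionSpec) -> np.ndarray:
    """Noise-free Beer-Lambert intensity: R * exp(-2 * cumsum(mu) * dz)."""
    if phantom.shape != (acq.n_depth_pixels, acq.n_lateral_pixels):
        raise GeometryError(
            f"phantom shape {phantom.shape} does not match acquisition grid "
            f"({acq.n_depth_pixels}, {acq.n_lateral_pixels})"
        )
    if not math.isclose(phantom.pixel_pitch_axial, acq.pixel_pitch_axial, rel_tol=1e-6):
        raise GeometryError("phantom axial pitch inconsistent with acquisition spec")
    dz = acq.pixel_pitch_axial
    attenuation = np.exp(-2.0 * dz * np.cumsum(phantom.mu_map, axis=0))
    return phantom.reflectivity_map * attenuation


def render_bscan(phantom: TissuePhantom, acq: AcquisitionSpec, seed: int,
                 jitter: tuple[int, int] = (0, 0)) -> BScanFrame:
    """Render one speckled B-scan of the phantom.

    ``jitter`` applies a circular integer (depth, lateral) shift to the
    phantom-driven mean intensity before speckle, emulating inter-frame
    motion that translational registration must undo exactly.
    """
    mean = expected_intensity(phantom, acq)
    if jitter != (0, 0):
        mean = np.roll(mean, jitter, axis=(0, 1))
    rng = np.random.default_rng(seed)
    k = acq.speckle_shape
    img = mean if math.isinf(k) else mean * rng.gamma(k, 1.0 / k, size=mean.shape)
    if acq.noise_floor > 0:
        img = img + acq.noise_floor * rng.exponential(1.0, size=mean.shape)
    return BScanFrame(img, acq.scan_depth, acq.scan_width)


def inject_saturation(frame: BScanFrame, columns) -> BScanFrame:
    """Overwrite the listed lateral columns with the maximum representable
    intensity at every depth (a specular-reflection stripe artifact)."""
    columns = list(columns)
    w = frame.pixels.shape[1]
    for c in columns:
        if not (0 <= int(c) < w):
            raise IndexError(f"saturation column {c} outside width {w}")
    out = frame.pixels.copy()
    if not columns:
        return frame.with_pixels(out)
    if np.issubdtype(out.dtype, np.integer):
        level = np.iinfo(out.dtype).max
    else:
        level = max(float(out.max()), SATURATION_LEVEL)
    out[:, np.asarray(columns, dtype=int)] = level
    return frame.with_pixels(out)


def _saturation_columns(rng: np.random.Generator, width: int) -> np.ndarray:
    """Pick stripe columns covering ~4% of the width (1-3 contiguous stripes)."""
    total = max(2, round(0.04 * width))
    n_stripes = int(rng.integers(1, 4))
    widths = np.maximum(1, np.diff(np.linspace(0, total, n_stripes + 1).astype(int)))
    cols: list[int] = []
    for wdt in widths:
        start = int(rng.integers(0, max(1, width - int(wdt))))
        cols.extend(range(start, min(width, start + int(wdt))))
    return np.unique(cols)


def render_volume(phantom: TissuePhantom, acq: AcquisitionSpec, n_frames: int,
                  seed: int) -> OCTVolume:
    """Render a volume of B-scans with independent speckle, inter-frame
    integer jitter in [-max_jitter, max_jitter]^2, and saturation stripes
    injected per frame with probability ``saturation_probability``."""
    if n_frames < 1:
        raise InvalidParameterError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    frames = []
    for _ in range(n_frames):
        jit = tuple(int(j) for j in rng.integers(-acq.max_jitter, acq.max_jitter + 1, size=2))
        frame_seed = int(rng.integers(0, 2**31))
        frame = render_bscan(phantom, acq, frame_seed, jitter=jit)
        if acq.saturation_probability > 0 and rng.random() < acq.saturation_probability:
            frame = inject_saturation(frame, _saturation_columns(rng, acq.n_lateral_pixels))
        frames.append(frame.pixels)
    meta = VolumeMetadata(
        label=phantom.label,
        pixel_pitch_axial=acq.pixel_pitch_axial,
        pixel_pitch_lateral=acq.pixel_pitch_lateral,
        seed=seed,
    )
    return OCTVolume(np.stack(frames), meta)


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DatasetSpec:
    """Per-class volume counts and shared acquisition settings.

    The default layout mirrors the study's data separation at reduced scale:
    15/10/5 training volumes and 2/3/3 held-out test volumes for
    NOR/GBM/PCNSL, 20 frames per volume (11 despeckled frames per volume
    after the 10-frame sliding window).
    """

    train_volumes: dict = field(default_factory=lambda: {"NOR": 15, "GBM": 10, "PCNSL": 5})
    test_volumes: dict = field(default_factory=lambda: {"NOR": 2, "GBM": 3, "PCNSL": 3})
    frames_per_volume: int = 20
    acq: AcquisitionSpec = field(default_factory=AcquisitionSpec)

    def __post_init__(self) -> None:
        for d in (self.train_volumes, self.test_volumes):
            for k, v in d.items():
                TissueClass.from_string(k)
                if int(v) < 0:
                    raise InvalidParameterError("volume counts must be >= 0")
        if self.frames_per_volume < 1:
            raise InvalidParameterError("frames_per_volume must be >= 1")


def _digitize(frames: np.ndarray) -> np.ndarray:
    """Quantize linear float intensity to the 16-bit digitizer range."""
    scaled = np.clip(frames / DIGITIZER_FULL_SCALE, 0.0, 1.0) * 65535.0
    return np.round(scaled).astype(np.uint16)


def generate_dataset(spec: DatasetSpec, out_dir, seed: int) -> pd.DataFrame:
    """Write a labeled synthetic dataset and return its manifest.

    Per volume: ``<volume_id>.tif`` (multi-page uint16 stack),
    ``<volume_id>.json`` sidecar metadata, and ``<volume_id>.mask.tif``
    (ground-truth inclusion mask, uint8) for interpretability experiments.
    The manifest CSV has one row per volume with a ``split_hint`` column
    separating the training pool from the held-out test volumes.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(seed)
    rows = []
    counter = 0
    for split, counts in (("train", spec.train_volumes), ("test", spec.test_volumes)):
        for label_str in ("NOR", "GBM", "PCNSL"):
            label = TissueClass.from_string(label_str)
            n_vols = int(counts.get(label_str, 0))
            mu_bases = stratified_mu_bases(label, n_vols, master)
            for i in range(n_vols):
                vol_seed = int(master.integers(0, 2**31))
                vid = f"V{counter:03d}_{label_str}"
                pspec = default_phantom_spec(label, vol_seed, mu_base=float(mu_bases[i]))
                phantom = build_phantom(
                    pspec, (spec.acq.n_depth_pixels, spec.acq.n_lateral_pixels),
                    spec.acq.pixel_pitch_axial, spec.acq.pixel_pitch_lateral,
                )
                volume = render_volume(phantom, spec.acq, spec.frames_per_volume, vol_seed)
                volume.frames = _digitize(volume.frames)
                meta = replace(
                    volume.metadata,
                    volume_id=vid,
                    patient_id=f"PT_{label_str}_{i // 4:02d}",
                    specimen_id=f"SP_{label_str}_{i // 2:02d}",
                )
                volume.metadata = meta
                path = out_dir / f"{vid}.tif"
                from .frames import write_volume  # deferred: avoids import cycle at module load
                write_volume(volume, path)
                tifffile.imwrite(out_dir / f"{vid}.mask.tif",
                                 phantom.inclusion_mask.astype(np.uint8))
                rows.append({
                    "volume_id": vid,
                    "patient_id": meta.patient_id,
                    "specimen_id": meta.specimen_id,
                    "label": label_str,
                    "path": str(path),
                    "split_hint": split,
                    "seed": vol_seed,
                })
                counter += 1
    manifest = pd.DataFrame(rows, columns=[
        "volume_id", "patient_id", "specimen_id", "label", "path", "split_hint", "seed",
    ])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    logger.info("wrote %d volumes to %s", len(manifest), out_dir)
    return manifest


def load_inclusion_mask(manifest_row) -> np.ndarray:
    """Read the ground-truth inclusion mask written next to a volume."""
    path = Path(manifest_row["path"])
    return tifffile.imread(path.with_name(path.stem + ".mask.tif")).astype(bool)
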