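"""Volume IO and B-scan preprocessing.

Implements the despeckling pipeline used before classification: translational
registration of adjacent B-scans, sliding-window averaging of 10 registered
frames, exclusion of frames carrying saturation-stripe artifacts,
standardization to 128 x 256 pixels in [0, 1] (2.5 mm x 5.0 mm), and bounded
affine augmentation (shear/zoom capped at a ratio of 0.1 so morphology is
preserved).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from skimage import transform as sktransform

from .core import (
    BScanFrame,
    FormatError,
    FrameRecord,
    GeometryError,
    InsufficientFramesError,
    InvalidParameterError,
    MetadataError,
    OCTVolume,
    TissueClass,
    VolumeMetadata,
    logger,
)

STANDARD_SHAPE = (128, 256)
STANDARD_DEPTH_MM = 2.5
DEFAULT_WINDOW = 10
DEFAULT_SATURATION_THRESHOLD = 0.02
# column-mean is flagged as saturated when above median + MAD_FACTOR * MAD
MAD_FACTOR = 6.0


# ---------------------------------------------------------------------------
# IO: multi-page TIFF stack + JSON sidecar
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.stem + ".json")


def write_volume(volume: OCTVolume, path) -> Path:
    """Write a volume as a multi-page TIFF plus a ``<volume_id>.json`` sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, volume.frames, photometric="minisblack")
    with open(_sidecar_path(path), "w") as fh:
        json.dump(volume.metadata.to_dict(), fh, indent=1, sort_keys=True)
    return path


def read_volume(path) -> OCTVolume:
    """Read a volume; pixel values are preserved without rescaling."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise MetadataError(f"missing sidecar metadata file: {sidecar}")
    with open(sidecar) as fh:
        meta = VolumeMetadata.from_dict(json.load(fh))
    meta.source_path = str(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None, ...]
    if frames.ndim != 3:
        raise FormatError(f"{path}: pages do not form a uniform 3D stack")
    return OCTVolume(frames, meta)


# ---------------------------------------------------------------------------
# Registration
# ---------------------------------------------------------------------------

def register_translation(reference: BScanFrame, moving: BScanFrame) -> tuple[int, int]:
    """Integer (dz, dx) maximizing circular cross-correlation.

    If ``moving`` equals ``reference`` circularly shifted by (dz, dx), the
    returned shift is exactly (dz, dx); applying (-dz, -dx) to ``moving``
    aligns it to ``reference``.
    """
    a = np.asarray(reference.pixels, dtype=np.float64)
    b = np.asarray(moving.pixels, dtype=np.float64)
    if a.shape != b.shape:
        raise GeometryError(f"frame shapes differ: {a.shape} vs {b.shape}")
    cc = np.fft.ifft2(np.fft.fft2(b) * np.conj(np.fft.fft2(a))).real
    dz, dx = np.unravel_index(np.argmax(cc), cc.shape)
    if dz > a.shape[0] // 2:
        dz -= a.shape[0]
    if dx > a.shape[1] // 2:
        dx -= a.shape[1]
    return int(dz), int(dx)


def _align_to(reference: np.ndarray, moving: np.ndarray, ref_frame: BScanFrame,
              mov_frame: BScanFrame) -> np.ndarray:
    dz, dx = register_translation(ref_frame, mov_frame)
    return np.roll(moving, (-dz, -dx), axis=(0, 1))


# ---------------------------------------------------------------------------
# Despeckle: registered sliding-window averaging
# ---------------------------------------------------------------------------

def despeckle_stack(volume: OCTVolume, window: int = DEFAULT_WINDOW, stride: int = 1,
                    register: bool = True) -> list[BScanFrame]:
    """Average ``window`` consecutive B-scans (each registered to the window's
    first frame) with the given stride; returns floor((N-w)/stride)+1 frames."""
    if window < 1 or stride < 1:
        raise InvalidParameterError("window and stride must be >= 1")
    n = volume.n_frames
    if n < window:
        raise InsufficientFramesError(
            f"volume has {n} frames; despeckle window of {window} requires at least {window}"
        )
    depth_extent = volume.depth_extent
    lateral_extent = volume.lateral_extent
    frames = volume.frames.astype(np.float64)
    out = []
    for start in range(0, n - window + 1, stride):
        ref = frames[start]
        ref_frame = BScanFrame(ref, depth_extent, lateral_extent)
        acc = ref.copy()
        for k in range(1, window):
            mov = frames[start + k]
            if register:
                mov_frame = BScanFrame(mov, depth_extent, lateral_extent)
                mov = _align_to(ref, mov, ref_frame, mov_frame)
            acc += mov
        out.append(BScanFrame(acc / window, depth_extent, lateral_extent))
    return out


# ---------------------------------------------------------------------------
# Saturation-stripe exclusion
# ---------------------------------------------------------------------------

def saturation_score(frame: BScanFrame) -> float:
    """Fraction of lateral columns whose column-mean intensity exceeds the
    robust per-frame threshold median + 6 * MAD of the column means."""
    colmeans = np.asarray(frame.pixels, dtype=np.float64).mean(axis=0)
    med = np.median(colmeans)
    mad = np.median(np.abs(colmeans - med))
    return float(np.mean(colmeans > med + MAD_FACTOR * mad))


def filter_frames(frames: list[BScanFrame],
                  threshold: float = DEFAULT_SATURATION_THRESHOLD) -> list[BScanFrame]:
    """Keep frames with saturation_score < threshold; exclusions are logged."""
    kept = []
    for i, f in enumerate(frames):
        s = saturation_score(f)
        if s < threshold:
            kept.append(f)
        else:
            logger.info("excluding frame %d: saturation score %.4f >= %.4f", i, s, threshold)
    if frames and not kept:
        logger.warning("all %d frames excluded by saturation filter", len(frames))
    return kept


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

def standardize(frame: BScanFrame) -> BScanFrame:
    """Resample to 128 x 256 covering 2.5 mm x 5.0 mm, min-max normalized.

    When the input depth extent differs from 2.5 mm the frame is first cropped
    (or zero-padded) at the bottom to 2.5 mm at its native pitch. A constant
    frame standardizes to all zeros with a warning.
    """
    px = np.asarray(frame.pixels, dtype=np.float64)
    if px.size == 0:
        raise InvalidParameterError("cannot standardize an empty frame")
    pitch = frame.pixel_pitch_axial
    if not math.isclose(frame.depth_extent, STANDARD_DEPTH_MM, rel_tol=1e-6):
        target_rows = max(1, int(round(STANDARD_DEPTH_MM / pitch)))
        if target_rows <= px.shape[0]:
            px = px[:target_rows]
        else:
            pad = np.zeros((target_rows - px.shape[0], px.shape[1]))
            px = np.vstack([px, pad])
    resized = sktransform.resize(
        px, STANDARD_SHAPE, order=1, mode="edge",
        anti_aliasing=(px.shape[0] > STANDARD_SHAPE[0] or px.shape[1] > STANDARD_SHAPE[1]),
        preserve_range=True,
    )
    lo, hi = float(resized.min()), float(resized.max())
    if hi - lo <= 0:
        logger.warning("degenerate constant frame: standardized to all zeros")
        out = np.zeros(STANDARD_SHAPE)
    else:
        out = (resized - lo) / (hi - lo)
    return BScanFrame(out, STANDARD_DEPTH_MM, frame.lateral_extent)


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentParams:
    """Bounds of the random affine augmentation.

    Shear and zoom are hard-capped at a ratio of 0.1 so the morphological
    features the classifier relies on are not altered; rotation (deg) and
    translation (fraction of extent) default to conservative values.
    """

    rotation_deg: float = 10.0
    translation_frac: float = 0.05
    shear: float = 0.1
    zoom: float = 0.1

    def __post_init__(self) -> None:
        if abs(self.shear) > 0.1 + 1e-12:
            raise InvalidParameterError("shear ratio exceeds the hard cap of 0.1")
        if abs(self.zoom) > 0.1 + 1e-12:
            raise InvalidParameterError("zoom ratio exceeds the hard cap of 0.1")
        if self.rotation_deg < 0 or self.translation_frac < 0:
            raise InvalidParameterError("rotation and translation bounds must be >= 0")


def augment(frame: BScanFrame, seed: int, params: AugmentParams = AugmentParams()) -> BScanFrame:
    """Random combination of rotation, translation, shear and zoom.

    Deterministic given ``seed``; with all bounds zero the frame is returned
    unchanged. Output shape and [0, 1] value range are preserved.
    """
    if (params.rotation_deg == 0 and params.translation_frac == 0
            and params.shear == 0 and params.zoom == 0):
        return frame.with_pixels(frame.pixels.copy())
    rng = np.random.default_rng(seed)
    rot = math.radians(rng.uniform(-params.rotation_deg, params.rotation_deg))
    shear = math.atan(rng.uniform(-params.shear, params.shear))
    zoom = 1.0 + rng.uniform(-params.zoom, params.zoom)
    h, w = frame.pixels.shape
    ty = rng.uniform(-params.translation_frac, params.translation_frac) * h
    tx = rng.uniform(-params.translation_frac, params.translation_frac) * w
    center = np.array([w / 2.0, h / 2.0])
    tf = (sktransform.AffineTransform(translation=-center)
          + sktransform.AffineTransform(scale=zoom, rotation=rot, shear=shear)
          + sktransform.AffineTransform(translation=center + np.array([tx, ty])))
    warped = sktransform.warp(frame.pixels, tf.inverse, order=1, mode="constant",
                              cval=0.0, preserve_range=True)
    return frame.with_pixels(np.clip(warped, 0.0, None))


# ---------------------------------------------------------------------------
# Volume -> FrameRecords, frame-dataset IO
# ---------------------------------------------------------------------------

# Displayed dynamic range of the log-compressed B-scan, in dB below the frame
# peak. 40 dB is a conventional OCT display window.
LOG_DYNAMIC_RANGE_DB = 40.0

# Border cropped from every side of a despeckled frame before
# standardization: pixels within the largest expected inter-frame shift are
# not valid after translational registration (wrap seams / unobserved edges)
# and would otherwise imprint a spurious vertical discontinuity that mimics a
# tissue attenuation cliff.
REGISTRATION_MARGIN_PX = 3


def crop_registration_margin(frame: BScanFrame,
                             margin: int = REGISTRATION_MARGIN_PX) -> BScanFrame:
    """Remove the registration-invalid border, rescaling the physical extents."""
    if margin <= 0:
        return frame
    rows, cols = frame.pixels.shape
    if rows <= 2 * margin or cols <= 2 * margin:
        raise InvalidParameterError(
            f"frame {rows}x{cols} too small for a {margin}px registration margin")
    px = frame.pixels[margin:rows - margin, margin:cols - margin]
    return BScanFrame(px, frame.depth_extent * px.shape[0] / rows,
                      frame.lateral_extent * px.shape[1] / cols)


def log_compress(frame: BScanFrame, dynamic_range_db: float = LOG_DYNAMIC_RANGE_DB
                 ) -> BScanFrame:
    """Convert linear backscatter intensity to the conventional log (dB) scale,
    floored ``dynamic_range_db`` below the frame peak.

    OCT intensity decays exponentially with depth, so on a linear scale almost
    all image contrast sits in the first few hundred micrometers; the log scale
    turns the class-discriminating attenuation rate into a linear brightness
    gradient the classifier can see everywhere in the frame.
    """
    px = np.asarray(frame.pixels, dtype=np.float64)
    peak = px.max()
    if peak <= 0:
        return frame.with_pixels(px)
    floor = peak * 10.0 ** (-dynamic_range_db / 10.0)
    db = 10.0 * np.log10(np.maximum(px, floor) / floor)
    return frame.with_pixels(db)


def preprocess_volume(volume: OCTVolume, window: int = DEFAULT_WINDOW, stride: int = 1,
                      sat_threshold: float = DEFAULT_SATURATION_THRESHOLD,
                      register: bool = True, log_scale: bool = True,
                      registration_margin: int = REGISTRATION_MARGIN_PX
                      ) -> list[FrameRecord]:
    """Despeckle, crop the registration margin, exclude saturated frames,
    log-compress, standardize.

    Averaging runs on linear intensity (the physically meaningful domain for
    speckle reduction); log compression is applied afterwards, before the
    resize/normalize step, and can be disabled with ``log_scale=False``.
    """
    if volume.metadata.label is None:
        raise MetadataError(f"volume {volume.metadata.volume_id!r} has no class label")
    despeckled = despeckle_stack(volume, window=window, stride=stride, register=register)
    records = []
    for i, f in enumerate(despeckled):
        f = crop_registration_margin(f, registration_margin)
        if saturation_score(f) >= sat_threshold:
            logger.info("volume %s: excluding despeckled frame %d (saturation)",
                        volume.metadata.volume_id, i)
            continue
        records.append(FrameRecord(
            frame=standardize(log_compress(f) if log_scale else f),
            label=volume.metadata.label,
            volume_id=volume.metadata.volume_id,
            window_start_index=i * stride,
        ))
    return records


def preprocess_manifest(manifest: pd.DataFrame, window: int = DEFAULT_WINDOW,
                        stride: int = 1,
                        sat_threshold: float = DEFAULT_SATURATION_THRESHOLD,
                        register: bool = True, log_scale: bool = True) -> list[FrameRecord]:
    """Preprocess every volume listed in a manifest table."""
    records = []
    for _, row in manifest.iterrows():
        volume = read_volume(row["path"])
        records.extend(preprocess_volume(volume, window=window, stride=stride,
                                         sat_threshold=sat_threshold, register=register,
                                         log_scale=log_scale))
    return records


def write_frame_dataset(records: list[FrameRecord], out_dir) -> pd.DataFrame:
    """Write standardized frames (float32 TIFF) plus a frame manifest CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, r in enumerate(records):
        fid = f"F{i:05d}_{r.volume_id}"
        tifffile.imwrite(out_dir / f"{fid}.tif", r.frame.pixels.astype(np.float32))
        rows.append({"frame_id": fid, "volume_id": r.volume_id,
                     "label": r.label.value, "window_start_index": r.window_start_index})
    df = pd.DataFrame(rows, columns=["frame_id", "volume_id", "label", "window_start_index"])
    df.to_csv(out_dir / "frames.csv", index=False)
    return df


def read_frame_dataset(in_dir) -> list[FrameRecord]:
    in_dir = Path(in_dir)
    df = pd.read_csv(in_dir / "frames.csv")
    records = []
    for _, row in df.iterrows():
        px = tifffile.imread(in_dir / f"{row['frame_id']}.tif").astype(np.float64)
        records.append(FrameRecord(
            frame=BScanFrame(px, STANDARD_DEPTH_MM, 5.0),
            label=TissueClass.from_string(row["label"]),
            volume_id=str(row["volume_id"]),
            window_start_index=int(row["window_start_index"]),
        ))
    return records
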