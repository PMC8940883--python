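"""Shared data types, exceptions and seed plumbing for the OCT pipeline.

Axis convention used everywhere: a B-scan raster is indexed ``[depth_row,
lateral_col]`` with row 0 the shallowest depth; indices are 0-based. A volume
stacks B-scans along axis 0, so ``volume.frames[k]`` is the k-th B-scan.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

logger = logging.getLogger("octbrain")

CLASS_ORDER = ("NOR", "GBM", "PCNSL")


class TissueClass(str, Enum):
    """Three-way tissue label: normal brain, glioblastoma, CNS lymphoma."""

    NOR = "NOR"
    GBM = "GBM"
    PCNSL = "PCNSL"

    @classmethod
    def from_string(cls, s: str) -> "TissueClass":
        try:
            return cls(s)
        except ValueError:
            raise LabelError(f"unknown tissue class {s!r}; expected one of {CLASS_ORDER}")

    @property
    def index(self) -> int:
        return CLASS_ORDER.index(self.value)


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class OctBrainError(Exception):
    """Base class for package errors."""


class InvalidParameterError(OctBrainError, ValueError):
    pass


class GeometryError(OctBrainError, ValueError):
    pass


class MetadataError(OctBrainError, IOError):
    pass


class FormatError(OctBrainError, IOError):
    pass


class InsufficientFramesError(OctBrainError, ValueError):
    pass


class LabelError(OctBrainError, ValueError):
    pass


class SplitError(OctBrainError, ValueError):
    pass


class LeakageError(OctBrainError, RuntimeError):
    """Raised when a volume id appears on both sides of a train/eval split."""


class DegenerateClassError(OctBrainError, ValueError):
    pass


class UndefinedMetricError(OctBrainError, ValueError):
    pass


class ConfigError(OctBrainError, ValueError):
    pass


# ---------------------------------------------------------------------------
# Rasters
# ---------------------------------------------------------------------------

@dataclass
class BScanFrame:
    """A single cross-sectional OCT intensity image.

    ``pixels`` holds linear (not log) backscatter intensity, finite and >= 0.
    ``depth_extent`` / ``lateral_extent`` are the physical spans in mm.
    """

    pixels: np.ndarray
    depth_extent: float
    lateral_extent: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise GeometryError(f"B-scan must be 2D, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels.astype(np.float64))):
            raise InvalidParameterError("B-scan contains non-finite intensities")
        if np.any(self.pixels < 0):
            raise InvalidParameterError("B-scan contains negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def pixel_pitch_axial(self) -> float:
        return self.depth_extent / self.pixels.shape[0]

    @property
    def pixel_pitch_lateral(self) -> float:
        return self.lateral_extent / self.pixels.shape[1]

    def with_pixels(self, pixels: np.ndarray) -> "BScanFrame":
        return BScanFrame(pixels, self.depth_extent, self.lateral_extent)


@dataclass
class VolumeMetadata:
    volume_id: str = ""
    patient_id: str = ""
    specimen_id: str = ""
    label: TissueClass | None = None
    pixel_pitch_axial: float = 0.0   # mm per depth pixel
    pixel_pitch_lateral: float = 0.0  # mm per lateral pixel
    seed: int | None = None
    source_path: str = ""

    def to_dict(self) -> dict:
        d = {
            "volume_id": self.volume_id,
            "patient_id": self.patient_id,
            "specimen_id": self.specimen_id,
            "label": self.label.value if self.label is not None else None,
            "pixel_pitch_axial": self.pixel_pitch_axial,
            "pixel_pitch_lateral": self.pixel_pitch_lateral,
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "VolumeMetadata":
        label = d.get("label")
        return cls(
            volume_id=d.get("volume_id", ""),
            patient_id=d.get("patient_id", ""),
            specimen_id=d.get("specimen_id", ""),
            label=TissueClass.from_string(label) if label else None,
            pixel_pitch_axial=float(d.get("pixel_pitch_axial", 0.0)),
            pixel_pitch_lateral=float(d.get("pixel_pitch_lateral", 0.0)),
            seed=d.get("seed"),
            source_path=d.get("source_path", ""),
        )


@dataclass
class OCTVolume:
    """An ordered stack of B-scans plus provenance metadata."""

    frames: np.ndarray  # (n_frames, depth, lateral)
    metadata: VolumeMetadata = field(default_factory=VolumeMetadata)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise GeometryError(
                f"volume must be a non-empty stack of 2D frames, got {self.frames.shape}"
            )
        if np.any(self.frames < 0):
            raise InvalidParameterError("volume contains negative intensities")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def depth_extent(self) -> float:
        return self.metadata.pixel_pitch_axial * self.frames.shape[1]

    @property
    def lateral_extent(self) -> float:
        return self.metadata.pixel_pitch_lateral * self.frames.shape[2]

    def frame(self, k: int) -> BScanFrame:
        return BScanFrame(self.frames[k], self.depth_extent, self.lateral_extent)


@dataclass
class FrameRecord:
    """A standardized frame ready for the classifier, with provenance.

    ``frame`` is 128 x 256 with values in [0, 1]; ``volume_id`` is retained so
    splits can guarantee that no volume straddles train and evaluation sets.
    """

    frame: BScanFrame
    label: TissueClass
    volume_id: str
    window_start_index: int = 0


# ---------------------------------------------------------------------------
# Seed fan-out
# ---------------------------------------------------------------------------

def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed < 2**31 deterministically from a master seed."""
    h = hashlib.sha256(f"{int(master_seed)}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def records_as_arrays(records) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Stack FrameRecords into (n, H, W, 1) float32 input + integer labels."""
    x = np.stack([r.frame.pixels for r in records]).astype(np.float32)[..., None]
    y = np.array([r.label.index for r in records], dtype=np.int64)
    vids = [r.volume_id for r in records]
    return x, y, vids


__all__ = [
    "TissueClass", "CLASS_ORDER", "BScanFrame", "OCTVolume", "VolumeMetadata",
    "FrameRecord", "stage_seed", "records_as_arrays", "replace",
    "OctBrainError", "InvalidParameterError", "GeometryError", "MetadataError",
    "FormatError", "InsufficientFramesError", "LabelError", "SplitError",
    "LeakageError", "DegenerateClassError", "UndefinedMetricError", "ConfigError",
    "logger",
]
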