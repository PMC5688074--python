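"""Reading and writing 3D/4D medical volumes and binary masks.

Conventions used throughout the package:

* voxel indexing is 0-based and arrays are ordered ``(x, y, z)`` spatially,
  with the time axis last for dynamic volumes: ``data[x, y, z, t]``;
* ``spacing`` is ``(sx, sy, sz)`` in millimetres, matching the header
  convention of MetaImage and NIfTI;
* per-time-point tube exposures (mAs) are not representable in standard
  image headers, so they travel in a JSON/YAML sidecar file
  (``<image>.protocol.json`` / ``.yaml``) or are passed explicitly.

Supported on-disk formats (via SimpleITK): MetaImage (``.mha``/``.mhd``) and
NIfTI-1 (``.nii``/``.nii.gz``), either as a true 4D image or as an ordered
series of 3D volumes with identical grids.  Masks are stored as unsigned
8-bit labels {0, 1}.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import SimpleITK as sitk
import yaml

__all__ = [
    "Volume3D",
    "Volume4D",
    "BinaryMask3D",
    "AcquisitionProtocol",
    "SubvolumeBox",
    "default_protocol",
    "load_volume4d",
    "save_volume4d",
    "load_volume3d",
    "save_volume3d",
    "load_mask",
    "save_mask",
]

Spacing = tuple[float, float, float]


def _check_spacing(spacing: Sequence[float]) -> Spacing:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be 3 positive values, got {spacing}")
    return spacing


@dataclass
class Volume3D:
    """A static scalar volume (e.g. a WTA/WTV map or one time point)."""

    data: np.ndarray
    spacing: Spacing

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume3D requires 3D data, got shape {self.data.shape}")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class BinaryMask3D:
    """A boolean mask sharing the grid of the volume it annotates."""

    data: np.ndarray
    spacing: Spacing

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"BinaryMask3D requires 3D data, got shape {self.data.shape}")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())


@dataclass
class Volume4D:
    """A registered dynamic acquisition I(x, y, z, i).

    ``exposures`` holds one positive mAs value per time point; they define
    the temporal weights of the weighted temporal average/variance.
    """

    data: np.ndarray
    spacing: Spacing
    exposures: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"Volume4D requires 4D data, got shape {self.data.shape}")
        if self.data.shape[3] < 2:
            raise ValueError("Volume4D requires at least 2 time points")
        self.spacing = _check_spacing(self.spacing)
        self.exposures = np.asarray(self.exposures, dtype=float)
        if self.exposures.shape != (self.data.shape[3],):
            raise ValueError(
                f"need one exposure per time point: {self.exposures.shape} "
                f"vs T={self.data.shape[3]}"
            )
        if np.any(self.exposures <= 0):
            raise ValueError("all exposures must be positive")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]


@dataclass
class AcquisitionProtocol:
    """Per-time-point exposures (mAs) and optional acquisition times (s)."""

    exposures: np.ndarray
    times_s: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.exposures = np.asarray(self.exposures, dtype=float)
        if self.exposures.size == 0:
            raise ValueError("protocol needs at least one exposure")
        if np.any(self.exposures <= 0):
            raise ValueError("all exposures must be positive")
        if self.times_s is not None:
            self.times_s = np.asarray(self.times_s, dtype=float)
            if self.times_s.shape != self.exposures.shape:
                raise ValueError("times_s must match exposures in length")

    def __len__(self) -> int:
        return int(self.exposures.size)


def default_protocol() -> AcquisitionProtocol:
    """The whole-brain dynamic protocol used as package default.

    19 volume acquisitions: one high-dose 200 mAs scan 5 s after contrast
    injection, 13 scans every 2 s at 100 mAs, then 5 scans every 5 s at
    75 mAs.
    """
    exposures = np.array([200.0] + [100.0] * 13 + [75.0] * 5)
    times = np.concatenate(
        [
            [5.0],
            5.0 + 2.0 * np.arange(1, 14),  # 7 .. 31 s
            31.0 + 5.0 * np.arange(1, 6),  # 36 .. 56 s
        ]
    )
    return AcquisitionProtocol(exposures=exposures, times_s=times)


@dataclass(frozen=True)
class SubvolumeBox:
    """An axis-aligned box in voxel indices: inclusive lower, exclusive upper."""

    lower: tuple[int, int, int]
    upper: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.lower) != 3 or len(self.upper) != 3:
            raise ValueError("SubvolumeBox corners must be 3D")
        if any(u <= l for l, u in zip(self.lower, self.upper)):
            raise ValueError(f"empty box: {self.lower}..{self.upper}")
        if any(l < 0 for l in self.lower):
            raise ValueError("box lower corner must be nonnegative")

    def check_within(self, shape: Sequence[int]) -> None:
        if any(u > s for u, s in zip(self.upper, shape)):
            raise ValueError(f"box {self.lower}..{self.upper} exceeds grid {tuple(shape)}")

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, u) for l, u in zip(self.lower, self.upper))

    def mask(self, shape: Sequence[int]) -> np.ndarray:
        self.check_within(shape)
        m = np.zeros(tuple(shape), dtype=bool)
        m[self.slices] = True
        return m

    def to_dict(self) -> dict:
        return {"lower": list(self.lower), "upper": list(self.upper)}

    @classmethod
    def from_dict(cls, d: dict) -> "SubvolumeBox":
        return cls(lower=tuple(int(v) for v in d["lower"]), upper=tuple(int(v) for v in d["upper"]))


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def _array_from_image_3d(img: sitk.Image) -> tuple[np.ndarray, Spacing]:
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    return np.ascontiguousarray(arr.transpose(2, 1, 0)), tuple(img.GetSpacing())[:3]


def _image_from_array_3d(data: np.ndarray, spacing: Spacing) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(data.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in spacing))
    return img


def _sidecar_exposures(path: Path) -> np.ndarray | None:
    """Look for ``<image>.protocol.json|yaml`` next to the image file."""
    stem = path.name
    for suffix in (".gz", ".nii", ".mha", ".mhd"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
    for ext in (".protocol.json", ".protocol.yaml", ".protocol.yml"):
        sidecar = path.with_name(stem + ext)
        if sidecar.exists():
            text = sidecar.read_text()
            payload = json.loads(text) if ext.endswith("json") else yaml.safe_load(text)
            exposures = np.asarray(payload["exposures"], dtype=float)
            return exposures
    return None


def load_volume4d(
    path_or_paths: str | Path | Iterable[str | Path],
    exposures: Sequence[float] | None = None,
) -> Volume4D:
    """Load a dynamic volume from a 4D file or an ordered series of 3D files.

    Exposures are taken from, in order of precedence: the ``exposures``
    argument, a ``<image>.protocol.json|yaml`` sidecar next to the (first)
    file, else uniform weighting.
    """
    if isinstance(path_or_paths, (str, Path)):
        path = Path(path_or_paths)
        img = sitk.ReadImage(str(path))
        if img.GetDimension() != 4:
            raise ValueError(f"{path} is {img.GetDimension()}D, expected 4D (or pass a file series)")
        arr = sitk.GetArrayFromImage(img)  # (t, z, y, x)
        data = np.ascontiguousarray(arr.transpose(3, 2, 1, 0))
        spacing = tuple(img.GetSpacing())[:3]
        first_path = path
    else:
        paths = [Path(p) for p in path_or_paths]
        if len(paths) < 2:
            raise ValueError("a file series needs at least 2 time points")
        volumes = [_array_from_image_3d(sitk.ReadImage(str(p))) for p in paths]
        shapes = {v[0].shape for v in volumes}
        if len(shapes) != 1:
            raise ValueError(f"time points disagree on grid shape: {sorted(shapes)}")
        spacings = {v[1] for v in volumes}
        if len(spacings) != 1:
            raise ValueError(f"time points disagree on spacing: {sorted(spacings)}")
        data = np.stack([v[0] for v in volumes], axis=-1)
        spacing = volumes[0][1]
        first_path = paths[0]

    if exposures is None:
        exposures = _sidecar_exposures(first_path)
    if exposures is None:
        exposures = np.ones(data.shape[3])
    return Volume4D(data=data, spacing=spacing, exposures=np.asarray(exposures, dtype=float))


def save_volume4d(vol: Volume4D, path: str | Path, write_protocol_sidecar: bool = True) -> None:
    path = Path(path)
    if not np.all(np.isfinite(vol.data)):
        raise ValueError("refusing to save volume containing NaN/Inf")
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(vol.data.transpose(3, 2, 1, 0)), isVector=False
    )
    img.SetSpacing(tuple(float(s) for s in vol.spacing) + (1.0,))
    sitk.WriteImage(img, str(path))
    if write_protocol_sidecar:
        stem = path.name
        for suffix in (".gz", ".nii", ".mha", ".mhd"):
            if stem.endswith(suffix):
                stem = stem[: -len(suffix)]
        sidecar = path.with_name(stem + ".protocol.json")
        sidecar.write_text(json.dumps({"exposures": vol.exposures.tolist()}, indent=1))


def load_volume3d(path: str | Path) -> Volume3D:
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise ValueError(f"{path} is {img.GetDimension()}D, expected 3D")
    data, spacing = _array_from_image_3d(img)
    return Volume3D(data=data, spacing=spacing)


def save_volume3d(vol: Volume3D, path: str | Path) -> None:
    if not np.all(np.isfinite(vol.data)):
        raise ValueError("refusing to save volume containing NaN/Inf")
    sitk.WriteImage(_image_from_array_3d(vol.data, vol.spacing), str(path))


def load_mask(path: str | Path) -> BinaryMask3D:
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise ValueError(f"{path} is {img.GetDimension()}D, expected 3D")
    data, spacing = _array_from_image_3d(img)
    return BinaryMask3D(data=data > 0, spacing=spacing)


def save_mask(mask: BinaryMask3D, path: str | Path) -> None:
    sitk.WriteImage(_image_from_array_3d(mask.data.astype(np.uint8), mask.spacing), str(path))
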