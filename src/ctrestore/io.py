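"""CT volume / contour-mask I/O and run configuration.

Conventions
-----------
Voxel arrays are indexed ``(z, y, x)``, 0-based, with physical spacing
``(dz, dy, dx)`` in millimetres carried alongside.  DICOM series are
read-only input; NIfTI-1 is the canonical interchange format (written as
float32 for volumes, uint8 for masks).  Hounsfield units outside the
usual CT range are kept as-is on read — clipping belongs to preprocessing.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

__all__ = [
    "HUVolume", "ContourMask", "RunConfig", "GeometryError", "ConfigError",
    "VolumeValidationError", "read_volume", "write_volume", "read_mask",
    "write_mask", "load_config", "dump_config",
]


class GeometryError(ValueError):
    """Inconsistent slice geometry in a DICOM series."""


class ConfigError(ValueError):
    """One or more configuration keys violate their invariants."""


class VolumeValidationError(ValueError):
    """A volume or mask violates its structural invariants."""


# --------------------------------------------------------------------- types
@dataclass
class HUVolume:
    """A CT volume in Hounsfield units with voxel spacing in mm."""

    voxels: np.ndarray                       # (z, y, x), HU
    spacing: tuple = (3.0, 0.9765, 0.9765)   # (dz, dy, dx) mm
    origin: tuple = (0.0, 0.0, 0.0)          # physical offset, mm
    orientation: str = "RAS"

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        self.validate()

    def validate(self):
        if self.voxels.ndim != 3:
            raise VolumeValidationError(
                f"voxel array must be rank 3, got rank {self.voxels.ndim}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeValidationError(
                f"spacing components must be > 0, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise VolumeValidationError("voxel intensities must be finite")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]


@dataclass
class ContourMask:
    """A binary segmentation volume aligned to an HUVolume grid."""

    voxels: np.ndarray
    spacing: tuple = (3.0, 0.9765, 0.9765)
    label: str = "structure"

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise VolumeValidationError(
                f"mask must be rank 3, got rank {self.voxels.ndim}")
        if not np.isin(self.voxels, (0, 1)).all():
            raise VolumeValidationError("mask values must be 0 or 1")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeValidationError(
                f"spacing components must be > 0, got {self.spacing}")
        self.voxels = self.voxels.astype(np.uint8)

    def check_alignment(self, vol: HUVolume):
        if self.voxels.shape != vol.voxels.shape:
            raise VolumeValidationError(
                f"mask shape {self.voxels.shape} != volume {vol.voxels.shape}")
        if not np.allclose(self.spacing, vol.spacing, atol=1e-4):
            raise VolumeValidationError(
                f"mask spacing {self.spacing} != volume {vol.spacing}")


@dataclass
class RunConfig:
    """Resolved run configuration; unset keys take the published defaults."""

    window_level: float = 400.0      # HU; (WL, WW)=(400, 2800) reproduces
    window_width: float = 2800.0     # the fixed (HU+1000)/2800 normalization
    patch_size: int = 256
    stride: int = 128
    lambda_cyc: float = 20.0
    lambda_iden: float = 0.5
    epochs: int = 250
    constant_epochs: int | None = None   # epochs at the base rate before the
                                         # linear decay; resolves to
                                         # min(150, epochs) when unset
    base_lr: float = 2e-4
    batch_size: int = 4
    seed: int = 0
    gan_loss: str = "lsgan"          # {"lsgan", "log"}
    init_std: float = 0.02
    base_channels: int = 64
    n_res_blocks: int = 9
    replay_pool: int = 50            # 0 disables the fake-image replay pool
    patches_per_slice: float = 1.0   # iterations/epoch scale factor: each
                                     # epoch visits every slice this many
                                     # times (in expectation)
    weight_profile: str = "uniform"  # {"uniform", "gaussian"}
    checkpoint_every: int = 50
    device: str = "cpu"

    @property
    def norm_offset(self) -> float:
        """Additive HU offset of the unit-interval map.

        The window [WL − WW/2, WL + WW/2] maps to [0, 1]; the defaults
        (WL=400, WW=2800) reproduce the fixed (HU + 1000)/2800 normalization.
        """
        return self.window_width / 2.0 - self.window_level

    def validate(self):
        if self.constant_epochs is None:
            self.constant_epochs = min(150, self.epochs)
        problems = []
        if self.patch_size < 32 or self.patch_size % 2:
            problems.append(f"patch_size={self.patch_size} (must be ≥32 and even)")
        if not (0 < self.stride <= self.patch_size):
            problems.append(f"stride={self.stride} (must satisfy 0 < stride ≤ patch_size)")
        if self.lambda_cyc < 0:
            problems.append(f"lambda_cyc={self.lambda_cyc} (must be ≥ 0)")
        if self.lambda_iden < 0:
            problems.append(f"lambda_iden={self.lambda_iden} (must be ≥ 0)")
        if self.epochs < 1:
            problems.append(f"epochs={self.epochs} (must be ≥ 1)")
        if self.constant_epochs < 0 or self.constant_epochs > self.epochs:
            problems.append(f"constant_epochs={self.constant_epochs} "
                            f"(must lie in [0, epochs])")
        if self.base_lr <= 0:
            problems.append(f"base_lr={self.base_lr} (must be > 0)")
        if self.batch_size < 1:
            problems.append(f"batch_size={self.batch_size} (must be ≥ 1)")
        if self.window_width <= 0:
            problems.append(f"window_width={self.window_width} (must be > 0)")
        if self.gan_loss not in ("lsgan", "log"):
            problems.append(f"gan_loss={self.gan_loss!r} (must be lsgan or log)")
        if self.weight_profile not in ("uniform", "gaussian"):
            problems.append(f"weight_profile={self.weight_profile!r}")
        if self.init_std <= 0:
            problems.append(f"init_std={self.init_std} (must be > 0)")
        if self.patches_per_slice <= 0:
            problems.append(f"patches_per_slice={self.patches_per_slice} "
                            f"(must be > 0)")
        if problems:
            raise ConfigError("invalid configuration: " + "; ".join(problems))
        return self


# ----------------------------------------------------------------------- I/O
def _nifti_affine(vol) -> np.ndarray:
    dz, dy, dx = vol.spacing
    origin = getattr(vol, "origin", (0.0, 0.0, 0.0))
    aff = np.diag([dx, dy, dz, 1.0])
    aff[:3, 3] = origin[::-1] if len(origin) == 3 else (0, 0, 0)
    return aff


def write_volume(vol: HUVolume, path, format: str = "nifti") -> None:
    """Write a volume; only NIfTI output is supported (DICOM is read-only)."""
    if format != "nifti":
        raise ValueError(f"unsupported output format {format!r}")
    vol.validate()
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    data = np.asarray(vol.voxels, dtype=np.float32).transpose(2, 1, 0)
    img = nib.Nifti1Image(data, _nifti_affine(vol))
    img.header.set_zooms((vol.spacing[2], vol.spacing[1], vol.spacing[0]))
    nib.save(img, str(path))


def _read_nifti(path) -> HUVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 2:
        data = data[:, :, None]
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    origin = tuple(float(v) for v in img.affine[:3, 3][::-1])
    return HUVolume(voxels=data.transpose(2, 1, 0), spacing=spacing,
                    origin=origin)


def _read_dicom_series(path) -> HUVolume:
    import pydicom

    path = Path(path)
    files = sorted(p for p in path.iterdir() if p.is_file())
    if not files:
        raise IOError(f"no files in DICOM directory {path}")
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception as exc:  # noqa: BLE001 - report the offending file
            raise IOError(f"cannot read DICOM file {f}: {exc}") from exc
        slices.append((f, ds))
    ref_orient = np.asarray(slices[0][1].ImageOrientationPatient, dtype=float)
    ref_ps = np.asarray(slices[0][1].PixelSpacing, dtype=float)
    for f, ds in slices[1:]:
        if not np.allclose(np.asarray(ds.ImageOrientationPatient, dtype=float),
                           ref_orient, atol=1e-4):
            raise GeometryError(f"slice {f.name} has inconsistent orientation")
        if not np.allclose(np.asarray(ds.PixelSpacing, dtype=float),
                           ref_ps, atol=1e-4):
            raise GeometryError(f"slice {f.name} has inconsistent pixel spacing")
    normal = np.cross(ref_orient[:3], ref_orient[3:])
    keyed = []
    for f, ds in slices:
        pos = np.asarray(ds.ImagePositionPatient, dtype=float)
        keyed.append((float(np.dot(pos, normal)), f, ds))
    keyed.sort(key=lambda t: t[0])
    arrs = []
    for _, f, ds in keyed:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arrs.append(ds.pixel_array.astype(np.float64) * slope + intercept)
    if len(keyed) > 1:
        dz = abs(keyed[1][0] - keyed[0][0])
    else:
        dz = float(getattr(keyed[0][2], "SliceThickness", 1.0))
    spacing = (dz if dz > 0 else 1.0, float(ref_ps[0]), float(ref_ps[1]))
    origin = tuple(float(v) for v in
                   np.asarray(keyed[0][2].ImagePositionPatient, dtype=float)[::-1])
    return HUVolume(voxels=np.stack(arrs), spacing=spacing, origin=origin)


def read_volume(path, format: str | None = None) -> HUVolume:
    """Read a CT volume (HU) from a NIfTI file or a DICOM series directory."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such path: {path}")
    if format is None:
        format = "dicom_series" if path.is_dir() else "nifti"
    if format == "nifti":
        try:
            return _read_nifti(path)
        except (nib.filebasedimages.ImageFileError, OSError) as exc:
            raise IOError(f"cannot read NIfTI {path}: {exc}") from exc
    if format == "dicom_series":
        return _read_dicom_series(path)
    raise ValueError(f"unknown format {format!r}")


def write_mask(mask: ContourMask, path) -> None:
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    data = mask.voxels.astype(np.uint8).transpose(2, 1, 0)
    img = nib.Nifti1Image(data, _nifti_affine(mask))
    img.header.set_zooms((mask.spacing[2], mask.spacing[1], mask.spacing[0]))
    nib.save(img, str(path))


def read_mask(path, label: str = "structure") -> ContourMask:
    vol = _read_nifti(Path(path))
    return ContourMask(voxels=np.rint(vol.voxels).astype(np.uint8),
                       spacing=vol.spacing, label=label)


# -------------------------------------------------------------------- config
def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML/JSON config; unset keys fall back to the defaults."""
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config root must be a mapping, got {type(raw)}")
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


def dump_config(cfg: RunConfig, path) -> None:
    """Write the resolved configuration snapshot as JSON."""
    Path(path).write_text(json.dumps(dataclasses.asdict(cfg), indent=2,
                                     sort_keys=True) + "\n")
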