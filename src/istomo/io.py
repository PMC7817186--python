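"""File formats, configuration and logging for the tomographic pipeline.

Volumes travel as 32-bit float TIFF stacks (one page per z-slice, ImageJ
compatible) or as HDF5 files, which are the native container because every
tomogram carries physical metadata: per-axis voxel pitch in nanometres
(z, y, x order), the refractive index of the surrounding medium, and an
optional acquisition timestamp.  Bare TIFF cannot hold the metadata
losslessly, so missing fields are filled from configuration defaults with a
logged warning.

All physical quantities use a fixed unit system: lengths in nm, time in
seconds, mass in femtograms, areas in square micrometres and concentrations
in fg/um^3.  Conversion helpers live here so the factors appear once.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import tifffile

logger = logging.getLogger("istomo")

# -- unit conversions (single source of truth) --------------------------------

NM_PER_UM = 1000.0
#: 1 g/mL expressed in fg/um^3
FG_PER_UM3_PER_G_PER_ML = 1000.0

#: default isotropic voxel pitch in nm (back-computed from a 437 nm = 2 voxel
#: dilation length used when defining the synapse region)
DEFAULT_PITCH_NM = 218.5
#: default refractive index of cell-culture medium
DEFAULT_MEDIUM_RI = 1.337


def nm_to_um(x: float | np.ndarray) -> float | np.ndarray:
    return x / NM_PER_UM


def um_to_nm(x: float | np.ndarray) -> float | np.ndarray:
    return x * NM_PER_UM


def voxel_volume_um3(pitch_nm: Sequence[float]) -> float:
    """Volume of one voxel in um^3 for a (z, y, x) pitch in nm."""
    pz, py, px = pitch_nm
    return (pz / NM_PER_UM) * (py / NM_PER_UM) * (px / NM_PER_UM)


# -- errors -------------------------------------------------------------------


class FormatError(ValueError):
    """Unreadable or wrongly structured file."""


class ShapeError(ValueError):
    """Array dimensionality or shape mismatch."""


class ValidationError(ValueError):
    """A domain invariant is violated."""


# -- domain types -------------------------------------------------------------


@dataclass
class Tomogram:
    """A reconstructed 3D refractive-index map.

    Parameters
    ----------
    values : ndarray, shape (nz, ny, nx)
        Real refractive-index values (dimensionless).
    pitch : tuple of float
        Voxel size in nm, (z, y, x) order.
    medium_ri : float
        Refractive index of the immersion medium.
    timestamp : float, optional
        Acquisition time in seconds relative to the series origin.
    """

    values: np.ndarray
    pitch: tuple[float, float, float] = (DEFAULT_PITCH_NM,) * 3
    medium_ri: float = DEFAULT_MEDIUM_RI
    timestamp: Optional[float] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ShapeError(f"tomogram must be 3D, got {self.values.ndim}D")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("tomogram contains non-finite values")
        self.pitch = tuple(float(p) for p in self.pitch)  # type: ignore[assignment]
        if len(self.pitch) != 3 or any(p <= 0 for p in self.pitch):
            raise ValidationError(f"pitch must be 3 positive values, got {self.pitch}")
        if not (1.30 <= self.medium_ri <= 1.40):
            raise ValidationError(
                f"medium RI {self.medium_ri} outside plausible aqueous range [1.30, 1.40]"
            )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def contrast(self) -> np.ndarray:
        """RI contrast n - n_m."""
        return self.values - np.float32(self.medium_ri)


@dataclass
class VolumeMetadata:
    """Optical acquisition parameters of the tomographic microscope."""

    wavelength_nm: float = 532.0
    na_illumination: float = 1.2
    na_detection: float = 1.2
    n_illuminations: int = 49

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0:
            raise ValidationError("wavelength must be positive")
        for na in (self.na_illumination, self.na_detection):
            if not (0 < na <= 1.49):
                raise ValidationError(f"numerical aperture {na} outside (0, 1.49]")
        if self.n_illuminations < 1:
            raise ValidationError("need at least one illumination")


@dataclass
class RunConfig:
    """Stage parameters for a full pipeline run, serializable to JSON.

    Field groups mirror the pipeline stages; every numeric value is checked
    against its stage's preconditions when loaded.
    """

    # io defaults
    pitch_nm: tuple[float, float, float] = (DEFAULT_PITCH_NM,) * 3
    medium_ri: float = DEFAULT_MEDIUM_RI
    # optics
    wavelength_nm: float = 532.0
    na_illumination: float = 1.2
    na_detection: float = 1.2
    n_illuminations: int = 49
    # annotation hyper-parameters
    ri_threshold: float = 1.345
    dilation_size: int = 1
    gaussian_sigma: float = 1.0
    # reconstruction
    regularization_iterations: int = 100
    regularization_tolerance: float = 1e-6
    # post-processing
    distmap_threshold_nm: float = 54.5
    is_dilation_voxels: int = 2
    surface_erosion_voxels: int = 1
    # densitometry
    alpha_ml_per_g: float = 0.185
    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        self.pitch_nm = tuple(float(p) for p in self.pitch_nm)  # type: ignore[assignment]
        if any(p <= 0 for p in self.pitch_nm):
            raise ValidationError("pitch components must be positive")
        if not (1.30 <= self.medium_ri <= 1.40):
            raise ValidationError("medium_ri outside [1.30, 1.40]")
        if self.ri_threshold <= self.medium_ri:
            raise ValidationError("ri_threshold must exceed medium_ri")
        if self.dilation_size < 0 or self.gaussian_sigma < 0:
            raise ValidationError("morphology sizes must be non-negative")
        if self.regularization_iterations < 0:
            raise ValidationError("iterations must be >= 0")
        if self.distmap_threshold_nm <= 0:
            raise ValidationError("distance threshold must be positive")
        if self.is_dilation_voxels < 0 or self.surface_erosion_voxels < 0:
            raise ValidationError("morphology radii must be non-negative")
        if self.alpha_ml_per_g <= 0:
            raise ValidationError("refractive-index increment must be positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        return cls(**data)


@dataclass
class CellMaskPair:
    """Binary effector and target masks on a common grid (voxelwise disjoint)."""

    effector: np.ndarray
    target: np.ndarray
    pitch: tuple[float, float, float] = (DEFAULT_PITCH_NM,) * 3

    def __post_init__(self) -> None:
        self.effector = np.asarray(self.effector, dtype=bool)
        self.target = np.asarray(self.target, dtype=bool)
        if self.effector.shape != self.target.shape:
            raise ShapeError("effector and target masks must share one shape")
        if self.effector.ndim != 3:
            raise ShapeError("masks must be 3D")
        if np.any(self.effector & self.target):
            raise ValidationError("effector and target masks overlap")
        self.pitch = tuple(float(p) for p in self.pitch)  # type: ignore[assignment]

    @property
    def union(self) -> np.ndarray:
        return self.effector | self.target


# -- volume IO ----------------------------------------------------------------


def read_tomogram(path: str | Path, config: Optional[RunConfig] = None) -> Tomogram:
    """Read a tomogram from a float TIFF stack or an HDF5 file.

    HDF5 files must contain a dataset ``/ri`` with attributes ``pitch_nm``
    and ``medium_ri``.  TIFF stacks carry no physical metadata; missing
    fields are filled from ``config`` (or package defaults) with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    config = config or RunConfig()

    if h5py.is_hdf5(path):
        with h5py.File(path, "r") as f:
            if "ri" not in f:
                raise FormatError(f"{path}: HDF5 file lacks /ri dataset")
            ds = f["ri"]
            values = np.asarray(ds[()], dtype=np.float32)
            pitch = tuple(ds.attrs.get("pitch_nm", config.pitch_nm))
            medium_ri = float(ds.attrs.get("medium_ri", config.medium_ri))
            timestamp = ds.attrs.get("timestamp", None)
            timestamp = float(timestamp) if timestamp is not None else None
    else:
        try:
            values = tifffile.imread(path)
        except Exception as exc:  # tifffile raises several exception types
            raise FormatError(f"{path}: not a readable TIFF or HDF5 file ({exc})")
        values = np.asarray(values, dtype=np.float32)
        logger.warning(
            "%s: TIFF carries no pitch/medium metadata; using defaults "
            "pitch=%s nm, medium_ri=%s", path, config.pitch_nm, config.medium_ri
        )
        pitch, medium_ri, timestamp = config.pitch_nm, config.medium_ri, None

    if values.ndim != 3:
        raise ShapeError(f"{path}: expected a 3D volume, got {values.ndim}D data")
    return Tomogram(values=values, pitch=pitch, medium_ri=medium_ri, timestamp=timestamp)


def write_tomogram(tom: Tomogram, path: str | Path) -> None:
    """Write a tomogram; format chosen by suffix (.h5/.hdf5 native, .tif stack)."""
    path = Path(path)
    if path.suffix.lower() in {".h5", ".hdf5"}:
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("ri", data=tom.values.astype(np.float32))
            ds.attrs["pitch_nm"] = tom.pitch
            ds.attrs["medium_ri"] = tom.medium_ri
            if tom.timestamp is not None:
                ds.attrs["timestamp"] = tom.timestamp
    else:
        tifffile.imwrite(path, tom.values.astype(np.float32), imagej=True)


#: label codes of the multi-label mask volume
LABEL_BACKGROUND, LABEL_EFFECTOR, LABEL_TARGET, LABEL_IS = 0, 1, 2, 3


def write_mask_set(pair: CellMaskPair, is_mask, path: str | Path) -> None:
    """Write effector/target/IS masks as one multi-label uint8 HDF5 volume.

    Labels: 0 background, 1 effector, 2 target, 3 synapse.  The synapse mask
    is stored as its own channel as well because it overlaps both cells by
    construction (it is an intersection of dilated masks).
    """
    is_arr = np.asarray(getattr(is_mask, "values", is_mask), dtype=bool)
    if is_arr.shape != pair.effector.shape:
        raise ShapeError("IS mask shape differs from cell masks")
    labels = np.zeros(pair.effector.shape, dtype=np.uint8)
    labels[pair.effector] = LABEL_EFFECTOR
    labels[pair.target] = LABEL_TARGET
    labels[is_arr] = LABEL_IS
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("labels", data=labels)
        ds.attrs["pitch_nm"] = pair.pitch
        f.create_dataset("mask_effector", data=pair.effector)
        f.create_dataset("mask_target", data=pair.target)
        f.create_dataset("mask_is", data=is_arr)


def read_mask_set(path: str | Path) -> tuple[CellMaskPair, np.ndarray]:
    """Inverse of :func:`write_mask_set`; returns the pair and the IS mask."""
    with h5py.File(path, "r") as f:
        pitch = tuple(f["labels"].attrs["pitch_nm"])
        eff = np.asarray(f["mask_effector"][()], dtype=bool)
        tgt = np.asarray(f["mask_target"][()], dtype=bool)
        is_arr = np.asarray(f["mask_is"][()], dtype=bool)
    return CellMaskPair(effector=eff, target=tgt, pitch=pitch), is_arr
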