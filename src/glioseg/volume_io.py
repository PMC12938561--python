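"""NIfTI volume I/O and the shared voxel-grid data model.

All stages of the pipeline operate on 3D grids indexed ``(x, y, z)`` with
0-based indices. Volumes read from disk are reoriented to RAS order so that

* axis 0 stacks **sagittal** slices,
* axis 1 stacks **coronal** slices,
* axis 2 stacks **axial** slices.

Label volumes use internal codes ``{0: background, 1: necrosis, 2: edema,
3: enhancing tumor}``; the BraTS export dialect maps enhancing tumor to 4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Tuple

import nibabel as nib
import numpy as np

MODALITY_ORDER = ("T1", "T1ce", "T2", "FLAIR")

#: internal integer codes for the three tumor subregions
BACKGROUND, NECROSIS, EDEMA, ENHANCING = 0, 1, 2, 3

#: label dialects: internal contiguous codes vs BraTS-style export codes
DIALECTS = {
    "internal": {0: 0, 1: 1, 2: 2, 3: 3},
    "brats": {0: 0, 1: 1, 2: 2, 3: 4},
}


@dataclass
class MultiModalVolume:
    """Co-registered per-modality intensity grids on one voxel lattice.

    Parameters
    ----------
    data : mapping of modality name -> 3D float array
        Grids must share one shape. FLAIR is mandatory: the whole-tumor
        masking stage runs on FLAIR alone.
    spacing : tuple of 3 floats
        Voxel size in mm along (sagittal, coronal, axial) axes.
    """

    data: Dict[str, np.ndarray]
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        ordered = {m: self.data[m] for m in MODALITY_ORDER if m in self.data}
        unknown = set(self.data) - set(MODALITY_ORDER)
        if unknown:
            raise ValueError(f"unknown modalities: {sorted(unknown)}")
        self.data = ordered
        if "FLAIR" not in self.data:
            raise ValueError("FLAIR modality is required")
        shapes = {m: g.shape for m, g in self.data.items()}
        if len({s for s in shapes.values()}) != 1:
            raise ValueError(f"modality grids differ in shape: {shapes}")
        for m, g in self.data.items():
            if g.ndim != 3:
                raise ValueError(f"{m}: non-3D input (ndim={g.ndim})")
            if not np.all(np.isfinite(g)):
                raise ValueError(f"{m}: non-finite intensities")
            self.data[m] = np.asarray(g, dtype=np.float64)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return next(iter(self.data.values())).shape

    @property
    def modalities(self) -> Tuple[str, ...]:
        return tuple(self.data)

    def with_data(self, data: Mapping[str, np.ndarray]) -> "MultiModalVolume":
        """Same grid metadata, new intensity grids."""
        return MultiModalVolume(dict(data), spacing=self.spacing, affine=self.affine.copy())


@dataclass
class BinaryMask:
    """Boolean voxel mask on the same lattice as its source volume."""

    data: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3D (ndim={self.data.ndim})")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())


@dataclass
class LabelVolume:
    """Integer subregion labels with internal codes {0,1,2,3}."""

    data: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"labels must be 3D (ndim={self.data.ndim})")
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.allclose(self.data, np.round(self.data)):
                raise ValueError("labels must be integer-valued")
            self.data = np.round(self.data).astype(np.int16)
        bad = set(np.unique(self.data)) - {0, 1, 2, 3}
        if bad:
            raise ValueError(f"label codes outside {{0,1,2,3}}: {sorted(bad)}")
        self.data = self.data.astype(np.int16)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape


def _canonicalize_img(img: nib.Nifti1Image) -> nib.Nifti1Image:
    """Reorient a NIfTI image so array axes follow RAS (sag, cor, ax)."""
    return nib.as_closest_canonical(img)


def read_volume(path: str | Path, modality: str = "FLAIR") -> tuple[np.ndarray, tuple, np.ndarray]:
    """Read one modality grid from a NIfTI file.

    Returns ``(grid, spacing, affine)`` with the grid canonicalized to RAS
    axis order (axis 0 sagittal, axis 1 coronal, axis 2 axial stacking).

    Raises
    ------
    FileNotFoundError
        If the path does not exist.
    ValueError
        If the image is not 3D.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = _canonicalize_img(nib.load(str(path)))
    grid = np.asarray(img.get_fdata(), dtype=np.float64)
    if grid.ndim == 4 and grid.shape[3] == 1:
        grid = grid[..., 0]
    if grid.ndim != 3:
        raise ValueError(f"non-3D input: {path} has ndim={grid.ndim}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return grid, spacing, np.asarray(img.affine)


def read_multimodal(paths: Mapping[str, str | Path]) -> MultiModalVolume:
    """Read several co-registered modality files into one volume.

    All files must agree on grid shape; shapes are checked against the
    first modality loaded.
    """
    data: Dict[str, np.ndarray] = {}
    spacing = (1.0, 1.0, 1.0)
    affine = np.eye(4)
    shape = None
    for mod in MODALITY_ORDER:
        if mod not in paths:
            continue
        grid, spacing, affine = read_volume(paths[mod], mod)
        if shape is None:
            shape = grid.shape
        elif grid.shape != shape:
            raise ValueError(
                f"{mod}: shape {grid.shape} inconsistent with previously loaded {shape}"
            )
        data[mod] = grid
    return MultiModalVolume(data, spacing=spacing, affine=affine)


def write_volume(grid: np.ndarray, path: str | Path,
                 spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0),
                 affine: np.ndarray | None = None) -> None:
    """Write a 3D grid to NIfTI with the given voxel spacing."""
    if affine is None:
        affine = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    img = nib.Nifti1Image(np.asarray(grid), affine)
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def read_labels(path: str | Path, dialect: str = "internal") -> LabelVolume:
    """Read an integer label volume, converting from the given dialect."""
    grid, spacing, _ = read_volume(path)
    grid = np.round(grid).astype(np.int16)
    if dialect == "brats":
        grid[grid == 4] = ENHANCING
    elif dialect != "internal":
        raise ValueError(f"unknown dialect: {dialect}")
    return LabelVolume(grid, spacing=spacing)


def write_labels(labels: LabelVolume, path: str | Path, dialect: str = "internal") -> None:
    """Write a label volume to NIfTI, mapping codes to the export dialect.

    BraTS dialect stores enhancing tumor as 4; internal keeps {1,2,3}.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect: {dialect}")
    mapping = DIALECTS[dialect]
    out = np.zeros(labels.shape, dtype=np.int16)
    for src, dst in mapping.items():
        out[labels.data == src] = dst
    write_volume(out, path, spacing=labels.spacing)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a binary mask as a 0/1 NIfTI volume."""
    write_volume(mask.data.astype(np.uint8), path, spacing=mask.spacing)
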