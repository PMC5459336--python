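"""NIfTI input/output, grid bookkeeping, atlases and masks.

All volumes in a study must live on one shared voxel grid; registration is
assumed to have happened upstream, so this module only *verifies* grid
compatibility (:func:`assert_same_grid`) and never resamples.

Voxel coordinates are 0-based array indices; world coordinates come only from
the affine. No orientation flipping is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import DataError, GridMismatchError

__all__ = [
    "VolumeGrid",
    "Volume3D",
    "BoldSeries",
    "LabelAtlas",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "load_label_atlas",
    "assert_same_grid",
    "roi_volume_fractions",
]


@dataclass(frozen=True)
class VolumeGrid:
    """A 3D voxel grid: shape, voxel size in mm, and voxel-to-world affine."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        vs = tuple(float(v) for v in self.voxel_size)
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size", vs)
        aff = np.asarray(self.affine, dtype=float)
        object.__setattr__(self, "affine", aff)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise DataError(f"grid shape must be 3 positive integers, got {shape}")
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise DataError(f"voxel sizes must be positive, got {vs}")
        if aff.shape != (4, 4):
            raise DataError(f"affine must be 4x4, got {aff.shape}")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise DataError("affine is singular")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    @classmethod
    def from_img(cls, img: nib.Nifti1Image) -> "VolumeGrid":
        zooms = img.header.get_zooms()[:3]
        return cls(tuple(img.shape[:3]), tuple(float(z) for z in zooms), img.affine)


@dataclass
class Volume3D:
    """A scalar field on a :class:`VolumeGrid` (e.g. a PET image or a 3D map)."""

    grid: VolumeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise DataError(
                f"value shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise DataError("Volume3D values must be finite")


@dataclass
class BoldSeries:
    """A 4D BOLD time series with repetition time and brain mask.

    ``values`` has shape ``grid.shape + (n_volumes,)``; the mask is boolean
    per voxel. Values are only required to be finite within the mask.
    """

    grid: VolumeGrid
    values: np.ndarray
    tr_seconds: float
    brain_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4 or self.values.shape[:3] != self.grid.shape:
            raise DataError(
                f"BOLD values must be 4D on grid {self.grid.shape}, got {self.values.shape}"
            )
        if self.n_volumes < 2:
            raise DataError("BoldSeries needs at least 2 volumes")
        if not (self.tr_seconds and self.tr_seconds > 0):
            raise DataError(
                "repetition time missing or non-positive; pass an explicit TR override"
            )
        if self.brain_mask is None:
            self.brain_mask = np.ones(self.grid.shape, dtype=bool)
        else:
            self.brain_mask = np.asarray(self.brain_mask).astype(bool)
        if self.brain_mask.shape != self.grid.shape:
            raise DataError("brain mask shape does not match grid")
        if not self.brain_mask.any():
            raise DataError("brain mask is empty")
        if not np.all(np.isfinite(self.values[self.brain_mask])):
            raise DataError("non-finite BOLD values inside brain mask")

    @property
    def n_volumes(self) -> int:
        return int(self.values.shape[3])

    def masked(self) -> np.ndarray:
        """Return the (n_masked_voxels, n_volumes) data matrix."""
        return self.values[self.brain_mask]

    def with_values(self, values: np.ndarray) -> "BoldSeries":
        return BoldSeries(self.grid, values, self.tr_seconds, self.brain_mask.copy())

    def with_mask(self, mask: np.ndarray) -> "BoldSeries":
        return BoldSeries(self.grid, self.values, self.tr_seconds, mask)


@dataclass
class LabelAtlas:
    """Integer-label ROI atlas (0 = background) with a label -> name map."""

    grid: VolumeGrid
    labels: np.ndarray
    names: dict[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.shape != self.grid.shape:
            raise DataError("atlas label shape does not match grid")
        if not np.issubdtype(self.labels.dtype, np.integer):
            lab = np.rint(self.labels).astype(int)
            if not np.allclose(lab, self.labels):
                raise DataError("atlas labels must be integers")
            self.labels = lab
        if self.labels.min() < 0:
            raise DataError("atlas labels must be non-negative")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.names)
        if missing:
            raise DataError(f"atlas labels without names: {sorted(missing)}")

    @property
    def region_ids(self) -> list[int]:
        return sorted(set(np.unique(self.labels)) - {0})

    def region_mask(self, label_id: int) -> np.ndarray:
        return self.labels == label_id


def read_volume(path: str | Path, tr_seconds: float | None = None) -> Volume3D | BoldSeries:
    """Read a 3D or 4D NIfTI-1 image.

    4D images become :class:`BoldSeries` (with an all-true mask; attach a real
    mask via :meth:`BoldSeries.with_mask`). The TR is taken from the header
    timing field unless ``tr_seconds`` overrides it; a zero/absent header TR
    without an override is an error.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
    except Exception as exc:  # malformed header / not NIfTI
        raise DataError(f"cannot read NIfTI image {path}: {exc}") from exc
    if data.ndim == 3:
        return Volume3D(VolumeGrid.from_img(img), data)
    if data.ndim == 4:
        grid = VolumeGrid.from_img(img)
        if tr_seconds is None:
            zooms = img.header.get_zooms()
            tr_seconds = float(zooms[3]) if len(zooms) > 3 else 0.0
        return BoldSeries(grid, data, tr_seconds)
    raise DataError(f"unsupported dimensionality {data.ndim} in {path} (need 3D or 4D)")


def write_volume(obj: Volume3D | BoldSeries | np.ndarray, path: str | Path,
                 grid: VolumeGrid | None = None) -> None:
    """Write a volume (3D) or series (4D) as NIfTI-1, preserving the grid."""
    if isinstance(obj, Volume3D):
        grid, data, tr = obj.grid, obj.values, None
    elif isinstance(obj, BoldSeries):
        grid, data, tr = obj.grid, obj.values, obj.tr_seconds
    else:
        if grid is None:
            raise DataError("writing a bare array requires a grid")
        data, tr = np.asarray(obj), None
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), grid.affine)
    zooms = grid.voxel_size
    if np.asarray(data).ndim == 4:
        zooms = zooms + (tr if tr is not None else 1.0,)
    img.header.set_zooms(zooms)
    if tr is not None:
        img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def read_mask(path: str | Path) -> tuple[VolumeGrid, np.ndarray]:
    """Read a {0,1} uint8 NIfTI mask; returns (grid, boolean array)."""
    vol = read_volume(path)
    if not isinstance(vol, Volume3D):
        raise DataError(f"mask must be 3D: {path}")
    vals = vol.values
    if not np.all(np.isin(np.unique(vals), (0.0, 1.0))):
        raise DataError(f"mask {path} has values other than 0/1")
    return vol.grid, vals.astype(bool)


def write_mask(mask: np.ndarray, grid: VolumeGrid, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), grid.affine)
    img.header.set_zooms(grid.voxel_size)
    nib.save(img, str(path))


def load_label_atlas(nii_path: str | Path, tsv_path: str | Path) -> LabelAtlas:
    """Load an atlas volume plus its 2-column TSV name map (label_id, name)."""
    vol = read_volume(nii_path)
    if not isinstance(vol, Volume3D):
        raise DataError("atlas image must be 3D")
    table = pd.read_csv(tsv_path, sep="\t")
    if table.shape[1] < 2:
        raise DataError("atlas name map needs columns (label_id, name)")
    ids, names = table.iloc[:, 0], table.iloc[:, 1]
    name_map = {int(i): str(n) for i, n in zip(ids, names)}
    if len(name_map) != len(table):
        raise DataError("duplicate label ids in atlas name map")
    return LabelAtlas(vol.grid, vol.values, name_map)


def _grid_of(obj) -> VolumeGrid:
    if isinstance(obj, VolumeGrid):
        return obj
    grid = getattr(obj, "grid", None)
    if grid is None:
        raise DataError(f"object of type {type(obj).__name__} carries no grid")
    return grid


def assert_same_grid(a, b, tol: float = 1e-4) -> None:
    """Require two gridded objects to share shape and affine (within ``tol``).

    Raises :class:`GridMismatchError` naming the offending field. Deliberately
    strict: the pipeline never resamples, so grids must already agree.
    """
    ga, gb = _grid_of(a), _grid_of(b)
    if ga.shape != gb.shape:
        raise GridMismatchError(f"shape mismatch: {ga.shape} vs {gb.shape}")
    if not np.allclose(ga.affine, gb.affine, atol=tol, rtol=0):
        diff = float(np.abs(ga.affine - gb.affine).max())
        raise GridMismatchError(f"affine mismatch: max abs difference {diff:g} > tol {tol:g}")


def roi_volume_fractions(atlas: LabelAtlas, brain_mask: np.ndarray) -> pd.DataFrame:
    """Per-region voxel counts, volumes (mm^3) and fractions of brain volume.

    Only voxels inside the brain mask count; fractions are region volume over
    whole brain-mask volume, so disjoint regions sum to <= 1.
    """
    brain_mask = np.asarray(brain_mask).astype(bool)
    if brain_mask.shape != atlas.grid.shape:
        raise GridMismatchError("brain mask shape does not match atlas grid")
    n_brain = int(brain_mask.sum())
    if n_brain == 0:
        raise DataError("empty brain mask")
    vox_mm3 = atlas.grid.voxel_volume_mm3
    rows = []
    for rid in atlas.region_ids:
        n = int(((atlas.labels == rid) & brain_mask).sum())
        rows.append(
            {
                "region_id": rid,
                "region": atlas.names[rid],
                "n_voxels": n,
                "volume_mm3": n * vox_mm3,
                "fraction": n / n_brain,
            }
        )
    return pd.DataFrame(rows, columns=["region_id", "region", "n_voxels", "volume_mm3", "fraction"])
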