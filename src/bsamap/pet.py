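"""FDG-PET SUVR normalization and cross-modal voxel-wise correlation.

SUVR divides each voxel's standardized uptake value by the mean SUV over a
reference region (conventionally the cerebellum, whose metabolism is spared
early in Alzheimer disease), making images comparable across subjects. The
correlation routine measures voxel-by-voxel Pearson agreement between an
activity map and a SUVR map within a (gray-matter) mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DataError
from .io import Volume3D, VolumeGrid, assert_same_grid

__all__ = ["SuvrMap", "PearsonResult", "suvr_map", "voxelwise_correlation"]


@dataclass
class SuvrMap:
    """A PET image normalized to a reference-region mean of exactly 1."""

    grid: VolumeGrid
    values: np.ndarray
    reference_name: str
    reference_mean: float

    def as_volume(self) -> Volume3D:
        return Volume3D(self.grid, self.values)


@dataclass
class PearsonResult:
    r: float
    n: int
    slope: float
    intercept: float
    p: float
    p_adjusted: float | None = None

    def to_dict(self) -> dict:
        out = {"r": self.r, "n": self.n, "slope": self.slope,
               "intercept": self.intercept, "p": self.p}
        if self.p_adjusted is not None:
            out["p_adjusted"] = self.p_adjusted
        return out


def suvr_map(pet: Volume3D, reference_mask: np.ndarray,
             reference_name: str = "cerebellum") -> SuvrMap:
    """Divide a PET volume by its mean over the reference region."""
    reference_mask = np.asarray(reference_mask).astype(bool)
    if reference_mask.shape != pet.grid.shape:
        raise DataError("reference mask shape does not match PET grid")
    if not reference_mask.any():
        raise DataError("empty reference region")
    ref_mean = float(pet.values[reference_mask].mean())
    if ref_mean <= 0:
        raise DataError(
            f"reference-region mean is {ref_mean:g}; expected positive SUV values"
        )
    return SuvrMap(pet.grid, pet.values / ref_mean, reference_name, ref_mean)


def voxelwise_correlation(a, b, mask: np.ndarray) -> PearsonResult:
    """Pearson r (plus regression line b ~ a) over the masked voxels.

    ``a`` and ``b`` may be Volume3D/ActivityMap/SuvrMap-like objects (anything
    with ``grid`` and ``values``) or bare arrays on the same shape as the mask.
    """
    mask = np.asarray(mask).astype(bool)

    def _values(obj):
        if hasattr(obj, "grid") and hasattr(obj, "values"):
            return obj
        return None

    oa, ob = _values(a), _values(b)
    if oa is not None and ob is not None:
        assert_same_grid(oa, ob)
    va = (oa.values if oa is not None else np.asarray(a, dtype=float))
    vb = (ob.values if ob is not None else np.asarray(b, dtype=float))
    if va.shape != mask.shape or vb.shape != mask.shape:
        raise DataError("fields and mask must share a shape")
    x, y = va[mask], vb[mask]
    n = int(x.size)
    if n < 3:
        raise DataError(f"need >= 3 masked voxels, got {n}")
    if float(x.std()) == 0.0 or float(y.std()) == 0.0:
        raise DataError("constant field within mask; correlation undefined")
    res = stats.linregress(x, y)
    return PearsonResult(
        r=float(res.rvalue), n=n, slope=float(res.slope),
        intercept=float(res.intercept), p=float(res.pvalue),
    )
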