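"""The BOLD-signal-amplitude (BSA) neuronal-activity metric.

For voxel *i* and neuronal component *j*, the BSA series is the Hadamard
product of the voxel's preprocessed BOLD time course S_i(t) with the
component's unit-variance time course W_j(t):

    BSA_ij(t) = S_i(t) * W_j(t)

The per-voxel activity is the sum over the k neuronal components of the
temporal standard deviation of BSA_ij weighted by the component's (z-scored)
spatial map value NC_ij:

    activity_i = sum_j SD(BSA_ij) * NC_ij          (sum_sd, default)
    activity_i = sum_j sqrt(SD(BSA_ij)) * NC_ij    (sum_sqrt_sd variant)

The square-root variant exists because the source method is described both
with and without it; both are first-class here and the configuration is
recorded on the output map. NC values are signed and unthresholded by
default; ``clip_negative_nc`` zeroes negative map values first, which keeps
the activity non-negative where maps are the only sign source.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .io import BoldSeries, LabelAtlas, Volume3D, VolumeGrid, assert_same_grid
from .ica import ComponentDecomposition
from .labeling import ComponentLabels

__all__ = [
    "ActivityConfig",
    "ActivityMap",
    "bsa_series",
    "component_contribution",
    "activity_map",
    "roi_means",
    "whole_brain_activity",
]

logger = logging.getLogger(__name__)

_AGGREGATIONS = ("sum_sd", "sum_sqrt_sd")
_DENOMINATORS = ("n-1", "n")


@dataclass(frozen=True)
class ActivityConfig:
    aggregation: str = "sum_sd"
    sd_denominator: str = "n-1"
    clip_negative_nc: bool = False

    def __post_init__(self) -> None:
        if self.aggregation not in _AGGREGATIONS:
            raise ConfigError(f"aggregation must be one of {_AGGREGATIONS}")
        if self.sd_denominator not in _DENOMINATORS:
            raise ConfigError(f"sd_denominator must be one of {_DENOMINATORS}")

    @property
    def ddof(self) -> int:
        return 1 if self.sd_denominator == "n-1" else 0


@dataclass
class ActivityMap:
    """A 3D neuronal-activity field plus the configuration that produced it."""

    grid: VolumeGrid
    mask: np.ndarray
    values: np.ndarray  # full 3D, zero outside mask
    config: ActivityConfig
    k_used: int

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape or self.mask.shape != self.grid.shape:
            raise DataError("activity values/mask must match the grid shape")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise DataError("non-finite activity values inside mask")
        self.values = self.values.copy()
        self.values[~self.mask] = 0.0

    def as_volume(self) -> Volume3D:
        return Volume3D(self.grid, self.values)


def bsa_series(s: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Hadamard product of a voxel time series with a component time course."""
    s = np.asarray(s, dtype=float)
    w = np.asarray(w, dtype=float)
    if s.shape != w.shape or s.ndim != 1:
        raise DataError(f"length mismatch: s has shape {s.shape}, w has {w.shape}")
    if s.size < 2:
        raise DataError("BSA needs series of length >= 2")
    return s * w


def component_contribution(s: np.ndarray, w: np.ndarray, nc: float,
                           cfg: ActivityConfig | None = None) -> float:
    """One component's contribution at one voxel: SD(BSA)*NC (or sqrt-SD variant)."""
    cfg = cfg or ActivityConfig()
    sd = float(np.std(bsa_series(s, w), ddof=cfg.ddof))
    if cfg.aggregation == "sum_sqrt_sd":
        sd = float(np.sqrt(sd))
    return sd * float(nc)


def activity_map(series: BoldSeries, dec: ComponentDecomposition,
                 labels: ComponentLabels, cfg: ActivityConfig | None = None) -> ActivityMap:
    """Voxel-wise neuronal-activity map over the brain mask.

    ``series`` must be the same preprocessed series the decomposition was fit
    to (grids and masks are checked). With k = 0 neuronal components the map
    is all-zero and a warning is logged.
    """
    cfg = cfg or ActivityConfig()
    assert_same_grid(series, dec)
    if not np.array_equal(series.brain_mask, dec.mask):
        raise DataError("series mask differs from decomposition mask")
    if len(labels.labels) != dec.n_components:
        raise DataError(
            f"labels cover {len(labels.labels)} components, decomposition has {dec.n_components}"
        )
    data = series.masked()  # (n_vox, n_t)
    if data.shape[1] != dec.n_volumes:
        raise DataError("series length differs from decomposition time courses")
    neuronal = labels.neuronal_indices
    acc = np.zeros(data.shape[0])
    for j in neuronal:
        w = dec.time_courses[j]
        sd = np.std(data * w[None, :], axis=1, ddof=cfg.ddof)
        if cfg.aggregation == "sum_sqrt_sd":
            sd = np.sqrt(sd)
        nc = dec.spatial_maps[j]
        if cfg.clip_negative_nc:
            nc = np.clip(nc, 0.0, None)
        acc += sd * nc
    if len(neuronal) == 0:
        logger.warning("no neuronal components (k = 0); activity map is all-zero")
    values = np.zeros(series.grid.shape)
    values[series.brain_mask] = acc
    return ActivityMap(series.grid, series.brain_mask.copy(), values, cfg, int(len(neuronal)))


def roi_means(source: ActivityMap | Volume3D, atlas: LabelAtlas,
              mask: np.ndarray | None = None) -> pd.DataFrame:
    """Mean/SD of a map over each atlas region (restricted to the brain mask).

    Regions that do not intersect the mask are reported with count 0 and
    missing mean/SD rather than dropped.
    """
    assert_same_grid(source, atlas)
    if isinstance(source, ActivityMap):
        values, m = source.values, source.mask
    else:
        values, m = source.values, np.ones(source.grid.shape, dtype=bool)
    if mask is not None:
        m = m & np.asarray(mask).astype(bool)
    rows = []
    for rid in atlas.region_ids:
        sel = (atlas.labels == rid) & m
        n = int(sel.sum())
        if n == 0:
            mean = sd = np.nan
        else:
            vox = values[sel]
            mean = float(vox.mean())
            sd = float(vox.std(ddof=1)) if n > 1 else np.nan
        rows.append({"region_id": rid, "region": atlas.names[rid],
                     "n_voxels": n, "mean": mean, "sd": sd})
    return pd.DataFrame(rows, columns=["region_id", "region", "n_voxels", "mean", "sd"])


def whole_brain_activity(amap: ActivityMap) -> float:
    """Whole-brain summary: the mean activity over the brain mask.

    A voxel mean (not a sum) so the summary is independent of grid resolution.
    """
    if not amap.mask.any():
        raise DataError("empty mask")
    return float(amap.values[amap.mask].mean())
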