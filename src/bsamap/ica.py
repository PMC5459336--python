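"""Single-subject spatial ICA of preprocessed BOLD series.

The 4D data (masked voxels x time) are decomposed as ``X ~ S @ A.T`` with the
sources *S* independent over voxels — spatial ICA, so each component is a 3D
map paired with a time course (the mixing weights *W*). The scale convention
is: time courses unit variance, amplitude folded into the spatial maps; the
maps handed downstream are additionally z-scored over the brain mask, while
the raw (amplitude-carrying) maps are kept for reconstruction.

FastICA (parallel/symmetric updates, PCA whitening to ``n_components``) does
the estimation; runs are deterministic for a fixed seed, and non-convergence
triggers up to three seeded restarts before raising.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .errors import DataError, NumericalError
from .io import BoldSeries, VolumeGrid, write_volume

logger = logging.getLogger(__name__)

__all__ = [
    "ComponentDecomposition",
    "SpatialICA",
    "decompose",
    "match_components",
    "high_freq_power_fraction",
]


@dataclass
class ComponentDecomposition:
    """ICA result: paired spatial maps and time courses on a fixed grid.

    ``spatial_maps`` are z-scored over the mask (mean 0, variance 1 per
    component); ``raw_maps`` carry the amplitude scale; ``time_courses`` have
    unit variance each.
    """

    grid: VolumeGrid
    mask: np.ndarray
    spatial_maps: np.ndarray  # (n_components, n_masked), z-scored
    raw_maps: np.ndarray  # (n_components, n_masked)
    time_courses: np.ndarray  # (n_components, n_volumes), unit variance
    seed: int
    n_iter: int = 0
    mean_course: np.ndarray | None = None  # per-timepoint mean removed by whitening

    @property
    def n_components(self) -> int:
        return int(self.spatial_maps.shape[0])

    @property
    def n_volumes(self) -> int:
        return int(self.time_courses.shape[1])

    def map_volume(self, j: int) -> np.ndarray:
        """The j-th z-scored spatial map as a full 3D array (0 outside mask)."""
        vol = np.zeros(self.grid.shape)
        vol[self.mask] = self.spatial_maps[j]
        return vol

    def reconstruct(self) -> np.ndarray:
        """Masked-data reconstruction from the retained subspace, (n_masked, n_t)."""
        rec = self.raw_maps.T @ self.time_courses
        if self.mean_course is not None:
            rec = rec + self.mean_course[None, :]
        return rec

    def save(self, directory: str | Path, prefix: str = "ica") -> None:
        """Serialize as 4D NIfTI (maps), TSV (time courses), JSON sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        maps4d = np.stack([self.map_volume(j) for j in range(self.n_components)], axis=-1)
        write_volume(maps4d, directory / f"{prefix}_maps.nii.gz", grid=self.grid)
        tc = pd.DataFrame(
            self.time_courses.T,
            columns=[f"component_{j}" for j in range(self.n_components)],
        )
        tc.to_csv(directory / f"{prefix}_timecourses.tsv", sep="\t", index=False)
        sidecar = {
            "n_components": self.n_components,
            "seed": int(self.seed),
            "n_iter": int(self.n_iter),
        }
        (directory / f"{prefix}.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


class SpatialICA(BaseEstimator):
    """Seeded spatial-ICA estimator over a masked BOLD series.

    Parameters
    ----------
    n_components : number of independent components to extract (default 30,
        the usual model order for single-subject resting-state ICA).
    seed : random seed; runs are bit-for-bit reproducible for a fixed seed.
    tol, max_iter : FastICA convergence control.
    n_restarts : extra seeded attempts on non-convergence before raising.

    Attributes (after :meth:`fit`)
    ------------------------------
    decomposition_ : :class:`ComponentDecomposition`
    n_iter_ : iterations used by the converged run.
    """

    def __init__(self, n_components: int = 30, seed: int = 0, tol: float = 1e-4,
                 max_iter: int = 500, n_restarts: int = 3):
        self.n_components = n_components
        self.seed = seed
        self.tol = tol
        self.max_iter = max_iter
        self.n_restarts = n_restarts

    def fit(self, series: BoldSeries) -> "SpatialICA":
        X = series.masked()  # (n_voxels, n_time)
        n_vox, n_t = X.shape
        bound = min(n_t - 1, n_vox)
        if not (1 <= self.n_components <= bound):
            raise DataError(
                f"n_components={self.n_components} out of range [1, {bound}] "
                f"(min(n_volumes - 1, masked voxels))"
            )
        if float(X.std()) == 0.0:
            raise DataError("constant data within mask; nothing to decompose")
        mean_course = X.mean(axis=0)
        last_err: Exception | None = None
        fallback: ComponentDecomposition | None = None
        for attempt in range(self.n_restarts + 1):
            seed = int(self.seed) + 7919 * attempt
            ica = FastICA(
                n_components=self.n_components,
                algorithm="parallel",
                whiten="unit-variance",
                fun="logcosh",
                tol=self.tol,
                max_iter=self.max_iter,
                random_state=seed,
            )
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always", ConvergenceWarning)
                try:
                    S = ica.fit_transform(X)  # (n_vox, n_comp) sources
                except Exception as exc:  # numerical failure inside FastICA
                    last_err = exc
                    continue
            converged = not any(
                issubclass(w.category, ConvergenceWarning) for w in caught
            )
            A = ica.mixing_  # (n_time, n_comp)
            tc_scale = A.std(axis=0)
            if np.any(tc_scale == 0):
                last_err = NumericalError("degenerate (constant) time course from ICA")
                continue
            time_courses = (A / tc_scale[None, :]).T  # unit variance each
            raw_maps = (S * tc_scale[None, :]).T  # amplitude folded into maps
            # canonical orientation: positive spatial skewness (flip map and
            # time course jointly; the sign of an IC is otherwise arbitrary)
            centered = raw_maps - raw_maps.mean(axis=1, keepdims=True)
            skew = (centered**3).mean(axis=1)
            flip = np.where(skew < 0, -1.0, 1.0)
            raw_maps *= flip[:, None]
            time_courses *= flip[:, None]
            mu = raw_maps.mean(axis=1, keepdims=True)
            sd = raw_maps.std(axis=1, keepdims=True)
            spatial_maps = (raw_maps - mu) / sd
            dec = ComponentDecomposition(
                grid=series.grid,
                mask=series.brain_mask.copy(),
                spatial_maps=spatial_maps,
                raw_maps=raw_maps,
                time_courses=time_courses,
                seed=seed,
                n_iter=int(ica.n_iter_),
                mean_course=mean_course,
            )
            if converged:
                self.decomposition_ = dec
                self.n_iter_ = int(ica.n_iter_)
                return self
            if fallback is None:
                fallback = dec
            logger.info("FastICA attempt with seed %d hit max_iter=%d", seed, self.max_iter)
        if fallback is not None:
            # When the model order exceeds the number of non-Gaussian sources,
            # the leftover whitened dimensions carry no contrast and the fixed
            # point cannot settle on them; the structured components are still
            # estimated. Keep the first fit rather than failing the run.
            logger.warning(
                "FastICA did not converge after %d seeded attempts; "
                "keeping the first fit (noise-dimension indeterminacy)",
                self.n_restarts + 1,
            )
            self.decomposition_ = fallback
            self.n_iter_ = fallback.n_iter
            return self
        raise NumericalError(
            f"spatial ICA failed after {self.n_restarts + 1} attempts: {last_err}"
        )


def decompose(series: BoldSeries, n_components: int = 30, seed: int = 0,
              **kwargs) -> ComponentDecomposition:
    """Functional wrapper around :class:`SpatialICA`."""
    return SpatialICA(n_components=n_components, seed=seed, **kwargs).fit(series).decomposition_


def match_components(est: ComponentDecomposition, truth_maps: np.ndarray,
                     mask: np.ndarray | None = None) -> pd.DataFrame:
    """One-to-one matching of estimated components to reference spatial maps.

    ``truth_maps`` is (n_truth, ...) — full 3D fields or already-masked
    vectors. The assignment maximizes total \\|Pearson r\\| (Hungarian
    algorithm); the signed r of each matched pair is reported, since ICA
    components carry an arbitrary sign.
    """
    mask = est.mask if mask is None else np.asarray(mask, dtype=bool)
    truth = np.asarray(truth_maps, dtype=float)
    if truth.ndim > 2:
        truth = truth.reshape(truth.shape[0], -1)[:, mask.ravel()]
    n_truth = truth.shape[0]
    if n_truth > est.n_components:
        raise DataError(
            f"{n_truth} reference sources but only {est.n_components} components"
        )
    est_maps = est.spatial_maps
    tz = (truth - truth.mean(axis=1, keepdims=True)) / truth.std(axis=1, keepdims=True)
    ez = (est_maps - est_maps.mean(axis=1, keepdims=True)) / est_maps.std(axis=1, keepdims=True)
    corr = tz @ ez.T / truth.shape[1]
    rows_, cols_ = linear_sum_assignment(-np.abs(corr))
    rows = []
    for t_idx, c_idx in zip(rows_, cols_):
        r = float(corr[t_idx, c_idx])
        rows.append(
            {"truth": int(t_idx), "component": int(c_idx), "r": r,
             "abs_r": abs(r), "sign": int(np.sign(r)) or 1}
        )
    return pd.DataFrame(rows).sort_values("truth").reset_index(drop=True)


def high_freq_power_fraction(time_course: np.ndarray, tr_seconds: float,
                             cutoff_hz: float = 0.1) -> float:
    """Fraction of spectral power (DC excluded) above ``cutoff_hz``.

    The screening feature used to reject artifact components: BOLD fluctuations
    of neuronal origin live below ~0.1 Hz, while scanner/physiological noise is
    spectrally flat or high-frequency.
    """
    x = np.asarray(time_course, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise DataError("time course must be 1D with length >= 4")
    power = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, d=tr_seconds)
    total = float(power[1:].sum())
    if total == 0.0:
        raise DataError("all-zero time course has no spectrum")
    return float(power[1:][freqs[1:] > cutoff_hz].sum() / total)
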