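"""Synthetic resting-state fMRI phantoms with known ground truth.

Each phantom subject is a 4D BOLD series built from planted spatial sources
(Gaussian blobs truncated at 3 sigma) times band-limited time courses (sums of
>= 3 random-phase sinusoids inside a 0.01-0.08 Hz band, unit variance before
amplitude scaling), plus structured noise: a linear drift, occasional
whole-volume spikes (scanner transients), and white Gaussian noise. Sources
may instead be *artifact* sources with white-noise time courses, giving the
spectral screen genuine negatives.

Cohorts model the study contrast: patients get a global source-amplitude
scale (< 1) and optionally lose sources at random, mimicking fewer and weaker
neuronal components. A PET-like surrogate image can be generated with a
designed voxel-wise correlation to the true activity field.

Ground-truth activity is computed through the activity module's own code path
on the noiseless sources, so the generator and the metric cannot drift apart;
an independent brute-force oracle in the test suite checks that path.

Default conditions: 20x20x12 grid at 3 mm isotropic, 150 volumes, TR 3 s,
five sources of amplitude 1 against white noise of SD 0.2 (amplitude SNR 5).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .activity import ActivityConfig, ActivityMap, activity_map
from .errors import ConfigError, DataError
from .io import BoldSeries, LabelAtlas, Volume3D, VolumeGrid
from .ica import ComponentDecomposition
from .labeling import ComponentLabels, NEURONAL, TemplateSet

__all__ = [
    "SourceSpec",
    "NoiseSpec",
    "PhantomSpec",
    "PhantomTruth",
    "PhantomSubject",
    "default_grid",
    "default_sources",
    "ellipsoid_mask",
    "generate_subject",
    "generate_cohort",
    "generate_pet_surrogate",
    "templates_from_spec",
    "atlas_from_spec",
    "truth_templates",
    "truth_atlas",
]


@dataclass(frozen=True)
class SourceSpec:
    """One planted source: a Gaussian blob with a band-limited time course.

    ``radius_mm`` is the Gaussian sigma; the blob is truncated at 3 sigma.
    ``band=None`` (or ``neuronal=False``) makes the time course white noise —
    an artifact source.
    """

    center: tuple[int, int, int]
    radius_mm: float
    amplitude: float = 1.0
    band: tuple[float, float] | None = (0.01, 0.08)
    neuronal: bool = True

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ConfigError("source radius must be > 0")
        if self.amplitude < 0:
            raise ConfigError("source amplitude must be >= 0")
        if self.neuronal and self.band is None:
            raise ConfigError("neuronal sources need a frequency band")


@dataclass(frozen=True)
class NoiseSpec:
    white_sd: float = 0.2
    drift_slope: float = 0.001  # signal units per second
    spike_rate: float = 0.02  # probability per volume
    spike_amplitude: float = 2.0


def default_grid() -> VolumeGrid:
    affine = np.diag([3.0, 3.0, 3.0, 1.0])
    return VolumeGrid((20, 20, 12), (3.0, 3.0, 3.0), affine)


def default_sources() -> tuple[SourceSpec, ...]:
    centers = [(5, 5, 4), (14, 5, 4), (5, 14, 4), (14, 14, 4), (9, 9, 8)]
    return tuple(SourceSpec(center=c, radius_mm=4.5) for c in centers)


@dataclass(frozen=True)
class PhantomSpec:
    grid: VolumeGrid = field(default_factory=default_grid)
    n_volumes: int = 150
    tr_seconds: float = 3.0
    sources: tuple[SourceSpec, ...] = field(default_factory=default_sources)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    group_amplitude_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n_volumes < 2 or self.tr_seconds <= 0:
            raise ConfigError("need n_volumes >= 2 and tr_seconds > 0")
        if self.group_amplitude_scale <= 0:
            raise ConfigError("group_amplitude_scale must be > 0")
        nyq = 1.0 / (2.0 * self.tr_seconds)
        for s in self.sources:
            if s.band is not None:
                lo, hi = s.band
                if not (0.0 < lo < hi < nyq):
                    raise ConfigError(
                        f"source band {s.band} outside (0, Nyquist={nyq:g})"
                    )


@dataclass
class PhantomTruth:
    """Ground truth for one phantom subject."""

    grid: VolumeGrid
    mask: np.ndarray
    source_maps: np.ndarray  # (n_sources, *grid.shape)
    source_time_courses: np.ndarray  # (n_sources, n_volumes), amplitude-scaled
    labels_truth: np.ndarray  # (n_sources,) bool — neuronal flags
    true_activity: ActivityMap


@dataclass
class PhantomSubject:
    subject_id: str
    group: str
    series: BoldSeries
    truth: PhantomTruth


def ellipsoid_mask(grid: VolumeGrid) -> np.ndarray:
    """Brain-like ellipsoid inscribed in the grid (semi-axes shape/2 - 0.5)."""
    idx = np.indices(grid.shape, dtype=float)
    center = [(s - 1) / 2.0 for s in grid.shape]
    semi = [max(s / 2.0 - 0.5, 1.0) for s in grid.shape]
    d2 = sum(((idx[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    return d2 <= 1.0


def _blob(grid: VolumeGrid, source: SourceSpec) -> np.ndarray:
    sigma_vox = [source.radius_mm / vs for vs in grid.voxel_size]
    idx = np.indices(grid.shape, dtype=float)
    d2 = sum(((idx[a] - source.center[a]) / sigma_vox[a]) ** 2 for a in range(3))
    blob = np.exp(-0.5 * d2)
    blob[d2 > 9.0] = 0.0  # truncate at 3 sigma
    return blob


def _band_limited_course(rng: np.random.Generator, n: int, tr: float,
                         band: tuple[float, float], n_sin: int = 3) -> np.ndarray:
    t = np.arange(n) * tr
    freqs = rng.uniform(band[0], band[1], size=n_sin)
    phases = rng.uniform(0, 2 * np.pi, size=n_sin)
    x = np.sum([np.sin(2 * np.pi * f * t + ph) for f, ph in zip(freqs, phases)], axis=0)
    sd = x.std()
    if sd == 0:
        raise DataError("degenerate sinusoid sum")
    return x / sd


def generate_subject(spec: PhantomSpec, seed: int) -> tuple[BoldSeries, PhantomTruth]:
    """One phantom subject: the noisy BOLD series plus its ground truth.

    Fully reproducible per seed; the source geometry depends only on the spec.
    """
    rng = np.random.default_rng(seed)
    grid = spec.grid
    mask = ellipsoid_mask(grid)
    n_src = len(spec.sources)
    maps = np.zeros((n_src,) + grid.shape)
    courses = np.zeros((n_src, spec.n_volumes))
    neuronal = np.zeros(n_src, dtype=bool)
    for s_idx, src in enumerate(spec.sources):
        maps[s_idx] = _blob(grid, src) * mask
        if src.neuronal and src.band is not None:
            tc = _band_limited_course(rng, spec.n_volumes, spec.tr_seconds, src.band)
            scale = src.amplitude * spec.group_amplitude_scale
            neuronal[s_idx] = True
        else:
            tc = rng.standard_normal(spec.n_volumes)
            tc = tc / tc.std() if tc.std() > 0 else tc
            scale = src.amplitude
        courses[s_idx] = tc * scale

    clean = np.einsum("sxyz,st->xyzt", maps, courses)

    data = clean.copy()
    t_sec = np.arange(spec.n_volumes) * spec.tr_seconds
    drift = spec.noise.drift_slope * (t_sec - t_sec.mean())
    data[mask] += drift[None, :]
    spike_volumes = rng.random(spec.n_volumes) < spec.noise.spike_rate
    if spike_volumes.any():
        signs = rng.choice((-1.0, 1.0), size=int(spike_volumes.sum()))
        spikes = np.zeros(spec.n_volumes)
        spikes[spike_volumes] = spec.noise.spike_amplitude * signs
        data[mask] += spikes[None, :]
    if spec.noise.white_sd > 0:
        data[mask] += rng.normal(0.0, spec.noise.white_sd,
                                 size=(int(mask.sum()), spec.n_volumes))
    data[~mask] = 0.0

    series = BoldSeries(grid, data, spec.tr_seconds, mask)
    truth = PhantomTruth(
        grid=grid,
        mask=mask,
        source_maps=maps,
        source_time_courses=courses,
        labels_truth=neuronal,
        true_activity=_true_activity(grid, mask, maps, courses, neuronal,
                                     clean, spec.tr_seconds),
    )
    return series, truth


def _true_activity(grid, mask, maps, courses, neuronal, clean,
                   tr_seconds) -> ActivityMap:
    """Noiseless activity through the activity module's own code path."""
    idx = np.flatnonzero(neuronal)
    if idx.size == 0:
        cfg = ActivityConfig()
        return ActivityMap(grid, mask, np.zeros(grid.shape), cfg, 0)
    flat = maps[idx][:, mask]  # (k, n_masked)
    scales = courses[idx].std(axis=1)
    if np.any(scales == 0):
        raise DataError("constant truth time course")
    w = courses[idx] / scales[:, None]
    raw = flat * scales[:, None]
    mu = raw.mean(axis=1, keepdims=True)
    sd = raw.std(axis=1, keepdims=True)
    dec = ComponentDecomposition(
        grid=grid, mask=mask, spatial_maps=(raw - mu) / sd, raw_maps=raw,
        time_courses=w, seed=0,
    )
    labels = ComponentLabels(
        gof=np.zeros((idx.size, 0)), assignment={},
        labels=np.array([NEURONAL] * idx.size, dtype=object),
        hf_fractions=np.zeros(idx.size),
    )
    series = BoldSeries(grid, clean, tr_seconds, mask)
    return activity_map(series, dec, labels, ActivityConfig())


def _subject_seeds(base_seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(base_seed).generate_state(n, dtype=np.uint32)
    return [int(s) & 0x7FFFFFFF for s in state]


def generate_cohort(
    spec: PhantomSpec,
    n_control: int,
    n_patient: int,
    patient_amplitude_scale: float = 0.6,
    patient_drop_sources: int = 1,
    base_seed: int = 0,
) -> list[PhantomSubject]:
    """A two-group cohort; patients get weaker and (optionally) fewer sources.

    Per-subject seeds derive deterministically from ``base_seed``; dropped
    sources are chosen at random per patient among the neuronal sources.
    """
    if n_control < 1 or n_patient < 1:
        raise ConfigError("need at least one subject per group")
    if patient_amplitude_scale <= 0:
        raise ConfigError("patient_amplitude_scale must be > 0")
    n_neuronal = sum(1 for s in spec.sources if s.neuronal)
    if patient_drop_sources >= n_neuronal:
        raise ConfigError(
            f"cannot drop {patient_drop_sources} of {n_neuronal} neuronal sources"
        )
    seeds = _subject_seeds(base_seed, n_control + n_patient)
    subjects: list[PhantomSubject] = []
    for i in range(n_control):
        series, truth = generate_subject(spec, seeds[i])
        subjects.append(PhantomSubject(f"control_{i:02d}", "control", series, truth))
    neuronal_idx = [j for j, s in enumerate(spec.sources) if s.neuronal]
    for i in range(n_patient):
        seed = seeds[n_control + i]
        rng = np.random.default_rng(seed + 1_000_003)
        drop = set(rng.choice(neuronal_idx, size=patient_drop_sources,
                              replace=False).tolist()) if patient_drop_sources else set()
        sources = tuple(s for j, s in enumerate(spec.sources) if j not in drop)
        pspec = replace(
            spec,
            sources=sources,
            group_amplitude_scale=spec.group_amplitude_scale * patient_amplitude_scale,
        )
        series, truth = generate_subject(pspec, seed)
        subjects.append(PhantomSubject(f"patient_{i:02d}", "patient", series, truth))
    return subjects


def generate_pet_surrogate(truth: PhantomTruth, target_r: float, seed: int) -> Volume3D:
    """A positive, SUV-like image with designed correlation to true activity.

    Built as ``r * z(activity) + sqrt(1 - r^2) * z(noise)`` on the mask and
    then mapped affinely into a positive range, so the population correlation
    with the true activity equals ``target_r`` by construction.
    """
    if not (-1.0 < target_r < 1.0):
        raise ConfigError("target_r must be in (-1, 1)")
    act = truth.true_activity.values[truth.mask]
    if act.std() == 0:
        raise DataError("constant true activity; cannot design a correlation")
    rng = np.random.default_rng(seed)
    a = (act - act.mean()) / act.std()
    e = rng.standard_normal(a.size)
    e = (e - e.mean()) / e.std()
    z = target_r * a + np.sqrt(1.0 - target_r**2) * e
    suv = 1.0 + 0.5 * (z - z.min())
    values = np.zeros(truth.grid.shape)
    values[truth.mask] = suv
    return Volume3D(truth.grid, values)


def templates_from_spec(spec: PhantomSpec, level: float = 0.5) -> TemplateSet:
    """Canonical template set from the spec's neuronal source geometry.

    Shared across a whole cohort (like a published network atlas), so it is
    independent of any one subject's realized sources.
    """
    grid = spec.grid
    mask = ellipsoid_mask(grid)
    names, masks = [], []
    for j, src in enumerate(spec.sources):
        if not src.neuronal:
            continue
        m = _blob(grid, src) * mask
        masks.append((m >= level * m.max()) & mask)
        names.append(f"network_{j}")
    if not masks:
        raise DataError("spec has no neuronal sources")
    return TemplateSet(grid, names, np.stack(masks))


def atlas_from_spec(spec: PhantomSpec, level: float = 0.5) -> LabelAtlas:
    """Canonical ROI atlas (one region per source core) from the spec geometry."""
    grid = spec.grid
    mask = ellipsoid_mask(grid)
    labels = np.zeros(grid.shape, dtype=int)
    names: dict[int, str] = {}
    for j, src in enumerate(spec.sources):
        m = _blob(grid, src) * mask
        region = (m >= level * m.max()) & mask & (labels == 0)
        labels[region] = j + 1
        names[j + 1] = f"source_{j}"
    return LabelAtlas(grid, labels, names)


def truth_templates(truth: PhantomTruth, level: float = 0.5) -> TemplateSet:
    """Template masks from the neuronal sources' supra-threshold support."""
    names, masks = [], []
    for j in np.flatnonzero(truth.labels_truth):
        m = truth.source_maps[j]
        template = (m >= level * m.max()) & truth.mask
        names.append(f"network_{j}")
        masks.append(template)
    if not masks:
        raise DataError("no neuronal sources to build templates from")
    return TemplateSet(truth.grid, names, np.stack(masks))


def truth_atlas(truth: PhantomTruth, level: float = 0.5) -> LabelAtlas:
    """Integer-label ROI atlas with one region per source's core support."""
    labels = np.zeros(truth.grid.shape, dtype=int)
    names: dict[int, str] = {}
    for j in range(truth.source_maps.shape[0]):
        m = truth.source_maps[j]
        region = (m >= level * m.max()) & truth.mask & (labels == 0)
        rid = j + 1
        labels[region] = rid
        names[rid] = f"source_{j}"
    return LabelAtlas(truth.grid, labels, names)
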