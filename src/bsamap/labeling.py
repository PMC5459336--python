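"""Neuronal-component identification by template matching.

Each ICA component's z-scored spatial map is scored against a set of
resting-state-network template masks with a goodness-of-fit (GoF) statistic:
the mean map value inside the template minus the mean over the rest of the
brain mask. Every template is assigned to its best-scoring component; a
component is *neuronal* when it wins at least one template with GoF at or
above threshold and its time course passes a high-frequency power screen.
Components failing the spectral screen are *non-neuronal*; everything else is
*undefined* and excluded from the neuronal count k.

The spectral screen is a deterministic stand-in for a trained per-component
classifier; externally produced labels can be plugged in via
``override_labels`` or a TSV file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .io import VolumeGrid, assert_same_grid, read_mask
from .ica import ComponentDecomposition, high_freq_power_fraction

__all__ = [
    "TemplateSet",
    "ComponentLabels",
    "load_templates",
    "gof_score",
    "gof_matrix",
    "assign_templates",
    "label_components",
    "count_neuronal",
    "NEURONAL",
    "NON_NEURONAL",
    "UNDEFINED",
]

NEURONAL = "neuronal"
NON_NEURONAL = "non-neuronal"
UNDEFINED = "undefined"


@dataclass
class TemplateSet:
    """Named resting-state-network template masks on one grid."""

    grid: VolumeGrid
    names: list[str]
    masks: np.ndarray  # (n_templates, *grid.shape) boolean

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks).astype(bool)
        if self.masks.ndim != 4 or self.masks.shape[1:] != self.grid.shape:
            raise DataError("template masks must be (n_templates, *grid.shape)")
        if len(self.names) != self.masks.shape[0]:
            raise DataError("template name count does not match mask count")
        if len(set(self.names)) != len(self.names):
            raise DataError("template names must be unique")
        if self.masks.shape[0] == 0:
            raise DataError("empty template set")
        for name, m in zip(self.names, self.masks):
            if not m.any():
                raise DataError(f"template '{name}' is empty")

    @property
    def n_templates(self) -> int:
        return int(self.masks.shape[0])


def load_templates(directory: str | Path, tsv_path: str | Path | None = None) -> TemplateSet:
    """Load a directory of 3D NIfTI masks; optional TSV gives (filename, name)."""
    directory = Path(directory)
    if tsv_path is not None:
        table = pd.read_csv(tsv_path, sep="\t")
        entries = [(directory / f, str(n)) for f, n in zip(table.iloc[:, 0], table.iloc[:, 1])]
    else:
        files = sorted(directory.glob("*.nii*"))
        entries = [(f, f.name.split(".nii")[0]) for f in files]
    if not entries:
        raise DataError(f"no templates found in {directory}")
    grids, masks, names = [], [], []
    for path, name in entries:
        grid, mask = read_mask(path)
        grids.append(grid)
        masks.append(mask)
        names.append(name)
    for g in grids[1:]:
        assert_same_grid(grids[0], g)
    return TemplateSet(grids[0], names, np.stack(masks))


@dataclass
class ComponentLabels:
    """Per-component template scores, assignments, and neuronal labels."""

    gof: np.ndarray  # (n_components, n_templates)
    assignment: dict[str, int]  # template name -> component index
    labels: np.ndarray  # (n_components,) str in {neuronal, non-neuronal, undefined}
    hf_fractions: np.ndarray  # (n_components,)
    template_names: list[str] = field(default_factory=list)

    @property
    def k(self) -> int:
        return int((self.labels == NEURONAL).sum())

    @property
    def neuronal_indices(self) -> np.ndarray:
        return np.flatnonzero(self.labels == NEURONAL)

    def to_frame(self) -> pd.DataFrame:
        n = len(self.labels)
        assigned = [
            ",".join(sorted(t for t, c in self.assignment.items() if c == j))
            for j in range(n)
        ]
        best_gof = self.gof.max(axis=1) if self.gof.size else np.full(n, np.nan)
        return pd.DataFrame(
            {
                "component": np.arange(n),
                "assigned_templates": assigned,
                "gof": best_gof,
                "hf_fraction": self.hf_fractions,
                "label": self.labels,
            }
        )


def gof_score(map_values: np.ndarray, template: np.ndarray, mask: np.ndarray,
              absolute: bool = False) -> float:
    """Goodness of fit of a spatial map to a template within a brain mask.

    GoF = mean(map inside template) - mean(map over mask outside template).
    With ``absolute=True`` the map's absolute values are scored instead
    (treats deactivation as fit).
    """
    template = np.asarray(template).astype(bool)
    mask = np.asarray(mask).astype(bool)
    vals = np.asarray(map_values, dtype=float)
    if template.shape != mask.shape or vals.shape != mask.shape:
        raise DataError("map, template, and mask must share a shape")
    if (template & ~mask).any():
        raise DataError("template must be a subset of the brain mask")
    inside = template
    outside = mask & ~template
    if not inside.any():
        raise DataError("template is empty")
    if not outside.any():
        raise DataError("template covers the whole mask; GoF undefined")
    if absolute:
        vals = np.abs(vals)
    return float(vals[inside].mean() - vals[outside].mean())


def gof_matrix(dec: ComponentDecomposition, tset: TemplateSet,
               absolute: bool = False) -> np.ndarray:
    """(n_components, n_templates) GoF scores of z-scored maps vs templates."""
    assert_same_grid(dec.grid, tset.grid)
    out = np.zeros((dec.n_components, tset.n_templates))
    for j in range(dec.n_components):
        vol = dec.map_volume(j)
        for t in range(tset.n_templates):
            out[j, t] = gof_score(vol, tset.masks[t], dec.mask, absolute=absolute)
    return out


def assign_templates(gof: np.ndarray, template_names: list[str] | None = None) -> dict[str, int]:
    """Assign each template to its highest-GoF component.

    Ties break toward the lowest component index. Several templates may share
    one component; each template is assigned to exactly one.
    """
    gof = np.asarray(gof, dtype=float)
    if gof.size == 0:
        raise DataError("empty GoF matrix")
    if not np.all(np.isfinite(gof)):
        raise DataError("non-finite GoF scores")
    n_templates = gof.shape[1]
    names = template_names or [f"template_{t}" for t in range(n_templates)]
    return {names[t]: int(np.argmax(gof[:, t])) for t in range(n_templates)}


def label_components(
    dec: ComponentDecomposition,
    tset: TemplateSet,
    tr_seconds: float,
    gof_threshold: float = 0.0,
    hf_threshold: float = 0.5,
    hf_cutoff_hz: float = 0.1,
    absolute_gof: bool = False,
    override_labels: np.ndarray | str | Path | None = None,
) -> ComponentLabels:
    """Label every component neuronal / non-neuronal / undefined.

    A component is neuronal iff it is the assigned winner of >= 1 template,
    that template's GoF meets ``gof_threshold``, and the fraction of its
    time-course power above ``hf_cutoff_hz`` is <= ``hf_threshold``. Failing
    the spectral screen makes it non-neuronal regardless of template fit.

    ``override_labels`` (array of label strings, or TSV with columns
    component/label) replaces the rule-based labels wholesale — the plug-in
    point for an external component classifier.
    """
    gof = gof_matrix(dec, tset, absolute=absolute_gof)
    assignment = assign_templates(gof, tset.names)
    hf = np.array(
        [high_freq_power_fraction(dec.time_courses[j], tr_seconds, hf_cutoff_hz)
         for j in range(dec.n_components)]
    )
    if override_labels is not None:
        if isinstance(override_labels, (str, Path)):
            table = pd.read_csv(override_labels, sep="\t")
            labels = np.full(dec.n_components, UNDEFINED, dtype=object)
            labels[table["component"].to_numpy(int)] = table["label"].to_numpy(str)
        else:
            labels = np.asarray(override_labels, dtype=object)
        if len(labels) != dec.n_components:
            raise DataError("override labels length != n_components")
        bad = set(labels) - {NEURONAL, NON_NEURONAL, UNDEFINED}
        if bad:
            raise DataError(f"unknown labels in override: {sorted(bad)}")
    else:
        labels = np.full(dec.n_components, UNDEFINED, dtype=object)
        for j in range(dec.n_components):
            passes_spectrum = hf[j] <= hf_threshold
            won_templates = [t for t, name in enumerate(tset.names)
                             if assignment[name] == j]
            template_ok = any(gof[j, t] >= gof_threshold for t in won_templates)
            if not passes_spectrum:
                labels[j] = NON_NEURONAL
            elif won_templates and template_ok:
                labels[j] = NEURONAL
            else:
                labels[j] = UNDEFINED
    labels = labels.astype(object)
    return ComponentLabels(
        gof=gof,
        assignment=assignment,
        labels=labels,
        hf_fractions=hf,
        template_names=list(tset.names),
    )


def count_neuronal(labels: ComponentLabels) -> int:
    """Number of neuronal components, k (a component counts once even when
    several templates map to it)."""
    return labels.k
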