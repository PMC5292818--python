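"""Between-group component selection, Z-maps, binary templates and features.

Components whose mixing weights separate the two reference groups (pooled
two-sample t, Bonferroni-corrected) are converted to Z-score maps and
binarised at ``Z >= 3.0`` (inclusive, positive tail) to form network
templates.  Template-mean features are then extracted from an independent
cohort: one column per template, named ``{modality}_IC_{id:02d}``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ica import Decomposition
from .imaging import SubjectMatrix

__all__ = [
    "NetworkTemplate",
    "compare_loadings",
    "bonferroni_select",
    "zscore_map",
    "binarize_template",
    "make_template",
    "select_networks",
    "extract_network_features",
]

DEFAULT_Z_THRESHOLD = 3.0


@dataclass
class NetworkTemplate:
    """Binary voxel mask from a Z-thresholded component map."""

    mask: np.ndarray
    component_id: int
    modality: str
    z_threshold: float = DEFAULT_Z_THRESHOLD
    t_stat: float = np.nan
    p_value: float = np.nan

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def usable(self) -> bool:
        return bool(self.mask.any())

    @property
    def name(self) -> str:
        return f"{self.modality}_IC_{self.component_id:02d}"


def compare_loadings(
    decomposition: Decomposition,
    labels,
    equal_var: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-component two-sample t-test on mixing-matrix columns.

    Pooled-variance (Student) t by default, with ``n1 + n2 - 2`` degrees of
    freedom; set ``equal_var=False`` for Welch.  Returns ``(t, p)`` arrays.
    Components with zero pooled variance get ``t = 0, p = 1`` with a warning.
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {list(groups)}")
    a = decomposition.mixing[labels == groups[0]]
    b = decomposition.mixing[labels == groups[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 subjects")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=equal_var)
    t, p = np.asarray(t, dtype=float), np.asarray(p, dtype=float)
    bad = ~np.isfinite(t)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} component(s) with zero pooled variance; "
            "setting t=0, p=1",
            RuntimeWarning,
        )
        t[bad], p[bad] = 0.0, 1.0
    return t, p


def bonferroni_select(p_values, alpha: float = 0.05) -> np.ndarray:
    """Indices with ``p < alpha / k`` (k = number of tests).

    An empty selection is valid and returned as an empty array.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    p = np.asarray(p_values, dtype=float)
    return np.flatnonzero(p < alpha / p.size)


def zscore_map(source_row: np.ndarray) -> np.ndarray:
    """Standardise a source's voxel values: (v - mean) / population SD."""
    v = np.asarray(source_row, dtype=float)
    sd = v.std(ddof=0)
    if sd == 0:
        raise ValueError("constant source row has no Z-map")
    return (v - v.mean()) / sd


def binarize_template(zmap: np.ndarray, z_threshold: float = DEFAULT_Z_THRESHOLD) -> np.ndarray:
    """Boolean mask ``Z >= threshold`` (inclusive boundary, positive tail)."""
    if z_threshold <= 0:
        raise ValueError("z_threshold must be positive")
    return np.asarray(zmap, dtype=float) >= z_threshold


def make_template(
    source_row: np.ndarray,
    analysis_mask: np.ndarray,
    component_id: int,
    modality: str,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    t_stat: float = np.nan,
    p_value: float = np.nan,
) -> NetworkTemplate:
    """Z-score a source row and embed the thresholded mask in 3-D.

    ``source_row`` is the in-mask voxel vector of one component;
    ``analysis_mask`` supplies the 3-D geometry.  Empty templates are
    returned flagged unusable (``usable`` is False) with a warning.
    """
    analysis_mask = np.asarray(analysis_mask, dtype=bool)
    flat = binarize_template(zscore_map(source_row), z_threshold)
    mask3d = np.zeros(analysis_mask.shape, dtype=bool)
    mask3d.ravel(order="C")[np.flatnonzero(analysis_mask.ravel(order="C"))] = flat
    tpl = NetworkTemplate(
        mask=mask3d,
        component_id=component_id,
        modality=modality,
        z_threshold=z_threshold,
        t_stat=t_stat,
        p_value=p_value,
    )
    if not tpl.usable:
        warnings.warn(
            f"template {tpl.name}: no voxel reaches Z >= {z_threshold}; "
            "flagged unusable",
            RuntimeWarning,
        )
    return tpl


def select_networks(
    decomposition: Decomposition,
    labels,
    analysis_mask: np.ndarray,
    modality: str,
    alpha: float = 0.05,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    equal_var: bool = True,
) -> tuple[list[NetworkTemplate], pd.DataFrame]:
    """Full selection stage: t-tests, Bonferroni, Z-maps, templates.

    Returns the usable templates of selected components plus a per-component
    report table (component_id, t, p, selected flag).
    """
    t, p = compare_loadings(decomposition, labels, equal_var=equal_var)
    selected = bonferroni_select(p, alpha)
    report = pd.DataFrame(
        {
            "component_id": np.arange(len(p)),
            "t": t,
            "p": p,
            "selected": np.isin(np.arange(len(p)), selected),
        }
    )
    templates = []
    for idx in selected:
        tpl = make_template(
            decomposition.sources[idx],
            analysis_mask,
            component_id=int(idx),
            modality=modality,
            z_threshold=z_threshold,
            t_stat=float(t[idx]),
            p_value=float(p[idx]),
        )
        if tpl.usable:
            templates.append(tpl)
    return templates, report


def extract_network_features(
    cohort: SubjectMatrix,
    templates: list[NetworkTemplate],
) -> pd.DataFrame:
    """Template-mean features: mean in-template voxel value per subject.

    All template voxels must lie inside the cohort's analysis mask; empty
    templates are rejected.  Returns a table keyed by ``subject_id`` with one
    column per template (``{modality}_IC_{id:02d}``).
    """
    features = {}
    cohort_flat = cohort.flat_indices
    for tpl in templates:
        if not tpl.usable:
            raise ValueError(f"template {tpl.name} is empty")
        if tpl.mask.shape != cohort.mask.shape:
            raise ValueError(
                f"template {tpl.name} geometry {tpl.mask.shape} does not match "
                f"cohort mask {cohort.mask.shape}"
            )
        tpl_flat = np.flatnonzero(tpl.mask.ravel(order="C"))
        col_pos = np.searchsorted(cohort_flat, tpl_flat)
        if (
            col_pos.max(initial=-1) >= cohort_flat.size
            or not np.array_equal(cohort_flat[col_pos], tpl_flat)
        ):
            raise ValueError(
                f"template {tpl.name} has voxels outside the cohort mask"
            )
        if tpl.name in features:
            raise ValueError(f"duplicate feature column {tpl.name}")
        features[tpl.name] = cohort.data[:, col_pos].mean(axis=1)
    out = pd.DataFrame(features, index=pd.Index(cohort.subject_ids, name="subject_id"))
    return out
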