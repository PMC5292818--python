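"""Synthetic cohort generators with retained ground truth.

The reference cohort mimics a two-group (patient/control) image set generated
as a linear mixture of near-orthogonal spatial sources, with group-shifted
mixing weights on a designated subset of components.  The survival cohort adds
a correlated clinical table and proportional-hazards conversion times censored
at a fixed horizon (36 months by default).

Component indices are 0-based throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .imaging import SubjectMatrix

__all__ = [
    "SourceAtlas",
    "GroundTruth",
    "ClinicalParams",
    "make_source_atlas",
    "simulate_reference_cohort",
    "simulate_survival_cohort",
    "simulate_study",
    "StudyData",
    "write_cohort",
    "write_ground_truth",
]

#: largest pairwise |cosine| tolerated between source maps
MAX_SOURCE_COSINE = 0.3


@dataclass
class SourceAtlas:
    """Spatial source maps (components x voxels) on a 3-D grid.

    Each map has unit Euclidean norm; maps are pairwise near-orthogonal
    (|cosine| < 0.3).  ``affected_ids`` marks the components that carry
    group and risk effects.
    """

    n_components: int
    grid_dims: tuple[int, int, int]
    source_maps: np.ndarray
    affected_ids: frozenset[int]

    def __post_init__(self) -> None:
        self.source_maps = np.asarray(self.source_maps, dtype=np.float64)
        self.affected_ids = frozenset(int(i) for i in self.affected_ids)
        k, v = self.source_maps.shape
        if k != self.n_components:
            raise ValueError("source_maps rows != n_components")
        if v != int(np.prod(self.grid_dims)):
            raise ValueError("source_maps columns != grid voxel count")
        norms = np.linalg.norm(self.source_maps, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("source maps must have unit norm")
        if not self.affected_ids <= set(range(self.n_components)):
            raise ValueError("affected_ids outside component range")

    def pairwise_cosines(self) -> np.ndarray:
        """Upper-triangle cosine similarities between source maps."""
        g = self.source_maps @ self.source_maps.T
        iu = np.triu_indices(self.n_components, k=1)
        return g[iu]


@dataclass
class GroundTruth:
    """Everything the generators know that the analysis must recover."""

    true_mixing: np.ndarray
    group_shift: float | None = None
    true_beta: dict[str, float] = field(default_factory=dict)
    baseline_rate: float | None = None
    censor_month: float = 36.0

    def __post_init__(self) -> None:
        if self.censor_month <= 0:
            raise ValueError("censor_month must be positive")
        if self.baseline_rate is not None and self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")


@dataclass
class ClinicalParams:
    """Sampling distributions for the clinical covariates.

    Defaults follow the demographics of a typical amnestic-MCI cohort
    (age ~73y, education ~16y, MMSE ~27, ADAS-cog ~11, CDR-SB ~1.5,
    ~62% male, APOE e4 allele frequencies ~0.44/0.43/0.13).
    """

    age_mean: float = 73.4
    age_sd: float = 7.4
    education_mean: float = 16.0
    education_sd: float = 2.6
    mmse_mean: float = 27.4
    mmse_sd: float = 1.8
    adas_mean: float = 10.9
    adas_sd: float = 4.9
    cdr_sb_mean: float = 1.5
    cdr_sb_sd: float = 0.9
    p_male: float = 0.62
    apoe_probs: tuple[float, float, float] = (0.44, 0.43, 0.13)
    #: correlation injected between ADAS-cog, CDR-SB and (negated) MMSE
    cognitive_corr: float = 0.5


def sample_clinical(params: ClinicalParams, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Draw a complete clinical table with correlated cognitive scores."""
    # shared latent severity factor couples the three cognitive scales
    rho = params.cognitive_corr
    latent = rng.standard_normal(n)
    mix = lambda: np.sqrt(rho) * latent + np.sqrt(1 - rho) * rng.standard_normal(n)
    adas = np.clip(params.adas_mean + params.adas_sd * mix(), 0.0, 70.0)
    cdr_sb = np.clip(params.cdr_sb_mean + params.cdr_sb_sd * mix(), 0.0, 18.0)
    mmse = np.clip(np.rint(params.mmse_mean - params.mmse_sd * mix()), 0, 30)
    table = pd.DataFrame(
        {
            "apoe_e4": rng.choice(3, size=n, p=np.asarray(params.apoe_probs)),
            "adas_cog": np.round(adas, 2),
            "cdr_sb": np.round(cdr_sb * 2) / 2.0,  # half-point scale
            "mmse": mmse.astype(int),
            "age": np.round(rng.normal(params.age_mean, params.age_sd, n), 1),
            "gender": (rng.random(n) < params.p_male).astype(int),
            "education": np.clip(
                np.rint(rng.normal(params.education_mean, params.education_sd, n)), 6, 20
            ).astype(int),
        }
    )
    return table


def _blob(grid: tuple[int, int, int], center: np.ndarray, radius: float) -> np.ndarray:
    """Gaussian blob (sigma = radius/2) truncated at 2.5 sigma, flattened C-order."""
    axes = np.ogrid[tuple(slice(0, d) for d in grid)]
    d2 = sum((ax - c) ** 2 for ax, c in zip(axes, center))
    sigma = radius / 2.0
    blob = np.exp(-d2 / (2.0 * sigma**2))
    blob[d2 > (2.5 * radius / 2.0 * 2.0) ** 2] = 0.0  # truncate far tail
    return blob.ravel(order="C")


def make_source_atlas(
    n_components: int,
    grid_dims: tuple[int, int, int],
    blob_radius: float = 2.0,
    seed: int = 0,
) -> SourceAtlas:
    """Place ``n_components`` non-overlapping smoothed spherical blobs.

    Centers are drawn at random (seeded) with a minimum pairwise distance of
    twice the blob radius; the resulting unit-norm maps are pairwise
    near-orthogonal.  Raises ``ValueError`` if the grid cannot host the
    requested number of blobs.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    grid_dims = tuple(int(d) for d in grid_dims)
    margin = blob_radius
    if any(d <= 2 * margin for d in grid_dims):
        raise ValueError(
            f"grid {grid_dims} too small for blobs of radius {blob_radius}"
        )
    rng = np.random.default_rng(seed)
    min_dist = 2.0 * blob_radius + 1.0
    centers: list[np.ndarray] = []
    # rejection sampling with restarts: early picks can block the rest
    for _ in range(500):
        centers = []
        for _ in range(500):
            cand = np.array(
                [rng.uniform(margin, d - 1 - margin) for d in grid_dims]
            )
            if all(np.linalg.norm(cand - c) >= min_dist for c in centers):
                centers.append(cand)
                if len(centers) == n_components:
                    break
        if len(centers) == n_components:
            break
    else:
        raise ValueError(
            f"grid {grid_dims} too small to place {n_components} "
            f"non-overlapping blobs of radius {blob_radius}"
        )
    maps = np.stack([_blob(grid_dims, c, blob_radius) for c in centers])
    maps /= np.linalg.norm(maps, axis=1, keepdims=True)
    # affected components default to the first half (at least one)
    n_affected = max(1, n_components // 2)
    atlas = SourceAtlas(
        n_components=n_components,
        grid_dims=grid_dims,
        source_maps=maps,
        affected_ids=frozenset(range(n_affected)),
    )
    cos = np.abs(atlas.pairwise_cosines())
    if cos.size and cos.max() >= MAX_SOURCE_COSINE:
        raise ValueError(
            f"source maps not near-orthogonal (max |cosine| {cos.max():.3f}); "
            "increase grid size or reduce blob radius"
        )
    return atlas


#: loading scale shared by the generators; sources are unit-norm so this sets
#: the signal RMS relative to noise_sd
LOADING_MEAN = 4.0
LOADING_SD = 1.0


def simulate_reference_cohort(
    atlas: SourceAtlas,
    n_per_group: int,
    group_shift: float = 1.5,
    noise_sd: float = 0.05,
    seed: int = 0,
    modality: str = "structural",
) -> tuple[SubjectMatrix, GroundTruth]:
    """Two-group cohort: data = mixing @ source_maps + Gaussian noise.

    The patient group's mean loading on each affected component is reduced by
    ``group_shift`` (patients have *less* signal in affected networks).
    Group labels are balanced: ``control`` then ``patient``.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    mixing = rng.normal(LOADING_MEAN, LOADING_SD, size=(n, atlas.n_components))
    affected = sorted(atlas.affected_ids)
    mixing[n_per_group:, affected] -= group_shift
    data = mixing @ atlas.source_maps
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    labels = np.array(["control"] * n_per_group + ["patient"] * n_per_group)
    matrix = SubjectMatrix(
        data=data,
        mask=np.ones(atlas.grid_dims, dtype=bool),
        subject_ids=[f"ref-{i:04d}" for i in range(n)],
        group_labels=labels,
        modality=modality,
    )
    truth = GroundTruth(true_mixing=mixing, group_shift=group_shift)
    return matrix, truth


def _component_column(modality: str, idx: int) -> str:
    return f"{modality}_comp_{idx:02d}"


def simulate_survival_cohort(
    atlas: SourceAtlas,
    true_beta: dict[str, float] | None = None,
    baseline_rate: float = 0.05,
    censor_month: float = 36.0,
    n: int = 200,
    seed: int = 0,
    clinical_params: ClinicalParams | None = None,
    noise_sd: float = 0.05,
    modality: str = "structural",
) -> tuple[SubjectMatrix, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Single-group cohort with proportional-hazards conversion times.

    The linear predictor is ``eta = sum_j beta_j * (x_j - mean(x_j))`` over the
    named covariates, which may be clinical columns or component loadings
    (named ``{modality}_comp_{j:02d}``).  Event times are drawn by inverse
    transform from the exponential hazard ``baseline_rate * exp(eta)``;
    times beyond ``censor_month`` are stored as censored records with
    ``time_months == censor_month`` exactly.

    Returns (image matrix, clinical table, survival table, ground truth).
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    if censor_month <= 0:
        raise ValueError("censor_month must be positive")
    if baseline_rate <= 0:
        raise ValueError("baseline_rate must be positive (all-zero hazard rejected)")
    rng = np.random.default_rng(seed)
    true_beta = dict(true_beta or {})
    clinical_params = clinical_params or ClinicalParams()

    loadings = rng.normal(LOADING_MEAN, LOADING_SD, size=(n, atlas.n_components))
    clinical = sample_clinical(clinical_params, n, rng)
    subject_ids = [f"mci-{i:04d}" for i in range(n)]
    clinical.insert(0, "subject_id", subject_ids)

    covariates = clinical.set_index("subject_id").astype(float)
    for j in range(atlas.n_components):
        covariates[_component_column(modality, j)] = loadings[:, j]

    eta = np.zeros(n)
    for name, beta in true_beta.items():
        if name not in covariates.columns:
            raise KeyError(f"true_beta names unknown covariate {name!r}")
        x = covariates[name].to_numpy()
        eta += beta * (x - x.mean())

    raw_time = rng.exponential(1.0, size=n) / (baseline_rate * np.exp(eta))
    event = raw_time <= censor_month
    time = np.where(event, np.maximum(np.round(raw_time, 1), 0.1), censor_month)

    survival = pd.DataFrame(
        {"subject_id": subject_ids, "time_months": time, "event": event}
    )
    matrix = SubjectMatrix(
        data=loadings @ atlas.source_maps
        + (rng.normal(0.0, noise_sd, size=(n, atlas.source_maps.shape[1])) if noise_sd > 0 else 0.0),
        mask=np.ones(atlas.grid_dims, dtype=bool),
        subject_ids=subject_ids,
        group_labels=np.where(event, "converter", "nonconverter"),
        modality=modality,
    )
    truth = GroundTruth(
        true_mixing=loadings,
        true_beta=true_beta,
        baseline_rate=baseline_rate,
        censor_month=censor_month,
    )
    return matrix, clinical, survival, truth


@dataclass
class StudyData:
    """A full two-modality synthetic study (reference + survival cohorts)."""

    atlases: dict[str, SourceAtlas]
    reference: dict[str, SubjectMatrix]
    reference_truth: dict[str, GroundTruth]
    survival_images: dict[str, SubjectMatrix]
    clinical: pd.DataFrame
    survival: pd.DataFrame
    truth: GroundTruth


def simulate_study(
    seed: int = 0,
    grid_dims: tuple[int, int, int] = (12, 12, 12),
    n_components: int = 4,
    blob_radius: float = 2.0,
    n_per_group: int = 30,
    group_shift: float = 1.5,
    noise_sd: float = 0.05,
    n_survival: int = 200,
    image_beta: float = -1.0,
    clinical_beta: dict[str, float] | None = None,
    baseline_rate: float = 0.05,
    censor_month: float = 36.0,
    clinical_params: ClinicalParams | None = None,
    modalities: tuple[str, ...] = ("structural", "metabolic"),
) -> StudyData:
    """Generate reference and survival cohorts for both modalities at once.

    Every affected component of every modality carries a loading effect of
    ``image_beta`` on the log hazard; ``clinical_beta`` adds clinical effects
    (default: ADAS-cog 0.10, CDR-SB 0.4, APOE 0.6).  A single survival
    outcome is shared across modalities.
    """
    if clinical_beta is None:
        clinical_beta = {"adas_cog": 0.10, "cdr_sb": 0.4, "apoe_e4": 0.6}
    root = np.random.default_rng(seed)
    seeds = {m: int(root.integers(2**31)) for m in modalities}
    surv_seed = int(root.integers(2**31))

    atlases, reference, ref_truth = {}, {}, {}
    for m in modalities:
        atlases[m] = make_source_atlas(
            n_components, grid_dims, blob_radius, seed=seeds[m]
        )
        reference[m], ref_truth[m] = simulate_reference_cohort(
            atlases[m], n_per_group, group_shift, noise_sd, seed=seeds[m] + 1,
            modality=m,
        )

    # one shared survival cohort: draw loadings per modality, one hazard
    rng = np.random.default_rng(surv_seed)
    loadings = {
        m: rng.normal(LOADING_MEAN, LOADING_SD, size=(n_survival, n_components))
        for m in modalities
    }
    clinical = sample_clinical(clinical_params or ClinicalParams(), n_survival, rng)
    subject_ids = [f"mci-{i:04d}" for i in range(n_survival)]
    clinical.insert(0, "subject_id", subject_ids)

    true_beta = dict(clinical_beta)
    eta = np.zeros(n_survival)
    for name, beta in clinical_beta.items():
        x = clinical[name].to_numpy(dtype=float)
        eta += beta * (x - x.mean())
    for m in modalities:
        for j in sorted(atlases[m].affected_ids):
            name = _component_column(m, j)
            true_beta[name] = image_beta
            x = loadings[m][:, j]
            eta += image_beta * (x - x.mean())

    raw_time = rng.exponential(1.0, size=n_survival) / (baseline_rate * np.exp(eta))
    event = raw_time <= censor_month
    time = np.where(event, np.maximum(np.round(raw_time, 1), 0.1), censor_month)
    survival = pd.DataFrame(
        {"subject_id": subject_ids, "time_months": time, "event": event}
    )

    survival_images = {}
    for m in modalities:
        data = loadings[m] @ atlases[m].source_maps
        if noise_sd > 0:
            data = data + rng.normal(0.0, noise_sd, size=data.shape)
        survival_images[m] = SubjectMatrix(
            data=data,
            mask=np.ones(grid_dims, dtype=bool),
            subject_ids=subject_ids,
            group_labels=np.where(event, "converter", "nonconverter"),
            modality=m,
        )

    truth = GroundTruth(
        true_mixing=np.hstack([loadings[m] for m in modalities]),
        true_beta=true_beta,
        baseline_rate=baseline_rate,
        censor_month=censor_month,
    )
    return StudyData(
        atlases=atlases,
        reference=reference,
        reference_truth=ref_truth,
        survival_images=survival_images,
        clinical=clinical,
        survival=survival,
        truth=truth,
    )


def write_cohort(matrix: SubjectMatrix, out_dir: str | Path) -> Path:
    """Write a cohort as per-subject NIfTI volumes plus a labels CSV."""
    from .imaging import ImageVolume, write_volume, unstack_subject

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for i, sid in enumerate(matrix.subject_ids):
        write_volume(
            ImageVolume(unstack_subject(matrix, i)), out_dir / f"{sid}.nii"
        )
    write_volume(
        ImageVolume(matrix.mask.astype(np.float64)), out_dir / "mask.nii"
    )
    pd.DataFrame(
        {"subject_id": matrix.subject_ids, "group": matrix.group_labels}
    ).to_csv(out_dir / "subjects.csv", index=False)
    return out_dir


def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = asdict(truth)
    payload["true_mixing"] = np.asarray(truth.true_mixing).tolist()
    path.write_text(json.dumps(payload, indent=2))
    return path
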