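"""Pipeline orchestration: data -> ICA -> selection -> Cox suite -> ROC.

A run is driven by a flat TOML configuration with exactly one data source:
a ``[synthetic]`` block (all generator parameters and seeds) or an
``[inputs]`` block pointing at cohorts on disk.  Every stage writes its
artifacts under the output directory, so downstream stages can be re-run
from disk without recomputation; the JSON report embeds the config hash and
per-stage provenance.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time as _time
import tomllib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import cox, evaluation, ica, selection, synthetic
from .imaging import ImageVolume, SubjectMatrix, read_volume, write_volume

__all__ = [
    "default_config",
    "load_config",
    "validate_config",
    "config_hash",
    "run_pipeline",
    "PipelineReport",
]

log = logging.getLogger("icasurv")

MODALITIES = ("structural", "metabolic")


def default_config() -> dict:
    """A complete, runnable synthetic configuration."""
    return {
        "seed": 0,
        "output_dir": "icasurv_out",
        "synthetic": {
            "grid_dims": [12, 12, 12],
            "n_components": 4,
            "blob_radius": 2.0,
            "n_per_group": 30,
            "group_shift": 1.5,
            "noise_sd": 0.05,
            "n_survival": 200,
            "image_beta": -1.0,
            "clinical_beta": {"adas_cog": 0.10, "cdr_sb": 0.4, "apoe_e4": 0.6},
            "baseline_rate": 0.05,
            "censor_month": 36.0,
        },
        "ica": {"order": 0, "tol": 1e-6, "max_iter": 512, "seed": 0},
        "selection": {"alpha": 0.05, "z_threshold": 3.0},
        "cox": {"tie_method": "breslow", "alpha": 0.05, "apoe_binary": False},
        "evaluation": {"rule": "youden", "threshold": 0.5},
    }


def load_config(path: str | Path) -> dict:
    """Read a TOML config and fill unspecified fields with defaults."""
    with open(path, "rb") as fh:
        user = tomllib.load(fh)
    cfg = default_config()
    if "inputs" in user:
        cfg.pop("synthetic", None)
    for key, value in user.items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def validate_config(cfg: dict) -> list[str]:
    """Return a list of problems; empty iff the config is runnable."""
    problems = []
    has_syn = "synthetic" in cfg
    has_inp = "inputs" in cfg
    if has_syn == has_inp:
        problems.append(
            "exactly one of [synthetic] and [inputs] must be present"
        )
    if "seed" not in cfg:
        problems.append("seed: missing (all seeds must be explicit)")
    if "output_dir" not in cfg:
        problems.append("output_dir: missing")
    ica_cfg = cfg.get("ica", {})
    if "seed" not in ica_cfg:
        problems.append("ica.seed: missing")
    alpha = cfg.get("selection", {}).get("alpha", 0.05)
    if not 0 < alpha < 1:
        problems.append(f"selection.alpha: must be in (0,1), got {alpha}")
    z = cfg.get("selection", {}).get("z_threshold", 3.0)
    if z <= 0:
        problems.append(f"selection.z_threshold: must be positive, got {z}")
    tie = cfg.get("cox", {}).get("tie_method", "breslow")
    if tie not in ("breslow", "efron"):
        problems.append(f"cox.tie_method: unknown method {tie!r}")
    rule = cfg.get("evaluation", {}).get("rule", "youden")
    if rule not in ("youden", "fixed"):
        problems.append(f"evaluation.rule: unknown rule {rule!r}")
    if has_syn:
        syn = cfg["synthetic"]
        if syn.get("n_survival", 200) < 10:
            problems.append("synthetic.n_survival: must be >= 10")
        if syn.get("baseline_rate", 0.05) <= 0:
            problems.append("synthetic.baseline_rate: must be positive")
    if has_inp:
        inp = cfg["inputs"]
        for key in ("reference_dir", "survival_dir", "clinical_csv", "survival_csv"):
            if key not in inp:
                problems.append(f"inputs.{key}: missing")
    return problems


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


@dataclass
class PipelineReport:
    """Machine-readable run summary aggregating all stage outputs."""

    config: dict
    config_hash: str
    stages: dict
    selection: dict
    cox_models: dict
    carried_forward: dict
    metrics: list

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "config_hash": self.config_hash,
                "stages": self.stages,
                "selection": self.selection,
                "cox_models": self.cox_models,
                "carried_forward": self.carried_forward,
                "metrics": self.metrics,
            },
            indent=2,
            default=str,
        )


# ---------------------------------------------------------------------------
# stage: data

def _load_cohort_dir(path: Path, modality: str) -> SubjectMatrix:
    table = pd.read_csv(path / "subjects.csv")
    mask = read_volume(path / "mask.nii").voxels > 0.5
    volumes = [read_volume(path / f"{sid}.nii") for sid in table["subject_id"]]
    from .imaging import stack_cohort

    return stack_cohort(
        volumes, mask, list(table["subject_id"]), table["group"].to_numpy(), modality
    )


def stage_data(cfg: dict, out: Path) -> dict:
    """Generate (or load) both cohorts; write them under ``out/data``."""
    data_dir = out / "data"
    if "synthetic" in cfg:
        syn = cfg["synthetic"]
        study = synthetic.simulate_study(
            seed=cfg["seed"],
            grid_dims=tuple(syn["grid_dims"]),
            n_components=syn["n_components"],
            blob_radius=syn["blob_radius"],
            n_per_group=syn["n_per_group"],
            group_shift=syn["group_shift"],
            noise_sd=syn["noise_sd"],
            n_survival=syn["n_survival"],
            image_beta=syn["image_beta"],
            clinical_beta=dict(syn["clinical_beta"]),
            baseline_rate=syn["baseline_rate"],
            censor_month=syn["censor_month"],
        )
        for m in MODALITIES:
            synthetic.write_cohort(study.reference[m], data_dir / f"{m}_reference")
            synthetic.write_cohort(study.survival_images[m], data_dir / f"{m}_survival")
        study.clinical.to_csv(data_dir / "clinical.csv", index=False)
        study.survival.to_csv(data_dir / "survival.csv", index=False)
        synthetic.write_ground_truth(study.truth, data_dir / "ground_truth.json")
        return {
            "reference": study.reference,
            "survival_images": study.survival_images,
            "clinical": study.clinical,
            "survival": study.survival,
        }
    inp = cfg["inputs"]
    reference = {
        m: _load_cohort_dir(Path(inp["reference_dir"]) / m, m) for m in MODALITIES
    }
    survival_images = {
        m: _load_cohort_dir(Path(inp["survival_dir"]) / m, m) for m in MODALITIES
    }
    return {
        "reference": reference,
        "survival_images": survival_images,
        "clinical": pd.read_csv(inp["clinical_csv"]),
        "survival": pd.read_csv(inp["survival_csv"]),
    }


def load_data(out: Path) -> dict:
    """Resume the data stage from artifacts on disk."""
    data_dir = out / "data"
    return {
        "reference": {
            m: _load_cohort_dir(data_dir / f"{m}_reference", m) for m in MODALITIES
        },
        "survival_images": {
            m: _load_cohort_dir(data_dir / f"{m}_survival", m) for m in MODALITIES
        },
        "clinical": pd.read_csv(data_dir / "clinical.csv"),
        "survival": pd.read_csv(data_dir / "survival.csv"),
    }


# ---------------------------------------------------------------------------
# stage: decompose

def stage_decompose(data: dict, cfg: dict, out: Path) -> dict:
    """Per-modality MDL + Infomax on the reference cohorts."""
    ica_cfg = cfg["ica"]
    dec_dir = out / "decompose"
    dec_dir.mkdir(parents=True, exist_ok=True)
    decs = {}
    for m, ref in data["reference"].items():
        order = ica_cfg.get("order") or None  # 0 means "use MDL"
        dec = ica.infomax_ica(
            ref,
            order=order,
            tol=ica_cfg["tol"],
            max_iter=ica_cfg["max_iter"],
            seed=ica_cfg["seed"],
        )
        decs[m] = dec
        cols = [f"IC_{i:02d}" for i in range(dec.n_components)]
        pd.DataFrame(dec.mixing, index=ref.subject_ids, columns=cols).to_csv(
            dec_dir / f"{m}_mixing.csv", index_label="subject_id"
        )
        np.savez(
            dec_dir / f"{m}_sources.npz",
            sources=dec.sources,
            mask=ref.mask,
            order=dec.order,
            row_means=dec.row_means,
            n_iter=dec.n_iter,
            final_update=dec.final_update,
            converged=dec.converged,
            seed=dec.seed if dec.seed is not None else -1,
        )
    return decs


def load_decompositions(data: dict, out: Path) -> dict:
    decs = {}
    for m in MODALITIES:
        mixing = pd.read_csv(out / "decompose" / f"{m}_mixing.csv", index_col=0)
        npz = np.load(out / "decompose" / f"{m}_sources.npz")
        decs[m] = ica.Decomposition(
            mixing=mixing.to_numpy(),
            sources=npz["sources"],
            order=int(npz["order"]),
            row_means=npz["row_means"],
            n_iter=int(npz["n_iter"]),
            final_update=float(npz["final_update"]),
            converged=bool(npz["converged"]),
            seed=int(npz["seed"]),
        )
    return decs


# ---------------------------------------------------------------------------
# stage: select

def stage_select(decs: dict, data: dict, cfg: dict, out: Path) -> dict:
    """Group comparison, Bonferroni selection and template construction."""
    sel_cfg = cfg["selection"]
    sel_dir = out / "select"
    (sel_dir / "templates").mkdir(parents=True, exist_ok=True)
    result = {}
    for m, dec in decs.items():
        ref = data["reference"][m]
        templates, report = selection.select_networks(
            dec,
            ref.group_labels,
            ref.mask,
            modality=m,
            alpha=sel_cfg["alpha"],
            z_threshold=sel_cfg["z_threshold"],
        )
        report.to_csv(sel_dir / f"{m}_selection.csv", index=False)
        for tpl in templates:
            write_volume(
                ImageVolume(tpl.mask.astype(np.float64)),
                sel_dir / "templates" / f"{tpl.name}.nii",
            )
        result[m] = {"templates": templates, "report": report}
        if not templates:
            log.warning("selection: no %s component survived Bonferroni", m)
    return result


def load_selection(decs: dict, data: dict, cfg: dict, out: Path) -> dict:
    sel_dir = out / "select"
    result = {}
    for m in MODALITIES:
        report = pd.read_csv(sel_dir / f"{m}_selection.csv")
        templates = []
        for _, row in report[report["selected"]].iterrows():
            cid = int(row["component_id"])
            name = f"{m}_IC_{cid:02d}"
            path = sel_dir / "templates" / f"{name}.nii"
            if not path.exists():  # was empty / unusable
                continue
            templates.append(
                selection.NetworkTemplate(
                    mask=read_volume(path).voxels > 0.5,
                    component_id=cid,
                    modality=m,
                    z_threshold=cfg["selection"]["z_threshold"],
                    t_stat=float(row["t"]),
                    p_value=float(row["p"]),
                )
            )
        result[m] = {"templates": templates, "report": report}
    return result


# ---------------------------------------------------------------------------
# stage: fit (features + Cox suite)

def _clinical_for_cox(clinical: pd.DataFrame, apoe_binary: bool) -> pd.DataFrame:
    clin = clinical.copy()
    if apoe_binary:
        clin["apoe_e4"] = (clin["apoe_e4"] > 0).astype(int)
    return clin


def stage_fit(sel: dict, data: dict, cfg: dict, out: Path) -> dict:
    """Template features on the survival cohort plus the five-model suite."""
    fit_dir = out / "fit"
    fit_dir.mkdir(parents=True, exist_ok=True)
    features = {}
    for m in MODALITIES:
        templates = sel[m]["templates"]
        if templates:
            feats = selection.extract_network_features(
                data["survival_images"][m], templates
            )
        else:
            feats = pd.DataFrame(
                index=pd.Index(data["survival_images"][m].subject_ids, name="subject_id")
            )
        feats.to_csv(fit_dir / f"features_{m}.csv")
        features[m] = feats
    clinical = _clinical_for_cox(data["clinical"], cfg["cox"]["apoe_binary"])
    suite = cox.run_model_suite(
        features["structural"],
        features["metabolic"],
        clinical,
        data["survival"],
        alpha=cfg["cox"]["alpha"],
        tie_method=cfg["cox"]["tie_method"],
    )
    for stage_name, model in suite.models.items():
        if model is not None:
            model.summary.to_csv(fit_dir / f"cox_{stage_name}.csv", index=False)
    (fit_dir / "suite.json").write_text(
        json.dumps(
            {
                "carried_forward": suite.carried_forward,
                "skipped": suite.skipped,
                "models": {
                    name: None
                    if model is None
                    else {
                        "loglik": model.loglik,
                        "loglik_null": model.loglik_null,
                        "converged": model.converged,
                        "n_events": model.n_events,
                        "n_subjects": model.n_subjects,
                        "covariates": list(model.summary["covariate"]),
                    }
                    for name, model in suite.models.items()
                },
            },
            indent=2,
        )
    )
    return {"features": features, "suite": suite}


# ---------------------------------------------------------------------------
# stage: evaluate

def stage_evaluate(fit: dict, data: dict, cfg: dict, out: Path) -> pd.DataFrame:
    """ROC metrics per model family from the logistic combination index."""
    eva_cfg = cfg["evaluation"]
    eva_dir = out / "evaluate"
    eva_dir.mkdir(parents=True, exist_ok=True)
    suite = fit["suite"]
    features = fit["features"]
    clinical = _clinical_for_cox(data["clinical"], cfg["cox"]["apoe_binary"])
    all_cov = (
        features["structural"]
        .join(features["metabolic"], how="inner")
        .join(clinical.set_index("subject_id").astype(float), how="inner")
    )
    surv = data["survival"].set_index("subject_id").loc[all_cov.index]
    labels = surv["event"].astype(int).to_numpy()

    rows = []
    for stage_name, model in suite.models.items():
        if model is None:
            continue
        factors = cox.significant_factors(model, cfg["cox"]["alpha"])
        if not factors:
            log.warning("evaluate: no significant factor in %s model", stage_name)
            continue
        roc = evaluation.evaluate_index(
            all_cov[factors], labels, rule=eva_cfg["rule"],
            threshold=eva_cfg["threshold"],
        )
        pd.DataFrame(
            {"fpr": roc.fpr, "tpr": roc.tpr, "threshold": roc.thresholds}
        ).to_csv(eva_dir / f"roc_{stage_name}.csv", index=False)
        rows.append(
            {
                "model": stage_name,
                "factors": ";".join(factors),
                "accuracy_pct": roc.accuracy,
                "sensitivity_pct": roc.sensitivity,
                "specificity_pct": roc.specificity,
                "auc": roc.auc,
            }
        )
    metrics = pd.DataFrame(rows)
    metrics.to_csv(eva_dir / "metrics.csv", index=False)
    return metrics


# ---------------------------------------------------------------------------

def run_pipeline(cfg: dict, out_dir: str | Path | None = None) -> PipelineReport:
    """Execute all stages in order and write the full report."""
    problems = validate_config(cfg)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    cfg = copy.deepcopy(cfg)
    out = Path(out_dir if out_dir is not None else cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    (out / "config_hash.txt").write_text(chash + "\n")
    (out / "config.json").write_text(json.dumps(cfg, indent=2, default=str))

    stages_meta = {}

    def timed(name, fn, *args):
        t0 = _time.perf_counter()
        log.info("stage %s: starting", name)
        try:
            result = fn(*args)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        # wall time is logged, not reported: report.json must be bit-identical
        # across reruns of the same config + seeds
        log.info(
            "stage %s: done in %.3f s", name, _time.perf_counter() - t0
        )
        stages_meta[name] = {"seed": cfg.get("seed"), "completed": True}
        return result

    data = timed("data", stage_data, cfg, out)
    decs = timed("decompose", stage_decompose, data, cfg, out)
    sel = timed("select", stage_select, decs, data, cfg, out)
    fit = timed("fit", stage_fit, sel, data, cfg, out)
    metrics = timed("evaluate", stage_evaluate, fit, data, cfg, out)

    suite = fit["suite"]
    report = PipelineReport(
        config=cfg,
        config_hash=chash,
        stages=stages_meta,
        selection={
            m: sel[m]["report"].to_dict(orient="records") for m in MODALITIES
        },
        cox_models={
            name: None if model is None else model.summary.to_dict(orient="records")
            for name, model in suite.models.items()
        },
        carried_forward=suite.carried_forward,
        metrics=metrics.to_dict(orient="records"),
    )
    (out / "report.json").write_text(report.to_json())
    return report
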