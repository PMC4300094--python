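"""End-to-end pipeline: phantom cohort through classification reports.

Every stage writes its artifacts to the run directory (manifest and
images, per-method masks, features CSV, ReliefF weights, subset-search
report, classification report, agreement report), so any stage can be
rerun or inspected in isolation.  A run is fully reproducible from its
configuration: the config (including all seeds) is serialised into the
run directory.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from breastcad import breast_seg, classify, evaluate, features, mass_seg, selection
from breastcad.phantom import CaseRecord, generate_cohort, save_cohort

__all__ = ["RunConfig", "run_pipeline", "load_config"]

log = logging.getLogger("breastcad")

METHODS = ("fcm", "fcm_gvf", "cv_ls")


@dataclass
class RunConfig:
    out_dir: str = "cad_run"
    n_benign: int = 10
    n_malignant: int = 10
    seed: int = 0
    methods: tuple[str, ...] = METHODS
    glcm_levels: int = 32
    glcm_distance: int = 1
    relieff_k: int = 10
    n_keep: int = 8
    subset_search: bool = True
    classifiers: tuple[str, ...] = ("svm", "fisher")
    resampling: tuple[str, ...] = ("loo", "half")
    n_half_repeats: int = 100
    inner_tuning: bool = False
    breast: breast_seg.BreastSegConfig = field(
        default_factory=breast_seg.BreastSegConfig
    )
    mass: mass_seg.MassSegConfig = field(default_factory=mass_seg.MassSegConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if "breast" in data:
            snake = data["breast"].pop("snake", None)
            data["breast"] = breast_seg.BreastSegConfig(**data["breast"])
            if snake:
                data["breast"].snake = breast_seg.SnakeParams(**snake)
        if "mass" in data:
            m = dict(data["mass"])
            ls = m.pop("level_set", None)
            fcm = m.pop("fcm", None)
            snake = m.pop("snake", None)
            data["mass"] = mass_seg.MassSegConfig(**m)
            if ls:
                data["mass"].level_set = mass_seg.LevelSetParams(**ls)
            if fcm:
                data["mass"].fcm = mass_seg.FcmParams(**fcm)
            if snake:
                data["mass"].snake = breast_seg.SnakeParams(**snake)
        for key in ("methods", "classifiers", "resampling"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


def _eval_factory(spec: classify.ClassifierSpec, scheme: str, cfg: RunConfig):
    def _eval(X, y):
        if scheme == "loo":
            return classify.leave_one_case_out(
                X, y, spec, inner_tuning=cfg.inner_tuning
            )
        return classify.leave_half_case_out(
            X, y, spec, n_repeats=cfg.n_half_repeats, seed=cfg.seed,
            inner_tuning=cfg.inner_tuning,
        )

    return _eval


def _segment_cohort(cohort, cfg: RunConfig, out: Path):
    masks: dict[str, list[np.ndarray]] = {m: [] for m in cfg.methods}
    mask_dir = out / "masks"
    mask_dir.mkdir(exist_ok=True)
    for case in cohort:
        t0 = time.time()
        breast_mask, _ = breast_seg.segment_breast(case.image, cfg.breast)
        log.info(
            "case=%s stage=breast_seg duration=%.2fs", case.case_id, time.time() - t0
        )
        for method in cfg.methods:
            t0 = time.time()
            mask, meta = mass_seg.segment_mass(
                case.image, breast_mask, method, cfg.mass
            )
            masks[method].append(mask)
            Image.fromarray(mask.astype(np.uint8) * 255).save(
                mask_dir / f"{case.case_id}.{method}.png"
            )
            log.info(
                "case=%s stage=mass_seg method=%s duration=%.2fs flags=%s",
                case.case_id, method, time.time() - t0, meta.get("flags", []),
            )
    return masks


def _feature_table(cohort, masks, cfg: RunConfig) -> pd.DataFrame:
    rows = []
    for case, mask in zip(cohort, masks):
        vec = features.extract_features(
            case.image, mask, distance=cfg.glcm_distance, levels=cfg.glcm_levels
        )
        rows.append({"case_id": case.case_id, "label": case.label, **vec})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and write all artifacts to the run directory."""
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(cfg), fh)

    cohort = generate_cohort(cfg.n_benign, cfg.n_malignant, cfg.seed)
    save_cohort(cohort, out / "phantoms")

    masks = _segment_cohort(cohort, cfg, out)

    report = evaluate.agreement_report(cohort, masks)
    report["summary"].to_csv(out / "table1.csv", index=False)
    report["scatter"].to_csv(out / "fig5_scatter.csv", index=False)
    report["aor"].to_csv(out / "fig6_aor_hist.csv", index=False)

    tables: dict[str, dict] = {}
    for method in cfg.methods:
        table = _feature_table(cohort, masks[method], cfg)
        table.to_csv(out / f"features.{method}.csv", index=False)
        X = table[list(features.FEATURE_NAMES)]
        y = table["label"].to_numpy()

        weights = selection.relieff_weights(X, y, k=cfg.relieff_k, seed=cfg.seed)
        wseries = weights.as_series().sort_values(ascending=False)
        wseries.rename("weight").to_csv(out / f"weights.{method}.csv")
        selected = selection.rank_and_select(weights, cfg.n_keep)

        method_report: dict = {"selected_features": selected}
        for clf_kind in cfg.classifiers:
            spec = classify.ClassifierSpec(kind=clf_kind)
            for scheme in cfg.resampling:
                evaluator = _eval_factory(spec, scheme, cfg)
                if cfg.subset_search:
                    subsets = selection.enumerate_subsets(selected)
                    best, search_report = selection.best_subset_search(
                        X, y, subsets, evaluator
                    )
                    search_report.to_csv(
                        out / f"subsets.{method}.{clf_kind}.{scheme}.csv",
                        index=False,
                    )
                    chosen = list(best)
                else:
                    chosen = selected
                res = evaluator(X[chosen], y)
                method_report[f"{clf_kind}_{scheme}"] = {
                    "subset": chosen,
                    "accuracy": res.accuracy,
                    "sensitivity": res.sensitivity,
                    "specificity": res.specificity,
                }
        tables[method] = method_report

    with open(out / "tables2_3.json", "w") as fh:
        json.dump(tables, fh, indent=2)
    return out
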