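"""End-to-end reproducible pipeline over a synthetic cohort.

Stages: simulate (phantoms + clinical tables) -> segment (threshold init +
active-contour refinement) -> extract (feature table) -> score (2:1 split,
survival forest, 0-100 score) -> evaluate (train/test/external prognosis
metrics) -> associate (feature x profile screen) -> reliability (repeat-scan
and between-algorithm ICC).  Every artifact lands in the run directory with
a manifest recording the config hash and per-stage seeds; rerunning with the
same config reproduces all numbers exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import association_table
from .features import FeatureConfig, extract_table
from .forest import RSFHyperParams, forest_to_dict, split_cohort
from .images import GrayImage, LesionMask
from .model import RadiomicScoreModel
from .phantom import (
    CohortConfig,
    make_lesion_phantom,
    make_repeat_pair,
    phantom_param_table,
    sample_phantom_configs,
    simulate_profiles,
    simulate_survival,
    write_cohort,
)
from .reliability import algorithm_pairs, reliability_study
from .segmentation import ContourParams, refine_active_contour, threshold_mask

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Declarative configuration of a full pipeline run."""

    out_dir: str = "lungrad_run"
    n_subjects: int = 150               # cohort A (split 2:1 train/test)
    n_external: int = 60                # cohort B (external validation)
    n_repeat: int = 30                  # cohort C (reliability pairs)
    image_size: int = 96
    pixel_spacing: float = 1.0
    # survival-generating effects (log HR per SD) and censoring
    log_hr: dict = field(default_factory=lambda: {"longhem": 0.7, "kurtosis": 0.4})
    baseline_hazard: float = 0.02
    censor_rate: float = 0.3
    mutation_shift: dict = field(default_factory=lambda: {"egfr": ("kurtosis", 1.0)})
    grade_link: dict = field(default_factory=lambda: {"longhem": 0.33})
    # segmentation
    threshold_low: float = 120.0
    threshold_high: float = 65535.0
    contour_method: str = "region"
    contour_max_iter: int = 50
    # feature extraction
    n_bins: int = 32
    glcm_distance: int = 1
    wavelet: str = "haar"
    # scoring / evaluation
    ntree: int = 50
    nodesize: int = 10
    nodedepth: int = 4
    horizons: tuple = (24.0, 60.0)
    alpha: float = 0.05
    # reliability
    repeat_noise_sd: float = 5.0
    repeat_shift_px: int = 1
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "horizons" in raw:
            raw["horizons"] = tuple(raw["horizons"])
        if "mutation_shift" in raw:
            raw["mutation_shift"] = {k: tuple(v) for k, v in raw["mutation_shift"].items()}
        return cls(**raw)


def _json_dump(obj, path: Path):
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _report_dict(rep) -> dict:
    out = {
        "n": rep.n, "n_events": rep.n_events,
        "concordance": rep.concordance,
        "auc": {f"{k:g}": v for k, v in rep.auc.items()},
        "logrank_chi2": rep.logrank_chi2, "logrank_p": rep.logrank_p,
    }
    if rep.hr is not None:
        out["hr"] = {
            "hr": rep.hr.hr, "ci_low": rep.hr.ci_low, "ci_high": rep.hr.ci_high,
            "se_log_hr": rep.hr.se_log_hr, "p_value": rep.hr.p_value,
            "n_low": rep.hr.n_group0, "n_high": rep.hr.n_group1,
        }
    return out


def _make_cohort(n, image_size, pixel_spacing, seed):
    configs = sample_phantom_configs(n, seed=seed, image_size=image_size,
                                     pixel_spacing=pixel_spacing)
    phantoms = [make_lesion_phantom(c) for c in configs]
    images = [p[0] for p in phantoms]
    masks = [p[1] for p in phantoms]
    return configs, images, masks


def _segment_cohort(images, init_masks, cfg: RunConfig):
    params = ContourParams(method=cfg.contour_method, max_iter=cfg.contour_max_iter)
    out = []
    for img in images:
        init = threshold_mask(img, cfg.threshold_low, cfg.threshold_high)
        if init.area_px == 0:
            raise RuntimeError("stage segment: threshold initialization empty")
        out.append(refine_active_contour(img, init, params))
    return out


def run_full_pipeline(config: RunConfig) -> Path:
    """Execute every stage; returns the run directory."""
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    cfg_dict = config.to_dict()
    # hash the scientific configuration only: the run location must not
    # change any reported number
    hashed = {k: v for k, v in cfg_dict.items() if k != "out_dir"}
    cfg_hash = hashlib.sha256(
        json.dumps(hashed, sort_keys=True, default=str).encode()
    ).hexdigest()
    stages_done = []
    fc = FeatureConfig(config.n_bins, config.glcm_distance, config.wavelet)

    def stage(name):
        logger.info("stage: %s", name)
        stages_done.append(name)

    try:
        stage("simulate")
        seeds = {"cohort_a": config.seed, "cohort_b": config.seed + 1,
                 "cohort_c": config.seed + 2, "clinical": config.seed + 3,
                 "split": config.seed + 4, "forest": config.seed + 5,
                 "repeat": config.seed + 6}
        configs_a, images_a, truth_a = _make_cohort(
            config.n_subjects, config.image_size, config.pixel_spacing, seeds["cohort_a"])
        configs_b, images_b, truth_b = _make_cohort(
            config.n_external, config.image_size, config.pixel_spacing, seeds["cohort_b"])

        stage("segment")
        masks_a = _segment_cohort(images_a, truth_a, config)
        masks_b = _segment_cohort(images_b, truth_b, config)

        stage("extract")
        feats_a = extract_table(images_a, masks_a, fc)
        feats_b = extract_table(images_b, masks_b, fc)

        stage("clinical")
        cohort_cfg = CohortConfig(
            n_subjects=config.n_subjects, log_hr=dict(config.log_hr),
            baseline_hazard=config.baseline_hazard, censor_rate=config.censor_rate,
            mutation_shift={k: tuple(v) for k, v in config.mutation_shift.items()},
            grade_link=dict(config.grade_link), seed=seeds["clinical"],
        )
        surv_a = simulate_survival(feats_a, cohort_cfg)
        prof_a = simulate_profiles(feats_a, phantom_param_table(configs_a), cohort_cfg)
        clinical_a = surv_a.merge(prof_a, on="subject_id")
        cohort_cfg_b = dataclasses.replace(
            cohort_cfg, n_subjects=config.n_external, seed=seeds["clinical"] + 100)
        surv_b = simulate_survival(feats_b, cohort_cfg_b)
        prof_b = simulate_profiles(feats_b, phantom_param_table(configs_b), cohort_cfg_b)
        clinical_b = surv_b.merge(prof_b, on="subject_id")

        write_cohort(run_dir / "cohort_a", images_a, masks_a, clinical_a)
        write_cohort(run_dir / "cohort_b", images_b, masks_b, clinical_b)
        feats_a.to_csv(run_dir / "features_a.csv", index=False)
        feats_b.to_csv(run_dir / "features_b.csv", index=False)

        stage("score")
        table_a = feats_a.merge(clinical_a[["subject_id", "time_months", "event"]],
                                on="subject_id")
        train, test = split_cohort(table_a, seed=seeds["split"])
        hyper = RSFHyperParams(ntree=config.ntree, nodesize=config.nodesize,
                               nodedepth=config.nodedepth, seed=seeds["forest"])
        model = RadiomicScoreModel.from_dataframe(train, hyper=hyper)
        results = model.fit()
        _json_dump(forest_to_dict(results.forest), run_dir / "forest.json")
        scores = pd.DataFrame({
            "subject_id": table_a["subject_id"],
            "score": results.predict_scores(table_a),
            "split": ["train" if s in set(train["subject_id"]) else "test"
                      for s in table_a["subject_id"]],
        })
        scores.to_csv(run_dir / "scores_a.csv", index=False)

        stage("evaluate")
        report = {
            "config_hash": cfg_hash,
            "train": _report_dict(results.evaluate(
                train, train["time_months"], train["event"], config.horizons)),
            "test": _report_dict(results.evaluate(
                test, test["time_months"], test["event"], config.horizons)),
            "external": _report_dict(results.evaluate(
                feats_b, clinical_b["time_months"], clinical_b["event"],
                config.horizons)),
        }
        _json_dump(report, run_dir / "prognosis.json")

        # KM step functions of the median-split groups (for plotting)
        strat = results.stratify(table_a, table_a["time_months"], table_a["event"])
        km_rows = []
        for grp in ("low", "high"):
            curve = strat[f"km_{grp}"]
            for t, s, r in zip(curve.times, curve.survival, curve.at_risk):
                km_rows.append({"group": grp, "time_months": t,
                                "survival": s, "at_risk": r})
        pd.DataFrame(km_rows).to_csv(run_dir / "km_curves.csv", index=False)

        stage("associate")
        long, matrix = association_table(feats_a, clinical_a, alpha=config.alpha)
        long.to_csv(run_dir / "associations.csv", index=False)
        matrix.to_csv(run_dir / "association_matrix.csv")

        stage("reliability")
        # two independent noisy acquisitions of the same underlying lesion
        n_rep = min(config.n_repeat, len(images_a))
        repeat_pairs = []
        for i in range(n_rep):
            scan1 = make_repeat_pair(
                images_a[i], masks_a[i], noise_sd=config.repeat_noise_sd,
                shift_px=0, seed=seeds["repeat"] + 2 * i)
            scan2 = make_repeat_pair(
                images_a[i], masks_a[i], noise_sd=config.repeat_noise_sd,
                shift_px=config.repeat_shift_px, seed=seeds["repeat"] + 2 * i + 1)
            repeat_pairs.append((scan1, scan2))
        rep_repeat = reliability_study(repeat_pairs, config=fc)
        rep_repeat.to_csv(run_dir / "reliability_repeat.csv", index=False)
        inits = [threshold_mask(images_a[i], config.threshold_low,
                                config.threshold_high) for i in range(n_rep)]
        rep_algo = reliability_study(
            algorithm_pairs(images_a[:n_rep], inits), config=fc)
        rep_algo.to_csv(run_dir / "reliability_algorithm.csv", index=False)

        manifest = {
            "package_version": __version__,
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in cfg_dict.items() if k != "out_dir"},
            "config_hash": cfg_hash,
            "seeds": seeds,
            "stages": stages_done,
            "outputs": sorted(
                {p.name for p in run_dir.iterdir() if p.is_file()} | {"manifest.json"}
            ),
        }
        _json_dump(manifest, run_dir / "manifest.json")
    except Exception as exc:
        current = stages_done[-1] if stages_done else "init"
        raise RuntimeError(f"pipeline failed in stage '{current}': {exc}") from exc
    return run_dir
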