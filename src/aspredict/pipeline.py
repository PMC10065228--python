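"""End-to-end orchestration with file-based stage contracts and provenance.

Every stage reads and writes the documented CSV dialects, so stages are
independently runnable; a manifest records the SHA-256 of every artifact plus
the seed and config hash, and rerunning with the same config reproduces
identical artifacts.  The analysis is stratified: one run handles one sex.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import audit, cohort as _cohort, evaluate as _evaluate, features as _features
from . import model as _model, selection as _selection, synth as _synth
from .codes import SignatureSpec, default_aggregation_map, female_signature, male_signature
from .evaluate import AS, NON_AS

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Nested configuration for one sex stratum."""

    stratum: str = "male"                    # "male" | "female"
    seed: int = 0
    out_dir: str | Path = "run"
    synth: _synth.SynthConfig = field(default_factory=_synth.SynthConfig)
    match: _cohort.MatchConfig = field(default_factory=_cohort.MatchConfig)
    features: _features.FeatureConfig = field(default_factory=_features.FeatureConfig)
    selection: _selection.SelectionConfig = field(default_factory=_selection.SelectionConfig)
    tree: _model.TreeConfig = field(default_factory=_model.TreeConfig)
    train_fraction: float = 0.7
    suspected_fraction: float = 0.10
    population_size: int | None = None       # generalisability stage if set

    def validate(self) -> None:
        if self.stratum not in ("male", "female"):
            raise ValueError(f"stratum must be male/female, got {self.stratum!r}")
        self.synth.validate()
        self.match.validate()
        self.features.validate()
        self.selection.validate()
        self.tree.validate()
        if self.selection.n_cohorts != self.match.ratio:
            raise ValueError("selection.n_cohorts must equal match.ratio")

    def signature(self) -> SignatureSpec:
        return male_signature() if self.stratum == "male" else female_signature()


def make_config(stratum: str = "male", seed: int = 0, out_dir: str | Path = "run",
                n_cases: int = 380, ratio: int = 100,
                population_size: int | None = None,
                **overrides) -> RunConfig:
    """Study-condition config factory.

    Defaults mirror the investigated design: 1:100 matching, alpha 0.01,
    stability threshold 90% for the (larger) male stratum and 75% for the
    (smaller) female stratum, depth-3 Gini trees.
    """
    seeds = np.random.SeedSequence(seed).generate_state(8) % (2 ** 31)
    sex_ratio = 1.0 if stratum == "male" else 0.0
    cfg = RunConfig(
        stratum=stratum, seed=seed, out_dir=out_dir,
        synth=_synth.SynthConfig(n_cases=n_cases, controls_per_case=ratio,
                                 sex_ratio=sex_ratio, seed=int(seeds[0])),
        match=_cohort.MatchConfig(ratio=ratio, seed=int(seeds[1])),
        features=_features.FeatureConfig(),
        selection=_selection.SelectionConfig(
            stability_fraction=0.90 if stratum == "male" else 0.75,
            n_cohorts=ratio, seed=int(seeds[2])),
        tree=_model.TreeConfig(leaf_prefix="M" if stratum == "male" else "F"),
        population_size=population_size,
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    cfg.validate()
    return cfg


@dataclass
class RunResult:
    """In-memory handles on everything a run produced (artifacts are also on
    disk under ``out_dir``; see the manifest)."""

    config: RunConfig
    out_dir: Path
    patients: pd.DataFrame
    events: pd.DataFrame
    cohort: _cohort.MatchedCohort
    matrix: pd.DataFrame
    stability: _selection.StabilityResult
    lr: _selection.LRResult
    retained_features: list[str]
    pc_model: _selection.PCModel
    selected_model: _model.PCTreeModel
    model_report: pd.DataFrame
    metrics: dict[str, _evaluate.MetricsReport]
    mean_f: dict[str, float]
    auc: float
    roc: pd.DataFrame
    generalization: dict | None = None


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _split_scores(matrix: pd.DataFrame, table: pd.DataFrame, pc: _selection.PCModel,
                  split: str, ratio: int):
    """(case scores, list of per-set control scores) for one split."""
    t = table[table["split"] == split]
    case_units = t.loc[t["role"] == "case", "unit_id"]
    case_scores = _selection.project(pc, matrix.loc[case_units])
    control_scores = []
    for k in range(1, ratio + 1):
        units = t.loc[(t["role"] == "control") & (t["control_set"] == k), "unit_id"]
        control_scores.append(_selection.project(pc, matrix.loc[units]))
    return case_scores, control_scores


def run_pipeline(cfg: RunConfig) -> RunResult:
    """Execute every stage in order, persisting artifacts and a manifest."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    artifacts: dict[str, dict[str, str]] = {}
    aggmap = default_aggregation_map()

    def record(stage: str, paths: dict[str, Path]) -> None:
        artifacts.setdefault(stage, {}).update(
            {str(p.relative_to(out)): _sha256(p) for p in paths.values()})

    def stage(name):
        logger.info("stage: %s", name)
        return name

    # -- synth ---------------------------------------------------------------
    name = stage("synth")
    try:
        patients, events = _synth.generate_population(cfg.synth, [cfg.signature()])
        events = _synth.inject_suspected_pathway(patients, events,
                                                 cfg.suspected_fraction,
                                                 seed=cfg.synth.seed + 1)
        paths = _synth.write_tables(patients, events, out / "population", cfg.synth)
        record(name, paths)
    except Exception as exc:
        raise PipelineError(f"stage {name} failed: {exc}") from exc

    # -- cohort --------------------------------------------------------------
    name = stage("cohort")
    try:
        cases = _cohort.identify_cases(events)
        eligible, attrition = _cohort.apply_eligibility(cases, patients, cfg.match)
        matched = _cohort.match_controls(eligible, patients, events, cfg.match)
        matched = _cohort.split_train_test(matched, cfg.train_fraction,
                                           seed=cfg.match.seed + 1)
        cdir = out / "cohort"
        cdir.mkdir(exist_ok=True)
        _cohort.write_cohort(matched, cdir / "cohort.csv")
        attrition.to_csv(cdir / "attrition.csv", index=False, lineterminator="\r\n")
        record(name, {"cohort": cdir / "cohort.csv",
                      "attrition": cdir / "attrition.csv"})
    except Exception as exc:
        raise PipelineError(f"stage {name} failed: {exc}") from exc

    # -- features ------------------------------------------------------------
    name = stage("features")
    try:
        matrix = _features.build_features(events, matched.table, patients,
                                          cfg.features, aggmap)
        record(name, _features.write_matrix(matrix, out / "features"))
    except Exception as exc:
        raise PipelineError(f"stage {name} failed: {exc}") from exc

    # -- selection -----------------------------------------------------------
    name = stage("selection")
    try:
        table = matched.table
        train = table[table["split"] == "train"]
        case_units = train.loc[train["role"] == "case", "unit_id"]
        case_matrix = matrix.loc[case_units]
        control_matrices = []
        for k in range(1, matched.ratio + 1):
            units = train.loc[(train["role"] == "control")
                              & (train["control_set"] == k), "unit_id"]
            control_matrices.append(matrix.loc[units])
        stability = _selection.stability_screen(case_matrix, control_matrices,
                                                cfg.selection)
        selected = stability.selected
        lr_units = pd.concat([case_units, train.loc[
            (train["role"] == "control") & (train["control_set"] == 1), "unit_id"]])
        lr_labels = np.r_[np.ones(len(case_units)),
                          np.zeros(len(lr_units) - len(case_units))]
        lr = _selection.lr_filter(matrix.loc[lr_units, selected], lr_labels,
                                  cfg.selection)
        retained = lr.retained
        if len(retained) < 2:
            raise ValueError(f"only {len(retained)} features survived the "
                             "logistic filter; PCA needs at least 2")
        pc = _selection.fit_pca(matrix.loc[lr_units, retained], cfg.selection)
        sdir = out / "selection"
        sdir.mkdir(exist_ok=True)
        _selection.write_stability_report(stability, lr, sdir / "selection_report.csv")
        paths = _selection.write_pc_model(pc, sdir)
        record(name, {"report": sdir / "selection_report.csv", **paths})
    except Exception as exc:
        raise PipelineError(f"stage {name} failed: {exc}") from exc

    # -- model ---------------------------------------------------------------
    name = stage("model")
    try:
        sub = matrix[retained]
        case_scores, control_scores = _split_scores(sub, table, pc, "train",
                                                    matched.ratio)
        candidates = _model.fit_candidates(case_scores, control_scores, cfg.tree,
                                           pc_model=pc, n_cohorts=matched.ratio)
        best, report = _model.select_best(candidates, case_scores, control_scores)
        mdir = out / "model"
        mdir.mkdir(exist_ok=True)
        _model.write_tree_model(best, mdir / "model.txt",
                                pc_model_ref="../selection/pca_loadings.csv")
        report.to_csv(mdir / "model_selection.csv", index=False,
                      lineterminator="\r\n")
        _model.leaf_report(best).to_csv(mdir / "leaf_report.csv", index=False,
                                        lineterminator="\r\n")
        record(name, {"model": mdir / "model.txt",
                      "selection": mdir / "model_selection.csv",
                      "leaves": mdir / "leaf_report.csv"})
    except Exception as exc:
        raise PipelineError(f"stage {name} failed: {exc}") from exc

    # -- evaluate ------------------------------------------------------------
    name = stage("evaluate")
    try:
        metrics_rows: dict[str, _evaluate.MetricsReport] = {}
        mean_f: dict[str, float] = {}
        for split in ("train", "test"):
            cs, ctls = _split_scores(sub, table, pc, split, matched.ratio)
            case_pred = best.predict_scores(cs)[0]
            ctl1_pred = best.predict_scores(ctls[0])[0]
            cm = _evaluate.confusion(
                np.r_[case_pred, ctl1_pred],
                np.r_[np.repeat(AS, len(case_pred)),
                      np.repeat(NON_AS, len(ctl1_pred))])
            metrics_rows[split] = _evaluate.metrics(cm)
            fs = [_evaluate.f_value(
                float((case_pred == AS).sum()),
                float((case_pred == NON_AS).sum()),
                float((best.predict_scores(c)[0] == AS).sum()),
                float((best.predict_scores(c)[0] == NON_AS).sum()))
                for c in ctls]
            mean_f[split] = float(np.mean(fs))
        # pooled 1:ratio test evaluation (cohort prevalence ~1/(1+ratio))
        test = table[table["split"] == "test"]
        test_units = test["unit_id"]
        preds = _model.predict(best, sub.loc[test_units])
        observed = np.where(test["role"].to_numpy() == "case", AS, NON_AS)
        cm_pooled = _evaluate.confusion(preds["label"].to_numpy(), observed)
        metrics_rows["test_pooled"] = _evaluate.metrics(cm_pooled)
        roc, auc = _evaluate.roc_auc(preds["risk_score"].to_numpy(), observed)
        edir = out / "evaluation"
        edir.mkdir(exist_ok=True)
        _evaluate.metrics_frame(metrics_rows).to_csv(
            edir / "metrics.csv", index_label="dataset", lineterminator="\r\n")
        roc.to_csv(edir / "roc.csv", index=False, lineterminator="\r\n")
        preds.to_csv(edir / "predictions_test.csv", index=False,
                     lineterminator="\r\n")
        (edir / "confusion_test_pooled.txt").write_text(
            _evaluate.format_confusion(cm_pooled) + "\n")
        record(name, {"metrics": edir / "metrics.csv", "roc": edir / "roc.csv",
                      "predictions": edir / "predictions_test.csv",
                      "confusion": edir / "confusion_test_pooled.txt"})
    except Exception as exc:
        raise PipelineError(f"stage {name} failed: {exc}") from exc

    # -- generalizability (optional) ----------------------------------------
    generalization = None
    if cfg.population_size is not None:
        name = stage("generalize")
        try:
            generalization = _run_generalization(cfg, patients, events, matched,
                                                 best, sub.columns, aggmap, out)
            record(name, generalization["paths"])
        except Exception as exc:
            raise PipelineError(f"stage {name} failed: {exc}") from exc

    manifest = {
        "seed": cfg.seed,
        "stratum": cfg.stratum,
        "version": __import__("aspredict").__version__,
        "config_sha256": hashlib.sha256(
            json.dumps(_config_blob(cfg), sort_keys=True).encode()).hexdigest(),
        "stages": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")
    (out / "run.log").write_text(
        f"completed in {time.time() - t0:.1f} s\n")

    return RunResult(config=cfg, out_dir=out, patients=patients, events=events,
                     cohort=matched, matrix=matrix, stability=stability, lr=lr,
                     retained_features=retained, pc_model=pc,
                     selected_model=best, model_report=report,
                     metrics=metrics_rows, mean_f=mean_f, auc=auc, roc=roc,
                     generalization=generalization)


def _config_blob(cfg: RunConfig) -> dict:
    blob = {"stratum": cfg.stratum, "seed": cfg.seed,
            "train_fraction": cfg.train_fraction,
            "suspected_fraction": cfg.suspected_fraction,
            "population_size": cfg.population_size}
    for name in ("synth", "match", "features", "selection", "tree"):
        blob[name] = {k: (list(v) if isinstance(v, tuple) else v)
                      for k, v in asdict(getattr(cfg, name)).items()}
    return blob


def _run_generalization(cfg: RunConfig, dev_patients, dev_events, matched,
                        best, feature_columns, aggmap, out: Path) -> dict:
    """Population-mode validation: a fresh general-population sample plus the
    development cases, predicted with the developed model, reported with and
    without the development participants (the all-population vs
    development-excluded distinction)."""
    pop_cfg = _synth.SynthConfig(
        n_cases=1, controls_per_case=1,
        population_size=cfg.population_size,
        case_prevalence=cfg.synth.case_prevalence,
        sex_ratio=cfg.synth.sex_ratio, seed=cfg.synth.seed + 101,
        background_code_rate=cfg.synth.background_code_rate,
        diag_age_range=cfg.synth.diag_age_range)
    pop_patients, pop_events = _synth.generate_population(pop_cfg, [cfg.signature()])

    dev_case_ids = set(matched.case_ids)
    dev_pat = dev_patients[dev_patients["patient_id"].isin(dev_case_ids)]
    dev_ev = dev_events[dev_events["patient_id"].isin(dev_case_ids)]
    patients = pd.concat([pop_patients, dev_pat], ignore_index=True)
    events = pd.concat([pop_events, dev_ev], ignore_index=True)

    # index date: diagnosis for cases, end of registration for everyone else
    units = patients[["patient_id"]].copy()
    units["unit_id"] = units["patient_id"]
    units["index_date"] = patients["diagnosis_date"].fillna(patients["reg_end"])
    mat = _features.build_features(events, units, patients, cfg.features, aggmap)
    mat = mat.reindex(columns=feature_columns, fill_value=0)
    preds = _model.predict(best, mat)
    observed = pd.Series(
        np.where(patients.set_index("patient_id").loc[mat.index, "true_status"]
                 == "case", AS, NON_AS), index=mat.index)
    reports = _evaluate.generalize(preds.set_index("unit_id")["label"],
                                   observed, dev_case_ids)
    gdir = out / "generalization"
    gdir.mkdir(exist_ok=True)
    rows = {key: rep for key, (cm, rep) in reports.items()}
    _evaluate.metrics_frame(rows).to_csv(gdir / "metrics.csv",
                                         index_label="dataset",
                                         lineterminator="\r\n")
    text = "\n\n".join(f"{key}:\n{_evaluate.format_confusion(cm)}"
                       for key, (cm, rep) in reports.items())
    (gdir / "confusion.txt").write_text(text + "\n")
    return {"reports": reports, "paths": {"metrics": gdir / "metrics.csv",
                                          "confusion": gdir / "confusion.txt"}}
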