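"""Cross-source experiment orchestration.

Runs the full pipeline for one experiment plan — optional per-source
control-decile normalization, replicate averaging, zero-feature filtering,
cutoff grid search, linear-margin training — and evaluates on held-out
and cross-source validation sets.

Two plan shapes are supported:

* *single-source*: train on one case/control source, validate on the other
  source's samples and on the control-only third source;
* *mixed*: train on both case/control sources after randomly removing a
  fixed number of cancer samples, which together with the third source's
  controls form the validation pool.

The validation MCC pools the second-source samples with the third-source
controls (single-source plans) or the held-out cancers with the
third-source controls (mixed plans).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .classify import EvaluationReport, LinearMarginModel, evaluate, train
from .containers import CLASS_CANCER, CLASS_CONTROL, ReplicateMatrix
from .normalize import apply_quantile_map, fit_quantile_maps
from .selection import (
    DEFAULT_INTENSITY_GRID,
    DEFAULT_P_GRID,
    DISABLED_INTENSITY_GRID,
    SelectionResult,
    optimize_filters,
)
from .summarize import average_replicates, filter_zero_features

__all__ = ["ExperimentPlan", "ExperimentResult", "CrossSourceExperiment", "run_experiment", "compare_runs"]


@dataclass(frozen=True)
class ExperimentPlan:
    """One row of the cross-source experiment grid.

    ``train_sources`` with one element gives a single-source plan whose
    validation set is ``validation_source`` plus the controls of
    ``control_source``; with two or more elements, ``holdout_n_cancer``
    cancer samples are removed at random (seeded) from the mixed training
    set and form the validation pool together with the third source's
    controls.
    """

    train_sources: tuple
    validation_source: str | None = None
    control_source: str | None = "C"
    holdout_n_cancer: int = 0
    normalize: bool = False
    p_grid: tuple = DEFAULT_P_GRID
    i_grid: tuple | None = None          # None → default grid, or disabled when normalized
    cv_folds: int = 10
    seed: int = 0
    C: float = 1.0
    name: str = ""

    def effective_i_grid(self) -> tuple:
        if self.normalize:
            # normalized bins have no raw intensity scale: filter disabled
            return DISABLED_INTENSITY_GRID
        return DEFAULT_INTENSITY_GRID if self.i_grid is None else self.i_grid

    def same_but_normalization(self, other: "ExperimentPlan") -> bool:
        return replace(self, normalize=False, name="") == replace(other, normalize=False, name="")


@dataclass
class ExperimentResult:
    """Table-style report of one experiment run."""

    plan: ExperimentPlan
    selection: SelectionResult
    model: LinearMarginModel
    training_report: EvaluationReport
    validation_reports: dict          # set name -> EvaluationReport
    n_features_input: int
    n_features_filtered: int
    training_sample_ids: list = field(repr=False, default_factory=list)
    holdout_sample_ids: list = field(repr=False, default_factory=list)

    @property
    def cv_accuracy(self) -> float:
        return self.selection.cv_accuracy

    @property
    def mcc_training(self) -> float:
        return self.training_report.mcc

    @property
    def validation_report(self) -> EvaluationReport | None:
        """Pooled validation confusion table, or None with no validation set."""
        if not self.validation_reports:
            return None
        pooled = None
        for rep in self.validation_reports.values():
            pooled = rep if pooled is None else pooled + rep
        return pooled

    @property
    def mcc_validation(self) -> float | None:
        rep = self.validation_report
        return None if rep is None else rep.mcc

    def row(self) -> dict:
        """Flat report row mirroring the experiment-grid table layout."""
        sel = self.selection
        r = {
            "normalization": "yes" if self.plan.normalize else "no",
            "training_set": "+".join(self.plan.train_sources),
            "p_cutoff": sel.params.p_cutoff,
            "intensity_cutoff": (
                "NA" if sel.params.intensity_cutoff is None else sel.params.intensity_cutoff
            ),
            "n_features": len(sel.features),
            "cv_accuracy": sel.cv_accuracy,
            "training_controls": f"{self.training_report.tn}/{self.training_report.tn + self.training_report.fp}",
            "training_cancers": f"{self.training_report.tp}/{self.training_report.tp + self.training_report.fn}",
            "mcc_training": round(self.mcc_training, 2),
        }
        for name, rep in self.validation_reports.items():
            n_ctrl = rep.tn + rep.fp
            n_can = rep.tp + rep.fn
            if n_ctrl:
                r[f"validation_{name}_controls"] = f"{rep.tn}/{n_ctrl}"
            if n_can:
                r[f"validation_{name}_cancers"] = f"{rep.tp}/{n_can}"
        r["mcc_validation"] = (
            "NA" if self.mcc_validation is None else round(self.mcc_validation, 2)
        )
        return r

    def summary(self) -> str:
        lines = [f"Experiment: {self.plan.name or '+'.join(self.plan.train_sources)}"]
        lines += [f"  {k}: {v}" for k, v in self.row().items()]
        lines.append(
            f"  features: {self.n_features_input} input, "
            f"{self.n_features_filtered} after zero filter, "
            f"{len(self.selection.features)} selected"
        )
        return "\n".join(lines)


def _holdout_cancers(rm: ReplicateMatrix, train_sources, n: int, seed: int) -> list:
    cancers = [
        sid
        for sid, row in rm.samples.iterrows()
        if row["source"] in train_sources and row["class"] == CLASS_CANCER
    ]
    if n > len(cancers):
        raise ValueError(f"cannot hold out {n} of {len(cancers)} cancer samples")
    rng = np.random.default_rng(seed)
    return sorted(rng.choice(cancers, size=n, replace=False).tolist())


def run_experiment(plan: ExperimentPlan, rm: ReplicateMatrix) -> ExperimentResult:
    """Execute one plan end to end; deterministic for fixed (plan, data)."""
    present = set(rm.samples["source"])
    wanted = set(plan.train_sources)
    if plan.validation_source:
        wanted.add(plan.validation_source)
    if plan.control_source:
        wanted.add(plan.control_source)
    missing = wanted - present
    if missing:
        raise ValueError(f"planned source(s) absent from data: {sorted(missing)}")

    work = rm
    if plan.normalize:
        qmaps = fit_quantile_maps(work)  # each source vs its own controls
        work = apply_quantile_map(work, qmaps)

    sm = average_replicates(work)
    sm, _removed = filter_zero_features(sm)

    # training / validation split
    holdout: list = []
    if len(plan.train_sources) > 1 and plan.holdout_n_cancer:
        holdout = _holdout_cancers(rm, plan.train_sources, plan.holdout_n_cancer, plan.seed)
    train_ids = [
        sid
        for sid, row in sm.samples.iterrows()
        if row["source"] in plan.train_sources and sid not in set(holdout)
    ]
    sm_train = sm.subset_samples(train_ids)

    sel = optimize_filters(
        sm_train,
        p_grid=plan.p_grid,
        i_grid=plan.effective_i_grid(),
        cv_folds=plan.cv_folds,
        seed=plan.seed,
        C=plan.C,
    )
    model = train(sm_train.data[sel.features], sm_train.labels, C=plan.C)
    training_report = evaluate(model, sm_train.data[sel.features], sm_train.labels)

    validation_reports: dict = {}
    if plan.validation_source:
        ids = [
            sid for sid, row in sm.samples.iterrows() if row["source"] == plan.validation_source
        ]
        sv = sm.subset_samples(ids)
        validation_reports["second_source"] = evaluate(model, sv.data[sel.features], sv.labels)
    if holdout:
        sv = sm.subset_samples(holdout)
        validation_reports["holdout"] = evaluate(model, sv.data[sel.features], sv.labels)
    if plan.control_source:
        ids = [
            sid
            for sid, row in sm.samples.iterrows()
            if row["source"] == plan.control_source and row["class"] == CLASS_CONTROL
        ]
        if ids:
            sv = sm.subset_samples(ids)
            validation_reports["third_source"] = evaluate(
                model, sv.data[sel.features], sv.labels
            )

    return ExperimentResult(
        plan=plan,
        selection=sel,
        model=model,
        training_report=training_report,
        validation_reports=validation_reports,
        n_features_input=len(rm.features),
        n_features_filtered=len(sm.features),
        training_sample_ids=train_ids,
        holdout_sample_ids=holdout,
    )


class CrossSourceExperiment:
    """Model-object wrapper: ``CrossSourceExperiment(data, plan).fit()``."""

    def __init__(self, data: ReplicateMatrix, plan: ExperimentPlan):
        self.data = data
        self.plan = plan

    def fit(self) -> ExperimentResult:
        return run_experiment(self.plan, self.data)


def compare_runs(report_no_norm: ExperimentResult, report_norm: ExperimentResult) -> dict:
    """Effect of normalization between two otherwise identical runs."""
    if not report_no_norm.plan.same_but_normalization(report_norm.plan):
        raise ValueError("plans differ by more than the normalization flag")
    a, b = report_no_norm, report_norm
    d_mcc = (
        None
        if a.mcc_validation is None or b.mcc_validation is None
        else b.mcc_validation - a.mcc_validation
    )
    out = {
        "delta_cv_accuracy": b.cv_accuracy - a.cv_accuracy,
        "delta_mcc_training": b.mcc_training - a.mcc_training,
        "delta_mcc_validation": d_mcc,
        "normalization_improved_validation": (d_mcc is not None and d_mcc > 0),
    }
    return out
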