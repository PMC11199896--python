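"""Evaluation protocols and metrics for ErrP classification.

Five scenarios, each producing a grid of per-(train unit, test unit) metric
cells:

* **leave_one_subject_out** — within one session, train on all other
  subjects (5-fold CV model selection, pretraining-phase settings), test on
  the held-out subject.
* **one_train_one_test** — train on a single subject (5-fold CV,
  fine-tuning-phase settings), test separately on every other subject; the
  from-scratch baseline for transfer experiments.
* **cross_task** — pretrain on a source-task set, fine-tune per target
  subject, test on each remaining target subject; reported alongside the
  non-pretrained one-train-one-test baseline with per-column deltas.
* **within_session** — per subject per session, stratified 5-fold CV; the
  cell reports the mean over held-out folds.
* **cross_session** — per subject, train on one session and test on the
  other, both directions.

Metrics per cell (percent): accuracy at a 0.5 threshold on the error-class
probability, AUC (probability that a random error trial outscores a random
correct trial, ties credited one half), error_rate (recall of the error
class) and correct_rate (recall of the correct class).
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import roc_auc_score

from .io_store import EpochSet
from .model import ErrPNet, ModelConfig
from .train import CVResult, TrainConfig, finetune, pretrain

logger = logging.getLogger(__name__)


# -- metrics ------------------------------------------------------------------

@dataclass(frozen=True)
class MetricCell:
    """One grid cell; rates in percent."""

    accuracy: float
    auc: float
    error_rate: float
    correct_rate: float
    n_error: int
    n_correct: int
    scenario: str = ""
    train_unit: str = ""
    test_unit: str = ""

    def as_row(self) -> dict:
        return {
            "scenario": self.scenario, "train_unit": self.train_unit,
            "test_unit": self.test_unit,
            "accuracy": round(self.accuracy, 2), "auc": round(self.auc, 2),
            "error_rate": round(self.error_rate, 2),
            "correct_rate": round(self.correct_rate, 2),
        }


def compute_metrics(scores: np.ndarray, labels: np.ndarray, **ids) -> MetricCell:
    """Metric cell from per-sample error-class probabilities.

    ``accuracy`` is exactly the prevalence-weighted mean of the two class
    recalls.  With single-class labels the AUC is undefined and reported as
    NaN with a warning.
    """
    scores = np.asarray(scores, dtype=np.float64).reshape(-1)
    labels = np.asarray(labels).astype(int).reshape(-1)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    if scores.size and (scores.min() < 0 or scores.max() > 1):
        raise ValueError("scores must be probabilities in [0, 1]")
    pred = (scores >= 0.5).astype(int)
    err_mask, corr_mask = labels == 1, labels == 0
    n_err, n_corr = int(err_mask.sum()), int(corr_mask.sum())
    error_rate = 100.0 * (pred[err_mask] == 1).mean() if n_err else float("nan")
    correct_rate = 100.0 * (pred[corr_mask] == 0).mean() if n_corr else float("nan")
    accuracy = 100.0 * (pred == labels).mean()
    if n_err and n_corr:
        auc = 100.0 * roc_auc_score(labels, scores)
    else:
        warnings.warn("AUC undefined for single-class labels; reporting NaN")
        auc = float("nan")
    return MetricCell(accuracy, auc, error_rate, correct_rate, n_err, n_corr, **ids)


class MetricsReport:
    """A list of metric cells with marginal summaries and CSV/text output."""

    def __init__(self, cells: list[MetricCell] | None = None, meta: dict | None = None):
        self.cells: list[MetricCell] = list(cells or [])
        self.meta: dict = dict(meta or {})

    def append(self, cell: MetricCell) -> None:
        self.cells.append(cell)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([c.as_row() for c in self.cells])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.2f")

    def mean(self, metric: str = "accuracy", scenario: str | None = None) -> float:
        """Unweighted mean of a metric over cells (the tables' Average rows)."""
        vals = [getattr(c, metric) for c in self.cells
                if scenario is None or c.scenario == scenario]
        return float(np.nanmean(vals)) if vals else float("nan")

    def column_means(self, metric: str = "accuracy", scenario: str | None = None) -> dict[str, float]:
        """Mean metric per train unit (the grids' per-column averages)."""
        out: dict[str, list[float]] = {}
        for c in self.cells:
            if scenario is not None and c.scenario != scenario:
                continue
            out.setdefault(c.train_unit, []).append(getattr(c, metric))
        return {k: float(np.nanmean(v)) for k, v in sorted(out.items())}

    def render(self, metric: str = "accuracy") -> str:
        """Aligned text grid: rows = test units, columns = train units."""
        frame = self.to_frame()
        if frame.empty:
            return "(empty report)"
        blocks = []
        for scenario, grp in frame.groupby("scenario", sort=False):
            pivot = grp.pivot_table(index="test_unit", columns="train_unit",
                                    values=metric, aggfunc="mean")
            cols = [str(c) for c in pivot.columns]
            width = max(8, *(len(c) for c in cols),
                        *(len(str(i)) for i in pivot.index))
            header = " | ".join(["test/train".ljust(width)] +
                                [c.rjust(width) for c in cols])
            rule = "-|-".join(["-" * width] * (len(cols) + 1))
            rows = []
            for idx, row in pivot.iterrows():
                cells = ["     -".rjust(width) if np.isnan(v) else f"{v:.2f}".rjust(width)
                         for v in row]
                rows.append(" | ".join([str(idx).ljust(width)] + cells))
            blocks.append(f"### {scenario} ({metric}, %)\n" +
                          "\n".join([header, rule] + rows))
        return "\n\n".join(blocks)


# -- scenario harness ---------------------------------------------------------

SCENARIOS = ("within_session", "cross_session", "leave_one_subject_out",
             "one_train_one_test", "cross_task")


@dataclass
class ScenarioSpec:
    """Inputs for one evaluation scenario."""

    kind: str
    target: EpochSet
    source: EpochSet | None = None
    session: str | None = None  # session filter for LOSO / one-train-one-test
    model_config: ModelConfig = field(default_factory=ModelConfig)
    pretrain_config: TrainConfig = field(default_factory=TrainConfig.pretrain_defaults)
    finetune_config: TrainConfig = field(default_factory=TrainConfig.finetune_defaults)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in SCENARIOS:
            raise ValueError(f"unknown scenario kind '{self.kind}'")


def _unit_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence(seed, spawn_key=(index,)).generate_state(1)[0] % (2 ** 31))


def _cell_from_network(net: ErrPNet, test: EpochSet, **ids) -> MetricCell:
    scores = net.predict_proba(test.data)[:, 1]
    return compute_metrics(scores, test.labels, **ids)


def _cv_best(data: EpochSet, model_config: ModelConfig, config: TrainConfig,
             seed: int) -> CVResult:
    return pretrain(data, model_config, dataclasses.replace(config, seed=seed))


def run_loso(spec: ScenarioSpec) -> MetricsReport:
    """Leave-one-subject-out within one session."""
    target = spec.target.where(session=spec.session) if spec.session else spec.target
    subjects = target.subject_ids
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least two subjects")
    report = MetricsReport(meta={"scenario": "leave_one_subject_out"})
    for i, held_out in enumerate(subjects):
        train_set = target.subset(target.subjects != held_out)
        test_set = target.where(subject=held_out)
        assert held_out not in set(train_set.subjects)
        cv = _cv_best(train_set, spec.model_config, spec.pretrain_config,
                      _unit_seed(spec.seed, i))
        report.append(_cell_from_network(cv.best_network, test_set,
                                         scenario="leave_one_subject_out",
                                         train_unit="rest", test_unit=held_out))
        logger.info("LOSO %s: %.2f%%", held_out, report.cells[-1].accuracy)
    return report


def run_one_train_one_test(spec: ScenarioSpec) -> MetricsReport:
    """Train on one subject, test separately on every other subject."""
    target = spec.target.where(session=spec.session) if spec.session else spec.target
    subjects = target.subject_ids
    if len(subjects) < 2:
        raise ValueError("one-train-one-test needs at least two subjects")
    report = MetricsReport(meta={"scenario": "one_train_one_test"})
    for i, train_subj in enumerate(subjects):
        cv = _cv_best(target.where(subject=train_subj), spec.model_config,
                      spec.finetune_config, _unit_seed(spec.seed, i))
        for test_subj in subjects:
            if test_subj == train_subj:
                continue
            report.append(_cell_from_network(cv.best_network,
                                             target.where(subject=test_subj),
                                             scenario="one_train_one_test",
                                             train_unit=train_subj,
                                             test_unit=test_subj))
    return report


def run_cross_task(spec: ScenarioSpec, baseline: MetricsReport | None = None) -> MetricsReport:
    """Pretrain on the source task, fine-tune per target subject, test on the
    remaining target subjects; pairs the grid with the non-pretrained
    one-train-one-test baseline for per-column deltas.

    Pass a precomputed ``baseline`` report to avoid re-running it.
    """
    if spec.source is None:
        raise ValueError("cross_task needs a source set")
    src_tasks, tgt_tasks = set(spec.source.tasks), set(spec.target.tasks)
    if src_tasks & tgt_tasks:
        raise ValueError(f"source and target must be distinct tasks, both have {src_tasks & tgt_tasks}")
    target = spec.target.where(session=spec.session) if spec.session else spec.target
    subjects = target.subject_ids
    cv = _cv_best(spec.source, spec.model_config, spec.pretrain_config, spec.seed)
    checkpoint = cv.best_network
    sha = hashlib.sha256(np.concatenate(
        [p.data.ravel() for p in checkpoint.parameters()]).tobytes()).hexdigest()[:16]
    report = MetricsReport(meta={"scenario": "cross_task", "checkpoint_sha": sha,
                                 "per_column_checkpoint_sha": {}})
    for i, ft_subj in enumerate(subjects):
        ft_cfg = dataclasses.replace(spec.finetune_config, seed=_unit_seed(spec.seed, i))
        tuned = finetune(checkpoint, target.where(subject=ft_subj), ft_cfg)
        report.meta["per_column_checkpoint_sha"][ft_subj] = sha
        for test_subj in subjects:
            if test_subj == ft_subj:
                continue
            report.append(_cell_from_network(tuned, target.where(subject=test_subj),
                                             scenario="cross_task",
                                             train_unit=ft_subj, test_unit=test_subj))
    if baseline is None:
        baseline = run_one_train_one_test(spec)
    for cell in baseline.cells:
        report.append(dataclasses.replace(cell, scenario="non_pretrained"))
    pre = report.column_means(scenario="cross_task")
    base = report.column_means(scenario="non_pretrained")
    report.meta["column_delta"] = {k: pre[k] - base[k] for k in pre if k in base}
    return report


def run_within_session(spec: ScenarioSpec) -> MetricsReport:
    """Per subject per session: stratified 5-fold CV, mean held-out-fold cell."""
    target = spec.target
    report = MetricsReport(meta={"scenario": "within_session"})
    unit = 0
    for subj in target.subject_ids:
        for sess in target.where(subject=subj).session_ids:
            subset = target.where(subject=subj, session=sess)
            cv = _cv_best(subset, spec.model_config, spec.pretrain_config,
                          _unit_seed(spec.seed, unit))
            unit += 1
            fold_cells = []
            for fold in cv.folds:
                val = subset.subset(fold.val_indices)
                scores = fold.network.predict_proba(val.data)[:, 1]
                fold_cells.append(compute_metrics(scores, val.labels))
            name = f"{subj}/session{sess}"
            report.append(MetricCell(
                accuracy=float(np.mean([c.accuracy for c in fold_cells])),
                auc=float(np.nanmean([c.auc for c in fold_cells])),
                error_rate=float(np.nanmean([c.error_rate for c in fold_cells])),
                correct_rate=float(np.nanmean([c.correct_rate for c in fold_cells])),
                n_error=sum(c.n_error for c in fold_cells),
                n_correct=sum(c.n_correct for c in fold_cells),
                scenario="within_session", train_unit=name, test_unit=name))
    return report


def run_cross_session(spec: ScenarioSpec) -> MetricsReport:
    """Per subject: train on one session, test on the other, both directions."""
    target = spec.target
    report = MetricsReport(meta={"scenario": "cross_session"})
    unit = 0
    for subj in target.subject_ids:
        sessions = target.where(subject=subj).session_ids
        if len(sessions) < 2:
            raise ValueError(f"cross_session needs >= 2 sessions for subject {subj}")
        for train_sess in sessions:
            for test_sess in sessions:
                if test_sess == train_sess:
                    continue
                train_set = target.where(subject=subj, session=train_sess)
                test_set = target.where(subject=subj, session=test_sess)
                assert not (set(zip(train_set.subjects, train_set.sessions)) &
                            set(zip(test_set.subjects, test_set.sessions)))
                cv = _cv_best(train_set, spec.model_config, spec.pretrain_config,
                              _unit_seed(spec.seed, unit))
                unit += 1
                report.append(_cell_from_network(
                    cv.best_network, test_set, scenario="cross_session",
                    train_unit=f"{subj}/session{train_sess}",
                    test_unit=f"{subj}/session{test_sess}"))
    return report


def run_scenario(spec: ScenarioSpec) -> MetricsReport:
    """Dispatch on ``spec.kind``."""
    return {
        "leave_one_subject_out": run_loso,
        "one_train_one_test": run_one_train_one_test,
        "cross_task": run_cross_task,
        "within_session": run_within_session,
        "cross_session": run_cross_session,
    }[spec.kind](spec)


# -- reference baseline -------------------------------------------------------

def lda_baseline(train_set: EpochSet, test_set: EpochSet, **ids) -> MetricCell:
    """Linear discriminant analysis on flattened 128-dim epochs.

    The svd solver pools class covariances without shrinkage and remains
    defined for singular covariance (pseudo-inverse behaviour); serves as a
    deterministic sanity-check comparator for the network.
    """
    if len(np.unique(train_set.labels)) != 2:
        raise ValueError("LDA baseline needs both classes in the training data")
    n_tr, n_te = len(train_set), len(test_set)
    lda = LinearDiscriminantAnalysis(solver="svd")
    lda.fit(train_set.data.reshape(n_tr, -1), train_set.labels)
    scores = lda.predict_proba(test_set.data.reshape(n_te, -1))[:, 1]
    return compute_metrics(scores, test_set.labels, **ids)
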