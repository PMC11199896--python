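"""Metrics and scenario orchestration."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import brute_force_auc
from errpnet.evaluate import (MetricsReport, ScenarioSpec, compute_metrics,
                              lda_baseline, run_cross_session, run_cross_task,
                              run_loso, run_one_train_one_test, run_scenario,
                              run_within_session)
from errpnet.io_store import EpochSet
from errpnet.synth import SynthConfig, TaskShift, generate_epochset, generate_task_pair
from errpnet.train import TrainConfig

FAST_PT = TrainConfig.pretrain_defaults(epochs=2)
FAST_FT = TrainConfig.finetune_defaults(epochs=2, k_folds=5)


def spec_for(kind, target, source=None, **kw):
    return ScenarioSpec(kind=kind, target=target, source=source,
                        pretrain_config=FAST_PT, finetune_config=FAST_FT, **kw)


# -- metrics ------------------------------------------------------------------

def test_compute_metrics_worked_example():
    cell = compute_metrics(np.array([0.9, 0.4, 0.3, 0.2]), np.array([1, 1, 0, 0]))
    assert cell.accuracy == 75.0
    assert cell.error_rate == 50.0
    assert cell.correct_rate == 100.0
    assert cell.auc == 100.0  # all four error/correct pairs concordant


def test_compute_metrics_perfect_and_tied():
    perfect = compute_metrics(np.array([0.9, 0.8, 0.1, 0.2]), np.array([1, 1, 0, 0]))
    assert (perfect.accuracy, perfect.error_rate, perfect.correct_rate,
            perfect.auc) == (100.0, 100.0, 100.0, 100.0)
    tied = compute_metrics(np.full(10, 0.4), np.array([1, 0] * 5))
    assert tied.auc == 50.0


def test_single_class_auc_is_nan_with_warning():
    with pytest.warns(UserWarning, match="AUC"):
        cell = compute_metrics(np.array([0.9, 0.8]), np.array([1, 1]))
    assert np.isnan(cell.auc)
    assert cell.error_rate == 100.0


@given(st.integers(0, 2 ** 31 - 1))
def test_auc_equals_brute_force_concordance(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, 300))
    scores = np.round(rng.random(n), 2)  # rounding forces ties
    labels = rng.integers(0, 2, n)
    if len(np.unique(labels)) < 2:
        labels[0], labels[1] = 0, 1
    cell = compute_metrics(scores, labels)
    assert cell.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-9)


@given(st.integers(0, 2 ** 31 - 1))
def test_accuracy_is_prevalence_weighted_recall_mean(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 200))
    scores = rng.random(n)
    labels = rng.integers(0, 2, n)
    if len(np.unique(labels)) < 2:
        labels[0], labels[1] = 0, 1
    c = compute_metrics(scores, labels)
    weighted = (c.error_rate * c.n_error + c.correct_rate * c.n_correct) / n
    assert c.accuracy == pytest.approx(weighted, abs=1e-9)


def test_metrics_report_csv_and_means(tmp_path):
    cells = [compute_metrics(np.array([0.9, 0.1]), np.array([1, 0]),
                             scenario="x", train_unit="a", test_unit=str(i))
             for i in range(3)]
    report = MetricsReport(cells)
    assert report.mean("accuracy") == 100.0
    path = tmp_path / "m.csv"
    report.to_csv(path)
    text = path.read_text()
    assert text.count("\n") == 4  # header + 3 cells
    assert "accuracy" in text and "error_rate" in text
    report.to_csv(tmp_path / "m2.csv")
    assert (tmp_path / "m2.csv").read_text() == text  # reproducible output


# -- LDA baseline -------------------------------------------------------------

def _gaussian_sets(sep, seed=0, n=300):
    rng = np.random.default_rng(seed)

    def one(seed_offset):
        rng2 = np.random.default_rng(seed + seed_offset)
        labels = rng2.integers(0, 2, n)
        data = rng2.standard_normal((n, 2, 64))
        data[labels == 1] += sep
        return EpochSet(data, labels, np.full(n, "s01"), np.full(n, "1"),
                        np.full(n, "t"), ("FCz", "Cz"), 64.0)

    return one(1), one(2)


def test_lda_separated_gaussians():
    train, test = _gaussian_sets(sep=1.0)
    cell = lda_baseline(train, test)
    assert cell.accuracy >= 95.0


def test_lda_null_auc_near_chance():
    aucs = []
    for seed in range(10):
        train, test = _gaussian_sets(sep=0.0, seed=seed)
        aucs.append(lda_baseline(train, test).auc)
    assert np.mean(aucs) == pytest.approx(50.0, abs=5.0)


def test_lda_deterministic():
    train, test = _gaussian_sets(sep=0.5, seed=3)
    a, b = lda_baseline(train, test), lda_baseline(train, test)
    assert a == b


def test_noise_degrades_lda_separability():
    """More background noise never helps (non-strict, 1-point tolerance)."""
    means = []
    for noise in (0.5, 2.5, 8.0):
        accs = []
        for seed in range(10):
            cfg = SynthConfig(n_subjects=1, epochs_per_subject=160, noise_sd=noise,
                              sessions_per_subject=2, seed=40 + seed)
            es = generate_epochset(cfg)
            accs.append(lda_baseline(es.where(session="1"), es.where(session="2")).accuracy)
        means.append(np.mean(accs))
    assert means[0] + 1.0 >= means[1] >= means[2] - 1.0


# -- scenarios (scaled-down smoke runs) ---------------------------------------

@pytest.fixture(scope="module")
def small_multi():
    return generate_epochset(SynthConfig(
        n_subjects=3, epochs_per_subject=50, sessions_per_subject=1,
        noise_sd=2.0, seed=21))


def test_loso_grid_structure(small_multi):
    report = run_loso(spec_for("leave_one_subject_out", small_multi))
    assert len(report.cells) == 3  # one per held-out subject
    assert {c.test_unit for c in report.cells} == set(small_multi.subject_ids)
    assert all(c.train_unit == "rest" for c in report.cells)
    assert np.isfinite(report.mean("accuracy"))


def test_one_train_one_test_grid(small_multi):
    report = run_one_train_one_test(spec_for("one_train_one_test", small_multi))
    assert len(report.cells) == 6  # 3 x 2 off-diagonal cells
    assert all(c.train_unit != c.test_unit for c in report.cells)
    cols = report.column_means()
    assert set(cols) == set(small_multi.subject_ids)


def test_cross_task_pairs_baseline_and_provenance():
    src_cfg = SynthConfig(n_subjects=2, epochs_per_subject=50, task_id="src",
                          sessions_per_subject=1, noise_sd=2.0, seed=22)
    tgt_cfg = dataclasses.replace(src_cfg, task_id="tgt",
                                  task_shift=TaskShift(0.8, 0.02, 1.1))
    src, tgt = generate_task_pair(src_cfg, tgt_cfg)
    spec = spec_for("cross_task", tgt, source=src)
    report = run_cross_task(spec)
    scen = {c.scenario for c in report.cells}
    assert scen == {"cross_task", "non_pretrained"}
    # every fine-tuned column descends from the same pretrained checkpoint
    shas = set(report.meta["per_column_checkpoint_sha"].values())
    assert len(shas) == 1 and shas == {report.meta["checkpoint_sha"]}
    assert set(report.meta["column_delta"]) == set(tgt.subject_ids)


def test_cross_task_rejects_same_task(small_multi):
    with pytest.raises(ValueError, match="distinct"):
        run_cross_task(spec_for("cross_task", small_multi, source=small_multi))


def test_within_and_cross_session(two_session_set):
    within = run_within_session(spec_for("within_session", two_session_set))
    assert len(within.cells) == 4  # 2 subjects x 2 sessions
    cross = run_cross_session(spec_for("cross_session", two_session_set))
    assert len(cross.cells) == 4  # both directions per subject
    for c in cross.cells:
        assert c.train_unit != c.test_unit
    single = two_session_set.subset(two_session_set.sessions == "1")
    with pytest.raises(ValueError, match="session"):
        run_cross_session(spec_for("cross_session", single))


def test_run_scenario_dispatch(small_multi):
    report = run_scenario(spec_for("leave_one_subject_out", small_multi))
    assert report.cells
    with pytest.raises(ValueError):
        ScenarioSpec(kind="bogus", target=small_multi)


def test_report_render_mentions_units(small_multi):
    report = run_loso(spec_for("leave_one_subject_out", small_multi))
    text = report.render()
    assert "s01" in text and "accuracy" in text
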