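"""Statistical and determinism contracts of the synthetic ErrP generator."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from errpnet.synth import (ErpTemplate, SynthConfig, TaskShift, generate_epochset,
                           generate_task_pair, make_template)


def test_determinism_bit_identical():
    cfg = SynthConfig(n_subjects=2, epochs_per_subject=50, seed=5)
    a, b = generate_epochset(cfg), generate_epochset(cfg)
    assert a == b
    c = generate_epochset(dataclasses.replace(cfg, seed=6))
    assert not np.array_equal(a.data, c.data)


def test_class_counts_exact_per_subject():
    cfg = SynthConfig(n_subjects=3, epochs_per_subject=97, error_fraction=0.205, seed=1)
    es = generate_epochset(cfg)
    for s in es.subject_ids:
        sub = es.where(subject=s)
        assert sub.labels.sum() == round(0.205 * 97)
        assert len(sub) == 97


def test_default_error_fraction_matches_observed_prevalence():
    # ~1322 errors in 6437 trials => 0.2054
    assert SynthConfig().error_fraction == pytest.approx(1322 / 6437, abs=0.005)


def test_canonical_shape_and_finiteness():
    es = generate_epochset(SynthConfig(n_subjects=2, epochs_per_subject=30, seed=2))
    es.validate_canonical()
    assert np.isfinite(es.data).all()
    assert es.sampling_rate == 64.0


def test_empty_config_yields_empty_set():
    assert len(generate_epochset(SynthConfig(n_subjects=2, epochs_per_subject=0))) == 0


def test_zero_jitter_template_equals_population():
    cfg = SynthConfig(subject_jitter=(0.0, 0.0), seed=3)
    t = make_template(cfg, 0)
    assert t.ne_latency_s == cfg.template.ne_latency_s
    assert t.ne_amplitude == cfg.template.ne_amplitude
    assert t.pe_amplitude == cfg.template.pe_amplitude


def test_template_seed_determinism():
    cfg = SynthConfig(seed=4)
    a, b = make_template(cfg, 2), make_template(cfg, 2)
    assert a == b
    assert make_template(cfg, 3) != a


def test_template_jitter_monte_carlo_sd():
    """Sample sd of the Ne latency over 1000 draws within 15% of configured."""
    cfg = SynthConfig(subject_jitter=(0.02, 0.05), seed=7)
    lats = np.array([make_template(cfg, i).ne_latency_s for i in range(1000)])
    assert lats.std() == pytest.approx(0.02, rel=0.15)


def test_template_invariants_rejected():
    with pytest.raises(ValueError):
        ErpTemplate(ne_latency_s=0.5, pe_latency_s=0.3)
    with pytest.raises(ValueError):
        ErpTemplate(ne_amplitude=2.0)


def test_noiseless_means_recover_template():
    """noise_sd=0: error mean equals the subject template, correct mean flat."""
    cfg = SynthConfig(n_subjects=1, epochs_per_subject=40, noise_sd=0.0,
                      sessions_per_subject=1, seed=8)
    es = generate_epochset(cfg)
    rng = np.random.default_rng(np.random.SeedSequence(8, spawn_key=(0,)))
    template = make_template(cfg, 0, rng)
    err_mean = es.data[es.labels == 1].mean(axis=0)
    np.testing.assert_allclose(err_mean, template.waveform(), atol=1e-5)
    np.testing.assert_allclose(es.data[es.labels == 0], 0.0, atol=1e-12)


def test_error_vs_correct_difference_at_ne_latency():
    """Mean waveforms differ by the configured Ne amplitude (within 3 SE)."""
    cfg = SynthConfig(n_subjects=1, epochs_per_subject=2500, noise_sd=2.0,
                      subject_jitter=(0.0, 0.0), sessions_per_subject=1, seed=9)
    es = generate_epochset(cfg)
    t_idx = round(cfg.template.ne_latency_s * 64)
    err = es.data[es.labels == 1][:, 0, t_idx]
    corr = es.data[es.labels == 0][:, 0, t_idx]
    se = np.sqrt(err.var() / len(err) + corr.var() / len(corr))
    expected = cfg.template.waveform()[0, t_idx]  # Ne trough (plus Pe tail)
    assert abs((err.mean() - corr.mean()) - expected) < 3 * se


def test_degraded_subject_preset():
    base = SynthConfig(n_subjects=2, epochs_per_subject=400, noise_sd=1.0,
                       subject_jitter=(0.0, 0.0), sessions_per_subject=1,
                       degraded_subjects=(1,), seed=10)
    es = generate_epochset(base)
    good = es.where(subject="s01")
    bad = es.where(subject="s02")
    # near-zero template on the degraded subject
    amp_good = np.abs(good.data[good.labels == 1].mean(axis=0)).max()
    amp_bad = np.abs(bad.data[bad.labels == 1].mean(axis=0)).max()
    assert amp_bad < 0.2 * amp_good
    # doubled background noise
    assert bad.data[bad.labels == 0].std() > 1.5 * good.data[good.labels == 0].std()


def test_one_over_f_noise_spectrum_slopes_down():
    cfg = SynthConfig(n_subjects=1, epochs_per_subject=400, error_fraction=0.5,
                      noise_sd=1.0, noise_spectrum="one_over_f",
                      sessions_per_subject=1, seed=11)
    es = generate_epochset(cfg)
    corr = es.data[es.labels == 0]
    psd = np.abs(np.fft.rfft(corr, axis=-1)) ** 2
    mean_psd = psd.mean(axis=(0, 1))
    freqs = np.fft.rfftfreq(64, 1 / 64.0)
    low = mean_psd[(freqs >= 1) & (freqs < 8)].mean()
    high = mean_psd[(freqs >= 16) & (freqs <= 32)].mean()
    assert low > 3 * high


def test_task_pair_seed_determinism():
    src_cfg = SynthConfig(n_subjects=2, epochs_per_subject=40, task_id="a", seed=12)
    tgt_cfg = dataclasses.replace(src_cfg, task_id="b")
    p1 = generate_task_pair(src_cfg, tgt_cfg)
    p2 = generate_task_pair(src_cfg, tgt_cfg)
    assert p1[0] == p2[0] and p1[1] == p2[1]
    assert set(p1[0].tasks) != set(p1[1].tasks)


def test_task_pair_amplitude_scale_halves_ne():
    src_cfg = SynthConfig(n_subjects=2, epochs_per_subject=1300, noise_sd=1.0,
                          subject_jitter=(0.0, 0.02), sessions_per_subject=1,
                          task_id="a", seed=13)
    tgt_cfg = dataclasses.replace(src_cfg, task_id="b",
                                  task_shift=TaskShift(amplitude_scale=0.5))
    src, tgt = generate_task_pair(src_cfg, tgt_cfg)
    t_idx = round(0.25 * 64)

    def ne_amp(es):
        return (es.data[es.labels == 1][:, 0, t_idx].mean()
                - es.data[es.labels == 0][:, 0, t_idx].mean())

    assert ne_amp(tgt) == pytest.approx(0.5 * ne_amp(src), rel=0.15)


def test_task_pair_zero_shift_is_null():
    """With no shift the pair is exchangeable: Ne-amplitude t-test flat."""
    pvals = []
    for rep in range(20):
        src_cfg = SynthConfig(n_subjects=1, epochs_per_subject=200, noise_sd=2.0,
                              subject_jitter=(0.0, 0.0), sessions_per_subject=1,
                              task_id="a", seed=100 + rep)
        tgt_cfg = dataclasses.replace(src_cfg, task_id="b")
        src, tgt = generate_task_pair(src_cfg, tgt_cfg)
        t_idx = round(0.25 * 64)
        a = src.data[src.labels == 1][:, 0, t_idx]
        b = tgt.data[tgt.labels == 1][:, 0, t_idx]
        pvals.append(stats.ttest_ind(a, b).pvalue)
    # under the null, at most a couple of 20 replicates dip below alpha=0.01
    assert (np.array(pvals) < 0.01).sum() <= 2


def test_config_validation():
    with pytest.raises(ValueError):
        SynthConfig(error_fraction=0.0)
    with pytest.raises(ValueError):
        SynthConfig(noise_sd=-1.0)
    with pytest.raises(ValueError):
        SynthConfig(noise_spectrum="pink-ish")
    with pytest.raises(ValueError):
        SynthConfig.from_dict({"n_subjects": 2, "bogus": 1})
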