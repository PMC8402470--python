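import numpy as np
import pytest

import canegait as cg
from canegait.events import ConfigurationError
from canegait.simulate import corrupt


def test_recording_span_and_truth_strides():
    cfg = cg.GaitSimConfig(n_strides=40, stride_period=1.1, seed=0)
    rec, kin, gt = cg.simulate(cfg)
    assert gt.timeline.n_strides == 40
    assert kin.timestamps[-1] == pytest.approx(40 * 1.1, abs=2 * 1.1)
    assert rec.fsr.n_channels == 16
    assert np.all(rec.fsr.forces >= 0)
    # cane stream at 50 Hz, reference at 100 Hz
    assert np.median(np.diff(rec.fsr.timestamps)) == pytest.approx(0.02)
    assert np.median(np.diff(kin.timestamps)) == pytest.approx(0.01)


def test_same_seed_is_bitwise_identical():
    cfg = cg.GaitSimConfig(n_strides=5, injected_lag=0.2, seed=9)
    a_rec, a_kin, _ = cg.simulate(cfg)
    b_rec, b_kin, _ = cg.simulate(cfg)
    np.testing.assert_array_equal(a_rec.fsr.forces, b_rec.fsr.forces)
    np.testing.assert_array_equal(a_rec.cane_angle, b_rec.cane_angle)
    np.testing.assert_array_equal(a_kin.tracked_foot_speed, b_kin.tracked_foot_speed)


def test_infeasible_phase_fractions_rejected():
    bad = dict(cg.GaitSimConfig().phase_fractions)
    bad["mid_stance"] = 0.85  # out of canonical order
    with pytest.raises(ConfigurationError):
        cg.GaitSimConfig(phase_fractions=bad)


def test_planted_event_validation():
    with pytest.raises(ConfigurationError):
        cg.PlantedEvent("NotAVariable", "max", 0.5)
    with pytest.raises(ConfigurationError):
        cg.PlantedEvent("CoMZ", "peak", 0.5)


def test_noiseless_pipeline_recovers_planted_offset_exactly(clean_sim):
    cfg, (rec, kin, gt) = clean_sim
    layout = cg.load_default_layout()
    derived = cg.differentiate(cg.smooth(cg.compute_derived(rec.fsr, layout)))
    cands = cg.detect_stride_extrema(derived, gt.timeline)
    out = cg.consolidate_events(cands, min_strides=cfg.n_strides, total_strides=cfg.n_strides)
    planted = [
        e for e in out
        if (e.variable, e.kind, e.phase) == ("CoMZ", "max", "pre_swing")
    ]
    assert len(planted) == 1
    true_offset = (0.45 - cfg.phase_fractions["pre_swing"]) * cfg.stride_period
    # one cane-stream sample period of slack
    assert planted[0].median_offset == pytest.approx(true_offset, abs=0.02)


def test_corrupt_identity_and_dropout_rate(rng):
    x = rng.uniform(1, 2, size=(400, 3))
    np.testing.assert_array_equal(corrupt(x, 0.0, 0.0, seed=1), x)
    rates = [
        np.mean(np.all(corrupt(x, 0.05, 0.0, seed=s) == 0.0, axis=1))
        for s in range(20)
    ]
    assert np.mean(rates) == pytest.approx(0.05, abs=0.01)


def test_smoothing_suppresses_injected_spikes(clean_sim):
    """Short spikes on the raw forces do not move the planted event."""
    cfg, (rec, kin, gt) = clean_sim
    layout = cg.load_default_layout()

    def planted_offset(forces):
        fsr = cg.FSRSeries(timestamps=rec.fsr.timestamps, forces=forces)
        derived = cg.differentiate(cg.smooth(cg.compute_derived(fsr, layout)))
        cands = cg.detect_stride_extrema(derived, gt.timeline)
        out = cg.consolidate_events(cands, min_strides=10, total_strides=cfg.n_strides)
        match = [
            e for e in out
            if (e.variable, e.kind, e.phase) == ("CoMZ", "max", "pre_swing")
        ]
        assert len(match) == 1
        return match[0].median_offset

    clean = planted_offset(rec.fsr.forces)
    spiky = corrupt(rec.fsr.forces, 0.0, 0.01, spike_amplitude=0.5, seed=4)
    assert planted_offset(spiky) == pytest.approx(clean, abs=0.02)
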