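import numpy as np
import pytest

import canegait as cg
from canegait.events import (
    ConfigurationError,
    consolidate_events,
    detect_stride_extrema,
    normalize_stride_time,
    select_central_strides,
    smooth,
)
from canegait.segmentation import PHASES
from canegait.variables import DerivedSeries, InsufficientDataError


def _derived(t, **channels):
    return DerivedSeries(timestamps=t, channels={k: np.asarray(v) for k, v in channels.items()})


def _timeline(n, period=1.0, t0=0.5, fractions=None):
    if fractions is None:
        fractions = [0.0, 0.1, 0.3, 0.5, 0.6, 0.73, 0.87]
    strides = [
        {p: t0 + (k + f) * period for p, f in zip(PHASES, fractions)}
        for k in range(n)
    ]
    return cg.PhaseTimeline(strides=strides, recording_end=t0 + n * period)


# --- Savitzky-Golay stage ----------------------------------------------------

def test_savgol_reproduces_cubics_and_constants():
    t = np.arange(300) * 0.02
    cubic = 0.3 * t**3 - 2.0 * t**2 + t - 5.0
    d = smooth(_derived(t, CoMZ=cubic, MPUp=np.full_like(t, 7.0)), window=11)
    h = 5  # half-window: boundary fits use asymmetric windows
    np.testing.assert_allclose(d.channels["CoMZ"][h:-h], cubic[h:-h], atol=1e-9)
    np.testing.assert_allclose(d.channels["MPUp"], 7.0, atol=1e-9)


def test_smoothing_shrinks_noise_variance(rng):
    t = np.arange(500) * 0.02
    for _ in range(5):
        noise = rng.normal(0, 1, t.size)
        d = smooth(_derived(t, CoMZ=noise), window=11)
        assert d.channels["CoMZ"].var() < noise.var()


@pytest.mark.parametrize("window", [10, 3, 1001])
def test_smooth_window_preconditions(window):
    t = np.arange(100) * 0.02
    with pytest.raises(ConfigurationError):
        smooth(_derived(t, CoMZ=np.sin(t)), window=window)


# --- central-stride selection ------------------------------------------------

def test_central_stride_selection_window():
    tl = select_central_strides(_timeline(40), n=30)
    assert tl.n_strides == 30
    # strides 6..35 (1-indexed) survive: first kept contact is stride 5's
    assert tl.initial_contacts()[0] == pytest.approx(0.5 + 5 * 1.0)
    assert tl.initial_contacts()[-1] == pytest.approx(0.5 + 34 * 1.0)


def test_central_selection_identity_and_error():
    tl30 = _timeline(30)
    assert select_central_strides(tl30, n=30).strides == tl30.strides
    with pytest.raises(InsufficientDataError):
        select_central_strides(_timeline(20), n=30)


def test_odd_surplus_discards_extra_leading_stride():
    tl = select_central_strides(_timeline(33), n=30)
    assert tl.initial_contacts()[0] == pytest.approx(0.5 + 2 * 1.0)


# --- extremum detection and phase referencing --------------------------------

def test_flat_channel_yields_no_candidates():
    tl = _timeline(4)
    t = np.arange(0, 5, 0.02)
    cands = detect_stride_extrema(_derived(t, CoMZ=np.full_like(t, 3.0)), tl)
    assert cands == []


def test_extremum_at_phase_onset_has_zero_offset():
    tl = _timeline(4)
    t = np.arange(0, 5, 0.002)
    # plant a sharp maximum exactly at every pre_swing onset (t0 + k + 0.5)
    y = np.zeros_like(t)
    for k in range(4):
        y += np.exp(-0.5 * ((t - (1.0 + k)) / 0.03) ** 2)
    cands = detect_stride_extrema(_derived(t, CoMZ=y), tl)
    maxima = [c for c in cands if c.kind == "max"]
    assert maxima and all(c.referenced_phase == "pre_swing" for c in maxima)
    assert max(abs(c.offset) for c in maxima) < 0.005


def test_event_before_onset_reports_negative_offset(clean_sim):
    cfg, (rec, kin, gt) = clean_sim
    derived = cg.differentiate(
        smooth(cg.compute_derived(rec.fsr, cg.load_default_layout()))
    )
    cands = detect_stride_extrema(derived, gt.timeline)
    planted = [
        c for c in cands
        if c.variable == "CoMZ" and c.kind == "max" and c.referenced_phase == "pre_swing"
    ]
    assert len(planted) >= cfg.n_strides - 1
    assert all(c.offset < 0 for c in planted)
    # planted 5% of the cycle before the pre-swing onset
    true_offset = -0.05 * cfg.stride_period
    assert abs(np.median([c.offset for c in planted]) - true_offset) < 0.02


# --- consistency filter -------------------------------------------------------

def _candidates_in_k_strides(k):
    return [
        cg.EventCandidate(
            variable="CoMZ", kind="max", stride_id=s, time=float(s),
            referenced_phase="pre_swing", offset=-0.05,
        )
        for s in range(k)
    ]


@pytest.mark.parametrize("k, retained", [(24, False), (25, True), (30, True)])
def test_consistency_filter_boundary(k, retained):
    out = consolidate_events(_candidates_in_k_strides(k), min_strides=25, total_strides=30)
    assert bool(out) is retained
    if retained:
        assert out[0].n_strides_detected == k
        assert out[0].median_offset == pytest.approx(-0.05)


def test_duplicate_candidates_in_one_stride_count_once():
    cands = _candidates_in_k_strides(25) + _candidates_in_k_strides(5)
    out = consolidate_events(cands, min_strides=25, total_strides=30)
    assert out[0].n_strides_detected == 25


# --- stride-time normalization -------------------------------------------------

def test_identical_strides_equal_their_mean(clean_sim):
    cfg, (rec, kin, gt) = clean_sim
    derived = cg.compute_derived(rec.fsr, cg.load_default_layout())
    norm = normalize_stride_time(derived, gt.timeline)
    for name, rows in norm.curves.items():
        for row in rows:
            np.testing.assert_allclose(row, norm.mean_curves[name], atol=1e-6)
    for p in PHASES:
        assert norm.phase_fractions[p] == pytest.approx(
            cfg.phase_fractions[p], abs=1e-9
        )


def test_single_stride_mean_is_that_stride():
    tl = _timeline(1)
    t = np.arange(0, 2, 0.02)
    d = _derived(t, CoMZ=np.sin(2 * np.pi * t))
    norm = normalize_stride_time(d, tl)
    np.testing.assert_allclose(norm.curves["CoMZ"][0], norm.mean_curves["CoMZ"])
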