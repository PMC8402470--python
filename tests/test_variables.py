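import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from canegait.layout import load_default_layout
from canegait.variables import (
    ChannelCountError,
    DerivedSeries,
    FSRSeries,
    InsufficientDataError,
    compute_derived,
    compute_derived_naive,
    differentiate,
)

# independent oracle: the ten top-side x coordinates of the reference handle
TOP_X = [-15.21, -5.29, 4.71, 14.58, 24.44, 34.50, 44.60, 54.71, 64.80, 74.86]


def _series(forces):
    forces = np.atleast_2d(np.asarray(forces, dtype=float))
    t = np.arange(forces.shape[0]) * 0.02
    return FSRSeries(timestamps=t, forces=forces)


def test_uniform_grip_centres_on_mean_coordinates(layout):
    d = compute_derived(_series(np.full(16, 2.5)), layout)
    assert d.channels["CoMXUp"][0] == pytest.approx(np.mean(TOP_X), abs=1e-9)


@pytest.mark.parametrize(
    "sensor, comx, comz", [(3, 4.71, 85.22), (1, -15.21, 85.05), (16, 64.65, 54.08)]
)
def test_single_active_sensor_pins_centre_of_pressure(layout, sensor, comx, comz):
    f = np.zeros(16)
    f[sensor - 1] = 3.7
    d = compute_derived(_series(f), layout)
    assert d.channels["CoMX"][0] == pytest.approx(comx, abs=1e-9)
    assert d.channels["CoMZ"][0] == pytest.approx(comz, abs=1e-9)
    side_channel = "CoMXUp" if sensor <= 10 else "CoMXDown"
    assert d.channels[side_channel][0] == pytest.approx(comx, abs=1e-9)


def test_unloaded_sample_is_masked_not_fabricated(layout):
    d = compute_derived(_series(np.zeros(16)), layout)
    for name in ("CoMXUp", "CoMXDown", "CoMX", "CoMZ"):
        assert not d.valid[name][0]
        assert np.isnan(d.channels[name][0])
    assert d.channels["MPUp"][0] == 0.0
    assert d.channels["MPDown"][0] == 0.0


def test_mean_pressure_is_subset_sum_over_subset_size(layout):
    f = np.arange(1.0, 17.0)
    d = compute_derived(_series(f), layout)
    assert d.channels["MPUp"][0] == pytest.approx(f[:10].sum() / 10)
    assert d.channels["MPDown"][0] == pytest.approx(f[10:].sum() / 6)


def test_channel_count_mismatch_rejected(layout):
    with pytest.raises(ChannelCountError):
        compute_derived(
            FSRSeries(timestamps=[0.0], forces=np.ones((1, 15))), layout
        )


def test_vectorized_matches_naive_loop_oracle(layout, rng):
    forces = rng.uniform(0, 5, size=(200, 16))
    forces[rng.random(200) < 0.05] = 0.0  # include unloaded samples
    s = _series(forces)
    fast = compute_derived(s, layout)
    slow = compute_derived_naive(s, layout)
    for name in fast.channels:
        np.testing.assert_array_equal(fast.valid[name], slow.valid[name])
        ok = fast.valid[name]
        np.testing.assert_allclose(
            fast.channels[name][ok], slow.channels[name][ok], rtol=1e-9
        )


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    # subnormal forces are excluded: a weighted mean of subnormals quantizes
    # to whole ulps and can leave the coordinate hull; sensors never emit them
    forces=st.lists(
        st.floats(min_value=0.0, max_value=100.0, allow_nan=False, allow_subnormal=False),
        min_size=16,
        max_size=16,
    ),
    scale=st.floats(min_value=1e-3, max_value=1e3),
)
def test_convexity_and_scale_invariance(forces, scale):
    layout = load_default_layout()
    f = np.asarray(forces)
    d = compute_derived(_series(f), layout)
    subsets = {
        "CoMXUp": (layout.x, layout.top_mask),
        "CoMXDown": (layout.x, layout.bottom_mask),
        "CoMX": (layout.x, slice(None)),
        "CoMZ": (layout.z, slice(None)),
    }
    for name, (coord, mask) in subsets.items():
        if d.valid[name][0]:
            assert coord[mask].min() - 1e-9 <= d.channels[name][0] <= coord[mask].max() + 1e-9
    d2 = compute_derived(_series(scale * f), layout)
    for name in subsets:
        if d.valid[name][0]:
            assert d2.channels[name][0] == pytest.approx(d.channels[name][0], rel=1e-9)
    for name in ("MPUp", "MPDown"):
        assert d2.channels[name][0] == pytest.approx(scale * d.channels[name][0], rel=1e-9)


def test_layout_row_order_does_not_matter(layout, rng):
    forces = rng.uniform(0, 5, size=(20, 16))
    shuffled = layout.to_frame().sample(frac=1.0, random_state=0)
    lay2 = type(layout).from_frame(shuffled)
    a = compute_derived(_series(forces), layout)
    b = compute_derived(_series(forces), lay2)
    for name in a.channels:
        np.testing.assert_array_equal(a.channels[name], b.channels[name])


def test_differentiate_constant_linear_and_sinusoid():
    t = np.arange(200) * 0.02
    chans = {
        "CoMZ": np.full_like(t, 80.0),
        "CoMX": 3.0 * t,
        "MPUp": np.sin(2 * np.pi * 1.5 * t),
    }
    d = differentiate(DerivedSeries(timestamps=t, channels=chans))
    np.testing.assert_allclose(d.channels["dCoMZ"], 0.0, atol=1e-12)
    np.testing.assert_allclose(d.channels["dCoMX"][1:-1], 3.0, rtol=1e-9)
    w = 2 * np.pi * 1.5
    expected = w * np.cos(w * t)
    # central differences: error bound (w*dt)^2/6 * w ~ 0.056 at dt = 0.02
    bound = 1.1 * w**3 * 0.02**2 / 6
    np.testing.assert_allclose(d.channels["dMPUp"][1:-1], expected[1:-1], atol=bound)


def test_differentiate_requires_three_samples():
    with pytest.raises(InsufficientDataError):
        differentiate(
            DerivedSeries(timestamps=[0.0, 0.02], channels={"CoMZ": [1.0, 2.0]})
        )
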