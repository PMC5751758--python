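"""Per-block feature computations against hand values and brute-force oracles."""

import numpy as np
import pytest

import bruteforce as bf
from emostage.features import blocks
from emostage.features.registry import (
    EXPECTED_BLOCKS,
    REGISTRY,
    build_registry,
)

FS = 128.0
RNG = np.random.default_rng(20240917)


# --------------------------------------------------------------------------
# registry structure


def test_registry_blocks_and_total():
    reg = build_registry()
    assert len(reg) == 742
    assert reg.blocks == EXPECTED_BLOCKS
    lengths = [hi - lo + 1 for lo, hi in reg.blocks.values()]
    assert lengths == [448, 56, 96, 8, 34, 4, 20, 55, 21]
    assert len(set(reg.names)) == 742


# --------------------------------------------------------------------------
# EEG time/frequency


def test_constant_signal_degenerate_conventions():
    out = blocks.eeg_time_freq(np.full(512, 3.7), FS)
    mean, var, p2p, skew, kurt = out[:5]
    assert mean == pytest.approx(3.7)
    assert var == pytest.approx(0.0, abs=1e-24)
    assert p2p == 0
    assert skew == kurt == 0
    activity, mobility, complexity = out[11:14]
    assert activity == mobility == complexity == 0


def test_sinusoid_concentrates_power_in_alpha():
    t = np.arange(512) / FS
    x = np.sin(2 * np.pi * 10.0 * t)
    out = blocks.eeg_time_freq(x, FS)
    theta, alpha, beta, gamma = out[5:9]
    assert alpha > 50 * max(theta, beta, gamma)
    assert out[11] == pytest.approx(np.var(x))    # Hjorth activity = variance


def test_white_noise_hjorth_complexity_exceeds_one():
    x = RNG.standard_normal(10_000)
    _, _, complexity = blocks.hjorth_parameters(x)
    assert complexity > 1


def test_hemispheric_asymmetry_is_right_minus_left():
    left = np.array([1.5, 1.5, 1.0, 0.5])
    right = np.array([1.5, 2.0, 1.0, 0.5])
    asym = blocks.hemispheric_asymmetry(left, right)
    assert asym == pytest.approx([0.0, 0.5, 0.0, 0.0])
    assert blocks.hemispheric_asymmetry(right, left) == pytest.approx(-asym)


def test_entropy_extremes():
    t = np.arange(512) / FS
    assert blocks.spectral_entropy(np.sin(2 * np.pi * 10 * t), FS) < 0.2
    assert blocks.spectral_entropy(RNG.standard_normal(4096), FS) > 0.9
    assert blocks.shannon_entropy(np.full(100, 2.0)) == 0.0
    assert blocks.c0_complexity(np.sin(2 * np.pi * 10 * t)) < 0.05


# --------------------------------------------------------------------------
# extrema ratios and difference statistics


def test_alternating_signal_extrema_ratios():
    x = np.array([0.0, 1.0, 0.0, 1.0, 0.0])
    assert blocks.max_ratio(x) == pytest.approx(2 / 5)
    assert blocks.min_ratio(x) == pytest.approx(2 / 5)


def test_monotone_and_triangle_extrema():
    ramp = np.linspace(0, 1, 50)
    assert blocks.max_ratio(ramp) == blocks.min_ratio(ramp) == 0
    tri = np.concatenate([np.linspace(0, 1, 25), np.linspace(1, 0, 25)[1:]])
    tri = np.tile(tri, 4)
    assert blocks.max_ratio(tri) == blocks.min_ratio(tri)


def test_linear_ramp_difference_features():
    # dyadic step so first differences are exactly constant in float
    x = np.arange(200) * 0.5
    out = blocks.emg_features(x, FS)
    # layout: mean, var, power, 1Diff (mean, median, min, var, max, ...), 2Diff
    assert out[6] == pytest.approx(0.0, abs=1e-18)      # 1Diff-Var
    assert np.allclose(out[10:17], 0.0, atol=1e-12)     # 2Diff block all zero


def test_constant_temperature_has_no_band_power():
    out = blocks.tmp_features(np.full(512, 33.0), FS)
    assert out[0] == pytest.approx(33.0)
    assert out[1] == out[2] == out[3] == 0.0


# --------------------------------------------------------------------------
# cardiovascular features


def test_pnn50_hand_count():
    assert blocks.pnn50(np.array([800.0, 860.0, 865.0, 920.0])) == pytest.approx(2 / 3)


def test_triangular_index_of_constant_nn_series():
    assert blocks.triangular_index(np.full(10, 800.0)) == pytest.approx(1.0)


def test_periodic_pulse_at_60_bpm():
    t = np.arange(int(8 * FS)) / FS
    x = np.sin(2 * np.pi * 1.0 * t)                  # one beat per second
    vals, missing = blocks.bvp_features(x, FS)
    assert not missing.any()
    names = [n.replace("BVP-", "") for n in
             REGISTRY.names[REGISTRY.blocks["bvp"][0] - 1:REGISTRY.blocks["bvp"][1]]]
    f = dict(zip(names, vals))
    assert f["Hr-Mean"] == pytest.approx(60.0, abs=1.0)
    # peak positions jitter by one sample at fs=128, ~0.5 bpm of spread
    assert f["Hr-Var"] == pytest.approx(0.0, abs=1.5)
    # band-pass edge transients can move edge peaks by a few samples
    assert f["Hrv-Range"] == pytest.approx(0.0, abs=50.0)
    assert f["Hrv-pNN50"] == 0.0


def test_flat_pulse_flags_missing():
    vals, missing = blocks.bvp_features(np.zeros(512), FS)
    assert missing.all() and not vals.any()


# --------------------------------------------------------------------------
# respiration and skin conductance


def test_rsp_output_length_and_periodic_breathing():
    # 24 s holds >= 3 full breath cycles, enough for the derived sub-series
    t = np.arange(int(24 * FS)) / FS
    x = np.sin(2 * np.pi * 0.25 * t)
    vals, missing = blocks.rsp_features(x, FS)
    assert vals.shape == (55,) and missing.shape == (55,)
    assert not missing.any()
    names = [n.replace("RSP-", "") for n in
             REGISTRY.names[REGISTRY.blocks["rsp"][0] - 1:REGISTRY.blocks["rsp"][1]]]
    f = dict(zip(names, vals))
    assert f["RSPPulse-Mean"] == pytest.approx(4.0, abs=0.1)    # 0.25 Hz breaths
    assert f["RSPAmpl-Var"] == pytest.approx(0.0, abs=1e-3)

    doubled = dict(zip(names, blocks.rsp_features(2 * x, FS)[0]))
    assert doubled["RSPAmpl-Mean"] == pytest.approx(2 * f["RSPAmpl-Mean"], rel=1e-6)
    assert doubled["RSPPulse-Mean"] == pytest.approx(f["RSPPulse-Mean"], rel=1e-6)


def test_gsr_rising_and_decay_times():
    n = int(4 * FS)
    rising = blocks.gsr_features(np.linspace(0, 1, n), FS)
    assert rising[0] == pytest.approx(4.0, abs=2 / FS)   # rising time
    assert rising[1] == 0.0                              # decay time
    tri = np.concatenate([np.linspace(0, 1, n // 2),
                          np.linspace(1, 0, n // 2)])
    out = blocks.gsr_features(tri, FS)
    assert out[0] == pytest.approx(out[1], abs=2 / FS)
    assert out.shape == (21,)


# --------------------------------------------------------------------------
# oracle equivalence on random signals


@pytest.mark.parametrize("trial", range(5))
def test_statistics_match_bruteforce(trial):
    x = RNG.standard_normal(100) * RNG.uniform(0.5, 3) + RNG.uniform(-2, 2)
    xs = x.tolist()
    out = blocks.eeg_time_freq(x, FS)
    assert out[0] == pytest.approx(bf.mean(xs))
    assert out[1] == pytest.approx(bf.var(xs))
    assert out[2] == pytest.approx(bf.ptp(xs))
    assert out[3] == pytest.approx(bf.skewness(xs))
    assert out[4] == pytest.approx(bf.kurtosis_excess(xs))
    for i, (lo, hi) in enumerate([(4, 7), (8, 15), (16, 31), (32, 45)]):
        assert out[5 + i] == pytest.approx(bf.band_power(xs, FS, lo, hi))
    act, mob, comp = bf.hjorth(xs)
    assert out[11] == pytest.approx(act)
    assert out[12] == pytest.approx(mob)
    assert out[13] == pytest.approx(comp)

    nl = blocks.eeg_nonlinear(x, FS)
    assert nl[0] == pytest.approx(bf.spectral_entropy(xs, FS))
    assert nl[1] == pytest.approx(bf.shannon_entropy(xs))
    assert nl[2] == pytest.approx(bf.c0_complexity(xs))

    assert blocks.max_ratio(x) == pytest.approx(bf.extrema_counts(xs)[0] / len(xs))
    assert blocks.min_ratio(x) == pytest.approx(bf.extrema_counts(xs)[1] / len(xs))


def test_ratio_features_bounded_and_psd_nonnegative():
    for _ in range(10):
        x = RNG.standard_normal(80)
        assert 0 <= blocks.max_ratio(x) <= 1
        assert 0 <= blocks.min_ratio(x) <= 1
        _f, pxx = blocks.periodogram(x, FS)
        assert (pxx >= 0).all()
        g = blocks.gsr_features(x, FS)
        assert g[0] + g[1] <= len(x) / FS + 1e-9   # rising + decay <= window
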