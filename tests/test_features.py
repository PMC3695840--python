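"""Peak detection, the six dynamic features, pattern taxonomy, synthetic signals."""

import numpy as np
import pytest

import nfkbse as nk
from nfkbse.features import (
    FeatureSettings,
    PatternLabel,
    PeakSettings,
    detect_peaks,
    extract_features_series,
    classify_pattern,
    classify_series,
    feature_distributions,
    pattern_distribution,
)
from nfkbse.signals import SyntheticSignalSpec, generate_synthetic_signal


def brute_force_extrema(t, y, settings: PeakSettings):
    """Independent oracle: test every interior grid point against both
    neighbors, then apply the same prominence/floor/interleaving rules."""
    from scipy.signal import peak_prominences

    gmax = y.max()
    prom_thr = settings.prominence_frac * gmax
    raw_max = [i for i in range(1, len(y) - 1) if y[i] > y[i - 1] and y[i] >= y[i + 1]]
    raw_min = [i for i in range(1, len(y) - 1) if y[i] < y[i - 1] and y[i] <= y[i + 1]]
    if prom_thr > 0:
        pm = peak_prominences(y, raw_max)[0] if raw_max else np.array([])
        raw_max = [i for i, p in zip(raw_max, pm) if p >= prom_thr]
        pn = peak_prominences(-y, raw_min)[0] if raw_min else np.array([])
        raw_min = [i for i, p in zip(raw_min, pn) if p >= prom_thr]
    else:
        raw_max, raw_min = [], []
    raw_max = [i for i in raw_max if y[i] >= settings.amplitude_floor]
    events = sorted([(t[i], y[i], True) for i in raw_max] + [(t[i], y[i], False) for i in raw_min])
    out = []
    for ev in events:
        if out and out[-1][2] == ev[2]:
            if (ev[2] and ev[1] > out[-1][1]) or (not ev[2] and ev[1] < out[-1][1]):
                out[-1] = ev
        else:
            out.append(ev)
    peaks = [(tt, vv) for tt, vv, p in out if p]
    troughs = [(tt, vv) for tt, vv, p in out if not p]
    return peaks, troughs


class TestDetectPeaks:
    def test_constant_series_has_no_structure(self):
        t = np.linspace(0, 10, 101)
        pl = detect_peaks(t, np.ones_like(t))
        assert pl.n_peaks == 0 and len(pl.trough_times) == 0

    def test_sine_analytic_extrema(self):
        t = np.linspace(0, 4 * np.pi, 4001)
        pl = detect_peaks(t, 1 + np.sin(t))
        assert pl.peak_times == pytest.approx([np.pi / 2, 5 * np.pi / 2], abs=0.02)
        # the inter-peak valley plus the trailing minimum after the last peak
        assert pl.trough_times == pytest.approx([3 * np.pi / 2, 7 * np.pi / 2], abs=0.02)

    def test_matches_brute_force_oracle_on_simulation(self, wt_ensemble):
        settings = PeakSettings()
        for traj in wt_ensemble.trajectories[:20]:
            t, y = traj.t_h, traj.series("NFkBn")
            pl = detect_peaks(t, y, settings)
            peaks, troughs = brute_force_extrema(t, y, settings)
            assert list(pl.peak_times) == [p[0] for p in peaks]
            assert list(pl.trough_times) == [p[0] for p in troughs]

    def test_matches_brute_force_oracle_on_noisy_synthetic(self):
        spec = SyntheticSignalSpec(family="damped_cosine", decay_h=3.0, noise=0.03)
        t, y = generate_synthetic_signal(spec, seed=4)
        settings = PeakSettings(amplitude_floor=1e-3)
        pl = detect_peaks(t, y, settings)
        peaks, troughs = brute_force_extrema(t, y, settings)
        assert list(pl.peak_times) == [p[0] for p in peaks]
        assert list(pl.trough_values) == [p[1] for p in troughs]

    def test_peaks_and_troughs_interleave(self, bkeko_ensemble):
        for traj in bkeko_ensemble.trajectories[:20]:
            pl = detect_peaks(traj.t_h, traj.series("NFkBn"))
            events = sorted(
                [(tt, 1) for tt in pl.peak_times] + [(tt, 0) for tt in pl.trough_times]
            )
            kinds = [k for _, k in events]
            assert all(a != b for a, b in zip(kinds, kinds[1:]))

    def test_input_validation(self):
        with pytest.raises(ValueError):
            detect_peaks(np.arange(2.0), np.arange(2.0))
        with pytest.raises(ValueError):
            detect_peaks(np.arange(5.0), np.array([0.0, 1.0, np.nan, 1.0, 0.0]))


class TestExtractFeatures:
    def test_shifted_sine_analytic_features(self):
        t = np.linspace(0, 4 * np.pi, 8001)
        feats, _ = extract_features_series(t, 1 + np.sin(t))
        assert feats.first_maximum == pytest.approx(2.0, rel=1e-4)
        assert feats.first_translocation_time == pytest.approx(np.pi / 2, abs=0.01)
        assert feats.first_period == pytest.approx(2 * np.pi, abs=0.02)
        assert feats.ratio_first_min_to_first_max == pytest.approx(0.0, abs=1e-6)
        assert feats.ratio_second_max_to_first_max == pytest.approx(1.0, rel=1e-4)

    def test_monotone_saturating_has_undefined_peak_features(self):
        t = np.linspace(0, 12, 1201)
        feats, _ = extract_features_series(t, 1 - np.exp(-t))
        assert not feats.defined("first_translocation_time")
        assert not feats.defined("ratio_steady_state_to_first_max")
        assert feats.steady_state == pytest.approx(1.0, abs=1e-3)
        assert feats.n_peaks == 0

    def test_scale_equivariance(self, wt_trajectory):
        """y -> c*y multiplies first_maximum by c; ratios and times unchanged."""
        t, y = wt_trajectory.t_h, wt_trajectory.series("NFkBn")
        a, _ = extract_features_series(t, y)
        c = 37.5
        b, _ = extract_features_series(t, c * y, FeatureSettings(
            peaks=PeakSettings(amplitude_floor=6e-6 * c)))
        assert b.first_maximum == pytest.approx(c * a.first_maximum, rel=1e-12)
        for name in ("first_translocation_time", "first_period",
                     "ratio_first_min_to_first_max",
                     "ratio_second_max_to_first_max",
                     "ratio_steady_state_to_first_max"):
            assert b.value(name) == pytest.approx(a.value(name), rel=1e-9)

    def test_time_shift_equivariance(self, wt_trajectory):
        t, y = wt_trajectory.t_h, wt_trajectory.series("NFkBn")
        a, _ = extract_features_series(t, y)
        b, _ = extract_features_series(t + 2.5, y)
        assert b.first_translocation_time == pytest.approx(
            a.first_translocation_time + 2.5, abs=1e-12)
        assert b.first_period == pytest.approx(a.first_period, abs=1e-12)

    def test_features_consistent_with_peak_list(self, bkeko_ensemble):
        for traj in bkeko_ensemble.trajectories[:10]:
            feats, peaks = extract_features_series(traj.t_h, traj.series("NFkBn"))
            if peaks.n_peaks >= 1:
                assert feats.first_maximum == peaks.peak_values[0]
            if peaks.n_peaks >= 2:
                assert feats.first_period == pytest.approx(
                    peaks.peak_times[1] - peaks.peak_times[0])


class TestClassifier:
    def test_sustained_sine(self):
        t = np.linspace(0, 20, 4001)
        assert classify_series(t, 1 + np.sin(2 * np.pi * t / 2)) is PatternLabel.SUSTAINED_OSCILLATION

    def test_monotone_increase(self):
        t = np.linspace(0, 10, 1001)
        assert classify_series(t, 1 - np.exp(-t)) is PatternLabel.MONOTONIC_INCREASING

    def test_single_peak(self):
        t = np.linspace(0, 10, 1001)
        assert classify_series(t, t * np.exp(-t)) is PatternLabel.SINGLE_PEAKED

    def test_damped_cosine_with_fast_decay_is_damped(self):
        """Peak amplitude decaying 0.3x per cycle falls below the declared
        0.6 sustained threshold."""
        period = 2.0
        decay = -period / np.log(0.3)
        spec = SyntheticSignalSpec(family="damped_cosine", period_h=period,
                                   decay_h=decay, duration_h=12.0)
        t, y = generate_synthetic_signal(spec)
        assert classify_series(t, y) is PatternLabel.DAMPED_OSCILLATION

    def test_classification_total_on_ensemble(self, wt_features):
        labels = set(wt_features["pattern"])
        valid = {m.value for m in PatternLabel}
        assert labels <= valid
        assert len(wt_features) == 200


class TestDistributions:
    def test_point_mass_for_single_replicate(self):
        t = np.linspace(0, 12, 1201)
        feats, _ = extract_features_series(t, 1 + np.sin(t))
        summary = feature_distributions([feats])
        s = summary["first_maximum"]
        assert s.n_defined == 1 and s.counts.sum() == 1
        assert s.mean == pytest.approx(2.0, rel=1e-3)

    def test_mean_matches_direct_mean(self, wt_features):
        dists = feature_distributions(wt_features)
        for name in ("first_maximum", "first_period"):
            col = wt_features[name].dropna()
            assert dists[name].mean == pytest.approx(col.mean(), rel=1e-12)
            assert dists[name].n_defined == len(col)

    def test_all_undefined_feature_is_flagged_not_raised(self):
        t = np.linspace(0, 10, 1001)
        feats, _ = extract_features_series(t, 1 - np.exp(-t))
        summary = feature_distributions([feats])
        s = summary["first_translocation_time"]
        assert s.n_defined == 0 and s.n_undefined == 1 and np.isnan(s.mean)

    def test_pattern_fractions_sum_to_one(self, wt_features):
        fr = pattern_distribution(wt_features["pattern"])
        assert sum(fr.values()) == pytest.approx(1.0, abs=1e-12)
        assert set(fr) == {m.value for m in PatternLabel}

    def test_uniform_labels(self):
        fr = pattern_distribution([PatternLabel.SINGLE_PEAKED] * 5)
        assert fr["single_peaked"] == 1.0 and fr["damped_oscillation"] == 0.0


class TestSyntheticSignals:
    def test_damped_cosine_infinite_decay_is_sustained_sine(self):
        spec = SyntheticSignalSpec(family="damped_cosine", period_h=2.0, duration_h=10.0)
        t, y = generate_synthetic_signal(spec)
        feats, _ = extract_features_series(t, y)
        assert feats.first_period == pytest.approx(2.0, abs=0.02)
        assert feats.ratio_second_max_to_first_max == pytest.approx(1.0, rel=1e-6)

    def test_constant_family_is_monotonic_class(self):
        t, y = generate_synthetic_signal(SyntheticSignalSpec(family="constant", baseline=0.5))
        assert classify_series(t, y) is PatternLabel.MONOTONIC_INCREASING

    def test_noise_is_seeded_and_reproducible(self):
        spec = SyntheticSignalSpec(noise=0.1)
        _, y1 = generate_synthetic_signal(spec, seed=9)
        _, y2 = generate_synthetic_signal(spec, seed=9)
        _, y3 = generate_synthetic_signal(spec, seed=10)
        assert np.array_equal(y1, y2) and not np.array_equal(y1, y3)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            SyntheticSignalSpec(family="sawtooth")
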