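"""Window standardization, cross-correlogram and observation extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from cmacdyn.crosscorr import (confidence_bound, crosscorrelogram, extract_all,
                               extract_observations, lags_axis,
                               standardize_window)
from cmacdyn.preprocess import ProcessedTrack, process_table
from cmacdyn.synthetic import CohortConfig, LagRule, generate_cohort


def brute_force_correlogram(a, t, max_lag):
    """Independent double-loop Σ-product oracle."""
    n = len(a)
    denom = np.sqrt(np.dot(a, a) * np.dot(t, t))
    out = []
    for lag in range(-max_lag, max_lag + 1):
        s = 0.0
        for k in range(n):
            if 0 <= k - lag < n:
                s += a[k] * t[k - lag]
        out.append(s / denom)
    return np.array(out)


class TestStandardize:
    def test_window_sd_variant(self):
        out = standardize_window([1.0, 2.0, 3.0])
        assert out.mean() == pytest.approx(0.0)
        assert out.std(ddof=1) == pytest.approx(1.0)

    def test_supplied_scale_only_centres(self):
        out = standardize_window([5.0, 7.0, 9.0], scale=1.0)
        assert out == pytest.approx([-2.0, 0.0, 2.0])

    def test_constant_window_degenerate(self):
        assert standardize_window([4.0, 4.0, 4.0]) is None

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            standardize_window([1.0, 2.0])


class TestCorrelogram:
    def test_identical_series_unit_peak_at_zero(self):
        a = standardize_window([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        r = crosscorrelogram(a, a, 3)
        assert r[3] == pytest.approx(1.0)
        assert np.argmax(np.abs(r)) == 3

    def test_negated_series(self):
        a = standardize_window([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        r = crosscorrelogram(a, -a, 3)
        assert r[3] == pytest.approx(-1.0)

    def test_shifted_series_peaks_at_positive_lag(self, rng):
        base = rng.normal(size=13)
        a = base[:-1] - base[:-1].mean()
        t = base[1:] - base[1:].mean()   # t anticipates a by one step
        r = crosscorrelogram(a, t, 5)
        assert lags_axis(5)[np.argmax(np.abs(r))] == 1

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 9))
            a = rng.normal(size=n)
            t = rng.normal(size=n)
            ours = crosscorrelogram(a, t, n - 1)
            oracle = brute_force_correlogram(a, t, n - 1)
            np.testing.assert_allclose(ours, oracle, atol=1e-12)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_role_reversal_negates_lags_preserves_r(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        a, t = rng.normal(size=n), rng.normal(size=n)
        fwd = crosscorrelogram(a, t, n - 1)
        rev = crosscorrelogram(t, a, n - 1)
        np.testing.assert_allclose(fwd, rev[::-1], atol=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            crosscorrelogram([1.0, 2.0, 3.0], [1.0, 2.0], 1)


class TestConfidenceBound:
    def test_values(self):
        assert confidence_bound(4) == pytest.approx(1.0)
        assert confidence_bound(6) == pytest.approx(2.0 / np.sqrt(6))
        assert confidence_bound(6) == pytest.approx(0.816496, abs=1e-6)

    def test_printed_gate(self):
        # the standard 3-min window's bound rounds to the printed 0.8 gate
        assert round(confidence_bound(6), 1) == 0.8


def _exact_coupling_track(n=10):
    """Deterministic positively coupled track: tension == area (lag 0)."""
    rng = np.random.default_rng(4)
    area = 2.0 + np.cumsum(rng.normal(0, 0.1, size=n))
    return ProcessedTrack(
        cell_id="c", track_id=0, timepoint=np.arange(n),
        area_raw=area, area_smooth=area, v_tension=area.copy(),
        v_tension_raw=area.copy(), cy=np.ones(n),
        d_area=np.diff(area), d_tension=np.diff(area))


class TestExtraction:
    def test_exact_coupling_all_windows_significant(self):
        track = _exact_coupling_track(10)
        obs = extract_observations(track, window_len=6)
        assert len(obs) == 5
        assert all(o.sign == 1 and o.lag == 0 for o in obs)
        assert all(o.r == pytest.approx(1.0) for o in obs)

    def test_track_of_window_length_gives_one_window(self):
        track = _exact_coupling_track(6)
        obs = extract_observations(track, window_len=6)
        assert len(obs) == 1

    def test_short_track_gives_nothing(self):
        track = _exact_coupling_track(5)
        assert extract_observations(track, window_len=6) == []

    def test_context_values_read_at_window_start(self):
        track = _exact_coupling_track(8)
        obs = extract_observations(track, window_len=6)
        o = obs[1]
        assert o.window_start == 1
        assert o.A0 == pytest.approx(track.area_smooth[1])
        assert o.dA == pytest.approx(track.area_smooth[2] - track.area_smooth[1])

    def test_decoupled_track_false_positive_rate_near_gate_alpha(self):
        """In control-mode (tension-insensitive) tracks the fraction of
        significant windows stays small — the gate's false-positive rate,
        not the ~60% seen for coupled tracks."""
        cfg = CohortConfig(n_cells=6, tracks_per_cell=20, probe_mode="control",
                           channel_noise_sd=0.02, seed=8)
        tracks = process_table(generate_cohort(cfg))
        n_windows = sum(max(t.lifetime - 6 + 1, 0) for t in tracks)
        obs = extract_all(tracks)
        assert len(obs) / n_windows < 0.15

    def test_construction_with_exact_generator_coupling(self):
        """coupling_strength=1, zero noise, lag 0 → every evaluated window
        across the cohort is significant with |r| = 1."""
        cfg = CohortConfig(n_cells=1, tracks_per_cell=6, coupling_strength=1.0,
                           channel_noise_sd=0.0, lag_rule=LagRule(lag=0),
                           stable_fraction=0.0, seed=6)
        tracks = process_table(generate_cohort(cfg))
        obs = extract_all(tracks)
        assert obs, "expected significant windows"
        assert all(abs(o.r) == pytest.approx(1.0, abs=1e-6) for o in obs)
        assert all(o.lag == 0 for o in obs)
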