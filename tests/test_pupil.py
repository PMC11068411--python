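"""Pupil preprocessing: circle fit, blink handling, filtering, features."""
import numpy as np
import pandas as pd
import pytest
from scipy import signal

from pupilsdt.pupil import (
    PupilTrace,
    bin_by_baseline,
    extract_features,
    fit_pupil_circle,
    interpolate_blinks,
    lowpass_trace,
    normalize_baselines,
    outcome_aligned_average,
    preprocess_trace,
    session_features,
    tertile_group,
    zscore_session,
)
from pupilsdt.synth import CohortConfig, generate_cohort

from conftest import make_trials


def flat_trace(value=0.0, n=400, mask=None):
    m = np.zeros(n, dtype=bool) if mask is None else mask
    return PupilTrace(values=np.full(n, float(value)), blink_mask=m)


class TestCircleFit:
    def test_twelve_points_on_circle(self):
        theta = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        pts = np.column_stack([1 + 2 * np.cos(theta), 1 + 2 * np.sin(theta)])
        (cx, cy), r, area = fit_pupil_circle(pts)
        assert (cx, cy) == pytest.approx((1.0, 1.0))
        assert area == pytest.approx(4 * np.pi)

    def test_three_point_circumscription(self):
        # hand oracle: solving the 3x3 linear system for (0,0),(2,0),(1,1)
        # gives center (1, 0), radius 1
        (cx, cy), r, _ = fit_pupil_circle([(0, 0), (2, 0), (1, 1)])
        assert (cx, cy) == pytest.approx((1.0, 0.0), abs=1e-12)
        assert r == pytest.approx(1.0)

    def test_rotation_invariance(self):
        theta = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        pts = np.column_stack([3 * np.cos(theta), 3 * np.sin(theta)]) + [5, -2]
        ang = 0.7
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        _, r1, _ = fit_pupil_circle(pts)
        _, r2, _ = fit_pupil_circle(pts @ R.T)
        assert r1 == pytest.approx(r2)

    def test_collinear_points_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            fit_pupil_circle([(0, 0), (1, 1), (2, 2), (3, 3)])


class TestBlinkInterpolation:
    def test_identity_without_blinks(self):
        tr = flat_trace(2.0)
        out = interpolate_blinks(tr)
        assert np.array_equal(out.values, tr.values)

    def test_linear_bridge(self):
        tr = PupilTrace(
            values=np.array([1.0, -99, -99, 4.0]),
            blink_mask=np.array([False, True, True, False]),
        )
        out = interpolate_blinks(tr)
        assert out.values == pytest.approx([1.0, 2.0, 3.0, 4.0])

    def test_edge_hold(self):
        tr = PupilTrace(
            values=np.array([-99, -99, 5.0, 6.0]),
            blink_mask=np.array([True, True, False, False]),
        )
        out = interpolate_blinks(tr)
        assert out.values == pytest.approx([5.0, 5.0, 5.0, 6.0])

    def test_fully_masked_rejected(self):
        with pytest.raises(ValueError):
            interpolate_blinks(flat_trace(mask=np.ones(10, dtype=bool)))


class TestLowpass:
    def _attenuation(self, freq, n=20000):
        fs = 20.0
        t = np.arange(n) / fs
        tr = PupilTrace(values=np.sin(2 * np.pi * freq * t),
                        blink_mask=np.zeros(n, dtype=bool))
        out = lowpass_trace(tr).values[n // 4: -n // 4]
        ref = np.sin(2 * np.pi * freq * t)[n // 4: -n // 4]
        # amplitude ratio and phase via least-squares on quadrature pair
        c = np.cos(2 * np.pi * freq * t)[n // 4: -n // 4]
        A = np.column_stack([ref, c])
        coef = np.linalg.lstsq(A, out, rcond=None)[0]
        amp = float(np.hypot(*coef))
        phase = float(np.arctan2(coef[1], coef[0]))
        return amp, phase

    @pytest.mark.parametrize("freq", [1.0, 5.0])
    def test_squared_butterworth_magnitude(self, freq):
        """Forward-backward filtering applies |H|^2 of the designed filter."""
        b, a = signal.butter(4, 3.5 / 10.0)
        _, h = signal.freqz(b, a, worN=[2 * np.pi * freq / 20.0])
        expected = np.abs(h[0]) ** 2
        amp, phase = self._attenuation(freq)
        assert amp == pytest.approx(expected, rel=1e-3)
        assert phase == pytest.approx(0.0, abs=1e-3)

    def test_near_unity_passband_matches_analog_form(self):
        # at 1 Hz the squared 4th-order magnitude 1/(1+(f/3.5)^8) ~ 0.99996
        amp, _ = self._attenuation(1.0)
        assert amp == pytest.approx(1.0 / (1.0 + (1.0 / 3.5) ** 8), abs=5e-4)

    def test_constant_unchanged(self):
        out = lowpass_trace(flat_trace(3.7))
        assert out.values == pytest.approx(3.7, abs=1e-6)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass_trace(flat_trace(), cutoff=10.0)


class TestZscore:
    def test_moments(self):
        rng = np.random.default_rng(1)
        tr = PupilTrace(values=5 + 3 * rng.normal(size=2000),
                        blink_mask=np.zeros(2000, dtype=bool))
        out = zscore_session(tr)
        assert out.values.mean() == pytest.approx(0.0, abs=1e-10)
        assert out.values.std() == pytest.approx(1.0, abs=1e-10)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=500)
        m = np.zeros(500, dtype=bool)
        a = zscore_session(PupilTrace(values=v, blink_mask=m))
        b = zscore_session(PupilTrace(values=7.0 - 2.5 * v, blink_mask=m))
        assert a.values == pytest.approx(-b.values, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            zscore_session(flat_trace(1.0))


class TestFeatures:
    def test_flat_trace(self):
        tr = flat_trace(2.5)
        f = extract_features(tr, stimulus_onset=10.0)
        assert f.baseline == pytest.approx(2.5)
        assert f.dilation == pytest.approx(0.0)

    def test_step_at_onset(self):
        n = 400
        v = np.zeros(n)
        onset = 10.0
        v[200:] = 1.0  # step exactly at the onset sample
        tr = PupilTrace(values=v, blink_mask=np.zeros(n, dtype=bool))
        f = extract_features(tr, onset)
        assert f.baseline == pytest.approx(0.0)
        assert f.dilation == pytest.approx(1.0)

    def test_kernel_window_mean_quadrature(self):
        # dilation equals the sample-grid mean of a known kernel over [0, 5]
        n, fs, onset = 400, 20.0, 10.0
        t = np.arange(n) / fs
        tp = 1.2
        x = np.clip((t - onset) / tp, 0, None)
        v = np.where(t >= onset, x * np.exp(1 - x), 0.0)
        tr = PupilTrace(values=v, blink_mask=np.zeros(n, dtype=bool))
        f = extract_features(tr, onset)
        idx = slice(200, 301)
        assert f.dilation == pytest.approx(v[idx].mean(), abs=1e-12)

    def test_window_outside_record_absent(self):
        f = extract_features(flat_trace(n=50), stimulus_onset=2.0)
        assert f.baseline is None and f.dilation is None

    def test_heavily_masked_window_absent(self):
        mask = np.zeros(400, dtype=bool)
        mask[194:200] = True  # 6 of 10 baseline samples
        f = extract_features(flat_trace(mask=mask), stimulus_onset=10.0)
        assert f.baseline is None


class TestNormalizeBaselines:
    def test_forced_values(self):
        assert normalize_baselines([2, 3, 5]) == pytest.approx([0.0, 1 / 3, 1.0])

    def test_bounds_and_affine_invariance(self):
        rng = np.random.default_rng(3)
        b = rng.normal(size=50)
        nb = normalize_baselines(b)
        assert nb.min() == 0.0 and nb.max() == 1.0
        assert normalize_baselines(3.0 + 2.0 * b) == pytest.approx(nb)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            normalize_baselines([1.0, 1.0, 1.0])


class TestTertiles:
    @pytest.mark.parametrize(
        "b, group",
        [(0.0, "low"), (0.329, "low"), (0.33, "medium"), (0.5, "medium"),
         (0.66, "medium"), (0.661, "high"), (1.0, "high")],
    )
    def test_boundaries(self, b, group):
        assert tertile_group(b) == group

    def test_uniform_split(self):
        b = np.linspace(0, 1, 1000)
        groups = [tertile_group(x) for x in b]
        fracs = {g: groups.count(g) / len(groups) for g in ("low", "medium", "high")}
        assert fracs["low"] == pytest.approx(0.33, abs=0.01)
        assert fracs["medium"] == pytest.approx(0.33, abs=0.01)
        assert fracs["high"] == pytest.approx(0.34, abs=0.01)


class TestBinning:
    def test_edge_value_lands_in_last_bin(self, session_05):
        feats = session_features(session_05)
        assert feats["bin"].max() <= 19
        top = feats.loc[feats["norm_baseline"] == 1.0, "bin"]
        assert (top == 19).all()

    def test_per_bin_recount_matches_brute_force(self, session_05):
        feats = session_features(session_05)
        trials = session_05.trials.iloc[20:].reset_index(drop=True)
        result = bin_by_baseline(trials, feats)
        # brute-force recount of one populated bin
        b = next(iter(result))
        sel = (feats["bin"] == b).to_numpy()
        sub = trials[sel]
        n_sp = (sub.stimulus == "S_PLUS").sum()
        n_hits = (sub.outcome == "HIT").sum()
        assert result[b].n_splus == n_sp and result[b].n_hits == n_hits
        assert result[b].hit_rate == pytest.approx((n_hits + 0.5) / (n_sp + 1))

    def test_single_hit_bin_finite(self):
        trials = make_trials(["S_PLUS", "S_MINUS"], ["HIT", "CORRECT_REJECTION"],
                             rts=[0.5, np.nan])
        feats = pd.DataFrame(
            {"trial_index": [0, 1], "baseline": [0.1, 0.2],
             "dilation": [0, 0], "norm_baseline": [0.0, 1.0],
             "tertile": ["low", "high"], "bin": [0, 0]}
        )
        res = bin_by_baseline(trials, feats)
        assert np.isfinite(res[0].d_prime) and np.isfinite(res[0].criterion)


class TestPipelineOrder:
    def test_order_is_interp_filter_zscore(self, session_05):
        tr = session_05.pupil
        manual = zscore_session(lowpass_trace(interpolate_blinks(tr)))
        auto = preprocess_trace(tr)
        assert np.array_equal(manual.values, auto.values)

    def test_swapping_stages_changes_result(self, session_05):
        tr = session_05.pupil
        swapped = lowpass_trace(zscore_session(interpolate_blinks(tr)))
        auto = preprocess_trace(tr)
        assert not np.allclose(swapped.values, auto.values)


class TestAlignedAverage:
    def test_window_has_111_samples(self, small_cohort):
        curves, taxis, _ = outcome_aligned_average(small_cohort[:3])
        assert taxis.size == 111
        assert taxis[0] == pytest.approx(-0.5) and taxis[-1] == pytest.approx(5.0)

    def test_amplitude_ordering_recovered(self):
        # generator default amplitudes: hit > FA > miss > CR
        cfg = CohortConfig(go_fractions=(0.5,), n_sessions=25, n_trials=200)
        cohort = generate_cohort(cfg, master_seed=21)
        curves, taxis, _ = outcome_aligned_average(cohort)
        evoked = {
            o: c[taxis >= 0].max() - c[taxis < 0].mean() for o, c in curves.items()
        }
        assert (
            evoked["HIT"] > evoked["FALSE_ALARM"] > evoked["MISS"]
            > evoked["CORRECT_REJECTION"]
        )
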