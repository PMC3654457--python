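"""Per-flash estimators: response window, gain, template projections,
baseline noise, and detection threshold."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rodgain import metrics
from rodgain.metrics import (NoDetectableResponse, Template,
                             baseline_noise_sd, default_baseline_window,
                             detection_threshold, find_response_window,
                             gain_from_responses, make_template,
                             metrics_table, template_projection)
from rodgain.simulate import (SimulationConfig, WeberGain,
                              simulate_protocol_suite, to_spike_counts)

DT = 1e-3


def brute_force_window(mean, i_flash, criterion=0.2):
    """Independent oracle: enumerate contiguous supra-criterion runs after
    the flash and keep the one containing the global peak."""
    post = mean[i_flash:]
    thr = criterion * post.max()
    above = post >= thr
    runs = []
    start = None
    for i, a in enumerate(above):
        if a and start is None:
            start = i
        elif not a and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, above.size))
    peak = int(np.argmax(post))
    for a, b in runs:
        if a <= peak < b:
            return (i_flash + a, i_flash + b)
    raise AssertionError("no run contains the peak")


class TestFindResponseWindow:
    def test_triangular_response_twenty_percent_criterion(self):
        mean = np.zeros(1000)
        mean[500:600] = np.concatenate([np.linspace(0, 10, 50),
                                        np.linspace(10, 0, 50)])
        win = find_response_window(mean, 0.45, DT)
        assert np.all(mean[win[0]: win[1]] >= 2.0)
        # samples adjacent to the window are below the 20% criterion
        assert mean[win[0] - 1] < 2.0 and mean[win[1]] < 2.0

    def test_no_response_signalled(self):
        with pytest.raises(NoDetectableResponse):
            find_response_window(np.zeros(100), 0.01, DT)

    def test_multi_lobe_tiebreak_matches_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            mean = np.zeros(400)
            # two separated lobes with random heights
            h1, h2 = rng.uniform(1, 10, 2)
            mean[120:160] = h1 * np.sin(np.linspace(0, np.pi, 40))
            mean[250:320] = h2 * np.sin(np.linspace(0, np.pi, 70))
            win = find_response_window(mean, 0.1, DT)
            assert win == brute_force_window(mean, 100)

    def test_flash_outside_trace_rejected(self):
        with pytest.raises(ValueError):
            find_response_window(np.ones(100), 0.5, DT)


class TestGainFromResponses:
    def test_noiseless_integration(self):
        # trials integrating to 2 pC at flash strength 0.004 -> 500 pC/(R*/rod)
        trial = np.zeros(1000)
        trial[300:500] = 10.0  # 200 samples x 10 pA x 1 ms = 2 pC
        gp = gain_from_responses([trial] * 5, (300, 500), (0, 250), 0.004, DT)
        assert gp.gain == pytest.approx(500.0, rel=1e-12)
        assert gp.sd == 0.0
        assert gp.n_trials == 5

    def test_linearity_leaves_gain_unchanged(self):
        base = np.zeros(1000)
        base[300:500] = 1.0
        g1 = gain_from_responses([base], (300, 500), (0, 250), 0.01, DT).gain
        g2 = gain_from_responses([2 * base], (300, 500), (0, 250), 0.02, DT).gain
        assert g1 == pytest.approx(g2, rel=1e-12)

    def test_baseline_subtraction(self):
        trial = np.full(1000, 3.0)
        trial[300:500] += 10.0
        gp = gain_from_responses([trial], (300, 500), (0, 250), 0.004, DT)
        assert gp.gain == pytest.approx(500.0, rel=1e-12)

    def test_window_validation(self):
        trial = np.zeros(100)
        with pytest.raises(ValueError, match="zero length"):
            gain_from_responses([trial], (50, 80), (30, 30), 0.01, DT)
        with pytest.raises(ValueError, match="disjoint"):
            gain_from_responses([trial], (40, 80), (30, 50), 0.01, DT)

    def test_weber_gain_ratio_recovered_from_simulation(self, weber_config):
        ts = simulate_protocol_suite(
            "flash_series", weber_config,
            {"backgrounds": [0.0, 0.08], "flash_strength": 0.05},
            n_trials=150, seed=21)
        table = metrics_table(ts)
        g0 = table.loc[table.background == 0.0].iloc[0]
        g1 = table.loc[table.background == 0.08].iloc[0]
        ratio = g1.gain / g0.gain
        se = ratio * math.hypot(g1.gain_sd / g1.gain, g0.gain_sd / g0.gain) \
            / math.sqrt(g1.n_trials)
        assert abs(ratio - 0.5) < 3 * se


class TestTemplateProjection:
    def _template(self, rng, n=80):
        w = rng.normal(size=n)
        return Template((100, 100 + n), w, 0.01)

    def test_self_projection_is_squared_norm(self, rng):
        t = self._template(rng)
        assert template_projection(t.weights, t, 1.0) == pytest.approx(
            float(t.weights @ t.weights), rel=1e-12)

    def test_orthogonal_segment_projects_to_zero(self):
        t = Template((0, 4), np.array([1.0, 0.0, -1.0, 0.0]), 0.01)
        assert template_projection(np.array([0.0, 5.0, 0.0, 5.0]), t) == 0.0

    def test_length_mismatch_rejected(self, rng):
        t = self._template(rng)
        with pytest.raises(ValueError, match="length"):
            template_projection(np.zeros(10), t)

    def test_white_noise_projection_distribution(self, rng):
        # nu over white noise: mean 0, SD = sigma * ||template||
        t = self._template(rng)
        sigma = 0.7
        segs = rng.normal(0, sigma, size=(10**5, t.length))
        nus = segs @ t.weights
        norm = math.sqrt(float(t.weights @ t.weights))
        se_mean = nus.std() / math.sqrt(nus.size)
        assert abs(nus.mean()) < 3 * se_mean
        se_sd = sigma * norm * math.sqrt(0.5 / nus.size)
        assert abs(nus.std(ddof=1) - sigma * norm) < 3 * se_sd


class TestDetectionThreshold:
    def test_definition(self):
        tp = detection_threshold([2.0, 2.0, 2.0], [0.5, -0.5, 0.5, -0.5])
        assert tp.theta == pytest.approx(np.std([0.5, -0.5, 0.5, -0.5], ddof=1) / 2.0)

    def test_homogeneity_in_noise(self, rng):
        nus = rng.normal(0, 1, 100)
        t1 = detection_threshold([2.0] * 10, nus).theta
        t2 = detection_threshold([2.0] * 10, 2 * nus).theta
        assert t2 == pytest.approx(2 * t1, rel=1e-12)

    def test_inverse_in_gain(self, rng):
        # halving the signal projections doubles threshold at fixed noise
        gammas = rng.normal(4, 0.1, 50)
        nus = rng.normal(0, 1, 50)
        t1 = detection_threshold(gammas, nus).theta
        t2 = detection_threshold(gammas / 2, nus).theta
        assert t2 == pytest.approx(2 * t1, rel=1e-12)

    def test_undetectable_response_signalled(self):
        with pytest.raises(NoDetectableResponse):
            detection_threshold([-1.0, 0.5], [0.1, -0.1])
        with pytest.raises(ValueError):
            detection_threshold([1.0], [0.1])

    @given(scale=st.floats(1e-3, 1e3))
    @settings(max_examples=30, derandomize=True)
    def test_invariant_under_template_rescaling(self, scale):
        rng = np.random.default_rng(8)
        w = rng.normal(size=50)
        seg = rng.normal(size=(40, 50))
        noise = rng.normal(size=(40, 50))
        t1 = Template((0, 50), w, 0.01)
        t2 = Template((0, 50), scale * w, 0.01)
        thetas = []
        for t in (t1, t2):
            gam = [template_projection(s, t, 0.01) for s in seg]
            nus = [template_projection(s, t) for s in noise]
            thetas.append(detection_threshold(gam, nus).theta)
        assert thetas[0] == pytest.approx(thetas[1], rel=1e-9)


class TestBaselineNoise:
    def test_silent_traces_give_zero(self):
        t = Template((0, 50), np.ones(50), 0.01)
        assert baseline_noise_sd([np.zeros(200)] * 3, (10, 60), t) == 0.0

    def test_requires_two_trials(self):
        t = Template((0, 50), np.ones(50), 0.01)
        with pytest.raises(ValueError, match="2 trials"):
            baseline_noise_sd([np.zeros(200)], (10, 60), t)

    def test_continuous_noise_projection(self, rng):
        sigma, n = 0.4, 4000
        w = rng.normal(size=60)
        t = Template((0, 60), w, 0.01)
        trials = rng.normal(0, sigma, size=(n, 200))
        sd = baseline_noise_sd(list(trials), (20, 80), t)
        norm = math.sqrt(float(w @ w))
        se = sigma * norm * math.sqrt(0.5 / n)
        assert abs(sd - sigma * norm) < 3 * se


class TestCrossModeConsistency:
    def test_spike_and_current_gain_ratios_agree(self, weber_config):
        # the background-induced gain change measured from spike counts
        # matches the one measured from currents (unity-line comparison)
        ts = simulate_protocol_suite(
            "flash_series", weber_config,
            {"backgrounds": [0.0, 0.08], "flash_strength": 0.1},
            n_trials=120, seed=31)
        rng = np.random.default_rng(99)
        ratios = {}
        for mode in ("current", "spikes"):
            gains = {}
            for bg in (0.0, 0.08):
                grp = ts.select(background=bg)
                if mode == "current":
                    trials = [tr.samples for tr in grp]
                    dt = grp.traces[0].dt
                    t_flash = 1.0
                else:
                    trials = [to_spike_counts(tr, rng, spikes_per_pa=20.0)
                              for tr in grp]
                    dt = 0.01
                    t_flash = 1.0
                mean = np.mean(trials, axis=0)
                win = find_response_window(mean, t_flash, dt)
                base = default_baseline_window(t_flash, dt)
                gp = gain_from_responses(trials, win, base, 0.1, dt)
                gains[bg] = (gp.gain, gp.sd / math.sqrt(gp.n_trials))
            r = gains[0.08][0] / gains[0.0][0]
            se = r * math.hypot(gains[0.08][1] / gains[0.08][0],
                                gains[0.0][1] / gains[0.0][0])
            ratios[mode] = (r, se)
        diff = ratios["current"][0] - ratios["spikes"][0]
        se = math.hypot(ratios["current"][1], ratios["spikes"][1])
        assert abs(diff) < 3 * se

    def test_fixed_and_adaptive_windows_agree(self, weber_config):
        ts = simulate_protocol_suite(
            "flash_series", weber_config,
            {"backgrounds": [0.0, 0.08], "flash_strength": 0.1},
            n_trials=80, seed=41)
        adaptive = metrics_table(ts)
        grp = ts.select(background=0.0)
        mean = grp.stack().mean(axis=0)
        win = find_response_window(mean, 1.0, grp.traces[0].dt)
        fixed = metrics_table(ts, fixed_window=win)
        for a, f in zip(adaptive.gain, fixed.gain):
            assert f == pytest.approx(a, rel=0.15)


class TestMetricsTable:
    def test_columns_and_monotone_gain(self, weber_config):
        ts = simulate_protocol_suite(
            "flash_series", weber_config,
            {"backgrounds": [0.0, 0.08, 0.8], "flash_strengths": [0.05, 0.1, 0.5]},
            n_trials=60, seed=13)
        table = metrics_table(ts)
        assert list(table.columns) == ["background", "gain", "gain_sd",
                                       "noise_sd", "threshold", "n_trials"]
        g = table.set_index("background").gain
        assert g[0.0] > g[0.08] > g[0.8]
        assert (table.threshold > 0).all()
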