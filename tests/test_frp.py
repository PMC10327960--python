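"""Marginal FRP reconstruction, baselines, ROI averaging, window means."""

import numpy as np
import pandas as pd
import pytest

import fixdeconv as fd
from fixdeconv.design import FIXATION
from fixdeconv.frp import WINDOWS


def make_betas(formula, events, coef, fs=250.0, window=(-0.2, 0.5),
               ch_names=("c0",)):
    """Wrap raw coefficients in a BetaSet over a tiny expanded design."""
    mass = fd.build_mass_design(events, formula)
    design = fd.time_expand(mass, events["time"], window, fs, 40000)
    n_ch = len(ch_names)
    assert coef.shape == (n_ch, mass.P, design.L)
    return fd.BetaSet(coefficients=coef, design=design,
                      iterations=np.zeros(n_ch), residual_norm=np.zeros(n_ch),
                      converged=np.ones(n_ch, bool), ch_names=list(ch_names))


def category_events(n=40, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "event_type": FIXATION,
        "time": np.sort(rng.uniform(1, 120, n)),
        "category": rng.choice(fd.CATEGORIES, n),
        "incoming_saccade_size": rng.gamma(2.5, 1.6, n),
    })


CAT_FORMULA = fd.ModelFormula({FIXATION: (
    fd.Intercept(), fd.Categorical("category", fd.CATEGORIES, "other"))})


class TestReconstruction:
    def test_reference_category_equals_intercept_betas(self, rng):
        events = category_events()
        coef = rng.normal(size=(1, 4, 175))
        betas = make_betas(CAT_FORMULA, events, coef)
        frp = fd.reconstruct_marginal_frps(betas, {})
        np.testing.assert_array_equal(frp.waveforms["other"], coef[:, 0])

    def test_category_difference_equals_dummy_betas(self, rng):
        events = category_events()
        coef = rng.normal(size=(1, 4, 175))
        betas = make_betas(CAT_FORMULA, events, coef)
        frp = fd.reconstruct_marginal_frps(betas, {})
        diff = frp.waveforms["precursor"] - frp.waveforms["other"]
        np.testing.assert_allclose(diff, coef[:, 1], rtol=0, atol=1e-14)

    def test_spline_contribution_from_basis_at_mean(self, rng):
        formula = fd.ModelFormula({FIXATION: (
            fd.Intercept(), fd.Spline("incoming_saccade_size", 5))})
        events = category_events()
        coef = rng.normal(size=(1, 5, 175))
        betas = make_betas(formula, events, coef)
        f1 = fd.reconstruct_marginal_frps(betas, {"incoming_saccade_size": 2.0})
        f2 = fd.reconstruct_marginal_frps(betas, {"incoming_saccade_size": 6.0})
        basis = betas.design.bases["incoming_saccade_size"]
        dw = basis.evaluate([2.0])[0] - basis.evaluate([6.0])[0]
        expect = np.tensordot(dw, coef[:, 1:, :], axes=(0, 1))
        got = f1.waveforms["(all)"] - f2.waveforms["(all)"]
        np.testing.assert_allclose(got, expect, atol=1e-12)

    def test_missing_covariate_mean_rejected(self, rng):
        formula = fd.ModelFormula({FIXATION: (
            fd.Intercept(), fd.Spline("incoming_saccade_size", 5))})
        betas = make_betas(formula, category_events(),
                           rng.normal(size=(1, 5, 175)))
        with pytest.raises(ValueError, match="missing covariate mean"):
            fd.reconstruct_marginal_frps(betas, {})


class TestBaseline:
    def frp(self, w):
        times = (np.arange(175) - 50) / 250.0
        return fd.MarginalFRP(waveforms={"a": w}, times=times,
                              ch_names=["c0"])

    def test_constant_waveform_zeroed(self):
        out = fd.baseline_correct(self.frp(np.full((1, 175), 3.7)))
        np.testing.assert_allclose(out.waveforms["a"], 0.0)

    def test_idempotent(self, rng):
        f = self.frp(rng.normal(size=(1, 175)))
        once = fd.baseline_correct(f)
        twice = fd.baseline_correct(once)
        np.testing.assert_allclose(once.waveforms["a"], twice.waveforms["a"])

    def test_post_onset_window_covers_five_samples(self):
        w = np.zeros((1, 175))
        times = (np.arange(175) - 50) / 250.0
        # half-open [0, 20) ms at 250 Hz: samples at 0, 4, 8, 12, 16 ms
        idx = np.flatnonzero((times >= 0) & (times < 0.020))
        assert len(idx) == 5
        w[0, idx] = [10, 0, 0, 0, 0]
        out = fd.baseline_correct(self.frp(w), (0.0, 0.020))
        assert out.waveforms["a"][0, idx].mean() == pytest.approx(0.0)
        assert out.waveforms["a"][0, 0] == pytest.approx(-2.0)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="no samples"):
            fd.baseline_correct(self.frp(np.zeros((1, 175))), (0.001, 0.003))


def montage_frp(rng, constant_roi=None):
    names, _, spec = fd.make_montage(n_per_roi=7)
    w = rng.normal(size=(56, 175))
    if constant_roi:
        idx = [names.index(c) for c in spec.rois[constant_roi]]
        w[idx] = w[idx[0]]
    times = (np.arange(175) - 50) / 250.0
    frp = fd.MarginalFRP(waveforms={"a": w}, times=times, ch_names=names)
    return frp, spec


class TestROIs:
    def test_eight_rois_consume_56_distinct_channels(self):
        _, _, spec = fd.make_montage(n_per_roi=7)
        assert len(spec.rois) == 8
        all_chans = [c for chans in spec.rois.values() for c in chans]
        assert len(all_chans) == 56 == len(set(all_chans))
        assert {f for f, _ in spec.factors.values()} == {
            "frontal", "central", "parietal", "occipital"}

    def test_identical_channels_average_to_themselves(self, rng):
        frp, spec = montage_frp(rng, constant_roi="OL")
        out = fd.roi_average(frp, spec)
        src = frp.waveforms["a"][frp.ch_names.index("OL1")]
        np.testing.assert_allclose(
            out.waveforms["a"][out.ch_names.index("OL")], src)

    def test_permuting_channels_within_roi_is_invariant(self, rng):
        frp, spec = montage_frp(rng)
        shuffled = fd.ROISpec(
            rois={k: list(reversed(v)) for k, v in spec.rois.items()},
            factors=spec.factors)
        a = fd.roi_average(frp, spec)
        b = fd.roi_average(frp, shuffled)
        for cat in a.waveforms:
            np.testing.assert_allclose(a.waveforms[cat], b.waveforms[cat])

    def test_missing_channel_rejected_by_name(self, rng):
        frp, spec = montage_frp(rng)
        frp.ch_names[frp.ch_names.index("PL3")] = "gone"
        with pytest.raises(ValueError, match="PL3"):
            fd.roi_average(frp, spec)

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(ValueError, match="7 channels"):
            fd.ROISpec(rois={"OL": ["a", "b"]},
                       factors={"OL": ("occipital", "left")})

    def test_baseline_commutes_with_roi_averaging(self, rng):
        frp, spec = montage_frp(rng)
        a = fd.roi_average(fd.baseline_correct(frp), spec)
        b = fd.baseline_correct(fd.roi_average(frp, spec))
        np.testing.assert_allclose(a.waveforms["a"], b.waveforms["a"],
                                   atol=1e-12)


class TestWindowMean:
    def test_constant_waveform(self, rng):
        frp, spec = montage_frp(rng)
        frp.waveforms["a"][:] = 2.5
        roi = fd.roi_average(frp, spec)
        wm = fd.window_mean(roi, "late", spec)
        np.testing.assert_allclose(wm["amplitude"], 2.5)
        assert set(wm["region"]) == {"frontal", "central", "parietal",
                                     "occipital"}

    def test_linear_ramp_has_midpoint_mean(self):
        times = np.arange(175) / 250.0 - 0.2
        w = np.zeros((1, 175))
        on = (times >= 0.2) & (times < 0.4)
        w[0, on] = np.linspace(0, 1, on.sum())
        frp = fd.MarginalFRP(waveforms={"a": w}, times=times, ch_names=["OL"])
        wm = fd.window_mean(frp, (0.2, 0.4))
        assert wm["amplitude"].iloc[0] == pytest.approx(0.5, abs=1 / on.sum())

    def test_lambda_window_is_centered_on_peak_latency(self):
        t0, t1 = WINDOWS["lambda"]
        assert (t0, t1) == (0.030, 0.130)
        assert (t0 + t1) / 2 == pytest.approx(0.080)

    def test_window_outside_lag_range_rejected(self, rng):
        frp, _ = montage_frp(rng)
        with pytest.raises(ValueError, match="no samples"):
            fd.window_mean(frp, (2.0, 3.0))


class TestCodingInvariance:
    def test_category_differences_invariant_to_reference_level(self, rng):
        # fit the same noiseless two-category signal with either level as
        # reference; reconstructed category difference must agree
        fs = 250.0
        times = np.cumsum(rng.uniform(0.3, 0.6, 30)) + 1.0
        cats = np.array(["p", "o"] * 15)
        k_p = np.hanning(100) * 4
        k_o = np.sin(np.linspace(0, np.pi, 100)) * 2
        n_samples = int(times.max() * fs) + 200
        sig = np.zeros(n_samples)
        for t, c in zip(times, cats):
            s = int(round(t * fs))
            sig[s:s + 100] += k_p if c == "p" else k_o
        eeg = fd.ContinuousEEG(sig[None], fs, ["c0"])
        events = pd.DataFrame({"event_type": FIXATION, "time": times,
                               "category": cats})
        diffs = []
        for ref in ("o", "p"):
            formula = fd.ModelFormula({FIXATION: (
                fd.Intercept(), fd.Categorical("category", ("p", "o"), ref))})
            mass = fd.build_mass_design(events, formula)
            design = fd.time_expand(mass, times, (0.0, 0.4), fs, n_samples)
            betas = fd.fit_deconvolution(eeg, design)
            frp = fd.reconstruct_marginal_frps(betas, {})
            diffs.append(frp.waveforms["p"] - frp.waveforms["o"])
        np.testing.assert_allclose(diffs[0], diffs[1], atol=1e-7)
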