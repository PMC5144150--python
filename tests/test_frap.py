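"""FRAP normalization algebra and recovery-curve fitting."""

import math

import numpy as np
import pytest

from chromodyn.frap import fit_recovery, full_scale, normalize_trace, summarize_constructs
from chromodyn.reference import FRAP_REFERENCE
from chromodyn.synthetic import FrapSimParams, generate_frap_trace


def make_fits(construct, n, seed0, n_post=600, dt=0.2, noise=0.02):
    ref = FRAP_REFERENCE[construct]
    fits = []
    for i in range(n):
        p = FrapSimParams(mobile_fraction=ref.mobile_fraction,
                          t_half_s=ref.t_half_s, bleach_depth=0.8,
                          n_pre=25, n_post=n_post, dt_s=dt,
                          noise_sd=noise, seed=seed0 + i)
        f = fit_recovery(normalize_trace(generate_frap_trace(p)))
        f.construct = construct
        fits.append(f)
    return fits


class TestNormalization:
    def test_anchors_are_exact_on_noiseless_trace(self):
        p = FrapSimParams(noise_sd=0, n_post=100)
        nt = normalize_trace(generate_frap_trace(p))
        assert nt.i_fs[:25].mean() == pytest.approx(1.0, abs=1e-12)
        assert nt.i_fs[25] == 0.0

    def test_double_normalization_cancels_acquisition_bleaching(self):
        p = FrapSimParams(mobile_fraction=0.6, t_half_s=10, bleach_depth=0.8,
                          n_pre=25, n_post=600, dt_s=0.5,
                          acquisition_bleach_rate=0.0005, noise_sd=0)
        nt = normalize_trace(generate_frap_trace(p))
        tau = nt.tau_s
        model = 0.6 * (1 - np.exp(-math.log(2) / 10 * tau))
        np.testing.assert_allclose(nt.post, model, atol=1e-6)
        assert nt.post[-1] == pytest.approx(0.6, abs=1e-6)

    def test_reduces_to_simple_ratio_without_background_and_decay(self):
        p = FrapSimParams(noise_sd=0, n_post=50)
        tr = generate_frap_trace(p)
        nt = normalize_trace(tr)
        i = tr.roi_bleach
        expected = (i - i[25]) / (i[:25].mean() - i[25])
        np.testing.assert_allclose(nt.i_fs, expected, atol=1e-12)

    def test_full_scale_is_idempotent(self):
        rng = np.random.default_rng(8)
        series = np.concatenate([np.full(10, 1.0), 0.2 + 0.6 * rng.random(40)])
        once = full_scale(series, 10)
        np.testing.assert_allclose(full_scale(once, 10), once, atol=1e-12)

    def test_unbleached_trace_rejected(self):
        p = FrapSimParams(noise_sd=0, n_post=50)
        tr = generate_frap_trace(p)
        tr.roi_bleach[:] = 1.0  # no bleach depth
        with pytest.raises(ValueError):
            normalize_trace(tr)

    def test_too_few_prebleach_frames_rejected(self):
        p = FrapSimParams(n_pre=3, n_post=50, noise_sd=0)
        with pytest.raises(ValueError):
            normalize_trace(generate_frap_trace(p))


class TestFitRecovery:
    def test_exact_recovery_on_noiseless_model(self):
        p = FrapSimParams(mobile_fraction=1.0, t_half_s=10, bleach_depth=0.8,
                          n_pre=25, n_post=300, dt_s=0.2, noise_sd=0)
        fit = fit_recovery(normalize_trace(generate_frap_trace(p)))
        assert fit.t_half_s == pytest.approx(10.0, abs=1e-6)
        assert fit.mobile_fraction == pytest.approx(1.0, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_agrees_with_grid_search_oracle(self):
        """Brute force: k over 10^4 log-spaced values with the closed-form
        least-squares amplitude per k must agree with the nonlinear fit to
        three significant digits."""
        p = FrapSimParams(mobile_fraction=0.7, t_half_s=18.0, bleach_depth=0.8,
                          n_pre=25, n_post=50, dt_s=1.7, noise_sd=0)
        nt = normalize_trace(generate_frap_trace(p))
        tau, y = nt.tau_s, nt.post
        ks = np.logspace(-4, 1, 10_000)
        best = None
        for k in ks:
            g = 1 - np.exp(-k * tau)
            denom = g @ g
            if denom == 0:
                continue
            a = (y @ g) / denom
            ssr = np.sum((y - a * g) ** 2)
            if best is None or ssr < best[0]:
                best = (ssr, a, k)
        _, a_star, k_star = best
        fit = fit_recovery(nt)
        assert fit.params["A"] == pytest.approx(a_star, rel=1e-3)
        assert fit.params["k"] == pytest.approx(k_star, rel=1e-3)

    def test_parameter_recovery_over_grid(self):
        """Median relative error of fitted t-half and mobile fraction stays
        under 5% across the (mobile fraction x half-time) grid at 2% noise."""
        rng_seed = 0
        for mf in (0.3, 0.6, 0.9):
            for th in (5.0, 15.0, 60.0):
                errs_t, errs_m = [], []
                for i in range(20):
                    rng_seed += 1
                    # acquisition matched to the kinetics: ~10 half-times
                    # of recovery sampled at t_half / 50
                    p = FrapSimParams(mobile_fraction=mf, t_half_s=th,
                                      bleach_depth=0.8, n_pre=25, n_post=500,
                                      dt_s=th / 50, noise_sd=0.02, seed=rng_seed)
                    fit = fit_recovery(normalize_trace(generate_frap_trace(p)))
                    errs_t.append(abs(fit.t_half_s - th) / th)
                    errs_m.append(abs(fit.mobile_fraction - mf) / mf)
                assert np.median(errs_t) < 0.05, (mf, th)
                assert np.median(errs_m) < 0.05, (mf, th)

    def test_r_squared_decreases_with_noise(self):
        r2 = {}
        for noise in (0.0, 0.02, 0.1):
            vals = []
            for s in range(5):
                p = FrapSimParams(mobile_fraction=0.7, t_half_s=15,
                                  n_post=400, dt_s=0.25,
                                  noise_sd=noise, seed=s)
                vals.append(fit_recovery(
                    normalize_trace(generate_frap_trace(p))).r_squared)
            r2[noise] = np.mean(vals)
        assert r2[0.0] == pytest.approx(1.0, abs=1e-12)
        assert r2[0.0] > r2[0.02] > r2[0.1]

    def test_double_exponential_model_available(self):
        p = FrapSimParams(mobile_fraction=0.8, t_half_s=12, n_post=400,
                          dt_s=0.25, noise_sd=0)
        nt = normalize_trace(generate_frap_trace(p))
        fit = fit_recovery(nt, model="double_exp")
        assert fit.model == "double_exp"
        assert fit.mobile_fraction == pytest.approx(0.8, abs=0.01)
        assert fit.t_half_s == pytest.approx(12, rel=0.02)

    def test_short_series_rejected(self):
        p = FrapSimParams(n_post=10, noise_sd=0)
        nt = normalize_trace(generate_frap_trace(p))
        with pytest.raises(ValueError):
            fit_recovery(nt)

    def test_severity_ordering_of_recovery_half_times(self):
        """Constructs simulated from their reported kinetics keep the
        severity-ordered ranking: WT slowest, then P152A, P152H, with
        P152R/T158M/R111G fastest."""
        means = {}
        for c in ("WT", "P152A", "P152H", "P152R", "T158M", "R111G"):
            n_post = 2000 if c in ("WT", "P152A", "P152H") else 600
            fits = make_fits(c, 3, seed0=300, n_post=n_post)
            means[c] = np.mean([f.t_half_s for f in fits])
        assert means["WT"] > means["P152A"] > means["P152H"]
        fast = max(means["P152R"], means["T158M"], means["R111G"])
        assert fast < means["P152H"]


class TestSummarizeConstructs:
    def test_identical_groups_not_significant(self):
        fits = make_fits("WT", 3, seed0=40, n_post=400)
        df = summarize_constructs({"WT": fits, "copy": list(fits)})
        row = df[df["construct"] == "copy"].iloc[0]
        assert row["p_t_half_vs_wt"] == pytest.approx(1.0)

    def test_fast_mutant_flagged_significant(self):
        df = summarize_constructs({
            "WT": make_fits("WT", 5, seed0=50, n_post=2000),
            "R111G": make_fits("R111G", 5, seed0=60, n_post=600),
        })
        row = df[df["construct"] == "R111G"].iloc[0]
        assert row["mean_t_half"] < 20
        assert row["p_t_half_vs_wt"] <= 0.05

    def test_singleton_group_excluded_and_single_construct_ok(self):
        fits = make_fits("WT", 2, seed0=70, n_post=300)
        df = summarize_constructs({"WT": fits, "lonely": fits[:1]})
        assert "lonely" not in set(df["construct"])
        assert np.isnan(df.iloc[0]["p_t_half_vs_wt"])
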