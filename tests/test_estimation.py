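"""Trait estimators: oracle examples, invariances, bootstrap behavior."""

import numpy as np
import pandas as pd
import pytest

import chlorotraits as ct

from conftest import make_dataset


def _adsorption_df(t, v, H=1e7, replicate=1):
    return pd.DataFrame({"replicate": replicate, "time_h": t,
                         "free_pfu_per_ml": v, "host_density": H})


def _onestep_df(t, ic, free, D, replicate=1):
    return pd.DataFrame({"replicate": replicate, "time_h": t,
                         "infectious_centers_per_ml": ic,
                         "free_pfu_per_ml": free,
                         "depolarized_cells_per_ml": D})


class TestFitAdsorption:
    def test_pure_exponential_recovers_slope(self):
        # V(t) = 1e6 * e^(-0.5 t), H = 1e7 -> k = 5e-8 mL/h, a ~ 1
        t = np.array([0.0, 0.5, 1.0, 1.5, 2.0])
        k, a = ct.fit_adsorption(_adsorption_df(t, 1e6 * np.exp(-0.5 * t)))
        assert k.estimate == pytest.approx(5e-8, rel=1e-3)
        assert a.estimate == pytest.approx(1.0, abs=1e-3)

    def test_constant_counts_give_zero_k(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        k, a = ct.fit_adsorption(_adsorption_df(t, np.full(4, 1e6)))
        assert k.estimate == 0.0
        assert "no_adsorption" in k.flags

    def test_plateau_model_recovers_generating_parameters(self):
        # V(t) = 1e6 * [0.2 + 0.8 e^-t] -> a = 0.8, k*H = 1/h
        t = np.arange(0.0, 6.1, 0.5)
        k, a = ct.fit_adsorption(_adsorption_df(t, 1e6 * (0.2 + 0.8 * np.exp(-t))))
        assert a.estimate == pytest.approx(0.8, rel=1e-6)
        assert k.estimate * 1e7 == pytest.approx(1.0, rel=1e-6)

    def test_all_zero_counts_flagged_not_silent(self):
        t = np.array([0.0, 1.0, 2.0])
        k, a = ct.fit_adsorption(_adsorption_df(t, np.zeros(3)))
        assert not np.isfinite(k.estimate)
        assert any(f.startswith("failed") for f in k.flags)


class TestEstimateDepolarization:
    @pytest.mark.parametrize("moi,frac,expected", [
        (2.0, 0.0, 0.0),
        (2.0, 1 - np.exp(-1.0), 0.5),
        (1.0, 1 - np.exp(-0.25), 0.25),
    ])
    def test_poisson_inversion(self, moi, frac, expected):
        df = pd.DataFrame({"replicate": [1, 2], "cells_total": [400, 400],
                           "cells_depolarized": [400 * frac] * 2,
                           "adsorbed_moi": moi})
        d = ct.estimate_depolarization(df)
        assert d.estimate == pytest.approx(expected, abs=1e-12)

    def test_saturation_flagged(self):
        df = pd.DataFrame({"replicate": [1], "cells_total": [100],
                           "cells_depolarized": [100], "adsorbed_moi": [2.0]})
        d = ct.estimate_depolarization(df)
        assert d.estimate == 1.0
        assert "saturated" in d.flags

    def test_counts_exceeding_total_rejected(self):
        df = pd.DataFrame({"replicate": [1], "cells_total": [100],
                           "cells_depolarized": [101], "adsorbed_moi": [2.0]})
        with pytest.raises(ValueError):
            ct.estimate_depolarization(df)


class TestFitLysisCurve:
    def test_recovers_generating_cdf_parameters(self):
        # C(t) = 0.8 * Phi((t-8)/1.5) on a half-hour grid
        from chlorotraits.synthetic import lysis_cdf
        t = np.arange(0.0, 16.1, 0.5)
        D = 1e6
        ic = 0.8 * D * (1 - lysis_cdf(t, 8.0, 1.5))
        mu, sig, r = ct.fit_lysis_curve(_onestep_df(t, ic, 0.0, D))
        assert r.estimate == pytest.approx(0.8, rel=1e-6)
        assert mu.estimate == pytest.approx(8.0, rel=1e-6)
        assert sig.estimate == pytest.approx(1.5, rel=1e-6)
        assert r.diagnostics["releasing_density"] == pytest.approx(0.8e6, rel=1e-6)

    def test_step_curve_degenerates_to_sigma_floor(self):
        t = np.arange(0.0, 16.1, 0.5)
        D = 1e6
        ic = D * (t < 8.0)
        mu, sig, r = ct.fit_lysis_curve(_onestep_df(t, ic, 0.0, D))
        assert r.estimate == pytest.approx(1.0, abs=1e-6)
        assert 7.5 <= mu.estimate <= 8.5
        assert sig.estimate == pytest.approx(0.25, abs=1e-9)  # half the grid step

    def test_all_zero_release_flags_mu_sigma(self):
        t = np.arange(0.0, 16.1, 1.0)
        mu, sig, r = ct.fit_lysis_curve(_onestep_df(t, np.zeros_like(t), 0.0, 1e6))
        assert r.estimate == 0.0
        assert mu.poorly_resolved and sig.poorly_resolved


class TestBurstSizes:
    def test_yield_arithmetic(self):
        # 4e8 PFU/mL final yield over 1e6 depolarized cells/mL, r=0.8
        t = np.array([0.0, 10.0, 20.0])
        free = np.array([0.0, 2e8, 4e8])
        df = _onestep_df(t, 0.0, free, 1e6)
        r = ct.TraitEstimate("r", 0.8, 0.8, 0.8)
        b_d, b_r = ct.estimate_burst_sizes(df, r)
        assert b_d.estimate == pytest.approx(400.0)
        assert b_r.estimate == pytest.approx(500.0)

    def test_zero_yield_and_r_one_identity(self):
        t = np.array([0.0, 10.0])
        df = _onestep_df(t, 0.0, np.zeros(2), 1e6)
        b_d, b_r = ct.estimate_burst_sizes(df, ct.TraitEstimate("r", 1.0, 1.0, 1.0))
        assert b_d.estimate == 0.0 and b_r.estimate == 0.0
        # r = 1 makes the two burst sizes identical by definition
        df2 = _onestep_df(t, 0.0, np.array([0.0, 3e8]), 1e6)
        b_d2, b_r2 = ct.estimate_burst_sizes(df2, ct.TraitEstimate("r", 1.0, 1.0, 1.0))
        assert b_d2.estimate == pytest.approx(b_r2.estimate)

    def test_zero_release_probability_flags_b_r(self):
        t = np.array([0.0, 10.0])
        df = _onestep_df(t, 0.0, np.array([0.0, 1e8]), 1e6)
        b_d, b_r = ct.estimate_burst_sizes(df, ct.TraitEstimate("r", 0.0, 0.0, 0.0))
        assert np.isfinite(b_d.estimate)
        assert not np.isfinite(b_r.estimate)
        assert "b_r_undefined_r_zero" in b_r.flags


class TestSpecificInfectivity:
    @pytest.mark.parametrize("a,d,r,expected", [
        (1.0, 1.0, 1.0, 1.0),
        (0.8, 0.5, 0.25, 0.1),
        (0.0, 0.9, 0.9, 0.0),
    ])
    def test_product(self, a, d, r, expected):
        s = ct.estimate_specific_infectivity(
            ct.TraitEstimate("a", a, a, a), ct.TraitEstimate("d", d, d, d),
            ct.TraitEstimate("r", r, r, r))
        assert s.estimate == pytest.approx(expected, abs=1e-12)

    def test_joint_bootstrap_propagation_not_interval_product(self):
        rng = np.random.default_rng(0)
        sa = np.clip(rng.normal(0.8, 0.02, 500), 0, 1)
        sd = np.clip(rng.normal(0.5, 0.02, 500), 0, 1)
        sr = np.clip(rng.normal(0.5, 0.02, 500), 0, 1)
        mk = lambda n, v, s: ct.TraitEstimate(n, v, v, v, diagnostics={"boot_samples": s})
        s = ct.estimate_specific_infectivity(mk("a", 0.8, sa), mk("d", 0.5, sd),
                                             mk("r", 0.5, sr))
        lo, hi = np.percentile(sa * sd * sr, [2.5, 97.5])
        assert s.ci_low == pytest.approx(min(lo, 0.2), rel=1e-9)
        assert s.ci_high == pytest.approx(max(hi, 0.2), rel=1e-9)

    def test_flag_propagates_from_components(self):
        bad = ct.TraitEstimate("a", float("nan"), float("nan"), float("nan"),
                               flags=["poorly_resolved"])
        good = ct.TraitEstimate("d", 0.5, 0.5, 0.5)
        s = ct.estimate_specific_infectivity(bad, good,
                                             ct.TraitEstimate("r", 0.5, 0.5, 0.5))
        assert any("component_a" in f for f in s.flags)


class TestFitDecay:
    def _decay_df(self, t, v):
        return pd.DataFrame({"replicate": 1, "time_h": t, "pfu_per_ml": v})

    def test_recovers_biphasic_parameters_vs_grid_search_oracle(self):
        t = np.array([0, 5, 10, 20, 40, 60, 80, 120, 160, 200.0])
        S = 1e6 * (0.01 + 0.99 * np.exp(-0.05 * t))
        m, p = ct.fit_decay(self._decay_df(t, S))
        # independent coarse grid-search oracle over (m, p) minimizing SSE
        ms = np.linspace(0.01, 0.2, 96)
        ps = np.linspace(0.0, 0.1, 101)
        M, P = np.meshgrid(ms, ps, indexing="ij")
        pred = 1e6 * (P[..., None] + (1 - P[..., None]) * np.exp(-M[..., None] * t))
        sse = ((np.log(pred) - np.log(S)) ** 2).sum(-1)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        assert abs(m.estimate - ms[i]) <= (ms[1] - ms[0])
        assert abs(p.estimate - ps[j]) <= (ps[1] - ps[0])
        assert m.estimate == pytest.approx(0.05, rel=1e-6)
        assert p.estimate == pytest.approx(0.01, rel=1e-6)

    def test_pure_exponential_matches_loglinear_slope(self):
        rng = np.random.default_rng(4)
        t = np.array([0, 10, 20, 40, 80, 120.0])
        S = 2e6 * np.exp(-0.03 * t) * np.exp(rng.normal(0, 0.1, t.size))
        m_fixed, p_fixed = ct.fit_decay(self._decay_df(t, S), fix_p=0.0)
        slope = np.polyfit(t, np.log(S), 1)[0]
        assert p_fixed.estimate == 0.0
        assert m_fixed.estimate == pytest.approx(-slope, rel=1e-6)

    def test_constant_titers_convention(self):
        t = np.array([0, 24, 48, 96.0])
        m, p = ct.fit_decay(self._decay_df(t, np.full(4, 5e5)))
        assert (m.estimate, p.estimate) == (0.0, 1.0)
        assert "no_decay_detected" in m.flags


class TestBootstrap:
    def test_zero_noise_gives_degenerate_interval(self, noiseless_design):
        tt = ct.draw_true_traits(1, seed=2)[0]
        df = ct.simulate_adsorption_assay(tt, noiseless_design)
        lo, hi, diag = ct.bootstrap_ci(
            lambda d: ct.fit_adsorption(d)[0].estimate, df, n_boot=100, seed=0)
        assert lo == pytest.approx(hi, rel=1e-9)
        assert lo == pytest.approx(tt.k, rel=1e-6)

    def test_same_seed_identical_intervals(self):
        tt = ct.draw_true_traits(1, seed=2)[0]
        design = ct.AssayDesign(n_replicates=5)
        df = ct.simulate_adsorption_assay(tt, design, np.random.default_rng(1))
        fit = lambda d: ct.fit_adsorption(d)[0].estimate
        r1 = ct.bootstrap_ci(fit, df, n_boot=120, seed=7)
        r2 = ct.bootstrap_ci(fit, df, n_boot=120, seed=7)
        assert r1[:2] == r2[:2]

    def test_n_boot_validation(self):
        with pytest.raises(ValueError):
            ct.bootstrap_ci(lambda d: 0.0, pd.DataFrame({"replicate": [1]}),
                            n_boot=50, seed=0)


class TestEstimateProfile:
    def test_noise_free_recovery_within_one_percent(self, noiseless_design):
        for seed in (1, 2):
            tt = ct.draw_true_traits(1, seed=seed)[0]
            ds = make_dataset(tt, noiseless_design)
            prof = ct.estimate_profile(ds, n_boot=0)
            truth = tt.as_dict()
            for name, est in prof.traits.items():
                assert est.estimate == pytest.approx(truth[name], rel=0.01), name

    def test_missing_decay_table_flags_m_p_only(self, noiseless_design):
        tt = ct.draw_true_traits(1, seed=3)[0]
        ds = make_dataset(tt, noiseless_design)
        ds.decay = None
        prof = ct.estimate_profile(ds, n_boot=0)
        assert prof["m"].poorly_resolved and prof["p"].poorly_resolved
        for name in ("a", "k", "d", "r", "mu_l", "sigma_l", "b_d", "b_r", "s"):
            assert not prof[name].poorly_resolved, name

    def test_order_constraints_on_output(self):
        tt = ct.draw_true_traits(1, seed=5)[0]
        ds = make_dataset(tt, ct.AssayDesign(), np.random.default_rng(8))
        prof = ct.estimate_profile(ds, n_boot=100, seed=1)
        tr = prof.traits
        assert tr["b_d"].estimate <= tr["b_r"].estimate * (1 + 1e-9)
        assert tr["s"].estimate <= min(tr["a"].estimate, tr["d"].estimate,
                                       tr["r"].estimate) + 1e-9
        for name in ("a", "d", "r", "s", "p"):
            assert 0.0 <= tr[name].estimate <= 1.0
            assert 0.0 <= tr[name].ci_low <= tr[name].ci_high <= 1.0
        for name, est in tr.items():
            assert est.ci_low <= est.estimate <= est.ci_high

    def test_row_order_and_replicate_label_invariance(self):
        tt = ct.draw_true_traits(1, seed=6)[0]
        ds = make_dataset(tt, ct.AssayDesign(n_replicates=4), np.random.default_rng(9))
        prof1 = ct.estimate_profile(ds, n_boot=0)
        shuffled = ct.AssayDataset(
            ds.strain_id,
            ds.adsorption.sample(frac=1, random_state=1).reset_index(drop=True),
            ds.depolarization.sample(frac=1, random_state=2).reset_index(drop=True),
            ds.onestep.sample(frac=1, random_state=3).reset_index(drop=True),
            ds.decay.sample(frac=1, random_state=4).reset_index(drop=True),
            None)
        relabel = {1: 10, 2: 20, 3: 30, 4: 40}
        for name in ("adsorption", "depolarization", "onestep", "decay"):
            df = getattr(shuffled, name)
            df["replicate"] = df["replicate"].map(relabel)
        prof2 = ct.estimate_profile(shuffled, n_boot=0)
        for name in prof1.traits:
            e1, e2 = prof1[name].estimate, prof2[name].estimate
            if np.isfinite(e1):
                assert e1 == pytest.approx(e2, rel=1e-9), name

    def test_same_seed_identical_profiles(self):
        tt = ct.draw_true_traits(1, seed=7)[0]
        ds = make_dataset(tt, ct.AssayDesign(n_replicates=4), np.random.default_rng(3))
        p1 = ct.estimate_profile(ds, n_boot=120, seed=42)
        p2 = ct.estimate_profile(ds, n_boot=120, seed=42)
        for name in p1.traits:
            assert (p1[name].ci_low, p1[name].ci_high) == \
                (p2[name].ci_low, p2[name].ci_high), name
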