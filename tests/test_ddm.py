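"""Drift-diffusion core: density identities, simulator oracle, fitting."""
import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from pupilsdt.ddm import (
    DDMParams,
    compare_models,
    fit_ddm,
    prob_upper_before,
    simulate_ddm,
    simulate_ddm_trials,
    total_nll,
    trial_nll,
    upper_density,
    wfpt_density,
)


def make_ddm_trials(params, n, p_go=0.5, seed=0, dt=1e-3, deadline=1.3):
    rng = np.random.default_rng(seed)
    stim = np.where(rng.random(n) < p_go, "S_PLUS", "S_MINUS")
    responded, rt = simulate_ddm_trials(params, stim, deadline=deadline, dt=dt, seed=rng)
    outcome = np.where(
        stim == "S_PLUS",
        np.where(responded, "HIT", "MISS"),
        np.where(responded, "FALSE_ALARM", "CORRECT_REJECTION"),
    )
    return pd.DataFrame({"stimulus": stim, "outcome": outcome, "reaction_time": rt})


class TestParams:
    def test_variant_constraints_enforced(self):
        with pytest.raises(ValueError):
            DDMParams(a=1.0, z=0.6, v_go=1.0, v_nogo=-1.0, t0=0.2, variant="M1")
        with pytest.raises(ValueError):
            DDMParams(a=1.0, z=0.5, v_go=1.0, v_nogo=-0.5, t0=0.2, variant="M2")
        # M4 allows both freedoms
        DDMParams(a=1.0, z=0.6, v_go=1.0, v_nogo=-0.5, t0=0.2, variant="M4")

    @pytest.mark.parametrize(
        "kw", [dict(a=-1.0), dict(z=0.0), dict(z=1.0), dict(t0=-0.1)]
    )
    def test_domain_errors(self, kw):
        base = dict(a=1.0, z=0.5, v_go=1.0, v_nogo=-1.0, t0=0.2)
        base.update(kw)
        with pytest.raises(ValueError):
            DDMParams(**base)


class TestDensity:
    def test_total_probability(self):
        a, z, v = 1.5, 0.6, 0.8
        lower = quad(lambda t: wfpt_density(t, a, z, v), 0, 60, limit=200)[0]
        upper = quad(lambda t: upper_density(t, a, z, v), 0, 60, limit=200)[0]
        assert lower + upper == pytest.approx(1.0, abs=1e-6)

    def test_driftless_symmetry(self):
        t = np.linspace(0.01, 3, 100)
        assert wfpt_density(t, 1.0, 0.5, 0.0) == pytest.approx(
            upper_density(t, 1.0, 0.5, 0.0)
        )

    @pytest.mark.parametrize("params", [(1.5, 0.6, 0.8), (0.8, 0.3, -1.5), (2.5, 0.5, 2.0)])
    def test_reflection_identity(self, params):
        a, z, v = params
        t = np.linspace(0.005, 4, 200)
        assert wfpt_density(t, a, z, v) == pytest.approx(
            upper_density(t, a, 1 - z, -v), abs=1e-12
        )

    def test_nonnegative_and_zero_for_nonpositive_time(self):
        t = np.linspace(-1, 5, 300)
        d = wfpt_density(t, 1.2, 0.4, 0.7)
        assert np.all(d >= 0)
        assert np.all(d[t <= 0] == 0)

    def test_series_truncation_converges(self):
        t = np.geomspace(1e-3, 10, 200)
        d1 = wfpt_density(t, 1.5, 0.6, 0.8, err=1e-10)
        d2 = wfpt_density(t, 1.5, 0.6, 0.8, err=1e-16)
        assert np.max(np.abs(d1 - d2)) < 1e-8

    def test_analytic_absorption_probability(self):
        # P(upper) = (1 - exp(-2 v z a)) / (1 - exp(-2 v a))
        a, z, v = 2.0, 0.5, 3.0
        x0 = z * a
        expected = (1 - np.exp(-2 * v * x0)) / (1 - np.exp(-2 * v * a))
        got = quad(lambda t: upper_density(t, a, z, v), 0, 40, limit=200)[0]
        assert got == pytest.approx(expected, abs=1e-6)


class TestSimulatorAgainstDensity:
    def test_strong_drift_dominates(self):
        p = DDMParams(a=1.0, z=0.5, v_go=50.0, v_nogo=-50.0, t0=0.1)
        responded, rt = simulate_ddm_trials(
            p, ["S_PLUS"] * 2000, deadline=1.3, dt=1e-4, seed=0
        )
        assert responded.mean() > 0.99
        assert np.nanmedian(rt) == pytest.approx(0.1, abs=0.02)

    def test_driftless_is_fair_coin(self):
        p = DDMParams(a=1.0, z=0.5, v_go=0.0, v_nogo=0.0, t0=0.0)
        responded, _ = simulate_ddm_trials(
            p, ["S_PLUS"] * 20_000, deadline=None, dt=1e-3, seed=1
        )
        assert abs(responded.mean() - 0.5) < 3 * np.sqrt(0.25 / 20_000)

    def test_rt_histogram_matches_density(self):
        """Binned simulated first-passage times track the series density."""
        a, z, v = 1.5, 0.5, 1.0
        p = DDMParams(a=a, z=z, v_go=v, v_nogo=-v, t0=0.0)
        n = 50_000
        responded, rt = simulate_ddm_trials(
            p, ["S_PLUS"] * n, deadline=None, dt=1e-4, seed=2, max_time=8.0
        )
        edges = np.arange(0.05, 2.0001, 0.05)
        counts, _ = np.histogram(rt[responded], bins=edges)
        dens_hat = counts / n / np.diff(edges)
        mid = 0.5 * (edges[:-1] + edges[1:])
        dens = upper_density(mid, a, z, v)
        se = np.sqrt(np.maximum(dens, 1e-4) / (n * np.diff(edges)))
        # 4 SE plus a small allowance for Euler boundary-crossing bias
        assert np.max(np.abs(dens_hat - dens) - 4 * se - 0.02 * dens) < 0.01

    def test_single_trial_api(self):
        resp, rt = simulate_ddm(
            DDMParams(a=1.0, z=0.5, v_go=3.0, v_nogo=-3.0, t0=0.2),
            "S_PLUS", seed=5,
        )
        assert resp in ("lick", "withhold")
        if resp == "lick":
            assert 0.2 < rt <= 1.3

    def test_deadline_below_t0_rejected(self):
        p = DDMParams(a=1.0, z=0.5, v_go=1.0, v_nogo=-1.0, t0=0.5)
        with pytest.raises(ValueError):
            simulate_ddm_trials(p, ["S_PLUS"], deadline=0.4, seed=0)


class TestLikelihood:
    def test_conservation_with_deadline(self):
        """Lick CDF at the deadline plus withhold probability equals one."""
        p = DDMParams(a=1.5, z=0.55, v_go=1.2, v_nogo=-0.8, t0=0.25)
        T = 1.3 - p.t0
        p_lick = prob_upper_before(T, p.a, p.z, p.v_go)
        nll_withhold = trial_nll(p, "S_PLUS", responded=False, rt=None, deadline=1.3)
        assert np.exp(-nll_withhold) + p_lick == pytest.approx(1.0, abs=1e-9)

    def test_symmetric_licks_equal(self):
        p = DDMParams(a=1.5, z=0.5, v_go=1.0, v_nogo=1.0, t0=0.2)
        nll_go = trial_nll(p, "S_PLUS", True, 0.6, deadline=1.3)
        nll_nogo = trial_nll(p, "S_MINUS", True, 0.6, deadline=1.3)
        assert nll_go == pytest.approx(nll_nogo)
        assert np.isfinite(nll_go)

    def test_rt_below_t0_hits_floor_with_warning(self):
        p = DDMParams(a=1.5, z=0.5, v_go=1.0, v_nogo=-1.0, t0=0.5)
        trials = pd.DataFrame(
            {"stimulus": ["S_PLUS"], "outcome": ["HIT"], "reaction_time": [0.3]}
        )
        with pytest.warns(RuntimeWarning, match="floor"):
            val = total_nll(p, trials)
        assert np.isfinite(val) and val > 100

    def test_generating_parameters_dominate_perturbations(self):
        gen = DDMParams(a=1.6, z=0.5, v_go=1.2, v_nogo=-1.2, t0=0.25)
        trials = make_ddm_trials(gen, 3000, seed=6)
        base = total_nll(gen, trials)
        rng = np.random.default_rng(7)
        worse = 0
        for _ in range(50):
            pert = DDMParams(
                a=gen.a * (1 + 0.3 * rng.uniform(-1, 1)),
                z=np.clip(gen.z + 0.1 * rng.uniform(-1, 1), 0.1, 0.9),
                v_go=gen.v_go * (1 + 0.3 * rng.uniform(-1, 1)),
                v_nogo=gen.v_nogo * (1 + 0.3 * rng.uniform(-1, 1)),
                t0=np.clip(gen.t0 * (1 + 0.3 * rng.uniform(-1, 1)), 0.01, 0.5),
            )
            if total_nll(pert, trials) > base:
                worse += 1
        assert worse >= 45  # a few near-equivalent perturbations are allowed


class TestFitting:
    def test_m1_parameter_recovery(self):
        gen = DDMParams(a=1.6, z=0.5, v_go=1.2, v_nogo=-1.2, t0=0.25, variant="M1")
        errs = []
        for rep in range(3):
            trials = make_ddm_trials(gen, 2000, seed=100 + rep)
            fit = fit_ddm(trials, "M1", n_starts=4, seed=rep)
            errs.append(
                [
                    abs(fit.params.a - gen.a) / gen.a,
                    abs(fit.params.v_go - gen.v_go) / gen.v_go,
                    abs(fit.params.t0 - gen.t0) / gen.t0,
                ]
            )
        med = np.median(errs, axis=0)
        assert np.all(med < 0.10)

    def test_m2_recovers_null_bias(self):
        gen = DDMParams(a=1.6, z=0.5, v_go=1.2, v_nogo=-1.2, t0=0.25)
        trials = make_ddm_trials(gen, 3000, seed=8)
        fit = fit_ddm(trials, "M2", n_starts=4, seed=9)
        assert fit.params.z == pytest.approx(0.5, abs=0.05)

    def test_fit_determinism(self):
        gen = DDMParams(a=1.4, z=0.5, v_go=1.0, v_nogo=-1.0, t0=0.2)
        trials = make_ddm_trials(gen, 500, seed=10)
        a = fit_ddm(trials, "M1", n_starts=3, seed=11)
        b = fit_ddm(trials, "M1", n_starts=3, seed=11)
        assert a.nll == b.nll
        assert a.params == b.params

    def test_aic_formula(self):
        gen = DDMParams(a=1.4, z=0.5, v_go=1.0, v_nogo=-1.0, t0=0.2)
        trials = make_ddm_trials(gen, 300, seed=12)
        fit = fit_ddm(trials, "M3", n_starts=2, seed=13)
        assert fit.aic == pytest.approx(2 * 4 + 2 * fit.nll)
        assert fit.bic == pytest.approx(4 * np.log(300) + 2 * fit.nll)


class TestModelComparison:
    def test_biased_asymmetric_data_prefers_m4(self):
        gen = DDMParams(a=1.6, z=0.65, v_go=1.5, v_nogo=-0.5, t0=0.25, variant="M4")
        trials = make_ddm_trials(gen, 5000, seed=14)
        table = compare_models(trials, n_starts=4, seed=15)
        assert table.iloc[0]["variant"] == "M4"

    def test_ranking_deterministic(self):
        gen = DDMParams(a=1.5, z=0.5, v_go=1.0, v_nogo=-1.0, t0=0.2)
        trials = make_ddm_trials(gen, 800, seed=16)
        t1 = compare_models(trials, n_starts=2, seed=17)
        t2 = compare_models(trials, n_starts=2, seed=17)
        pd.testing.assert_frame_equal(t1, t2)
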