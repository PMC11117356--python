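import math

import numpy as np
import pandas as pd
import pytest

from neoperem import PopulationParameters, load_final_model
from neoperem.estimate import (
    CovariateEffect,
    ScmConfig,
    TDMDataset,
    _Engine,
    _pop_to_x,
    base_structure,
    final_structure,
    fit,
    ofv,
    resample_subjects,
    scm,
)
from neoperem.syndata import CohortSpec, DesignSpec, generate_cohort, generate_tdm


@pytest.fixture(scope="module")
def small_data(final_pop):
    cohort = generate_cohort(CohortSpec(seed=21))
    return generate_tdm(cohort, DesignSpec(), final_pop, seed=22)


@pytest.fixture(scope="module")
def rich_noise_free_data():
    """Many observations, no IIV and no residual noise: deterministic limit."""
    pop = PopulationParameters(clp=1.09, vp=3.98, theta_crrt=1.04)
    cohort = generate_cohort(CohortSpec(n_subjects=12, seed=31))
    design = DesignSpec(n_obs_target=140, lloq=1e-9)
    return generate_tdm(cohort, design, pop, seed=32), pop


class TestTDMDataset:
    def test_csv_round_trip(self, small_data, tmp_path):
        p = tmp_path / "d.csv"
        small_data.to_csv(p)
        back = TDMDataset.from_csv(p)
        pd.testing.assert_frame_equal(back.df, small_data.df, check_dtype=False)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing required columns"):
            TDMDataset(pd.DataFrame({"ID": [1], "TIME": [0.0]}))

    def test_subject_needs_two_observations(self, small_data):
        df = small_data.df.copy()
        sid = df.ID.iloc[0]
        obs_rows = df[(df.ID == sid) & (df.EVID == 0)].index[1:]
        with pytest.raises(ValueError, match="two observations"):
            TDMDataset(df.drop(obs_rows))

    def test_subject_needs_a_dose(self, small_data):
        df = small_data.df.copy()
        sid = df.ID.iloc[0]
        with pytest.raises(ValueError, match="dose"):
            TDMDataset(df.drop(df[(df.ID == sid) & (df.EVID == 1)].index))

    def test_negative_time_rejected(self, small_data):
        df = small_data.df.copy()
        df.loc[df.index[0], "TIME"] = -1.0
        with pytest.raises(ValueError):
            TDMDataset(df)

    def test_counts(self, small_data):
        assert small_data.n_subjects == 45
        assert small_data.n_obs == len(
            small_data.df[(small_data.df.EVID == 0) & (small_data.df.MDV == 0)]
        )


class TestOfv:
    def test_zero_iiv_reduces_to_weighted_least_squares_deviance(self, small_data, final_pop):
        """With both omega2 = 0 the marginal likelihood is the fixed-effect
        proportional-error WLS deviance."""
        pop = PopulationParameters(
            clp=1.2, vp=4.5, theta_crrt=1.0, omega2_cl=0.0, omega2_v=0.0,
            sigma2_prop=0.2, bw_ref=7.88,
        )
        val = ofv(small_data, pop)
        eng = _Engine(small_data, final_structure())
        cl0, v0 = eng._typical_cl_v(_pop_to_x(eng, pop))
        f, _ = eng._pred(cl0, cl0 / v0)
        fv = np.maximum(f, 1e-6)
        var = 0.2 * fv * fv
        dev = float(np.sum(np.log(2 * np.pi * var) + (eng.y - f) ** 2 / var))
        assert val == pytest.approx(dev, abs=1e-6)

    def test_matches_gauss_hermite_quadrature_oracle(self, final_pop):
        """Laplace marginal vs brute-force 2-D Gauss-Hermite (32^2 nodes) on a
        small rich toy set (many observations per subject, modest variances,
        where the Gaussian approximation of the joint density is accurate)."""
        pop = PopulationParameters(clp=1.09, vp=3.98, theta_crrt=1.04,
                                   omega2_cl=0.05, omega2_v=0.05, sigma2_prop=0.01,
                                   bw_ref=7.88)
        cohort = generate_cohort(CohortSpec(n_subjects=3, seed=41))
        data = generate_tdm(cohort, DesignSpec(n_obs_target=90), pop, seed=42)
        val = ofv(data, pop)
        oracle = _gh_ofv(data, pop, nodes=32)
        assert val == pytest.approx(oracle, abs=0.1)

    def test_laplace_within_half_point_of_quadrature_on_sparse_instance(self):
        """On a sparse, noisy 3-subject instance the Laplace approximation
        stays within 0.5 of the quadrature oracle."""
        pop = PopulationParameters(clp=1.09, vp=3.98, theta_crrt=1.04,
                                   omega2_cl=0.09, omega2_v=0.2, sigma2_prop=0.04,
                                   bw_ref=7.88)
        cohort = generate_cohort(CohortSpec(n_subjects=3, seed=41))
        data = generate_tdm(cohort, DesignSpec(n_obs_target=36), pop, seed=42)
        assert ofv(data, pop) == pytest.approx(_gh_ofv(data, pop, nodes=32), abs=0.5)

    def test_likelihood_prefers_generating_parameters(self, final_pop):
        """On data simulated from the model, the OFV at the truth beats the
        OFV at 2x-perturbed parameters in a clear majority of replicates."""
        wins = 0
        n_rep = 30
        for r in range(n_rep):
            cohort = generate_cohort(CohortSpec(n_subjects=4, seed=500 + r))
            data = generate_tdm(cohort, DesignSpec(n_obs_target=24), final_pop, seed=600 + r)
            bad = PopulationParameters(
                clp=2 * final_pop.clp, vp=2 * final_pop.vp,
                theta_crrt=final_pop.theta_crrt, omega2_cl=final_pop.omega2_cl,
                omega2_v=final_pop.omega2_v, sigma2_prop=final_pop.sigma2_prop,
                bw_ref=final_pop.bw_ref,
            )
            if ofv(data, final_pop) < ofv(data, bad):
                wins += 1
        assert wins >= 0.7 * n_rep

    def test_nested_model_cannot_fit_worse_at_embedded_optimum(self, small_data):
        """A larger model evaluated at the smaller model's optimum (new
        coefficient zero) reproduces its OFV, so the fitted larger model
        can only improve."""
        f0 = fit(small_data, structure=base_structure(), seed=0, n_restarts=1,
                 compute_rse=False)
        trial = base_structure().with_effect(
            CovariateEffect("cl", "BW", "power", ref=7.88)
        )
        eng = _Engine(small_data, trial, n_quad=5)
        from neoperem.estimate import _warm_x0

        x0 = _warm_x0(eng, f0)
        assert eng.ofv(x0) == pytest.approx(f0.ofv, abs=1e-6)
        f1 = fit(small_data, structure=trial, x0=x0, n_restarts=0, compute_rse=False)
        assert f1.ofv <= f0.ofv + 1e-6


class TestFit:
    def test_recovers_parameters_in_noise_free_limit(self, rich_noise_free_data):
        """With no IIV and no residual noise the fit is a deterministic
        least-squares problem whose optimum is the generating truth."""
        data, pop = rich_noise_free_data
        res = fit(data, init=PopulationParameters(
            clp=1.0, vp=4.0, theta_crrt=1.0, omega2_cl=0.01, omega2_v=0.01,
            sigma2_prop=0.01, bw_ref=7.88), n_restarts=0, compute_rse=False)
        assert res.params["clp"] == pytest.approx(1.09, rel=1e-3)
        assert res.params["vp"] == pytest.approx(3.98, rel=1e-3)
        assert res.params["beta[categorical:CRRT->V]"] == pytest.approx(1.04, rel=1e-2)

    def test_single_subject_flags_unidentifiable_variances(self, final_pop):
        cohort = generate_cohort(CohortSpec(n_subjects=1, seed=51))
        data = generate_tdm(cohort, DesignSpec(n_obs_target=6), final_pop, seed=52)
        res = fit(data, seed=0, n_restarts=0, compute_rse=False)
        assert any("unidentifiable" in w for w in res.warnings)

    def test_estimates_invariant_to_relabeling_and_time_shift(self, small_data):
        res1 = fit(small_data, seed=0, n_restarts=0, compute_rse=False)
        # relabel subjects (reverse order) and shift every subject's clock
        df = small_data.df.copy()
        ids = list(dict.fromkeys(df.ID))
        df["ID"] = df.ID.map({s: i for i, s in enumerate(reversed(ids), start=1)})
        df["TIME"] = df["TIME"] + 5.0
        shifted = TDMDataset(df.sort_values(["ID", "TIME"], kind="stable").reset_index(drop=True))
        res2 = fit(shifted, seed=0, n_restarts=0, compute_rse=False)
        assert res2.ofv == pytest.approx(res1.ofv, abs=1e-6)
        for k in res1.params:
            assert res2.params[k] == pytest.approx(res1.params[k], rel=1e-4, abs=1e-8)

    def test_fit_result_exposes_population_parameters(self, small_data):
        res = fit(small_data, seed=0, n_restarts=0, compute_rse=False)
        est = res.estimates
        assert isinstance(est, PopulationParameters)
        assert est.clp == pytest.approx(res.params["clp"])
        assert est.bw_ref == 7.88

    def test_rse_reported_for_all_parameters(self, small_data):
        res = fit(small_data, seed=0, n_restarts=0)
        assert set(res.rse) == set(res.params)
        assert all(v >= 0 or np.isnan(v) for v in res.rse.values())


class TestScm:
    def test_infinite_threshold_returns_base_model(self, small_data):
        cfg = ScmConfig(candidates=(("cl", "BW", "power"),), threshold=np.inf)
        res = scm(small_data, cfg=cfg, seed=0)
        assert res.structure.name == "base"
        assert not res.steps.selected.any()

    def test_constant_covariate_skipped_with_warning(self, small_data):
        df = small_data.df.copy()
        df["FLAT"] = 1.0
        data = TDMDataset(df)
        cfg = ScmConfig(candidates=(("cl", "FLAT", "power"),))
        with pytest.warns(UserWarning, match="constant"):
            res = scm(data, cfg=cfg, seed=0)
        assert ("cl", "FLAT", "power", "constant") in res.skipped

    def test_strong_true_covariate_is_selected(self, small_data):
        cfg = ScmConfig(candidates=(("cl", "BW", "power"), ("cl", "CRCL", "power")))
        res = scm(small_data, cfg=cfg, seed=0)
        assert any(e.covariate == "BW" and e.target == "cl" for e in res.structure.effects)

    def test_noise_only_candidate_rarely_selected(self, final_pop):
        """Type-I control: a single pure-noise candidate at threshold 3.84
        should enter in roughly 5% of replicates."""
        n_rep, n_sel = 25, 0
        cfg = ScmConfig(candidates=(("cl", "PIM3", "power"),))
        for r in range(n_rep):
            cohort = generate_cohort(CohortSpec(seed=700 + r))
            data = generate_tdm(cohort, DesignSpec(), final_pop, seed=750 + r)
            res = scm(data, base=final_structure(), cfg=cfg, seed=r)
            n_sel += len(res.structure.effects) > len(final_structure().effects)
        # binomial(25, 0.05): >= 5 selections has probability < 1%
        assert n_sel <= 4


def _gh_ofv(data, pop, nodes=32):
    """Brute-force 2-D Gauss-Hermite marginal likelihood (test oracle)."""
    eng = _Engine(data, final_structure(bw_ref=pop.bw_ref))
    x = _pop_to_x(eng, pop)
    cl0, v0 = eng._typical_cl_v(x)
    w1, w2, s2 = pop.omega2_cl, pop.omega2_v, pop.sigma2_prop
    z, w = np.polynomial.hermite_e.hermegauss(nodes)
    total = 0.0
    for s in range(eng.n_subj):
        o0, o1 = eng.subj_off[s], eng.subj_off[s + 1]
        pm = (eng.p_obs >= o0) & (eng.p_obs < o1)
        loc = eng.p_obs[pm] - o0
        y = eng.y[o0:o1]
        logL_terms = []
        for a, wa in zip(z, w):
            for b, wb in zip(z, w):
                e1 = a * math.sqrt(w1)
                e2 = b * math.sqrt(w2)
                cl = cl0[o0:o1] * math.exp(e1)
                ke = cl / (v0[o0:o1] * math.exp(e2))
                f = np.zeros(o1 - o0)
                np.add.at(
                    f, loc,
                    (eng.p_rate[pm] / cl[loc])
                    * (-np.expm1(-ke[loc] * eng.p_tau1[pm]))
                    * np.exp(-ke[loc] * eng.p_tau2[pm]),
                )
                fv = np.maximum(f, 1e-6)
                var = s2 * fv * fv
                ll = -0.5 * np.sum(np.log(2 * np.pi * var) + (y - f) ** 2 / var)
                logL_terms.append(math.log(wa * wb) + ll)
        m = max(logL_terms)
        total += -2 * (m + math.log(sum(math.exp(t - m) for t in logL_terms)) - math.log(2 * math.pi))
    return total
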