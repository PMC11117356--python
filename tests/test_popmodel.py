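import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neoperem import (
    ConcentrationProfile,
    DoseEvent,
    IndividualParameters,
    PopulationParameters,
    Regimen,
    SubjectCovariates,
    conc_at,
    ft_above_mic,
    individual_params,
    profile,
)
from neoperem.simulate import build_regimen

from .conftest import ode_concentration


class TestIndividualParams:
    def test_typical_patient_matches_reported_cl_and_v(self, final_pop):
        """At the reference 7.88 kg off CRRT the typical CL is 1.09 L/h and Vd 3.98 L."""
        ind = individual_params(final_pop, SubjectCovariates(bw=7.88, crrt_on=0))
        assert ind.cl == pytest.approx(1.09, rel=1e-12)
        assert ind.v == pytest.approx(3.98, rel=1e-12)

    def test_crrt_doubles_vd(self, final_pop):
        """CRRT multiplies Vd by (1 + theta) = 2.04: 3.98 -> 8.1192 L."""
        ind = individual_params(final_pop, SubjectCovariates(bw=7.88, crrt_on=1))
        assert ind.v == pytest.approx(3.98 * 2.04, rel=1e-12)
        assert ind.cl == pytest.approx(1.09, rel=1e-12)

    def test_identity_at_reference_covariates(self):
        pop = PopulationParameters(clp=2.5, vp=9.0, theta_crrt=0.5, bw_ref=5.0)
        ind = individual_params(pop, SubjectCovariates(bw=5.0, crrt_on=0))
        assert (ind.cl, ind.v) == (2.5, 9.0)

    def test_body_weight_scaling_is_proportional(self, final_pop):
        half = individual_params(final_pop, SubjectCovariates(bw=3.94, crrt_on=0))
        assert half.cl == pytest.approx(1.09 / 2)
        assert half.v == pytest.approx(3.98 / 2)

    def test_random_effects_enter_exponentially(self, final_pop):
        cov = SubjectCovariates(bw=7.88, crrt_on=0)
        ind = individual_params(final_pop, cov, eta_cl=0.3, eta_v=-0.2)
        assert ind.cl == pytest.approx(1.09 * np.exp(0.3))
        assert ind.v == pytest.approx(3.98 * np.exp(-0.2))

    def test_nonfinite_eta_rejected(self, final_pop):
        cov = SubjectCovariates(bw=7.88, crrt_on=0)
        with pytest.raises(ValueError):
            individual_params(final_pop, cov, eta_cl=np.nan)

    def test_ke_is_cl_over_v(self):
        ind = IndividualParameters(cl=1.3, v=5.2)
        assert ind.ke == pytest.approx(1.3 / 5.2, rel=1e-13)


class TestDomainValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(clp=-1, vp=4),
            dict(clp=1, vp=0),
            dict(clp=1, vp=4, theta_crrt=-1.2),
            dict(clp=1, vp=4, omega2_cl=-0.1),
            dict(clp=1, vp=4, bw_ref=0),
        ],
    )
    def test_population_parameter_invariants(self, kwargs):
        with pytest.raises(ValueError):
            PopulationParameters(**kwargs)

    def test_dose_event_invariants(self):
        with pytest.raises(ValueError):
            DoseEvent(start=-1, rate=10, duration=0.5)
        with pytest.raises(ValueError):
            DoseEvent(start=0, rate=0, duration=0.5)
        with pytest.raises(ValueError):
            DoseEvent(start=0, rate=10, duration=0)

    def test_regimen_must_be_sorted(self):
        e1 = DoseEvent(start=8, rate=10, duration=0.5)
        e2 = DoseEvent(start=0, rate=10, duration=0.5)
        with pytest.raises(ValueError):
            Regimen(events=(e1, e2))

    def test_covariates_validated(self):
        with pytest.raises(ValueError):
            SubjectCovariates(bw=0)
        with pytest.raises(ValueError):
            SubjectCovariates(bw=3, crrt_on=2)
        with pytest.raises(ValueError):
            SubjectCovariates(bw=3, extras={"pna": np.inf})


class TestConcentration:
    def test_empty_regimen_gives_zero(self, typical_ind):
        assert conc_at(typical_ind, Regimen(events=()), 5.0) == 0.0

    def test_negative_time_rejected(self, typical_ind):
        reg = build_regimen("continuous", 120, 7.88, 168)
        with pytest.raises(ValueError):
            conc_at(typical_ind, reg, -0.1)

    def test_continuous_infusion_steady_state_is_rate_over_cl(self, typical_ind):
        """Css = R/CL: 39.4 mg/h / 1.09 L/h = 36.15 mg/L, independent of V."""
        reg = build_regimen("continuous", 120, 7.88, 2000.0)
        css = conc_at(typical_ind, reg, 1999.0)
        assert css == pytest.approx(39.4 / 1.09, rel=1e-6)
        other_v = IndividualParameters(cl=typical_ind.cl, v=17.0)
        assert conc_at(other_v, reg, 1999.0) == pytest.approx(css, rel=1e-6)

    def test_q8h_steady_state_peak_and_trough_match_ode_oracle(self, typical_ind):
        """20 mg/kg over 0.5 h q8h at steady state: peak ~41.7, trough ~5.3 mg/L."""
        reg = build_regimen("short_q8h", 20, 7.88, 168)
        t_peak, t_trough = 144.5, 152.0
        peak = conc_at(typical_ind, reg, t_peak)
        trough = conc_at(typical_ind, reg, t_trough - 1e-9)
        oracle = ode_concentration(typical_ind, reg, [t_peak, t_trough - 1e-9])
        assert peak == pytest.approx(oracle[0], abs=1e-4)
        assert trough == pytest.approx(oracle[1], abs=1e-4)
        assert 40 < peak < 44
        assert 4.5 < trough < 6.0

    def test_closed_form_matches_ode_on_random_regimens(self, rng_seed=20240517):
        """Superposition solution vs numeric integration on random draws."""
        rng = np.random.default_rng(rng_seed)
        for _ in range(20):
            cl = rng.uniform(0.2, 5.0)
            v = rng.uniform(0.5, 20.0)
            ind = IndividualParameters(cl=cl, v=v)
            events = []
            t0 = 0.0
            for _k in range(rng.integers(1, 5)):
                t0 += rng.uniform(0, 12)
                events.append(DoseEvent(start=t0, rate=rng.uniform(5, 200), duration=rng.uniform(0.25, 6)))
            reg = Regimen(events=tuple(events))
            times = np.sort(rng.uniform(0, t0 + 24, 5))
            ours = conc_at(ind, reg, times)
            oracle = ode_concentration(ind, reg, times)
            np.testing.assert_allclose(ours, oracle, atol=1e-4)

    def test_dose_rate_homogeneity(self, typical_ind):
        """Doubling every infusion rate doubles every concentration."""
        reg = build_regimen("short_q8h", 20, 7.88, 48)
        doubled = Regimen(
            events=tuple(DoseEvent(ev.start, 2 * ev.rate, ev.duration) for ev in reg.events)
        )
        t = np.linspace(0.25, 47.5, 40)
        np.testing.assert_allclose(
            conc_at(typical_ind, doubled, t), 2 * conc_at(typical_ind, reg, t), rtol=1e-12
        )

    def test_superposition_of_events(self, typical_ind):
        ev1 = DoseEvent(start=0.0, rate=100.0, duration=1.0)
        ev2 = DoseEvent(start=6.0, rate=50.0, duration=2.0)
        t = np.linspace(0, 24, 49)
        both = conc_at(typical_ind, Regimen(events=(ev1, ev2)), t)
        parts = conc_at(typical_ind, Regimen(events=(ev1,)), t) + conc_at(
            typical_ind, Regimen(events=(ev2,)), t
        )
        np.testing.assert_allclose(both, parts, rtol=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        cl=st.floats(0.1, 10),
        v=st.floats(0.3, 30),
        rate=st.floats(1, 500),
        dur=st.floats(0.1, 8),
        t=st.floats(0, 48),
    )
    def test_concentration_nonnegative_and_finite(self, cl, v, rate, dur, t):
        ind = IndividualParameters(cl=cl, v=v)
        reg = Regimen(events=(DoseEvent(start=0.0, rate=rate, duration=dur),))
        c = conc_at(ind, reg, t)
        assert np.isfinite(c) and c >= 0.0


class TestProfileAndFt:
    def test_single_point_grid_before_dosing(self, typical_ind):
        reg = Regimen(events=(DoseEvent(start=1.0, rate=10.0, duration=0.5),))
        prof = profile(typical_ind, reg, [0.0])
        np.testing.assert_array_equal(prof.conc, [0.0])

    def test_unsorted_grid_rejected(self, typical_ind):
        reg = build_regimen("continuous", 60, 7.88, 168)
        with pytest.raises(ValueError):
            profile(typical_ind, reg, [0.0, 2.0, 1.0])

    def test_continuous_steady_state_profile_is_flat_at_rate_over_cl(self, typical_ind):
        reg = build_regimen("continuous", 120, 7.88, 168)
        prof = profile(typical_ind, reg, np.arange(144.0, 168.1, 1.0))
        assert prof.conc.size == 25
        np.testing.assert_allclose(prof.conc, 39.4 / 1.09, rtol=0.01)

    def test_q8h_profile_peaks_at_end_of_infusion(self, typical_ind):
        reg = build_regimen("short_q8h", 20, 7.88, 168)
        grid = np.arange(144.0, 152.01, 0.25)
        prof = profile(typical_ind, reg, grid)
        assert grid[np.argmax(prof.conc)] == pytest.approx(144.5)
        oracle = ode_concentration(typical_ind, reg, grid)
        np.testing.assert_allclose(prof.conc, oracle, atol=1e-4)

    def test_ft_above_mic_extremes(self):
        prof = ConcentrationProfile(times=np.arange(4.0), conc=np.array([5.0, 6.0, 7.0, 8.0]))
        assert ft_above_mic(prof, 1.0) == 1.0
        assert ft_above_mic(prof, 100.0) == 0.0
        assert ft_above_mic(prof, 6.5) == 0.5

    def test_ft_requires_positive_mic(self):
        prof = ConcentrationProfile(times=np.array([0.0]), conc=np.array([1.0]))
        with pytest.raises(ValueError):
            ft_above_mic(prof, 0.0)

    def test_typical_trough_keeps_ft_at_one_for_mic4(self, typical_ind):
        """20 mg/kg q8h: the typical steady-state trough (~5.3) stays above MIC 4."""
        reg = build_regimen("short_q8h", 20, 7.88, 168)
        prof = profile(typical_ind, reg, np.arange(144.0, 168.1, 1.0))
        assert ft_above_mic(prof, 4.0) == 1.0
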