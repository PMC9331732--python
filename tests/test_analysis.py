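import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from kvclamp import analysis, library, protocols, simulate
from kvclamp.analysis import (
    AnalysisError,
    cohort_stats,
    extract_tail_amplitudes,
    fit_boltzmann,
    fit_double_exp,
    fit_recovery,
    fit_single_exp,
    fit_tau_law,
    measure_iv,
    t_test,
)


def boltzmann(V, vh, k):
    return 1.0 / (1.0 + np.exp(-(np.asarray(V) - vh) / k))


class TestBoltzmannFit:
    @pytest.mark.parametrize("vh,k", [(-21.5, 10.0), (7.8, 9.0), (-4.3, 12.0)])
    def test_exact_samples_recovered_to_machine_precision(self, vh, k):
        V = np.arange(-80.0, 61.0, 10.0)
        fit = fit_boltzmann(V, boltzmann(V, vh, k))
        assert fit.converged
        assert fit.params.V_half == pytest.approx(vh, abs=1e-6)
        assert fit.params.k == pytest.approx(k, abs=1e-6)

    def test_flat_curve_is_degenerate(self):
        with pytest.raises(AnalysisError):
            fit_boltzmann(np.arange(-80.0, 61.0, 10.0), np.full(15, 0.5))

    def test_too_few_points_rejected(self):
        with pytest.raises(AnalysisError):
            fit_boltzmann([-80, 0, 60], [0.0, 0.5, 1.0])


class TestSingleExpFit:
    def test_pure_exponential_recovered(self):
        t = np.arange(0, 200, 0.02)
        y = -1.7 * np.exp(-t / 9.4) + 0.3
        fit = fit_single_exp(t, y)
        assert fit.converged
        assert fit.tau == pytest.approx(9.4, abs=0.01)
        assert fit.amplitude == pytest.approx(-1.7, rel=1e-6)
        assert fit.offset == pytest.approx(0.3, abs=1e-9)

    @given(
        st.floats(0.5, 50.0),
        st.floats(0.2, 5.0),
        st.floats(-2.0, 2.0),
    )
    @settings(deadline=None, max_examples=25)
    def test_exact_recovery_property(self, tau, A, C):
        t = np.arange(0, 10 * tau, tau / 50)
        fit = fit_single_exp(t, A * np.exp(-t / tau) + C)
        assert fit.converged
        assert fit.tau == pytest.approx(tau, rel=1e-4)

    def test_constant_segment_flagged(self):
        t = np.arange(0, 100, 0.1)
        fit = fit_single_exp(t, np.full_like(t, 2.5))
        assert not fit.converged
        assert "amplitude_zero" in fit.flags

    def test_biexponential_input_raises_residual_diagnostic(self):
        t = np.arange(0, 200, 0.02)
        y = 0.6 * np.exp(-t / 3.0) + 0.4 * np.exp(-t / 60.0)
        fit = fit_single_exp(t, y)
        assert "nonmonoexponential" in fit.flags


class TestTauLawFit:
    @pytest.mark.parametrize("tau_vh,k_tau,vh", [(9.4, -25.0, -21.5), (31.7, -25.0, 7.8)])
    def test_exact_law_points_recovered(self, tau_vh, k_tau, vh):
        V = np.arange(-30.0, 61.0, 10.0)
        tau = tau_vh * np.exp((V - vh) / k_tau)
        fit = fit_tau_law(V, tau, vh)
        assert fit.converged
        assert fit.tau_at_Vhalf == pytest.approx(tau_vh, rel=1e-6)
        assert fit.k_tau == pytest.approx(k_tau, rel=1e-6)

    def test_voltage_independent_tau_flagged(self):
        fit = fit_tau_law([0.0, 10.0, 20.0], [5.0, 5.0, 5.0], 0.0)
        assert not fit.converged
        assert "tau_voltage_independent" in fit.flags
        assert math.isinf(fit.k_tau)

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(AnalysisError):
            fit_tau_law([0.0, 10.0, 20.0], [5.0, -1.0, 5.0], 0.0)


class TestDoubleExpFit:
    @pytest.mark.parametrize("tf,ts", [(4.9, 37.4), (5.8, 42.1)])
    def test_two_time_constants_recovered_within_2pct(self, tf, ts):
        t = np.arange(0, 90_000.0, 10.0)  # ms
        y = 2.0 * (0.3 * np.exp(-t / (1e3 * tf)) + 0.7 * np.exp(-t / (1e3 * ts)))
        fit = fit_double_exp(t, y)
        assert fit.tau_fast == pytest.approx(1e3 * tf, rel=0.02)
        assert fit.tau_slow == pytest.approx(1e3 * ts, rel=0.02)
        assert fit.frac_fast == pytest.approx(0.3, abs=0.01)
        assert fit.tau_fast < fit.tau_slow

    def test_single_exponential_input_flags_collapse(self):
        t = np.arange(0, 50_000.0, 10.0)
        y = np.exp(-t / 5000.0)
        fit = fit_double_exp(t, y)
        assert "component_collapse" in fit.flags
        assert fit.frac_fast < 0.02 or fit.frac_fast > 0.98 or (
            abs(fit.tau_slow - fit.tau_fast) / fit.tau_slow < 0.05
        )


class TestRecoveryFit:
    @pytest.mark.parametrize("tau", [3.4, 2.2])
    def test_exact_curve_recovered(self, tau):
        dt = np.asarray(protocols.DEFAULT_RECOVERY_INTERVALS_S)
        R = 1.0 - 0.6 * np.exp(-dt / tau)
        fit = fit_recovery(dt, R)
        assert fit.converged
        assert fit.tau == pytest.approx(tau, abs=0.05)

    def test_no_inactivation_flagged(self):
        dt = [0.1, 1.0, 5.0, 10.0]
        fit = fit_recovery(dt, [1.0, 1.0, 1.0, 1.0])
        assert not fit.converged
        assert "no_inactivation" in fit.flags

    def test_unphysical_ratios_rejected(self):
        with pytest.raises(AnalysisError):
            fit_recovery([0.1, 1.0, 5.0, 10.0], [0.5, 0.9, 1.0, 1.5])


@pytest.fixture(scope="module")
def wt(ref_species):
    return ref_species[library.WT]


class TestIvAndTails:

    def test_iv_steady_current_matches_calibration(self, wt, ref_species):
        p = protocols.build_iv_protocol()
        tab = measure_iv(simulate.simulate_protocol(wt, p), p)
        assert float(tab.loc[tab.step_V == 20.0, "current"].iloc[0]) == pytest.approx(2.1, rel=1e-6)
        mut_tab = measure_iv(
            simulate.simulate_protocol(ref_species[library.MUT], p), p
        )
        assert float(mut_tab.loc[mut_tab.step_V == 20.0, "current"].iloc[0]) == pytest.approx(
            0.4, rel=1e-6
        )

    def test_step_at_holding_measures_zero(self, wt):
        p = protocols.build_iv_protocol()
        tab = measure_iv(simulate.simulate_protocol(wt, p), p)
        assert float(tab.loc[tab.step_V == -80.0, "current"].iloc[0]) == pytest.approx(0.0, abs=1e-12)

    def test_mutant_current_smaller_at_every_activating_potential(self, ref_species):
        p = protocols.build_iv_protocol()
        wt_tab = measure_iv(simulate.simulate_protocol(ref_species[library.WT], p), p)
        mut_tab = measure_iv(simulate.simulate_protocol(ref_species[library.MUT], p), p)
        act = wt_tab.step_V >= -40.0
        assert (mut_tab.loc[act, "current"].to_numpy() < wt_tab.loc[act, "current"].to_numpy()).all()

    def test_normalized_tails_anchor_and_midpoint(self, wt):
        p = protocols.build_tail_protocol(-50.0)
        df = extract_tail_amplitudes(simulate.simulate_protocol(wt, p), p)
        assert df.normalized.max() == pytest.approx(1.0)
        assert float(df.loc[df.prepulse_V == 60.0, "normalized"].iloc[0]) == 1.0
        # prepulse at the generative midpoint reaches half the maximal tail
        interp = np.interp(-21.5, df.prepulse_V, df.normalized)
        assert interp == pytest.approx(0.5, abs=0.02)

    def test_zero_tails_rejected(self, wt):
        p = protocols.build_tail_protocol(-50.0)
        traces = simulate.simulate_protocol(wt, p)
        for tr in traces:
            tr.current = np.zeros_like(tr.current)
        with pytest.raises(AnalysisError):
            extract_tail_amplitudes(traces, p)


class TestCohortStatsAndTTest:
    def test_constant_values(self):
        assert cohort_stats([1.0, 1.0, 1.0]) == (1.0, 0.0, 3)

    def test_two_values_hand_computed(self):
        mean, sem, n = cohort_stats([0.0, 2.0])
        assert (mean, n) == (1.0, 2)
        assert sem == pytest.approx(1.0)  # sd = sqrt(2), sem = sqrt(2)/sqrt(2)

    def test_identical_groups_p_is_one(self):
        r = t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.p == 1.0 or r.p == pytest.approx(1.0)
        assert not r.significant

    def test_clear_separation_is_significant(self):
        r = t_test([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert r.significant and r.p < 0.05

    @given(
        st.lists(st.floats(-5, 5), min_size=3, max_size=12),
        st.lists(st.floats(-5, 5), min_size=3, max_size=12),
    )
    @settings(deadline=None, max_examples=40)
    def test_matches_reference_implementation(self, a, b):
        if np.var(a) + np.var(b) == 0:
            return
        ours = t_test(a, b)
        ref_t, ref_p = sps.ttest_ind(a, b, equal_var=True)
        assert ours.t == pytest.approx(float(ref_t), rel=1e-9, abs=1e-9)
        assert ours.p == pytest.approx(float(ref_p), rel=1e-9, abs=1e-12)

    def test_small_groups_rejected(self):
        with pytest.raises(AnalysisError):
            t_test([1.0], [1.0, 2.0])


class TestCharacterizeCell:
    def test_missing_protocol_is_reported(self, ref_species):
        with pytest.raises(AnalysisError, match="lacks protocols"):
            analysis.characterize_cell({"iv": []}, {})

    def test_noise_free_trio_recovers_generative_parameters(self, characterized_trio, ref_species):
        """End to end, every generative parameter is recovered within 2%
        (times) / 0.5 mV (voltages) from noise-free simulated cells."""
        for name, res in characterized_trio.items():
            sp = ref_species[name]
            assert res.V_half == pytest.approx(sp.activation.V_half, abs=0.5), name
            assert res.k == pytest.approx(sp.activation.k, abs=0.5), name
            assert res.act_tau_Vhalf == pytest.approx(sp.act_tau.tau_at_Vhalf, rel=0.02), name
            assert res.deact_tau_Vhalf == pytest.approx(sp.deact_tau.tau_at_Vhalf, rel=0.02), name
            assert res.tau_fast == pytest.approx(sp.inact.tau_fast, rel=0.02), name
            assert res.tau_slow == pytest.approx(sp.inact.tau_slow, rel=0.02), name
            assert res.tau_recovery == pytest.approx(sp.inact.tau_recovery, rel=0.02), name

    def test_cohort_means_converge_with_n(self, ref_species):
        """Boltzmann midpoints estimated per jittered cell average back to
        the generative midpoint as the cohort grows."""
        wt = ref_species[library.WT]
        p = protocols.build_tail_protocol(-50.0)
        errs = {}
        for n in (5, 20):
            spec = simulate.CohortSpec(n, wt, jitter_cv=0.05, noise_sd=0.01, seed=11)
            cohort = simulate.simulate_cohort(spec, [p])
            vhs = []
            for rec in cohort.values():
                df = extract_tail_amplitudes(rec["tail"], p)
                vhs.append(fit_boltzmann(df.prepulse_V, df.normalized).params.V_half)
            mean, sem, _ = cohort_stats(vhs)
            errs[n] = abs(mean - wt.activation.V_half)
        assert errs[20] < 1.5
        assert math.isfinite(errs[5])

    def test_cohort_sem_same_scale_as_reported(self, ref_species):
        """A 29-cell jittered WT cohort yields a V_half SEM within 3x of the
        0.4 mV reported for the experimental cohort of the same size."""
        wt = ref_species[library.WT]
        p = protocols.build_tail_protocol(-50.0)
        spec = simulate.CohortSpec(29, wt, jitter_cv=0.1, noise_sd=0.02, seed=7)
        cohort = simulate.simulate_cohort(spec, [p])
        vhs = []
        for rec in cohort.values():
            df = extract_tail_amplitudes(rec["tail"], p)
            vhs.append(fit_boltzmann(df.prepulse_V, df.normalized).params.V_half)
        _, sem, n = cohort_stats(vhs)
        assert n == 29
        assert sem < 3 * 0.4
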