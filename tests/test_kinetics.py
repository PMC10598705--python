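"""Forward model and fitting of single-turnover fluorescence transients."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phenoflux.kinetics as K
from phenoflux.kinetics import (
    DomainError,
    FitInputError,
    ScheduleError,
    STParams,
    STTrace,
    fit_single_turnover,
    frame_to_traces,
    induction_schedule,
    relaxation_schedule,
    simulate_induction,
    simulate_relaxation,
    simulate_trace_pair,
    traces_to_frame,
    yield_from_closure,
)


def brute_force_closure(C0, sigma, rho, n, dose, nsub=2000):
    """Independent oracle: micro-jump recursion at delta-dose resolution."""
    C = np.empty(n)
    c = C0
    k = sigma * dose / nsub
    for j in range(n):
        C[j] = c
        for _ in range(nsub):
            c = min(c + k * (1 - c) / (1 - rho * c), 1.0)
    return C, c


class TestYieldFromClosure:
    @pytest.mark.parametrize(
        "C,F0,Fm,rho,expected",
        [
            (0.0, 1000, 3000, 0.3, 1000.0),  # no closure returns F0
            (1.0, 1000, 3000, 0.3, 3000.0),  # full closure returns Fm
            (0.5, 1000, 3000, 0.4, 1750.0),  # 1000 + 2000*0.5*0.6/0.8
        ],
    )
    def test_examples(self, C, F0, Fm, rho, expected):
        assert yield_from_closure(C, F0, Fm, rho) == pytest.approx(expected)

    def test_linear_at_zero_connectivity(self):
        C = np.linspace(0, 1, 11)
        np.testing.assert_allclose(
            yield_from_closure(C, 1000, 3000, 0.0), 1000 + 2000 * C, rtol=1e-12
        )

    @given(
        C=st.floats(0, 1),
        rho=st.floats(0, 0.95, exclude_max=True),
        fv=st.floats(10, 1e5),
    )
    @settings(max_examples=100, deadline=None)
    def test_bounded_and_monotone(self, C, rho, fv):
        F0, Fm = 500.0, 500.0 + fv
        f = yield_from_closure(C, F0, Fm, rho)
        assert F0 - 1e-9 <= f <= Fm + 1e-9
        if C < 1:
            c2 = min(C + 0.01, 1.0)
            assert yield_from_closure(c2, F0, Fm, rho) >= f - 1e-9

    @pytest.mark.parametrize("bad", [dict(rho=1.0), dict(rho=-0.1), dict(C=1.2), dict(C=-0.2)])
    def test_domain_errors(self, bad):
        kw = dict(C=0.5, F0=1000.0, Fm=3000.0, rho=0.3)
        kw.update(bad)
        with pytest.raises(DomainError):
            yield_from_closure(kw["C"], kw["F0"], kw["Fm"], kw["rho"])

    def test_fm_not_above_f0_rejected(self):
        with pytest.raises(DomainError):
            yield_from_closure(0.5, 3000, 1000, 0.3)


class TestSchedules:
    def test_induction_spacing(self):
        s = induction_schedule(32)
        assert len(s) == 32
        np.testing.assert_allclose(np.diff(s.times_us), 4.7)  # 1.3 flash + 3.4 dark
        assert s.gap_us == pytest.approx(3.4)

    def test_relaxation_geometry(self):
        s = relaxation_schedule(40)
        gaps = np.diff(s.times_us) - s.flashlet_duration_us
        assert s.times_us[0] == pytest.approx(59.0)  # first gap 59 us
        assert np.all(np.diff(gaps) > 0)  # strictly increasing dark periods
        assert s.times_us[-1] == pytest.approx(300_000.0, rel=1e-6)  # 300 ms span
        # geometric growth: constant ratio
        ratios = gaps[1:] / gaps[:-1]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-9)

    def test_invalid_schedules(self):
        with pytest.raises(ScheduleError):
            K.FlashletSchedule("induction", [3.0, 2.0, 1.0])
        with pytest.raises(ScheduleError):
            K.FlashletSchedule("twilight", [0.0, 4.7])
        with pytest.raises(ScheduleError):
            K.FlashletSchedule("relaxation", [0.0, 100.0, 400_000.0])

    def test_wavelength_alias(self):
        assert K.canonical_wavelength(520) == 525
        assert K.canonical_wavelength(442) == 442
        with pytest.raises(DomainError):
            K.canonical_wavelength(632)


class TestSimulateInduction:
    def test_zero_dose_constant_at_f0(self, default_params):
        sched = induction_schedule(32, dose_per_flashlet=0.0)
        tr = simulate_induction(default_params, sched)
        np.testing.assert_allclose(tr.f_induction, default_params.F0)

    def test_saturating_dose_reaches_fm(self, default_params):
        sched = induction_schedule(32, dose_per_flashlet=0.05)
        tr = simulate_induction(default_params, sched)
        assert tr.f_induction[-1] == pytest.approx(default_params.Fm, rel=0.01)

    def test_monotone_and_bounded(self, default_params):
        tr = simulate_induction(default_params, induction_schedule(40))
        f = tr.f_induction
        assert np.all(np.diff(f) >= -1e-9)
        assert np.all(f >= default_params.F0 - 1e-9)
        assert np.all(f <= default_params.Fm + 1e-9)

    def test_agrees_with_brute_force_oracle(self):
        # sigma*dose*32 ~ 3 cumulative: the mid-saturation regime
        sigma, rho, dose, n = 500.0, 0.3, 3.0 / (500.0 * 32), 32
        p = STParams(F0=1000, Fm=3000, sigma_PSII=sigma, rho=rho)
        tr = simulate_induction(p, induction_schedule(n, dose))
        C_oracle, _ = brute_force_closure(0.0, sigma, rho, n, dose)
        f_oracle = yield_from_closure(C_oracle, 1000, 3000, rho)
        np.testing.assert_allclose(tr.f_induction, f_oracle, rtol=0.005)
        # and the train indeed nearly saturates variable fluorescence
        assert (tr.f_induction[-1] - 1000) / 2000 > 0.9

    def test_reopening_lowers_closure(self):
        p = STParams(F0=1000, Fm=3000, sigma_PSII=400, rho=0.3, tau1_us=100.0)
        sched = induction_schedule(32)
        off = simulate_induction(p, sched, reopening_enabled=False)
        on = simulate_induction(p, sched, reopening_enabled=True)
        assert on.f_induction[-1] < off.f_induction[-1]

    def test_wrong_phase_rejected(self, default_params):
        with pytest.raises(ScheduleError):
            simulate_induction(default_params, relaxation_schedule(20))


class TestSimulateRelaxation:
    def test_continuity_at_t0(self, default_params):
        gaps = 59.0 * 2.0 ** np.arange(10)
        times = np.concatenate([[0.0], np.cumsum(gaps + 1.3)])
        sched = K.FlashletSchedule("relaxation", times)
        tr = simulate_relaxation(default_params, 0.8, sched)
        expected = yield_from_closure(0.8, 1000, 3000, 0.4)
        assert tr.f_relaxation[0] == pytest.approx(expected)

    def test_full_reopening_returns_f0(self, default_params):
        sched = K.FlashletSchedule("relaxation", [5e4, 1.6e5, 2.99e5])
        tr = simulate_relaxation(default_params, 1.0, sched)
        assert tr.f_relaxation[-1] == pytest.approx(default_params.F0, rel=1e-6)

    def test_single_exponential_e_folding(self):
        p = STParams(F0=1000, Fm=3000, sigma_PSII=500, rho=0.0,
                     alpha=1.0, tau1_us=600.0, tau2_us=12_000.0)
        sched = K.FlashletSchedule("relaxation", [600.0, 1300.0])
        tr = simulate_relaxation(p, 0.9, sched)
        # rho = 0: F - F0 proportional to C, so C(600)/C_end = 1/e exactly
        frac = (tr.f_relaxation[0] - 1000) / (yield_from_closure(0.9, 1000, 3000, 0.0) - 1000)
        assert frac == pytest.approx(np.exp(-1), rel=1e-9)

    def test_monotone_non_increasing(self, default_params):
        tr = simulate_relaxation(default_params, 0.95, relaxation_schedule(40))
        assert np.all(np.diff(tr.f_relaxation) <= 1e-9)

    def test_degenerate_c_end(self, default_params):
        with pytest.raises(DomainError):
            simulate_relaxation(default_params, 0.0, relaxation_schedule(20))


class TestTraceContainer:
    def test_positive_fluorescence_required(self):
        sched = induction_schedule(20)
        with pytest.raises(FitInputError):
            STTrace(442, induction=sched, f_induction=np.full(20, -1.0))

    def test_length_mismatch(self):
        with pytest.raises(FitInputError):
            STTrace(442, induction=induction_schedule(20), f_induction=np.ones(19))


class TestFit:
    def test_noiseless_round_trip(self, default_params):
        tr = simulate_trace_pair(default_params, 442)
        fit = fit_single_turnover(tr, c0_fixed=0.0)
        assert fit.converged
        p, t = fit.params, default_params
        for got, want in [(p.F0, t.F0), (p.Fm, t.Fm), (p.sigma_PSII, t.sigma_PSII),
                          (p.rho, t.rho), (p.alpha, t.alpha),
                          (p.tau1_us, t.tau1_us), (p.tau2_us, t.tau2_us)]:
            assert got == pytest.approx(want, rel=1e-3)
        assert fit.phi_PSII == pytest.approx(2.0 / 3.0, rel=1e-3)

    def test_monte_carlo_recovery_at_one_percent_noise(self, default_params):
        errs = {"sigma": [], "tau1": []}
        for seed in range(50):
            rng = np.random.default_rng(seed)
            tr = simulate_trace_pair(default_params, 505, noise_rel=0.01, rng=rng)
            p = fit_single_turnover(tr, c0_fixed=0.0).params
            errs["sigma"].append(abs(p.sigma_PSII - 500) / 500)
            errs["tau1"].append(abs(p.tau1_us - 600) / 600)
        assert np.median(errs["sigma"]) <= 0.05
        assert np.median(errs["tau1"]) <= 0.05

    def test_bias_vanishes_with_noise(self, default_params):
        med = []
        for noise in (0.0, 0.001, 0.01):
            errs = []
            for seed in range(15):
                rng = np.random.default_rng(seed)
                tr = simulate_trace_pair(default_params, 505, noise_rel=noise, rng=rng)
                p = fit_single_turnover(tr, c0_fixed=0.0).params
                errs.append(abs(p.sigma_PSII - 500) / 500)
            med.append(np.median(errs))
        assert med[0] < 1e-6
        assert med[0] <= med[1] <= med[2]

    def test_sigma_rho_tradeoff_guard(self):
        """Fixing rho at truth must tighten sigma recovery (trade-off is real).

        The trade-off is sharpest for a light-adapted transient (initial
        closed fraction free), which is why the pipeline pins rho at light
        timepoints to the dark-reference value.
        """
        truth = STParams(F0=900, Fm=2500, sigma_PSII=450, rho=0.42, C0=0.3,
                         alpha=0.6, tau1_us=600, tau2_us=12_000)
        free, fixed = [], []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            tr = simulate_trace_pair(truth, 505, noise_rel=0.01, rng=rng)
            pf_ = fit_single_turnover(tr).params
            px = fit_single_turnover(tr, rho_fixed=0.42).params
            free.append(abs(pf_.sigma_PSII - 450) / 450)
            fixed.append(abs(px.sigma_PSII - 450) / 450)
        assert np.median(fixed) < np.median(free)

    def test_light_adapted_fit_with_dark_ties(self):
        """OB-tied F0 and pinned rho recover a quenched light-state transient."""
        fo_d, fm_d = 900.0, 2500.0
        fm_p = 1800.0
        phi = (fm_d - fo_d) / fm_d
        fo_p = fo_d / (phi + fo_d / fm_p)
        truth = STParams(F0=fo_p, Fm=fm_p, sigma_PSII=450, rho=0.42, C0=0.3,
                         alpha=0.6, tau1_us=600, tau2_us=12_000)
        rng = np.random.default_rng(5)
        tr = simulate_trace_pair(truth, 505, noise_rel=0.005, rng=rng)
        fit = fit_single_turnover(tr, rho_fixed=0.42, f0_from_dark=(fo_d, fm_d))
        p = fit.params
        assert p.Fm == pytest.approx(fm_p, rel=0.01)
        assert p.C0 == pytest.approx(0.3, abs=0.02)
        assert p.sigma_PSII == pytest.approx(450, rel=0.05)

    def test_flat_trace_not_converged(self):
        n_i, n_r = 32, 20
        tr = STTrace(
            442,
            induction=induction_schedule(n_i),
            relaxation=relaxation_schedule(n_r),
            f_induction=np.full(n_i, 1000.0),
            f_relaxation=np.full(n_r, 1000.0),
        )
        fit = fit_single_turnover(tr)
        assert not fit.converged
        assert np.isnan(fit.params.sigma_PSII)

    def test_too_few_flashlets_rejected(self, default_params):
        tr = simulate_trace_pair(default_params, 442, n_relaxation=20)
        short = STTrace(
            442, induction=induction_schedule(10),
            relaxation=tr.relaxation,
            f_induction=tr.f_induction[:10], f_relaxation=tr.f_relaxation,
        )
        with pytest.raises(FitInputError):
            fit_single_turnover(short)

    def test_unseparated_components_reported_missing(self):
        p = STParams(F0=1000, Fm=3000, sigma_PSII=500, rho=0.3,
                     alpha=0.5, tau1_us=800.0, tau2_us=1000.0)
        tr = simulate_trace_pair(p, 442)
        fit = fit_single_turnover(tr, c0_fixed=0.0)
        assert np.isnan(fit.params.tau2_us)
        assert fit.params.alpha == 1.0


class TestTraceTables:
    def test_round_trip(self, default_params, rng):
        traces = [
            simulate_trace_pair(default_params, w, noise_rel=0.01, rng=rng,
                                sample_id="s1", timepoint_index=t, repeat_index=r)
            for w in (442, 505) for t in (1, 2) for r in (1, 2)
        ]
        frame = traces_to_frame(traces)
        assert set(frame.columns) == set(K.TRACE_COLUMNS)
        back = frame_to_traces(frame)
        assert len(back) == len(traces)
        key = lambda tr: (tr.sample_id, tr.wavelength_nm, tr.timepoint_index, tr.repeat_index)
        orig = {key(tr): tr for tr in traces}
        for tr in back:
            np.testing.assert_allclose(tr.fluorescence, orig[key(tr)].fluorescence)

    def test_missing_columns_rejected(self):
        import pandas as pd

        with pytest.raises(FitInputError):
            frame_to_traces(pd.DataFrame({"sample_id": ["a"]}))
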