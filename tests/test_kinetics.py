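"""Two-state kinetics: simulation, closed forms, fitting, diagnostics."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.stats import linregress

from evsense.kinetics import (
    AVOGADRO,
    IdentifiabilityError,
    InjectionProtocol,
    Sensorgram,
    TwoStateRateSet,
    dissociation_closed_form,
    dissociation_eigenvalues,
    dissociation_linearity,
    fit_two_state,
    particles_to_molar,
    simulate_two_state,
    stepwise_constants,
)
from evsense.synthetic_data import PUBLISHED_RATES, GeneratorConfig, gen_sensorgram_set

CD9 = PUBLISHED_RATES["anti-CD9"]
CD63 = PUBLISHED_RATES["anti-CD63"]
CD81 = PUBLISHED_RATES["anti-CD81"]


def _ode_dissociation(rates, ab0, abstar0, t_grid):
    """Independent numeric oracle: integrate the C=0 system directly."""

    def rhs(_t, x):
        ab, abs_ = x
        return (
            -(rates.kd1 + rates.ka2) * ab + rates.kd2 * abs_,
            rates.ka2 * ab - rates.kd2 * abs_,
        )

    sol = solve_ivp(
        rhs, (0.0, t_grid[-1]), (ab0, abstar0), t_eval=t_grid,
        method="LSODA", rtol=1e-11, atol=1e-14,
    )
    assert sol.success
    return sol.y.sum(axis=0)


class TestParticlesToMolar:
    @pytest.mark.parametrize(
        "particles_per_ml, expected, rtol",
        [
            (0.0, 0.0, 0.0),
            (6.1e8, 6.1e8 * 1000 / AVOGADRO, 1e-12),  # ~1.013e-12 M stock
            (6.02214076e17, 1.0e-3, 1e-6),
        ],
    )
    def test_conversion(self, particles_per_ml, expected, rtol):
        got = particles_to_molar(particles_per_ml)
        assert got == pytest.approx(expected, rel=rtol, abs=1e-300)

    def test_stock_magnitude(self):
        # the study's EV stock, 6.1e8 particles/mL, is ~1 pM
        assert particles_to_molar(6.1e8) == pytest.approx(1.013e-12, rel=1e-3)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            particles_to_molar(-1.0)


class TestSimulateTwoState:
    def test_zero_concentration_gives_flat_zero(self):
        proto = InjectionProtocol(analyte_concentration=0.0)
        s = simulate_two_state(CD9, proto)
        assert np.all(s.response == 0.0)

    def test_langmuir_limit(self):
        # ka2, kd2 -> 0 reduces to 1:1 Langmuir binding
        rates = TwoStateRateSet(ka1=1e5, kd1=1e-3, ka2=1e-14, kd2=1e-14, rmax=100.0)
        C = 1e-7
        proto = InjectionProtocol(analyte_concentration=C)
        s = simulate_two_state(rates, proto)
        assoc = s.phase_mask("association")
        req = rates.rmax * C / (C + rates.kd1 / rates.ka1)
        expected = req * (1.0 - np.exp(-(rates.ka1 * C + rates.kd1) * s.time[assoc]))
        np.testing.assert_allclose(s.response[assoc], expected, rtol=1e-6)

    def test_long_association_reaches_linear_steady_state(self):
        # oracle: solve the 2x2 steady-state system directly
        rates = CD81
        C = 1e-5
        proto = InjectionProtocol(
            analyte_concentration=C, association_duration=50000.0,
            dissociation_duration=10.0, sampling_interval=100.0,
        )
        s = simulate_two_state(rates, proto)
        kobs = rates.ka1 * C
        A = np.array(
            [
                [-(kobs + rates.kd1 + rates.ka2), rates.kd2 - kobs],
                [rates.ka2, -rates.kd2],
            ]
        )
        x_ss = np.linalg.solve(A, [-kobs * rates.rmax, 0.0])
        assoc = s.phase_mask("association")
        assert s.response[assoc][-1] == pytest.approx(float(x_ss.sum()), rel=1e-6)

    def test_response_bounded_by_rmax_and_conserves_sites(self):
        proto = InjectionProtocol(analyte_concentration=1e-4)
        s = simulate_two_state(CD81, proto)
        assert np.all(s.response >= 0.0)
        assert np.all(s.response <= CD81.rmax * (1 + 1e-9))

    def test_dissociation_monotone_nonincreasing(self):
        proto = InjectionProtocol(analyte_concentration=1e-5)
        s = simulate_two_state(CD9, proto)
        diss = s.response[s.phase_mask("dissociation")]
        assert np.all(np.diff(diss) <= 1e-9 * diss.max())


class TestDissociationClosedForm:
    def test_identity_at_t0(self):
        assert dissociation_closed_form(CD9, 0.3, 0.1, 0.0) == pytest.approx(0.4, rel=1e-12)

    def test_single_exponential_limit(self):
        # conformational step switched (numerically) off, no AB* present
        rates = TwoStateRateSet(ka1=1e3, kd1=5e-3, ka2=1e-14, kd2=1e-14, rmax=100.0)
        t = np.linspace(0.0, 300.0, 61)
        got = dissociation_closed_form(rates, 0.7, 0.0, t)
        np.testing.assert_allclose(got, 0.7 * np.exp(-rates.kd1 * t), rtol=1e-8)

    def test_matches_ode_for_study_rates(self):
        t = np.arange(0.0, 301.0)
        cf = dissociation_closed_form(CD9, 0.3, 0.1, t)
        ode = _ode_dissociation(CD9, 0.3, 0.1, t)
        np.testing.assert_allclose(cf, ode, rtol=1e-8)

    def test_terminal_decay_rate_is_smallest_eigenvalue(self):
        # late decay follows exp(lambda_slow * t)
        lam = dissociation_eigenvalues(CD9)
        slow = lam[-1]  # smaller magnitude
        t1, t2 = 5.0e7, 5.2e7  # deep into the slow regime for anti-CD9
        r1 = dissociation_closed_form(CD9, 0.3, 0.1, t1)
        r2 = dissociation_closed_form(CD9, 0.3, 0.1, t2)
        rate = np.log(r1 / r2) / (t2 - t1)
        assert -rate == pytest.approx(slow, rel=1e-3)

    def test_nonincreasing(self):
        t = np.linspace(0, 300, 301)
        r = dissociation_closed_form(CD81, 0.5, 0.2, t)
        assert np.all(np.diff(r) <= 1e-12)

    def test_near_repeated_eigenvalue_uses_limiting_form(self):
        # kd1 ~= kd2 with ka2 -> 0 drives the system towards the
        # defective (repeated-eigenvalue) point; the limiting form must
        # stay finite and agree with the independent ODE oracle
        rates = TwoStateRateSet(ka1=1.0, kd1=1e-2, ka2=1e-9, kd2=1e-2, rmax=1.0)
        t = np.array([0.0, 10.0, 100.0, 300.0])
        r = dissociation_closed_form(rates, 0.5, 0.5, t)
        assert np.all(np.isfinite(r))
        assert r[0] == pytest.approx(1.0)
        np.testing.assert_allclose(r, _ode_dissociation(rates, 0.5, 0.5, t), rtol=1e-7)


class TestStepwiseConstants:
    def test_anti_cd9_reproduces_printed_cells(self):
        c = stepwise_constants(CD9)
        assert c.KD1 == pytest.approx(3.99e-6, rel=1e-2)
        assert c.KD2 == pytest.approx(2.51e-5, rel=1e-2)
        assert c.KD_total == pytest.approx(10.00e-11, rel=1e-2)

    def test_anti_cd81_total(self):
        assert stepwise_constants(CD81).KD_total == pytest.approx(5.16e-6, rel=1e-2)

    def test_symmetric_rates_give_unity(self):
        rates = TwoStateRateSet(ka1=2.0, kd1=2.0, ka2=0.5, kd2=0.5, rmax=1.0)
        c = stepwise_constants(rates)
        assert (c.KD1, c.KD2, c.KD_total) == (1.0, 1.0, 1.0)

    def test_product_identity_is_exact(self):
        c = stepwise_constants(CD63)
        assert c.KD_total == c.KD1 * c.KD2  # bitwise: computed as the product


class TestDissociationLinearity:
    @staticmethod
    def _sensorgram_from_decay(t, r, conc=1e-9):
        time = np.concatenate([[-1.0], t])
        resp = np.concatenate([[r[0]], r])
        phase = np.array(["association"] + ["dissociation"] * len(t), dtype=object)
        return Sensorgram(time, resp, phase, conc)

    def test_pure_exponential(self):
        k = 3.3e-3
        t = np.linspace(0.0, 300.0, 301)
        s = self._sensorgram_from_decay(t, 0.8 * np.exp(-k * t))
        fit = dissociation_linearity(s)
        assert fit.slope == pytest.approx(k, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_zero_at_window_start(self):
        t = np.linspace(0.0, 100.0, 101)
        s = self._sensorgram_from_decay(t, np.exp(-0.01 * t))
        r0 = s.response[s.phase_mask("dissociation")][0]
        assert np.log(r0 / r0) == 0.0

    def test_two_state_decay_matches_bruteforce_regression(self):
        t = np.arange(0.0, 301.0)
        r = dissociation_closed_form(CD9, 0.3, 0.1, t)
        s = self._sensorgram_from_decay(t, np.asarray(r))
        fit = dissociation_linearity(s)
        brute = linregress(t, np.log(r[0] / r))
        assert fit.slope == pytest.approx(brute.slope, rel=1e-12)
        assert fit.r_squared == pytest.approx(brute.rvalue**2, rel=1e-12)

    def test_nonpositive_tail_truncated_and_flagged(self):
        t = np.linspace(0.0, 10.0, 11)
        r = 1.0 - 0.15 * t  # crosses zero
        s = self._sensorgram_from_decay(t, r)
        fit = dissociation_linearity(s)
        assert fit.truncated
        assert fit.n_points < len(t)


class TestFitTwoState:
    def test_flat_response_raises_identifiability_error(self):
        t = np.arange(0.0, 391.0)
        phase = np.where(t <= 90.0, "association", "dissociation").astype(object)
        s = Sensorgram(t, np.zeros_like(t), phase, 1e-9)
        with pytest.raises(IdentifiabilityError):
            fit_two_state([s])

    def test_mixed_channels_rejected(self):
        cfg = GeneratorConfig(seed=1, spr_noise_sd_frac=0.0, concentrations=(6.1e7,))
        a = gen_sensorgram_set(cfg, "anti-CD9")[0]
        b = gen_sensorgram_set(cfg, "anti-CD63")[0]
        with pytest.raises(ValueError, match="channel"):
            fit_two_state([a, b])

    def test_noiseless_recovery_anti_cd63(self):
        # refit of noiseless simulated data at the study's four
        # concentrations recovers the generating parameters; the
        # saturation response is fixed at its known value because at
        # picomolar analyte only the product ka1*rmax is identifiable
        cfg = GeneratorConfig(seed=7, spr_noise_sd_frac=0.0)
        sensorgrams = gen_sensorgram_set(cfg, "anti-CD63")
        fit = fit_two_state(sensorgrams, fix={"rmax": CD63.rmax})
        assert fit.converged
        assert fit.rates.ka1 == pytest.approx(3.48e3, rel=1e-3)
        for name in ("ka1", "kd1", "ka2", "kd2"):
            assert getattr(fit.rates, name) == pytest.approx(
                getattr(CD63, name), rel=1e-3
            ), name
        c = fit.constants
        assert c.KD_total == c.KD1 * c.KD2

    def test_single_concentration_flagged(self):
        cfg = GeneratorConfig(seed=3, spr_noise_sd_frac=0.0, concentrations=(6.1e7,))
        sensorgrams = gen_sensorgram_set(cfg, "anti-CD63")
        fit = fit_two_state(sensorgrams, fix={"rmax": CD63.rmax})
        assert fit.poorly_identified


class TestRateSetValidation:
    @pytest.mark.parametrize("bad", [{"ka1": 0.0}, {"kd1": -1.0}, {"rmax": 0.0}])
    def test_nonpositive_rejected(self, bad):
        kwargs = dict(ka1=1.0, kd1=1.0, ka2=1.0, kd2=1.0, rmax=1.0)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            TwoStateRateSet(**kwargs)

    def test_nonmonotone_time_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            Sensorgram(
                np.array([0.0, 2.0, 1.0]),
                np.zeros(3),
                np.array(["association"] * 3, dtype=object),
                1e-9,
            )
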