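"""Two-pool spin dynamics: lineshapes, propagators, RF-pulse models."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from t1mt.spin_models import (
    WM_3T_FIT,
    RFPulse,
    SpinState,
    TwoPoolParameters,
    _kernel_modes,
    free_precession_propagator,
    generalized_bloch_propagate,
    generalized_bloch_propagator,
    graham_pulse_propagator,
    graham_saturation_rate,
    hs1_pulse,
    lineshape_fid,
    lineshape_value,
    longitudinal_drift,
    make_mono_model,
    pulse_propagator,
    rect_pulse,
    rotate_free_pool,
)

from conftest import angular_quadrature_fid, angular_quadrature_lineshape

T2S = 12.5e-6


# ----------------------------------------------------------------------------
# lineshapes
# ----------------------------------------------------------------------------


class TestLineshapes:
    def test_lorentzian_on_resonance_closed_form(self):
        assert lineshape_value("lorentzian", 0.0, T2S) == pytest.approx(
            T2S / np.pi, rel=1e-12
        )

    @pytest.mark.parametrize("kind", ["lorentzian", "gaussian", "super_lorentzian"])
    def test_unit_normalization_over_angular_frequency(self, kind):
        # symmetric log grid resolves the super-Lorentzian's integrable
        # on-resonance peak; the Lorentzian's slow 1/w^2 tail is added
        # analytically beyond the grid edge
        half = np.geomspace(0.05, 5e6, 150001)
        f = np.concatenate([-half[::-1], [0.0], half])
        g = lineshape_value(kind, f, T2S)
        integral = np.trapezoid(g, f) * 2.0 * np.pi
        tail = 2.0 / (np.pi * 2 * np.pi * 5e6 * T2S) if kind == "lorentzian" else 0.0
        assert integral + tail == pytest.approx(1.0, abs=1e-3)

    def test_super_lorentzian_matches_angular_quadrature(self):
        got = lineshape_value("super_lorentzian", 1e4, T2S)
        want = angular_quadrature_lineshape(1e4, T2S)
        assert got == pytest.approx(want, rel=1e-6)

    def test_super_lorentzian_finite_on_resonance(self):
        assert np.isfinite(lineshape_value("super_lorentzian", 0.0, T2S))

    def test_errors(self):
        with pytest.raises(ValueError):
            lineshape_value("voigt", 0.0, T2S)
        with pytest.raises(ValueError):
            lineshape_value("lorentzian", 0.0, -1e-6)


class TestFID:
    @pytest.mark.parametrize("kind", ["lorentzian", "gaussian", "super_lorentzian"])
    def test_normalized_at_zero(self, kind):
        assert lineshape_fid(kind, 0.0, T2S) == pytest.approx(1.0, abs=1e-12)

    def test_lorentzian_exponential(self):
        assert lineshape_fid("lorentzian", T2S, T2S) == pytest.approx(np.exp(-1))

    def test_super_lorentzian_matches_angular_quadrature(self):
        got = lineshape_fid("super_lorentzian", 2 * T2S, T2S)
        want = angular_quadrature_fid(2 * T2S, T2S)
        assert got == pytest.approx(want, rel=1e-6)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            lineshape_fid("gaussian", -1e-6, T2S)

    @pytest.mark.parametrize(
        ("kind", "offsets"),
        [
            ("gaussian", (0.0, 3e3, 1e4)),
            # the super-Lorentzian's on-resonance value is a quadrature
            # convention (the true limit diverges) and its FID has a slow
            # magic-angle tail, so the pair is checked off resonance
            ("super_lorentzian", (1e4, 2e4)),
        ],
    )
    def test_fourier_pair(self, kind, offsets):
        """g(D) and G(t) are a Fourier pair: the cosine transform of G
        reproduces g on a grid."""
        t = np.linspace(0.0, 300 * T2S, 400001)
        G = lineshape_fid(kind, t, T2S)
        for f0 in offsets:
            # g(w) = (1/pi) int_0^inf G(t) cos(w t) dt
            w = 2 * np.pi * f0
            got = np.trapezoid(G * np.cos(w * t), t) / np.pi
            want = lineshape_value(kind, f0, T2S)
            assert got == pytest.approx(want, rel=1e-3, abs=1e-9)

    @pytest.mark.parametrize("kind", ["gaussian", "super_lorentzian"])
    @pytest.mark.parametrize("t_max", [10e-3, 100e-6, 10e-6])
    def test_exponential_mode_expansion_accuracy(self, kind, t_max):
        amps, rates = _kernel_modes(kind, T2S, t_max)
        t = np.concatenate([[0.0], np.geomspace(t_max * 1e-5, t_max, 2000)])
        approx = np.exp(-np.outer(t, rates)) @ amps
        exact = lineshape_fid(kind, t, T2S)
        assert np.max(np.abs(approx - exact)) < 2e-3
        assert approx[0] == pytest.approx(1.0, abs=1e-9)


# ----------------------------------------------------------------------------
# parameters / state
# ----------------------------------------------------------------------------


class TestTypes:
    def test_parameter_invariants(self):
        with pytest.raises(ValueError):
            TwoPoolParameters(m0s=1.0, t1f=1, t1s=1, t2f=0.1, t2s=1e-5, rx=10)
        with pytest.raises(ValueError):
            TwoPoolParameters(m0s=0.1, t1f=-1, t1s=1, t2f=0.1, t2s=1e-5, rx=10)
        with pytest.raises(ValueError):
            TwoPoolParameters(m0s=0.1, t1f=1, t1s=1, t2f=0.1, t2s=1e-5, rx=-1)

    def test_equilibrium(self, wm_params):
        eq = SpinState.equilibrium(wm_params)
        assert eq.zf == pytest.approx(1 - wm_params.m0s)
        assert eq.zs == pytest.approx(wm_params.m0s)
        assert eq.one == 1.0

    def test_mono_model_equilibrium_has_empty_semisolid_pool(self):
        eq = SpinState.equilibrium(make_mono_model(1.0))
        assert eq.zs == 0.0 and eq.zf == 1.0

    def test_mono_model_rejects_nonpositive_times(self):
        with pytest.raises(ValueError):
            make_mono_model(-1.0)

    def test_rf_pulse_nominal_flip(self):
        p = rect_pulse(np.pi / 2, 1e-3)
        assert p.nominal_flip == pytest.approx(np.pi / 2, rel=1e-12)
        hs = hs1_pulse()
        assert hs.duration == 10e-3
        # refining preserves the waveform integral
        assert hs.refined(4).nominal_flip == pytest.approx(
            hs.nominal_flip, rel=1e-9
        )

    def test_rf_pulse_rejects_bad_durations(self):
        with pytest.raises(ValueError):
            RFPulse(0.0, np.array([1.0, 1.0]), np.array([0.0, 0.0]))


# ----------------------------------------------------------------------------
# free precession
# ----------------------------------------------------------------------------


class TestFreePrecession:
    def test_zero_duration_is_identity(self, wm_params):
        M = free_precession_propagator(wm_params, 0.0).matrix
        assert np.array_equal(M, np.eye(5))

    def test_negative_duration_rejected(self, wm_params):
        with pytest.raises(ValueError):
            free_precession_propagator(wm_params, -0.1)

    def test_composition(self, wm_params):
        a = free_precession_propagator(wm_params, 0.123)
        b = free_precession_propagator(wm_params, 0.077)
        c = free_precession_propagator(wm_params, 0.2)
        assert np.allclose((a @ b).matrix, c.matrix, atol=1e-10)

    def test_mono_limit_recovers_to_equilibrium(self):
        p = make_mono_model(1.0)
        st = free_precession_propagator(p, 50.0).apply(SpinState(0, 0, -1, 0, 1))
        assert st.zf == pytest.approx(1.0, abs=1e-9)

    def test_recovery_rates_equal_drift_eigenvalues(self, wm_params):
        """Biexponential recovery constants match an independent
        eigen-decomposition of the 2x2 longitudinal drift matrix."""
        L, _ = longitudinal_drift(wm_params)
        ev = np.sort(np.linalg.eigvals(L))
        t = 0.25
        M = free_precession_propagator(wm_params, t).matrix
        ev_prop = np.sort(np.log(np.linalg.eigvals(M[2:4, 2:4])) / t)
        assert np.allclose(ev, ev_prop, atol=1e-10)

    def test_fast_exchange_limit(self, wm_params):
        """For large exchange rates the slow recovery constant approaches the
        population-weighted mean of the pool relaxation rates."""
        r_inf = wm_params.m0f / wm_params.t1f + wm_params.m0s / wm_params.t1s
        errs = []
        for rx in (1e3, 1e4, 1e5):
            p = dataclasses.replace(wm_params, rx=rx)
            L, _ = longitudinal_drift(p)
            slow = -np.max(np.linalg.eigvals(L))
            errs.append(abs(slow - r_inf) / r_inf)
        assert errs[0] < 5e-3
        assert errs[0] > errs[1] > errs[2]


# ----------------------------------------------------------------------------
# rotations
# ----------------------------------------------------------------------------


class TestRotation:
    def test_zero_flip_is_identity(self):
        assert np.allclose(rotate_free_pool(0.0).matrix, np.eye(5))

    def test_inversion_flips_zf_only(self):
        st = rotate_free_pool(np.pi).apply(SpinState(0, 0, 0.79, 0.21, 1))
        assert st.zf == pytest.approx(-0.79, abs=1e-12)
        assert st.zs == pytest.approx(0.21, abs=1e-15)

    def test_two_quarter_turns_equal_half_turn(self):
        q = rotate_free_pool(np.pi / 2, 0.3).matrix
        h = rotate_free_pool(np.pi, 0.3).matrix
        assert np.allclose(q @ q, h, atol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        flip=st.floats(0, 2 * np.pi),
        phase=st.floats(0, 2 * np.pi),
        zf=st.floats(-0.79, 0.79),
    )
    def test_rotation_preserves_norm_and_homogeneous_component(
        self, flip, phase, zf
    ):
        st_ = rotate_free_pool(flip, phase).apply(SpinState(0.1, -0.2, zf, 0.2, 1))
        n0 = np.linalg.norm([0.1, -0.2, zf])
        assert np.hypot(st_.transverse_magnitude, st_.zf) == pytest.approx(
            n0, abs=1e-12
        )
        assert st_.one == pytest.approx(1.0, abs=1e-12)
        assert st_.zs == 0.2


# ----------------------------------------------------------------------------
# Graham's spectral model
# ----------------------------------------------------------------------------


class TestGraham:
    def test_cw_closed_form(self):
        """Continuous-wave limit: Rrf = pi w1^2 g(0) = w1^2 T2s for a
        Lorentzian on resonance."""
        w1 = 2 * np.pi * 100
        cw = rect_pulse(w1 * 0.05, 0.05)
        rrf = graham_saturation_rate(cw, "lorentzian", T2S)
        assert rrf == pytest.approx(w1**2 * T2S, rel=1e-3)

    def test_zero_amplitude_gives_zero_rate(self):
        p = RFPulse(1e-3, np.zeros(2), np.zeros(2))
        assert graham_saturation_rate(p, "super_lorentzian", T2S) == 0.0

    def test_rate_matches_dense_psd_quadrature(self):
        """1 ms rectangular pi pulse against a brute-force continuous Fourier
        transform x lineshape quadrature."""
        pulse = rect_pulse(np.pi, 1e-3)
        got = graham_saturation_rate(pulse, "super_lorentzian", T2S)
        # oracle: |S(f)|^2 of a rect pulse is (w1 tau sinc(f tau))^2; the
        # super-Lorentzian is negligible beyond a few hundred kHz
        w1, tau = np.pi / 1e-3, 1e-3
        want = 0.0
        for lo in np.arange(-4e5, 4e5, 1e5):
            f = np.linspace(lo, lo + 1e5, 100_001)
            psd = (w1 * tau * np.sinc(f * tau)) ** 2
            g = lineshape_value("super_lorentzian", f, T2S)
            want += np.trapezoid(psd * g, f)
        want *= np.pi / tau
        assert got == pytest.approx(want, rel=1e-4)

    def test_zero_duration_pulse_rejected(self):
        with pytest.raises(ValueError):
            rect_pulse(np.pi, 0.0)

    def test_zero_amplitude_pulse_equals_free_precession(self, wm_params):
        p = RFPulse(1e-3, np.zeros(2), np.zeros(2))
        M = graham_pulse_propagator(wm_params, p).matrix
        Mf = free_precession_propagator(wm_params, 1e-3).matrix
        assert np.allclose(M, Mf, atol=1e-9)

    def test_cw_saturation_fixed_point(self, wm_params):
        """Without exchange, long CW irradiation drives zs to the scalar-ODE
        fixed point (m0s/T1s) / (1/T1s + Rrf)."""
        p = dataclasses.replace(wm_params, rx=0.0)
        cw = rect_pulse(2 * np.pi * 500 * 0.2, 0.2, frequency_offset=3e3)
        rrf = graham_saturation_rate(cw, p.lineshape, p.t2s)
        st = graham_pulse_propagator(p, cw).apply(SpinState.equilibrium(p))
        want = (p.m0s / p.t1s) / (1.0 / p.t1s + rrf)
        assert st.zs == pytest.approx(want, abs=1e-6)


# ----------------------------------------------------------------------------
# generalized Bloch
# ----------------------------------------------------------------------------


class TestGeneralizedBloch:
    def test_zero_amplitude_equals_free_precession(self, wm_params):
        p = RFPulse(1e-3, np.zeros(2), np.zeros(2))
        M = generalized_bloch_propagator(wm_params, p).matrix
        Mf = free_precession_propagator(wm_params, 1e-3).matrix
        assert np.allclose(M, Mf, atol=1e-6)

    @pytest.mark.parametrize("flip", [np.pi / 3, np.pi / 2, np.pi])
    def test_pure_rotation_limit(self, flip):
        """T2s -> inf (FID = 1), relaxation and exchange off: a hard pulse
        multiplies zs by cos(flip)."""
        p = TwoPoolParameters(
            m0s=0.21, t1f=1e6, t1s=1e6, t2f=1e6, t2s=1e3, rx=0.0,
            lineshape="super_lorentzian",
        )
        st = generalized_bloch_propagate(
            p, rect_pulse(flip, 10e-6), SpinState.equilibrium(p)
        )
        assert st.zs / p.m0s == pytest.approx(np.cos(flip), abs=1e-6)

    def test_matches_brute_force_product_integration(self, wm_params):
        """Independent oracle: explicit Heun product integration of the
        coupled Volterra system on a fine grid."""
        pulse = rect_pulse(np.pi, 10e-6)
        st = generalized_bloch_propagator(wm_params, pulse).apply(
            SpinState.equilibrium(wm_params)
        )
        bf = _brute_force_volterra(wm_params, pulse, 4000)
        assert st.zs == pytest.approx(bf[3], abs=1e-4 * wm_params.m0s)
        assert st.zf == pytest.approx(bf[2], abs=1e-4)

    def test_waveform_refinement_converged(self, wm_params):
        """Halving (and 10x-refining) the waveform segmentation changes the
        remaining zs fraction by < 1e-4."""
        eq = SpinState.equilibrium(wm_params)
        for pulse in (rect_pulse(np.pi, 10e-6), hs1_pulse()):
            z1 = generalized_bloch_propagator(wm_params, pulse).apply(eq).zs
            z2 = (
                generalized_bloch_propagator(wm_params, pulse.refined(2))
                .apply(eq)
                .zs
            )
            z10 = (
                generalized_bloch_propagator(wm_params, pulse.refined(10))
                .apply(eq)
                .zs
            )
            assert abs(z1 - z2) / wm_params.m0s < 1e-4
            assert abs(z1 - z10) / wm_params.m0s < 1e-4

    def test_all_models_agree_without_semisolid_pool(self):
        """At m0s = 0 the three RF treatments act identically on every
        physical state (zs = 0)."""
        p = make_mono_model(1.0, 76.9e-3)
        states = [
            SpinState.equilibrium(p),
            SpinState(0.3, -0.2, 0.5, 0.0, 1.0),
            SpinState(0.0, 0.0, -1.0, 0.0, 1.0),
        ]
        for pulse in (rect_pulse(np.radians(25), 100e-6), hs1_pulse()):
            for st_ in states:
                a = pulse_propagator(p, pulse, "mono").apply(st_).to_vector()
                b = graham_pulse_propagator(p, pulse).apply(st_).to_vector()
                c = generalized_bloch_propagator(p, pulse).apply(st_).to_vector()
                assert np.allclose(b, a, atol=1e-6)
                assert np.allclose(c, a, atol=1e-6)

    def test_off_resonant_agreement_with_graham(self, wm_params):
        """10 ms pulse 5 kHz off resonance: spectral and rotation treatments
        of the semi-solid pool agree within 1%."""
        pulse = rect_pulse(np.pi, 10e-3, frequency_offset=5e3)
        eq = SpinState.equilibrium(wm_params)
        zs_gb = generalized_bloch_propagator(wm_params, pulse).apply(eq).zs
        zs_gr = graham_pulse_propagator(wm_params, pulse).apply(eq).zs
        assert abs(zs_gb - zs_gr) / abs(zs_gb) < 0.01

    def test_hard_inversion_divergence_graham_oversaturates(self, wm_params):
        """10 us on-resonant pi pulse: Graham's model fully saturates the
        semi-solid pool while the rotation-based model largely inverts it."""
        pulse = rect_pulse(np.pi, 10e-6)
        eq = SpinState.equilibrium(wm_params)
        zs_gb = generalized_bloch_propagator(wm_params, pulse).apply(eq).zs
        zs_gr = graham_pulse_propagator(wm_params, pulse).apply(eq).zs
        # Graham leaves less longitudinal polarization (over-saturation) ...
        assert abs(zs_gr) < abs(zs_gb)
        assert abs(zs_gr) < 0.05 * wm_params.m0s
        # ... while the rotation-based model largely inverts the pool
        assert zs_gb < -0.5 * wm_params.m0s

    def test_propagator_keeps_homogeneous_component(self, wm_params):
        M = generalized_bloch_propagator(wm_params, hs1_pulse()).matrix
        assert np.allclose(M[4], [0, 0, 0, 0, 1], atol=1e-12)


def _brute_force_volterra(params, pulse, n_steps):
    """Heun product integration of the generalized Bloch system (test oracle,
    deliberately independent of the production solver)."""
    p = params
    h = pulse.duration / n_steps
    t = np.linspace(0.0, pulse.duration, n_steps + 1)
    amp = np.interp(t, pulse.times, pulse.amp)
    ph = np.interp(t, pulse.times, pulse.total_phase())
    w = amp * np.exp(1j * ph)
    G = lineshape_fid(p.lineshape, t, p.t2s)
    L, bvec = longitudinal_drift(p)
    state = np.array([0.0, 0.0, p.m0f, p.m0s])
    zs_hist = np.empty(n_steps + 1)
    zs_hist[0] = state[3]

    def deriv(k, s, zs_h):
        x, y, z, zs = s
        wk = w[k]
        w1 = abs(wk)
        cp = np.real(wk) / w1 if w1 else 1.0
        sp = np.imag(wk) / w1 if w1 else 0.0
        dx = -x / p.t2f - w1 * sp * z
        dy = -y / p.t2f + w1 * cp * z
        dz = w1 * sp * x - w1 * cp * y + L[0, 0] * z + L[0, 1] * zs + bvec[0]
        kern = G[: k + 1][::-1] * np.real(wk * np.conj(w[: k + 1])) * zs_h[: k + 1]
        H = h * (np.sum(kern) - 0.5 * (kern[0] + kern[-1])) if k else 0.0
        dzs = -H + L[1, 0] * z + L[1, 1] * zs + bvec[1]
        return np.array([dx, dy, dz, dzs])

    for k in range(n_steps):
        d1 = deriv(k, state, zs_hist)
        pred = state + h * d1
        zs_hist[k + 1] = pred[3]
        d2 = deriv(k + 1, pred, zs_hist)
        state = state + 0.5 * h * (d1 + d2)
        zs_hist[k + 1] = state[3]
    return state
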