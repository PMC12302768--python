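import numpy as np
import pytest
from scipy.integrate import quad
from scipy.linalg import expm
from scipy.special import erf

from nexifit.forward import (
    TissueParams,
    directional_signal,
    nexi_invariant_kernels,
    nexi_kernel,
    project_legendre,
    rice_mean,
    rotinv_signal,
    smex_kernel,
)
from nexifit.scheme import PGSEWaveform, gradient_amplitude_for_b


def narrow_pulse_waveform(b, t):
    """Rectangular-pulse waveform with delta = 0.01 ms at the requested b."""
    delta = 0.01
    g = gradient_amplitude_for_b(b, t, delta, 0.0)
    return PGSEWaveform(g=g, delta=delta, ramp=0.0, separation=t)


def piecewise_expm_kernel(waveform, eps, params, n_steps=4000):
    """Independent oracle: piecewise-constant-q^2 matrix-exponential product."""
    f, dn, de, rn = (float(np.asarray(x)) for x in (params.f, params.dn, params.de, params.rn))
    re = rn * f / (1 - f) if f < 1 else 0.0
    rates = np.array([[-rn, re], [rn, -re]])
    diff = np.diag([dn * eps * eps, de])
    tgrid = np.linspace(0.0, waveform.duration, n_steps + 1)
    mid = 0.5 * (tgrid[:-1] + tgrid[1:])
    q2 = waveform.q_of_t(mid) ** 2
    dt = tgrid[1] - tgrid[0]
    m = np.array([f, 1 - f])
    for q2i in q2:
        m = expm((rates - q2i * diff) * dt) @ m
    return m.sum()


class TestNexiKernel:
    def test_b0_normalization(self, gm_params):
        k = nexi_kernel(0.0, 0.7, 20.0, gm_params)
        assert k.k == pytest.approx(1.0, abs=1e-14)

    def test_no_exchange_biexponential(self):
        p = TissueParams(f=0.5, dn=2.0, de=1.0, rn=0.0)
        k = nexi_kernel(1.0, 1.0, 20.0, p)
        assert k.k == pytest.approx(0.5 * np.exp(-2) + 0.5 * np.exp(-1), abs=1e-10)

    def test_amplitudes_sum_to_one(self, gm_params):
        k = nexi_kernel(3.5, 0.4, 21.0, gm_params)
        assert k.f1 + k.f2 == pytest.approx(1.0, abs=1e-12)

    def test_fast_exchange_monoexponential(self):
        # tex -> 0 with b fixed: K -> exp(-b (f dn eps^2 + (1-f) de))
        f, dn, de, b, eps, t = 0.4, 2.0, 1.0, 2.0, 0.8, 20.0
        p = TissueParams(f=f, dn=dn, de=de, rn=(1 - f) * 1e5)
        k = nexi_kernel(b, eps, t, p)
        expected = np.exp(-b * (f * dn * eps**2 + (1 - f) * de))
        assert k.k == pytest.approx(expected, rel=1e-6)

    def test_degenerate_coincident_exponents(self):
        # rn = 0 with b dn eps^2 = b de must not 0/0: both compartments decay alike
        p = TissueParams(f=0.3, dn=1.0, de=1.0, rn=0.0)
        k = nexi_kernel(2.0, 1.0, 20.0, p)
        assert k.k == pytest.approx(np.exp(-2.0), rel=1e-12)

    def test_matches_ode_kernel_in_narrow_pulse_limit(self):
        p = TissueParams(f=0.35, dn=2.5, de=0.9, rn=0.05)
        wf = narrow_pulse_waveform(6.5, 21.0)
        k_analytic = nexi_kernel(6.5, 0.3, 21.0, p).k
        k_ode = smex_kernel(wf, 0.3, p).k
        assert abs(k_analytic - k_ode) / k_analytic < 1e-3

    def test_input_validation(self, gm_params):
        with pytest.raises(ValueError):
            nexi_kernel(-1.0, 0.5, 20.0, gm_params)
        with pytest.raises(ValueError):
            nexi_kernel(1.0, 1.5, 20.0, gm_params)

    def test_physical_range_random_parameters(self):
        rng = np.random.default_rng(42)
        n = 300
        f = rng.uniform(0.01, 0.99, n)
        tex = rng.uniform(1, 50, n)
        dn = rng.uniform(0.1, 3, n)
        de = rng.uniform(0.1, 3, n)
        p = TissueParams(f=f, dn=np.maximum(dn, de), de=np.minimum(dn, de), rn=(1 - f) / tex)
        for b, t in [(2.3, 13.0), (6.5, 21.0), (17.5, 30.0), (17.5, 40.0)]:
            for eps in (0.0, 0.5, 1.0):
                k = nexi_kernel(b, eps, t, p).k
                assert np.all(k >= 0) and np.all(k <= 1 + 1e-12)

    def test_spherical_mean_decreases_with_diffusion_time(self, gm_params):
        # exchange signature: K0(t) strictly decreasing at fixed b when rn > 0
        times = np.array([13.0, 21.0, 30.0, 40.0])
        for b in (2.3, 6.5, 17.5):
            k0 = nexi_invariant_kernels(b, times, gm_params)[0]
            assert np.all(np.diff(k0) < 0)
        frozen = TissueParams(f=0.35, dn=2.5, de=0.9, rn=0.0)
        k0 = nexi_invariant_kernels(6.5, times, frozen)[0]
        assert np.ptp(k0) < 1e-12


class TestSmexKernel:
    def test_zero_gradient(self, gm_params):
        wf = PGSEWaveform(g=0.0, delta=6.0, ramp=0.83, separation=21.0)
        assert smex_kernel(wf, 0.5, gm_params).k == pytest.approx(1.0, abs=1e-9)

    def test_no_exchange_gaussian_compartments(self):
        # rn = 0: each compartment is Gaussian under any waveform, so the
        # finite-pulse kernel is exactly the bi-exponential at the waveform's b
        p = TissueParams(f=0.4, dn=2.0, de=1.0, rn=0.0)
        g = gradient_amplitude_for_b(3.0, 21.0, 6.0, 0.83)
        wf = PGSEWaveform(g=g, delta=6.0, ramp=0.83, separation=21.0)
        b = wf.b_value()
        for eps in (0.0, 0.5, 1.0):
            expected = 0.4 * np.exp(-b * 2.0 * eps**2) + 0.6 * np.exp(-b * 1.0)
            assert smex_kernel(wf, eps, p).k == pytest.approx(expected, rel=1e-7)

    def test_against_piecewise_expm_oracle(self, gm_params):
        g = gradient_amplitude_for_b(6.5, 21.0, 6.0, 0.83)
        wf = PGSEWaveform(g=g, delta=6.0, ramp=0.83, separation=21.0)
        for eps in (0.25, 0.75):
            oracle = piecewise_expm_kernel(wf, eps, gm_params)
            k = smex_kernel(wf, eps, gm_params).k
            assert abs(k - oracle) < 1e-5

    def test_step_halving_consistency(self, gm_params):
        g = gradient_amplitude_for_b(11.5, 30.0, 6.0, 0.83)
        wf = PGSEWaveform(g=g, delta=6.0, ramp=0.83, separation=30.0)
        k1 = smex_kernel(wf, 0.6, gm_params, rtol=1e-9).k
        k2 = smex_kernel(wf, 0.6, gm_params, rtol=1e-11).k
        assert abs(k1 - k2) < 1e-6


class TestLegendreProjection:
    def test_constant_kernel(self):
        kl = project_legendre(lambda e: np.full_like(e, 0.7), lmax=2)
        assert kl[0] == pytest.approx(0.7, abs=1e-12)
        assert kl[2] == pytest.approx(0.0, abs=1e-12)

    def test_polynomial_kernel(self):
        kl = project_legendre(lambda e: e**2, lmax=2)
        assert kl[0] == pytest.approx(1.0 / 3.0, abs=1e-10)
        assert kl[2] == pytest.approx(2.0 / 15.0, abs=1e-10)

    def test_stick_spherical_mean(self):
        # f = 1, rn = 0: K0 = sqrt(pi/(4 b dn)) erf(sqrt(b dn))
        b, dn = 4.8, 2.2
        p = TissueParams(f=1.0, dn=dn, de=1.0, rn=0.0)
        kl = project_legendre(lambda e: nexi_kernel(b, e, 20.0, p).k, lmax=0)
        expected = np.sqrt(np.pi / (4 * b * dn)) * erf(np.sqrt(b * dn))
        assert kl[0] == pytest.approx(expected, abs=1e-8)

    def test_odd_lmax_rejected(self):
        with pytest.raises(ValueError):
            project_legendre(lambda e: e, lmax=3)


class TestRotinvAndDirectional:
    def test_rotinv_products(self):
        p = TissueParams(f=0.5, dn=2.0, de=1.0, rn=0.1, p2=0.3)
        sl = rotinv_signal({0: 0.5, 2: 0.2}, p)
        assert sl[0] == pytest.approx(0.5)
        assert sl[2] == pytest.approx(0.06)
        iso = TissueParams(f=0.5, dn=2.0, de=1.0, rn=0.1, p2=0.0)
        assert rotinv_signal({2: 0.2}, iso)[2] == pytest.approx(0.0)

    def test_isotropic_signal_constant(self, mini_scheme):
        p = TissueParams(f=0.35, dn=2.5, de=0.9, rn=0.04, p2=0.0)
        s = directional_signal(mini_scheme, p, axis=[0, 0, 1])
        for b, t in mini_scheme.shells():
            idx = mini_scheme.shell_indices(b, t)
            assert np.ptp(s[idx]) < 1e-14
            k0 = nexi_invariant_kernels(b, t, p)[0]
            assert s[idx][0] == pytest.approx(float(k0), abs=1e-12)

    def test_b0_volumes_unity(self, mini_scheme, gm_params):
        s = directional_signal(mini_scheme, gm_params, axis=[1, 0, 0])
        assert np.all(s[mini_scheme.is_b0] == 1.0)


class TestRiceMean:
    def test_rayleigh_point(self):
        assert rice_mean(0.0, 1.0) == pytest.approx(np.sqrt(np.pi / 2), abs=1e-12)
        assert rice_mean(0.0, 0.02) == pytest.approx(0.02 * np.sqrt(np.pi / 2), abs=1e-14)

    def test_noiseless_limit(self):
        assert rice_mean(5.0, 0.0) == 5.0

    @pytest.mark.parametrize("ratio", [0.0, 0.3, 1.0, 3.0, 10.0, 29.0, 40.0, 100.0])
    def test_against_quadrature_oracle(self, ratio):
        sigma = 0.7
        nu = ratio * sigma
        # direct density integration (i0e-stabilized Rice pdf)
        from scipy.special import ive

        def density(x):
            z = x * nu / sigma**2
            return x / sigma**2 * np.exp(-((x - nu) ** 2) / (2 * sigma**2)) * ive(0, z)

        oracle, _ = quad(lambda x: x * density(x), 0, nu + 15 * sigma, limit=200)
        assert rice_mean(nu, sigma) == pytest.approx(oracle, abs=1e-8 * max(1.0, nu))

    def test_lower_bound_and_asymptote(self):
        rng = np.random.default_rng(1)
        nu = rng.uniform(0, 5, 50)
        sigma = rng.uniform(0.01, 1, 50)
        e = rice_mean(nu, sigma)
        assert np.all(e >= np.maximum(nu, sigma * np.sqrt(np.pi / 2)) - 1e-12)
        big = rice_mean(50.0, 1.0)
        assert big == pytest.approx(np.sqrt(50.0**2 + 1.0), rel=1e-3)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            rice_mean(-1.0, 1.0)
        with pytest.raises(ValueError):
            rice_mean(1.0, -1.0)
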