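import numpy as np
import pytest

from nexifit.estimation import (
    FitOptions,
    dictionary_init,
    fit_adam,
    fit_nlls,
    fit_roi,
    nexi_model,
    tv_penalty,
    _tv_grad,
)
from nexifit.invariants import RotInvSignal

B_SHELLS = np.array([2.3, 3.5, 4.8, 6.5] * 3 + [11.5, 11.5, 17.5])
T_SHELLS = np.array([13.0] * 4 + [21.0] * 4 + [30.0] * 4 + [21.0, 30.0, 30.0])


def make_rotinv(theta, options, sigma=None):
    s = nexi_model(theta, B_SHELLS, T_SHELLS, options)
    sl = {0: s[:, :, 0]}
    if options.lmax == 2:
        sl[2] = s[:, :, 1]
    return RotInvSignal(sl=sl, shells=list(zip(B_SHELLS, T_SHELLS)), sigma=sigma)


def random_truths(n, seed, with_p2=False):
    rng = np.random.default_rng(seed)
    f = rng.uniform(0.1, 0.9, n)
    tex = rng.uniform(5, 40, n)
    dn = rng.uniform(1.6, 2.9, n)
    de = rng.uniform(0.6, 1.4, n)
    cols = [f, dn, de, (1 - f) / tex]
    if with_p2:
        cols.append(rng.uniform(0.05, 0.45, n))
    return np.column_stack(cols)


class TestModelGradients:
    @pytest.mark.parametrize("lmax", [0, 2])
    def test_analytic_gradient_matches_finite_differences(self, lmax):
        options = FitOptions(lmax=lmax)
        theta = random_truths(6, seed=3, with_p2=lmax == 2)
        s, g = nexi_model(theta, B_SHELLS, T_SHELLS, options, with_grad=True)
        h = 1e-6
        for i in range(theta.shape[1]):
            tp, tm = theta.copy(), theta.copy()
            tp[:, i] += h
            tm[:, i] -= h
            fd = (
                nexi_model(tp, B_SHELLS, T_SHELLS, options)
                - nexi_model(tm, B_SHELLS, T_SHELLS, options)
            ) / (2 * h)
            assert np.max(np.abs(fd - g[:, i])) < 1e-7

    def test_rician_mean_model_floor(self):
        # with noise the model spherical mean can never drop below the
        # Rayleigh floor, unlike the noiseless model
        options = FitOptions(lmax=0, rician_mean=True)
        theta = np.array([[0.3, 2.5, 0.9, 0.02]])
        sigma = 0.05
        s_rm = nexi_model(theta, B_SHELLS, T_SHELLS, options, sigma=sigma)
        s_plain = nexi_model(theta, B_SHELLS, T_SHELLS, FitOptions(lmax=0))
        assert np.all(s_rm >= s_plain)
        assert np.all(s_rm[..., 0] >= sigma * np.sqrt(np.pi / 2) - 1e-12)


class TestDictionary:
    def test_self_match(self):
        options = FitOptions(lmax=0, dict_size=2000, seed=9)
        rng = np.random.default_rng(options.seed)
        names = options.param_names
        draws = np.stack(
            [rng.uniform(*options.dict_ranges[nm], size=options.dict_size) for nm in names],
            axis=1,
        )
        pick = draws[[17, 393, 1500]]
        meas = nexi_model(pick, B_SHELLS, T_SHELLS, options)
        theta, flagged = dictionary_init(meas, B_SHELLS, T_SHELLS, options)
        assert np.allclose(theta, pick)
        assert not flagged.any()

    def test_matches_brute_force_argmax(self):
        options = FitOptions(lmax=0, dict_size=500, seed=5)
        truths = random_truths(4, seed=21)
        meas = nexi_model(truths, B_SHELLS, T_SHELLS, options)
        theta, _ = dictionary_init(meas, B_SHELLS, T_SHELLS, options)
        # independent exhaustive scan
        rng = np.random.default_rng(options.seed)
        names = options.param_names
        draws = np.stack(
            [rng.uniform(*options.dict_ranges[nm], size=options.dict_size) for nm in names],
            axis=1,
        )
        atlas = nexi_model(draws, B_SHELLS, T_SHELLS, options)[:, :, 0]
        for v in range(truths.shape[0]):
            m = meas[v, :, 0]
            best, best_corr = -1, -np.inf
            for j in range(options.dict_size):
                a = atlas[j]
                corr = float(m @ a / (np.linalg.norm(m) * np.linalg.norm(a)))
                if corr > best_corr:
                    best, best_corr = j, corr
            assert np.allclose(theta[v], draws[best])

    def test_zero_vector_flagged_midpoint(self):
        options = FitOptions(lmax=0, dict_size=100, seed=1)
        meas = np.zeros((1, B_SHELLS.size, 1))
        theta, flagged = dictionary_init(meas, B_SHELLS, T_SHELLS, options)
        assert flagged[0]
        mid = [np.mean(options.dict_ranges[nm]) for nm in options.param_names]
        assert np.allclose(theta[0], mid)

    def test_deterministic(self):
        options = FitOptions(lmax=0, dict_size=300, seed=4)
        meas = nexi_model(random_truths(3, seed=2), B_SHELLS, T_SHELLS, options)
        a, _ = dictionary_init(meas, B_SHELLS, T_SHELLS, options)
        b, _ = dictionary_init(meas, B_SHELLS, T_SHELLS, options)
        assert np.array_equal(a, b)


class TestNLLS:
    def test_fixed_point_at_truth(self):
        options = FitOptions(lmax=2)
        theta = random_truths(3, seed=8, with_p2=True)
        ri = make_rotinv(theta, options)
        res = fit_nlls(ri, options, init=theta)
        est = np.column_stack([res.params[nm] for nm in options.param_names])
        assert np.max(np.abs(est - theta)) < 1e-6
        assert np.all(np.asarray(res.loss) < 1e-12)

    def test_noiseless_recovery_with_dictionary_init(self):
        options = FitOptions(lmax=0, seed=2)
        theta = random_truths(40, seed=13)
        ri = make_rotinv(theta, options)
        res = fit_nlls(ri, options)
        tex_true = (1 - theta[:, 0]) / theta[:, 3]
        assert np.median(np.abs(res.tex - tex_true) / tex_true) < 0.01

    def test_bounds_respected_on_pure_noise(self):
        options = FitOptions(lmax=0, seed=6)
        rng = np.random.default_rng(0)
        sl0 = np.abs(rng.normal(0, 0.05, size=(20, B_SHELLS.size)))
        ri = RotInvSignal(sl={0: sl0}, shells=list(zip(B_SHELLS, T_SHELLS)))
        res = fit_nlls(ri, options)
        for nm in options.param_names:
            lo, hi = options.bounds[nm]
            assert np.all(res.params[nm] >= lo - 1e-12)
            assert np.all(res.params[nm] <= hi + 1e-12)

    def test_rician_mean_requires_sigma(self):
        options = FitOptions(lmax=0, rician_mean=True)
        ri = make_rotinv(random_truths(2, seed=1), FitOptions(lmax=0))
        with pytest.raises(ValueError, match="sigma"):
            fit_nlls(ri, options)


class TestAdam:
    def test_fixed_point_at_truth(self):
        options = FitOptions(lmax=0, solver="adam")
        theta = random_truths(1, seed=18)
        ri = make_rotinv(theta, options)
        res = fit_adam(ri, options=options, init=theta)
        est = np.column_stack([res.params[nm] for nm in options.param_names])
        assert np.max(np.abs(est - theta)) < 1e-9
        assert res.loss < 1e-10

    def test_agrees_with_nlls_noiseless(self):
        options = FitOptions(lmax=0, seed=5)
        theta = random_truths(30, seed=31)
        ri = make_rotinv(theta, options)
        res_n = fit_nlls(ri, options)
        res_a = fit_adam(ri, options=FitOptions(lmax=0, solver="adam", seed=5))
        for nm in options.param_names:
            lo, hi = options.bounds[nm]
            scale = hi - lo
            agree = np.abs(res_a.params[nm] - res_n.params[nm]) / scale
            assert np.median(agree) < 0.01

    def test_seeded_determinism(self):
        options = FitOptions(lmax=0, solver="adam", seed=12, max_iter=200)
        theta = random_truths(10, seed=44)
        ri = make_rotinv(theta, options)
        noisy = {0: ri.s(0) + np.random.default_rng(3).normal(0, 0.02, ri.s(0).shape)}
        ri_noisy = RotInvSignal(sl=noisy, shells=ri.shells)
        r1 = fit_adam(ri_noisy, options=options)
        r2 = fit_adam(ri_noisy, options=options)
        for nm in options.param_names:
            assert np.array_equal(r1.params[nm], r2.params[nm])

    def test_bounds_respected_on_pure_noise(self):
        options = FitOptions(lmax=0, solver="adam", seed=6, max_iter=300)
        rng = np.random.default_rng(0)
        sl0 = np.abs(rng.normal(0, 0.05, size=(20, B_SHELLS.size)))
        ri = RotInvSignal(sl={0: sl0}, shells=list(zip(B_SHELLS, T_SHELLS)))
        res = fit_adam(ri, options=options)
        for nm in options.param_names:
            lo, hi = options.bounds[nm]
            assert np.all(res.params[nm] >= lo) and np.all(res.params[nm] <= hi)

    def test_empty_mask_rejected(self):
        options = FitOptions(lmax=0, solver="adam")
        ri = make_rotinv(random_truths(4, seed=1), options)
        with pytest.raises(ValueError, match="empty mask"):
            fit_adam(ri, mask=np.zeros(4, dtype=bool), options=options)


class TestTV:
    def test_constant_map(self):
        assert tv_penalty(np.full((8, 8), 0.3)) == 0.0

    def test_single_edge(self):
        assert tv_penalty(np.array([[0.0], [0.25]])) == pytest.approx(0.25)

    def test_checkerboard_edge_count(self):
        yy, xx = np.mgrid[0:8, 0:8]
        board = ((yy + xx) % 2).astype(float)
        # 2 * (8 rows/cols * 7 edges) unit jumps
        assert tv_penalty(board) == pytest.approx(112.0)

    def test_voxel_size_scaling(self):
        m = np.array([[0.0, 1.0]])
        assert tv_penalty(m, voxel_size=(1.0, 2.0)) == pytest.approx(0.5)

    def test_mask_excludes_edges(self):
        m = np.array([[0.0, 1.0, 0.0]])
        mask = np.array([[True, True, False]])
        assert tv_penalty(m, mask) == pytest.approx(1.0)

    def test_subgradient_matches_finite_differences(self):
        rng = np.random.default_rng(9)
        f = rng.uniform(0, 1, size=(6, 5))
        mask = rng.uniform(size=(6, 5)) > 0.2
        g = _tv_grad(f, mask, (1.0, 1.3))
        h = 1e-7
        for idx in [(0, 0), (2, 3), (5, 4), (3, 1)]:
            fp, fm = f.copy(), f.copy()
            fp[idx] += h
            fm[idx] -= h
            fd = (tv_penalty(fp, mask, (1.0, 1.3)) - tv_penalty(fm, mask, (1.0, 1.3))) / (2 * h)
            assert g[idx] == pytest.approx(fd, abs=1e-6)


class TestRoiFitting:
    def _table(self, theta, options):
        import pandas as pd

        s = nexi_model(theta, B_SHELLS, T_SHELLS, options)
        rows = []
        for r in range(theta.shape[0]):
            for i, (b, t) in enumerate(zip(B_SHELLS, T_SHELLS)):
                for li, l in enumerate(options.orders):
                    rows.append({"roi": f"roi{r}", "b": b, "t": t, "l": l, "value": s[r, i, li]})
        return pd.DataFrame(rows)

    def test_single_roi_recovers_truth(self):
        options = FitOptions(lmax=0, seed=3)
        theta = np.array([[0.32, 2.6, 0.85, 0.03]])
        res = fit_roi(self._table(theta, options), options)
        assert res.loc[0, "tex"] == pytest.approx((1 - 0.32) / 0.03, rel=1e-3)

    def test_six_rois_tex_identity(self):
        options = FitOptions(lmax=0, seed=3)
        theta = random_truths(6, seed=77)
        res = fit_roi(self._table(theta, options), options)
        assert len(res) == 6
        assert np.allclose(
            res["tex"], (1 - res["f"]) / np.maximum(res["rn"], 1e-6), rtol=1e-10
        )

    def test_missing_shell_errors(self):
        options = FitOptions(lmax=0)
        table = self._table(np.array([[0.3, 2.5, 0.9, 0.05], [0.4, 2.2, 1.1, 0.02]]), options)
        broken = table.iloc[:-1]  # second ROI loses its last shell
        with pytest.raises(ValueError, match="missing shell"):
            fit_roi(broken, options)
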