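import numpy as np
import pytest

from bayesr.model import (ConvergenceWarning, DropSchedule, MixtureSpec,
                          ModelData, ModelState, compute_pip, drop_variants,
                          run_em, run_mcmc, variance_components)


def make_data(y, W, X=None, weights=None, chrom=None, pos=None):
    """ModelData from an (n x m) variant matrix (columns become rows of Wt)."""
    W = np.asarray(W, dtype=np.float64)
    n, m = W.shape
    y = np.asarray(y, dtype=np.float64)
    X = np.ones((n, 1)) if X is None else X
    return ModelData(
        y=y, X=X, Wt=np.ascontiguousarray(W.T),
        weights=np.ones(n) if weights is None else weights,
        chrom=np.ones(m, dtype=np.int64) if chrom is None else chrom,
        pos=np.arange(1, m + 1) if pos is None else pos,
        variant_id=np.array([f"v{j}" for j in range(m)], dtype=object),
        centers=np.zeros(m))


def random_instance(n, m, seed, signal=0.0):
    rng = np.random.default_rng(seed)
    W = rng.integers(0, 3, size=(n, m)).astype(float)
    W -= W.mean(axis=0)
    y = rng.normal(size=n)
    if signal:
        beta = rng.normal(0, signal, size=m)
        y = W @ beta + rng.normal(size=n)
    return make_data(y, W)


class TestRunEm:
    def test_null_signal_shrinks(self):
        rng = np.random.default_rng(0)
        n, m = 300, 60
        W = rng.integers(0, 3, size=(n, m)).astype(float)
        W -= W.mean(axis=0)
        y = rng.normal(size=n)
        data = make_data(y, W)
        # wide classes make the null discrimination sharp
        spec = MixtureSpec(gamma=(0.0, 0.05, 0.2, 0.5), sigma_g2=float(y.var()))
        state = run_em(data, spec, max_iter=200, tol=1e-10)
        assert np.abs(state.v).max() < 0.05
        assert np.argmax(state.P) == 0
        assert state.P[0] > 0.5

    def test_scalar_ridge_oracle(self):
        # single variant with a strong effect; at the EM fixed point the
        # posterior-mean update must match the conjugate ridge closed form
        rng = np.random.default_rng(1)
        n = 200
        w = rng.integers(0, 3, size=n).astype(float)
        w -= w.mean()
        y = 0.8 * w + rng.normal(0, 0.3, size=n)
        data = make_data(y, w[:, None])
        spec = MixtureSpec(gamma=(0.0, 0.5, 0.7, 1.0), sigma_g2=1.0)
        state = run_em(data, spec, max_iter=500, tol=1e-13)
        resp = state.em_responsibility[0]
        assert resp[1:].sum() > 0.999  # slab certain for a strong signal
        tau_mix = 1.0 / np.sum(resp[1:] / (np.array(spec.gamma[1:]) * spec.sigma_g2))
        resid = y - data.X @ state.b
        oracle = (w @ resid) / (w @ w + state.sigma_e2 / tau_mix)
        # responsibility-weighted mean over the slab classes
        num = w @ resid
        oracle = 0.0
        for k, g in enumerate(spec.gamma):
            if g > 0:
                oracle += resp[k] * num / (w @ w + state.sigma_e2 / (g * spec.sigma_g2))
        assert abs(state.v[0] - oracle) < 1e-6

    def test_objective_monotone_on_random_instances(self):
        import warnings
        for seed in range(20):
            data = random_instance(60, 25, seed, signal=0.1)
            spec = MixtureSpec(sigma_g2=float(data.y.var()))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                state = run_em(data, spec, max_iter=40, tol=1e-12)
            obj = state.objective_trace
            assert (np.diff(obj) >= -1e-8 * np.maximum(1.0, np.abs(obj[:-1]))).all()

    def test_singular_design_rejected(self):
        rng = np.random.default_rng(2)
        W = rng.integers(0, 3, size=(30, 5)).astype(float)
        X = np.column_stack([np.ones(30), np.ones(30)])
        with pytest.raises(ValueError):
            make_data(rng.normal(size=30), W, X=X)

    def test_nonconvergence_warns(self):
        data = random_instance(50, 20, 0, signal=0.3)
        spec = MixtureSpec(sigma_g2=float(data.y.var()))
        with pytest.warns(ConvergenceWarning):
            run_em(data, spec, max_iter=2, tol=1e-15)


class TestComputePip:
    def test_always_slab(self):
        trace = np.full((20, 3), 3, dtype=np.int8)
        assert (compute_pip(class_trace=trace) == 1.0).all()

    def test_never_leaves_spike(self):
        trace = np.zeros((20, 3), dtype=np.int8)
        assert (compute_pip(class_trace=trace) == 0.0).all()

    def test_counting_oracle_10_iterations(self):
        rng = np.random.default_rng(3)
        trace = rng.integers(0, 4, size=(10, 7)).astype(np.int8)
        pip = compute_pip(class_trace=trace)
        for i in range(7):
            assert pip[i] == sum(1 for t in range(10) if trace[t, i] != 0) / 10.0

    def test_em_responsibilities(self):
        resp = np.array([[0.7, 0.1, 0.1, 0.1], [1.0, 0.0, 0.0, 0.0]])
        np.testing.assert_allclose(compute_pip(responsibilities=resp), [0.3, 0.0])

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            compute_pip(class_trace=np.zeros((0, 3)))
        with pytest.raises(ValueError):
            compute_pip()


def null_state(m, P=None):
    return ModelState(
        b=np.zeros(1), a=np.zeros(0), v=np.zeros(m),
        cls=np.zeros(m, dtype=np.int64),
        P=np.full(4, 0.25) if P is None else np.asarray(P),
        sigma_e2=1.0, sigma_a2=0.0, active=np.ones(m, dtype=bool))


class TestDropVariants:
    def test_d_zero_noop(self):
        state = null_state(10)
        spec = MixtureSpec()
        out_state, out_spec, dropped = drop_variants(state, spec,
                                                     np.linspace(0, 1, 10), 0.0)
        assert dropped.size == 0
        assert out_state is state and out_spec is spec

    def test_d09_keeps_exactly_10_percent(self):
        state = null_state(1000)
        pip = np.random.default_rng(0).random(1000)
        out_state, _, dropped = drop_variants(state, MixtureSpec(), pip, 0.9)
        assert dropped.size == 900
        assert out_state.active.sum() == 100

    def test_rank_threshold_oracle(self):
        # the retained set must be exactly the highest-PIP half
        rng = np.random.default_rng(1)
        pip = rng.random(40)
        state = null_state(40)
        out_state, _, dropped = drop_variants(state, MixtureSpec(), pip, 0.5)
        expected_dropped = set(np.argsort(pip, kind="stable")[:20])
        assert set(dropped) == expected_dropped
        assert (out_state.v[dropped] == 0).all()

    def test_tie_break_by_index(self):
        state = null_state(4)
        pip = np.array([0.5, 0.2, 0.2, 0.9])
        _, _, dropped = drop_variants(state, MixtureSpec(), pip, 0.5)
        assert list(dropped) == [1, 2]

    def test_prior_compensation_pseudo_counts(self):
        state = null_state(100, P=[0.4, 0.3, 0.2, 0.1])
        _, spec2, dropped = drop_variants(state, MixtureSpec(), np.arange(100) / 100,
                                          0.5)
        expected = np.ones(4) + 50 * np.array([0.4, 0.3, 0.2, 0.1])
        np.testing.assert_allclose(spec2.alpha, expected)

    def test_prior_compensation_literal(self):
        state = null_state(100, P=[0.4, 0.3, 0.2, 0.1])
        _, spec2, _ = drop_variants(state, MixtureSpec(), np.arange(100) / 100,
                                    0.5, compensation="literal")
        np.testing.assert_allclose(spec2.alpha,
                                   np.ones(4) + np.array([0.4, 0.3, 0.2, 0.1]))

    def test_invalid_d(self):
        with pytest.raises(ValueError):
            drop_variants(null_state(5), MixtureSpec(), np.zeros(5), 1.0)


class TestRunMcmc:
    def test_zero_iterations_returns_state(self):
        data = random_instance(40, 8, 0)
        spec = MixtureSpec(sigma_g2=1.0)
        state = null_state(8)
        summary = run_mcmc(state, data, spec, 0, seed=1)
        np.testing.assert_array_equal(summary.v_mean, state.v)
        assert (summary.pip == 0).all()

    def test_scalar_conjugate_oracle(self):
        # one variant, P degenerate at the largest class, strong signal:
        # posterior mean of v within 3 MC SEs of the conjugate closed form
        rng = np.random.default_rng(4)
        n = 300
        w = rng.integers(0, 3, size=n).astype(float)
        w -= w.mean()
        tau4 = 0.5
        y = 1.0 * w + rng.normal(0, 0.5, size=n)
        data = make_data(y, w[:, None])
        spec = MixtureSpec(gamma=(0.0, 1e-8, 1e-8, 0.5), sigma_g2=1.0,
                           alpha=(1e-4, 1e-4, 1e-4, 1e6))
        state = run_em(data, spec, max_iter=100, tol=1e-10)
        n_iter = 4000
        summary = run_mcmc(state, data, spec, n_iter, seed=9)
        sigma_e2 = summary.sigma_e2_mean
        resid = y - data.X @ summary.b_mean
        V = 1.0 / (w @ w / sigma_e2 + 1.0 / tau4)
        oracle = V * (w @ resid) / sigma_e2
        mc_se = np.sqrt(V / (n_iter / 5))  # conservative ESS
        assert abs(summary.v_mean[0] - oracle) < 3 * mc_se
        assert summary.pip[0] == 1.0

    def test_null_run_matches_prior_occupancy(self):
        # gamma so tiny every class is likelihood-indistinguishable: the
        # occupancy of each class must hover near the Dirichlet mean m/4
        rng = np.random.default_rng(5)
        n, m = 100, 40
        W = rng.integers(0, 3, size=(n, m)).astype(float)
        W -= W.mean(axis=0)
        y = rng.normal(size=n)
        data = make_data(y, W)
        spec = MixtureSpec(gamma=(0.0, 1e-12, 2e-12, 3e-12), sigma_g2=1.0)
        state = null_state(m)
        state.sigma_e2 = float(y.var())
        summary = run_mcmc(state, data, spec, 3000, seed=11)
        for k in range(4):
            assert abs(summary.occupancy[k] - m / 4) < 0.3 * m

    def test_simplex_preserved(self):
        data = random_instance(50, 10, 1, signal=0.2)
        spec = MixtureSpec(sigma_g2=float(data.y.var()))
        state = run_em(data, spec, max_iter=30, tol=1e-8)
        summary = run_mcmc(state, data, spec, 200, seed=2)
        np.testing.assert_allclose(summary.trace["P"].sum(axis=1), 1.0, atol=1e-12)

    def test_d0_bit_identical_to_no_drop(self):
        data = random_instance(60, 15, 2, signal=0.2)
        spec = MixtureSpec(sigma_g2=float(data.y.var()))
        state = run_em(data, spec, max_iter=20, tol=1e-8)
        s1 = run_mcmc(state, data, spec, 150, seed=3)
        s2 = run_mcmc(state, data, spec, 150,
                      schedule=DropSchedule(proportion=0.0, drop_point=50), seed=3)
        np.testing.assert_array_equal(s1.v_mean, s2.v_mean)
        np.testing.assert_array_equal(s1.pip, s2.pip)
        assert s1.sigma_e2_mean == s2.sigma_e2_mean

    def test_drop_at_iteration_deactivates(self):
        data = random_instance(60, 20, 3, signal=0.2)
        spec = MixtureSpec(sigma_g2=float(data.y.var()))
        state = run_em(data, spec, max_iter=20, tol=1e-8)
        summary = run_mcmc(state, data, spec, 200,
                           schedule=DropSchedule(proportion=0.5, drop_point=100),
                           seed=4)
        assert summary.active.sum() == 10
        assert (summary.drop_iter[~summary.active] == 100).all()
        assert (summary.drop_iter[summary.active] == -1).all()

    def test_drop_after_em_uses_responsibilities(self):
        data = random_instance(60, 20, 4, signal=0.3)
        spec = MixtureSpec(sigma_g2=float(data.y.var()))
        state = run_em(data, spec, max_iter=30, tol=1e-8)
        summary = run_mcmc(state, data, spec, 100,
                           schedule=DropSchedule(proportion=0.5, drop_point="em"),
                           seed=5)
        assert summary.active.sum() == 10
        assert (summary.drop_iter[~summary.active] == 0).all()

    def test_planted_qtl_survive_half_drop(self):
        # 10 strong planted QTL vs 90 noise variants; d = 0.5 keeps all QTL
        rng = np.random.default_rng(6)
        n, m = 400, 100
        W = rng.integers(0, 3, size=(n, m)).astype(float)
        W -= W.mean(axis=0)
        planted = np.arange(10)
        beta = np.zeros(m)
        beta[planted] = rng.choice([-1.0, 1.0], size=10) * 0.8
        y = W @ beta + rng.normal(0, 1.0, size=n)
        data = make_data(y, W)
        spec = MixtureSpec(sigma_g2=float(y.var()))
        state = run_em(data, spec, max_iter=50, tol=1e-8)
        summary = run_mcmc(state, data, spec, 600,
                           schedule=DropSchedule(proportion=0.5, drop_point=300),
                           seed=7, store_class_trace=True)
        pip_at_drop = (summary.trace["class"][:300] != 0).mean(axis=0)
        assert (pip_at_drop[planted] > 0.9).all()
        assert summary.active[planted].all()

    def test_occupancy_conserved_across_drop(self):
        # expected slab occupancy (active + prior-absorbed) is conserved
        rng = np.random.default_rng(8)
        n, m = 200, 60
        W = rng.integers(0, 3, size=(n, m)).astype(float)
        W -= W.mean(axis=0)
        beta = np.zeros(m)
        beta[:6] = 0.6
        y = W @ beta + rng.normal(size=n)
        data = make_data(y, W)
        spec = MixtureSpec(sigma_g2=float(y.var()))
        state = run_em(data, spec, max_iter=40, tol=1e-8)
        summary = run_mcmc(state, data, spec, 1200,
                           schedule=DropSchedule(proportion=0.7, drop_point=600),
                           seed=9, store_class_trace=True)
        trace = summary.trace["class"]
        pre_slab = (trace[:600] != 0).sum(axis=1).mean()
        n_dropped = int((~summary.active).sum())
        P_bar = summary.trace["P"][599]  # proportions at the drop point
        post_active_slab = (trace[600:] != 0).sum(axis=1).mean()
        post_total = post_active_slab + n_dropped * (1 - P_bar[0])
        assert abs(post_total - pre_slab) < 0.35 * max(pre_slab, 1.0)

    def test_relabeling_exchangeability(self):
        # permuting variants (carrying chrom/pos along) permutes v and PIP
        data = random_instance(50, 12, 10, signal=0.3)
        spec = MixtureSpec(sigma_g2=float(data.y.var()))
        perm = np.random.default_rng(0).permutation(12)
        data_p = ModelData(
            y=data.y, X=data.X, Wt=np.ascontiguousarray(data.Wt[perm]),
            weights=data.weights, chrom=data.chrom[perm], pos=data.pos[perm],
            variant_id=data.variant_id[perm], centers=data.centers[perm])
        st1 = run_em(data, spec, max_iter=25, tol=1e-8)
        st2 = run_em(data_p, spec, max_iter=25, tol=1e-8)
        np.testing.assert_allclose(st2.v, st1.v[perm], atol=1e-12)
        s1 = run_mcmc(st1, data, spec, 100, seed=3)
        s2 = run_mcmc(st2, data_p, spec, 100, seed=3)
        # equal up to float summation order in the dot products
        np.testing.assert_allclose(s2.v_mean, s1.v_mean[perm], atol=1e-10)
        np.testing.assert_array_equal(s2.pip, s1.pip[perm])

    def test_drop_point_beyond_n_iter_rejected(self):
        data = random_instance(30, 5, 0)
        state = null_state(5)
        with pytest.raises(ValueError):
            run_mcmc(state, data, MixtureSpec(), 10,
                     schedule=DropSchedule(proportion=0.5, drop_point=20), seed=1)


class TestVarianceComponents:
    def test_zero_effects_gives_zero(self):
        data = random_instance(40, 6, 0)
        state = null_state(6)
        summary = run_mcmc(state, data, MixtureSpec(sigma_g2=1e-30), 0, seed=1)
        vc = variance_components(summary, data)
        assert vc.h_M2 == 0.0 and vc.h_A2 == 0.0 and vc.h2 == 0.0

    def test_h2_identity(self):
        data = random_instance(80, 15, 1, signal=0.3)
        spec = MixtureSpec(sigma_g2=float(data.y.var()))
        state = run_em(data, spec, max_iter=20, tol=1e-8)
        summary = run_mcmc(state, data, spec, 100, seed=2)
        vc = variance_components(summary, data)
        assert vc.h2 == vc.h_M2 + vc.h_A2
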