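import numpy as np
import pandas as pd
import pytest

from jointmeta import _lmm
from jointmeta._surv import RiskSets
from jointmeta.data import MetaJointDataset, validate
from jointmeta.design import build_design
from jointmeta.em import (
    EMControl,
    JointParams,
    _baseline_rows,
    _cheb_coefs,
    build_grid,
    build_hazard_geometry,
    estep,
    fit_joint,
)
from jointmeta.groups import build_spec
from jointmeta.init_fits import fit_separate_longitudinal, fit_separate_survival
from jointmeta.simulate import SimulationScenario, simulate_dataset


def _setup(dataset, group, **ctrl_kw):
    control = EMControl(**ctrl_kw)
    design = build_design(dataset, build_spec(group))
    long_fit = fit_separate_longitudinal(design)
    surv_fit = fit_separate_survival(design)
    blocks = _lmm.subject_blocks(design)
    grid = build_grid(long_fit, design, control)
    risksets = RiskSets.build(design.data.T, design.data.delta, design.strata)
    geom = build_hazard_geometry(design, risksets)
    params = JointParams(
        beta1=long_fit.beta1.copy(),
        beta2=surv_fit.beta2.copy(),
        alpha2=0.0,
        alpha3=0.0 if design.spec.has_study_re else None,
        D=long_fit.D.copy(),
        A=long_fit.A if design.spec.has_study_re else np.zeros((0, 0)),
        sigma_e2=long_fit.sigma_e2,
        increments=[i.copy() for i in surv_fit.hazard.increments],
    )
    return design, blocks, grid, geom, params, risksets, long_fit, surv_fit


class TestChebyshevHazard:
    def test_cumulative_mass_matches_direct_sum(self, toy_dataset):
        """The separated representation reproduces brute-force sums."""
        design, blocks, grid, geom, params, risksets, *_ = _setup(toy_dataset, 0)
        params = JointParams(**{**params.__dict__, "alpha2": 0.8})
        Vrow, _ = _baseline_rows(risksets, geom, params.increments)
        B2 = grid.B2
        C = _cheb_coefs(params.alpha2 * B2[:, :, 1] * geom.h_of[:, None])
        a_lin = params.alpha2 * (B2[:, :, 0] + B2[:, :, 1] * geom.t0_of[:, None])
        q = np.maximum(np.einsum("nmj,nj->nm", C, Vrow), 0.0) * np.exp(a_lin)

        st = risksets.strata[0]
        te, lam = st.event_times, params.increments[0]
        T = design.data.T
        for i in [0, 5, 33]:
            sel = te <= T[i]
            for m in [0, grid.M // 2, grid.M - 1]:
                direct = np.sum(
                    lam[sel]
                    * np.exp(params.alpha2 * (B2[i, m, 0] + B2[i, m, 1] * te[sel]))
                )
                assert q[i, m] == pytest.approx(direct, rel=1e-9, abs=1e-12)

    def test_exp_coefficients_reproduce_function(self):
        z = np.array([-8.0, -1.0, 0.0, 2.5, 9.0])
        C = _cheb_coefs(z)
        x = np.linspace(-1, 1, 101)
        from numpy.polynomial.chebyshev import chebvander

        V = chebvander(x, C.shape[-1] - 1)
        recon = C @ V.T
        truth = np.exp(np.outer(z, x))
        # interpolation error scales with the row-wise function maximum
        err = np.abs(recon - truth)
        assert (err <= 1e-10 * truth.max(axis=1, keepdims=True) + 1e-12).all()


class TestEStep:
    def test_moments_match_dense_grid_oracle(self, toy_dataset):
        """Posterior moments vs direct 2-d integration for single subjects."""
        design, blocks, grid, geom, params, risksets, lf, sf = _setup(
            toy_dataset, 0, n_quad=15
        )
        params = JointParams(
            **{**params.__dict__, "alpha2": 0.6, "sigma_e2": lf.sigma_e2}
        )
        mom = estep(design, blocks, grid, geom, params, risksets)

        data = design.data
        st = risksets.strata[0]
        te, lam = st.event_times, params.increments[0]
        r = data.y - design.X1 @ params.beta1
        Dinv = np.linalg.inv(params.D)
        for i in [1, 17]:
            # dense grid over b2 around the adaptive centre
            mu = lf.moments.Eb2[i]
            sd = np.sqrt(np.diag(lf.moments.cond_cov2[i]))
            g0 = np.linspace(mu[0] - 8 * sd[0], mu[0] + 8 * sd[0], 401)
            g1 = np.linspace(mu[1] - 8 * sd[1], mu[1] + 8 * sd[1], 401)
            B0, B1 = np.meshgrid(g0, g1, indexing="ij")
            rows = data.obs_subject == i
            ri, ti = r[rows], data.t_obs[rows]
            ll = np.zeros_like(B0)
            for rj, tj in zip(ri, ti):
                ll += -0.5 * (rj - B0 - B1 * tj) ** 2 / params.sigma_e2
            ll += -0.5 * (
                Dinv[0, 0] * B0**2 + 2 * Dinv[0, 1] * B0 * B1 + Dinv[1, 1] * B1**2
            )
            xb = (design.X2 @ params.beta2)[i]
            sel = te <= data.T[i]
            cum = np.zeros_like(B0)
            for l_e, t_e in zip(lam[sel], te[sel]):
                cum += l_e * np.exp(params.alpha2 * (B0 + B1 * t_e))
            ll -= np.exp(xb) * cum
            if data.delta[i] == 1:
                ll += params.alpha2 * (B0 + B1 * data.T[i])
            w = np.exp(ll - ll.max())
            w /= w.sum()
            e0 = float((w * B0).sum())
            e1 = float((w * B1).sum())
            assert mom.Eb2[i, 0] == pytest.approx(e0, abs=2e-6)
            assert mom.Eb2[i, 1] == pytest.approx(e1, abs=2e-6)
            assert mom.Eb2b2[i, 0, 0] == pytest.approx(float((w * B0 * B0).sum()), abs=2e-6)
            assert mom.Eb2b2[i, 0, 1] == pytest.approx(float((w * B0 * B1).sum()), abs=2e-6)

    def test_zero_association_reduces_to_lmm_moments(self, toy_dataset):
        design, blocks, grid, geom, params, risksets, lf, _ = _setup(toy_dataset, 0)
        mom = estep(design, blocks, grid, geom, params, risksets)
        np.testing.assert_allclose(mom.Eb2, lf.moments.Eb2, atol=1e-6)
        lmm_second = lf.moments.Eb2b2
        np.testing.assert_allclose(mom.Eb2b2, lmm_second, atol=1e-6)

    def test_loglik_decomposes_at_zero_association(self, toy_dataset):
        """At alpha=0 the joint log-likelihood is LMM + full Cox (Breslow)."""
        design, blocks, grid, geom, params, risksets, lf, sf = _setup(toy_dataset, 0)
        mom = estep(design, blocks, grid, geom, params, risksets)
        # full survival likelihood with the Breslow baseline plugged in
        data = design.data
        xb = design.X2 @ params.beta2
        cum = risksets.cumhaz_at_T(params.increments, data.T)
        log_inc = np.zeros(data.n)
        for s, st in enumerate(risksets.strata):
            ev = st.event_rows
            pos = np.searchsorted(st.event_times, data.T[ev])
            log_inc[ev] = np.log(params.increments[s][pos])
        surv_full = float(
            np.sum(data.delta * (log_inc + xb)) - np.sum(cum * np.exp(xb))
        )
        assert mom.loglik == pytest.approx(lf.loglik + surv_full, abs=5e-4)


class TestFitJoint:
    @pytest.mark.parametrize("group", [0, 1, 3, 4, 5])
    def test_loglik_trace_monotone(self, toy_dataset, group):
        # small-sample fits can have a long (but monotone) EM tail
        res = fit_joint(toy_dataset, build_spec(group), EMControl(max_iter=500))
        assert res.converged, res.failure
        diffs = np.diff(res.loglik_trace)
        assert diffs.min() > -1e-6 * max(1.0, abs(res.loglik))

    def test_alpha_fixed_at_zero_reduces_to_separate_fits(self, toy_dataset):
        res = fit_joint(
            toy_dataset, build_spec(1), EMControl(estimate_association=False)
        )
        assert res.converged
        lf, sf = res.separate_long, res.separate_surv
        np.testing.assert_allclose(res.beta1, lf.beta1, rtol=1e-4, atol=1e-4)
        np.testing.assert_allclose(res.beta2, sf.beta2, rtol=1e-4, atol=1e-4)
        np.testing.assert_allclose(res.D, lf.D, rtol=2e-4, atol=2e-4)
        assert res.sigma_e2 == pytest.approx(lf.sigma_e2, rel=2e-4)
        assert res.alpha2 == 0.0

    def test_breslow_null_increment_is_inverse_risk_set(self):
        """Single event, alpha=0, beta2=0: increment = 1/|risk set|."""
        long = pd.DataFrame(
            {
                "study": ["A"] * 4,
                "subject": [1, 2, 3, 4],
                "time": [0.0] * 4,
                "y": [0.0, 0.1, -0.1, 0.2],
                "treat": [0, 0, 0, 0],
            }
        )
        surv = pd.DataFrame(
            {
                "study": ["A"] * 4,
                "subject": [1, 2, 3, 4],
                "survtime": [2.0, 3.0, 4.0, 5.0],
                "status": [1, 0, 0, 0],
                "treat": [0, 0, 0, 0],
            }
        )
        ds = validate(MetaJointDataset(long=long, surv=surv))
        sf = fit_separate_survival(ds, build_spec(0))
        # treat has no variation -> beta2 stays 0; the single event at t=2
        # has all four subjects at risk
        assert sf.beta2[0] == pytest.approx(0.0, abs=1e-8)
        assert sf.hazard.increments[0][0] == pytest.approx(0.25, rel=1e-9)

    def test_newton_update_matches_grid_search(self, toy_dataset):
        """M-step survival maximiser vs dense grid on a 1-d slice."""
        from jointmeta.em import _surv_profile_parts

        design, blocks, grid, geom, params, risksets, lf, sf = _setup(toy_dataset, 0)
        params = JointParams(**{**params.__dict__, "alpha2": 0.4})
        mom = estep(design, blocks, grid, geom, params, risksets)
        p2 = design.X2.shape[1]

        # profile objective over alpha2 at fixed beta2: grid vs derivative root
        def f_of_alpha(a):
            psi = np.concatenate([params.beta2, [a]])
            return _surv_profile_parts(
                design, grid, geom, mom, risksets, psi, p2, False
            )[0]

        alphas = np.linspace(-0.5, 1.5, 401)
        vals = [f_of_alpha(a) for a in alphas]
        a_grid = alphas[int(np.argmax(vals))]
        # gradient at the grid optimum should be ~0 compared with neighbours
        psi = np.concatenate([params.beta2, [a_grid]])
        _, gr, _, _ = _surv_profile_parts(
            design, grid, geom, mom, risksets, psi, p2, False
        )
        # the alpha2 component of the gradient changes sign within one cell
        up = np.concatenate([params.beta2, [a_grid + 0.005]])
        dn = np.concatenate([params.beta2, [a_grid - 0.005]])
        g_up = _surv_profile_parts(design, grid, geom, mom, risksets, up, p2, False)[1]
        g_dn = _surv_profile_parts(design, grid, geom, mom, risksets, dn, p2, False)[1]
        assert g_up[-1] < 0 < g_dn[-1]

    def test_failed_initialization_returns_failure_object(self, toy_dataset):
        ds = MetaJointDataset(
            long=toy_dataset.long.copy(), surv=toy_dataset.surv.assign(status=0)
        )
        res = fit_joint(validate(ds), build_spec(0))
        assert not res.converged
        assert res.failure is not None
        assert np.isnan(res.alpha2)

    def test_group4_risk_sets_stay_within_study(self, toy_dataset):
        design = build_design(toy_dataset, build_spec(4))
        rs = RiskSets.build(design.data.T, design.data.delta, design.strata)
        for s, st in enumerate(rs.strata):
            assert set(design.data.subj_study[st.subjects]) == {s}

    def test_joint_recovery_toy(self, toy_dataset):
        """Association and treatment effects recovered on the toy data."""
        res = fit_joint(toy_dataset, build_spec(3))
        assert res.converged
        # generous bands: K=2 studies, n=120
        assert 0.1 < res.alpha2 < 0.9
        assert res.sigma_e2 == pytest.approx(0.01, rel=0.5)
        np.testing.assert_allclose(res.D, [[1, 0.5], [0.5, 1.5]], atol=0.6)
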