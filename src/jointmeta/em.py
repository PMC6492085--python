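"""EM fitting of the one-stage joint model.

The joint likelihood couples a Gaussian linear mixed longitudinal sub-model
and a proportional-hazards sub-model with nonparametric (Breslow) baseline
through shared zero-mean random effects: the individual intercept/slope pair
``(b0, b1)`` enters the log hazard as ``alpha2 * (b0 + b1 * t)`` — the
longitudinal random-effect basis evaluated at event time, so the random
slope acts as a latent time-varying covariate — and the study-level effects
``b3`` as the time-constant ``alpha3 * z3'b3``.  A subject's own event
contribution therefore evaluates the association at their survival time
``T_S``, while inside risk-set (cumulative-hazard) sums the basis moves with
the event times.

Fitting treats the random effects as missing data.  The E-step evaluates
posterior expectations on a pseudo-adaptive Gauss–Hermite grid: abscissae
are centred at the conditional modes and scaled by the conditional
covariance Cholesky factors from the initial separate longitudinal fit,
then held fixed, so few points per dimension suffice.  Study-level effects
are integrated on an outer grid; conditional on an outer node, subjects are
independent and each is integrated on its own inner grid.  The M-step has
closed-form updates for the longitudinal fixed effects and all variance
components, a Breslow-type profile update for the baseline hazard, and a
damped Newton step for the survival coefficients and association
parameters.

Risk-set sums of ``exp(alpha2 * b1 * t_e)`` over subjects-by-nodes are made
tractable by a Chebyshev separation of the exponential in event time
(cosine-transform interpolation coefficients, fixed degree), reducing the
cost from O(n * nodes * events) to O(n * nodes * degree).

Because the abscissae are fixed, the algorithm is an exact EM for the
quadrature-discretised likelihood; the observed (quadrature) log-likelihood
is non-decreasing up to floating-point and Chebyshev truncation error,
which the test suite asserts on every fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.polynomial.chebyshev import chebvander
from numpy.polynomial.hermite_e import hermegauss
from scipy.special import logsumexp

from . import _lmm
from ._surv import BaselineHazard, RiskSets, fit_cox
from .data import MetaJointDataset
from .design import DesignBundle, build_design
from .groups import ModelGroupSpec

logger = logging.getLogger(__name__)

_EXP_CLIP = 500.0  # cap on log-hazard offsets before exponentiation
_CHEB_J = 40  # Chebyshev degree for the exp-in-time separation

# Chebyshev interpolation nodes and cosine-transform matrix (fixed degree)
_XQ = np.cos(np.pi * (np.arange(_CHEB_J) + 0.5) / _CHEB_J)
_MDCT = np.cos(
    np.pi * np.outer(np.arange(_CHEB_J), (np.arange(_CHEB_J) + 0.5)) / _CHEB_J
) * (2.0 / _CHEB_J)
_MDCT[0] /= 2.0


def _cheb_coefs(z: np.ndarray) -> np.ndarray:
    """Chebyshev coefficients of ``x -> exp(z * x)`` on [-1, 1].

    Vectorised over ``z``; appends a coefficient axis of length ``_CHEB_J``.
    """
    E = np.exp(np.clip(z[..., None] * _XQ, -_EXP_CLIP, _EXP_CLIP))
    return E @ _MDCT.T


@dataclass
class EMControl:
    """Tuning knobs for the EM run.

    ``n_quad`` is the number of Gauss–Hermite points per individual
    random-effect dimension; ``n_quad_study`` (default: same) per
    study-level dimension.  Convergence requires the maximum relative
    parameter change to fall below ``tol_param`` and the relative
    log-likelihood change below ``tol_loglik``.
    """

    max_iter: int = 200
    tol_param: float = 1e-4
    tol_loglik: float = 1e-6
    n_quad: int = 5
    n_quad_study: int | None = None
    newton_max: int = 25
    newton_tol: float = 1e-8
    estimate_association: bool = True


@dataclass
class JointParams:
    """Current parameter state of the EM."""

    beta1: np.ndarray
    beta2: np.ndarray
    alpha2: float
    alpha3: float | None  # None when the spec has no study-level REs
    D: np.ndarray
    A: np.ndarray
    sigma_e2: float
    increments: list  # baseline-hazard increments per stratum

    def flat(self) -> np.ndarray:
        parts = [self.beta1, self.beta2, [self.alpha2]]
        if self.alpha3 is not None:
            parts.append([self.alpha3])
        parts.append(self.D[np.triu_indices(2)])
        if self.A.size:
            parts.append(self.A[np.triu_indices(self.A.shape[0])])
        parts.append([self.sigma_e2])
        return np.concatenate([np.atleast_1d(np.asarray(p, float)) for p in parts])


@dataclass
class QuadratureGrid:
    """Pseudo-adaptive Gauss–Hermite abscissae and base log-weights."""

    B2: np.ndarray  # (n, M, 2) individual-effect nodes
    logw2: np.ndarray  # (n, M) log base weights (incl. Jacobian)
    B3: np.ndarray  # (K, S, q3) study-effect nodes
    logw3: np.ndarray  # (K, S)

    @property
    def M(self) -> int:
        return self.B2.shape[1]

    @property
    def S(self) -> int:
        return self.B3.shape[1]


def _ghe_nodes(dim: int, n_points: int):
    """Tensor-product probabilists' Gauss–Hermite rule.

    Returns nodes ``x_m`` and base log-weights ``log w_m + ||x_m||^2 / 2``
    such that ``int g(x) dx ~ sum_m exp(logw_m) g(x_m)`` for integrands
    that absorb their own Gaussian factor.
    """
    if dim == 0:
        return np.zeros((1, 0)), np.zeros(1)
    x, w = hermegauss(n_points)
    lw1 = np.log(w) + 0.5 * x**2
    idx = np.stack(
        np.meshgrid(*([np.arange(n_points)] * dim), indexing="ij"), axis=-1
    ).reshape(-1, dim)
    return x[idx], lw1[idx].sum(axis=1)


def build_grid(
    long_fit: _lmm.SeparateLongFit, design: DesignBundle, control: EMControl
) -> QuadratureGrid:
    """Centre/scale GH nodes at the separate-fit conditional moments."""
    mom = long_fit.moments
    K = design.data.K
    q3 = design.Z3_subj.shape[1]

    x2d, lw2d = _ghe_nodes(2, control.n_quad)
    L2 = np.linalg.cholesky(mom.cond_cov2 + 1e-12 * np.eye(2))
    B2 = mom.Eb2[:, None, :] + np.einsum("nij,mj->nmi", L2, x2d)
    logdet2 = np.log(L2[:, 0, 0] * L2[:, 1, 1])
    logw2 = lw2d[None, :] + logdet2[:, None]

    nS = control.n_quad_study or control.n_quad
    if q3:
        x3d, lw3d = _ghe_nodes(q3, nS)
        L3 = np.linalg.cholesky(mom.cov3 + 1e-12 * np.eye(q3))
        B3 = mom.Eb3[:, None, :] + np.einsum("kij,sj->ksi", L3, x3d)
        logdet3 = np.array([np.sum(np.log(np.diag(L))) for L in L3])
        logw3 = lw3d[None, :] + logdet3[:, None]
    else:
        B3 = np.zeros((K, 1, 0))
        logw3 = np.zeros((K, 1))
    return QuadratureGrid(B2=B2, logw2=logw2, B3=B3, logw3=logw3)


@dataclass
class HazardGeometry:
    """Per-stratum event-time scaling and per-subject risk-set positions."""

    Tb: list  # per stratum: Chebyshev basis at scaled event times (E, J)
    t0_of: np.ndarray  # (n,) stratum time-centre per subject
    h_of: np.ndarray  # (n,) stratum half-range per subject
    c_count: np.ndarray  # (n,) number of events at or before each subject's T
    ev_pos: np.ndarray  # (n,) own event-time index within stratum (-1 if censored)


def build_hazard_geometry(design: DesignBundle, risksets: RiskSets) -> HazardGeometry:
    data = design.data
    n = data.n
    Tb = []
    t0_of = np.zeros(n)
    h_of = np.zeros(n)
    c_count = np.zeros(n, dtype=np.intp)
    ev_pos = np.full(n, -1, dtype=np.intp)
    for s, st in enumerate(risksets.strata):
        te = st.event_times
        t0 = 0.5 * (te[0] + te[-1])
        h = max(0.5 * (te[-1] - te[0]), 1e-9)
        x = (te - t0) / h
        Tb.append(chebvander(x, _CHEB_J - 1))
        idx = np.flatnonzero(risksets.stratum_of == s)
        t0_of[idx] = t0
        h_of[idx] = h
        c_count[idx] = np.searchsorted(te, data.T[idx], side="right")
        ev = st.event_rows
        ev_pos[ev] = np.searchsorted(te, data.T[ev])
    return HazardGeometry(Tb=Tb, t0_of=t0_of, h_of=h_of, c_count=c_count, ev_pos=ev_pos)


@dataclass
class EStepMoments:
    """Posterior expectations needed by the M-step.

    ``P`` holds each subject's marginal posterior node weights over (outer
    study node, inner individual node); together with the node values it
    lets the M-step evaluate expectations of arbitrary association-term
    functionals at trial parameter values.
    """

    P: np.ndarray  # (n, S, M)
    wT: np.ndarray  # (n, M) individual association basis at T_S
    v: np.ndarray  # (n, S) study-level association term per outer node
    W: np.ndarray  # (K, S) outer posterior weights
    Eb2: np.ndarray  # (n, 2)
    Eb2b2: np.ndarray  # (n, 2, 2)
    Eb3: np.ndarray  # (n, q3) per subject
    Eb3b3_study: np.ndarray  # (K, q3, q3)
    Eb2b3: np.ndarray  # (n, 2, q3)
    Ew: np.ndarray  # (n,) E[b0 + b1 T_S]
    Ev: np.ndarray  # (n,) E[z3'b3]
    loglik: float


def _baseline_rows(risksets, geom, increments):
    """Per-subject cumulated Chebyshev-basis mass and own log increment."""
    n = len(geom.t0_of)
    Vrow = np.zeros((n, _CHEB_J))
    log_inc = np.zeros(n)
    for s, st in enumerate(risksets.strata):
        idx = np.flatnonzero(risksets.stratum_of == s)
        V = np.cumsum(increments[s][:, None] * geom.Tb[s], axis=0)
        c = geom.c_count[idx]
        has = c > 0
        Vrow[idx[has]] = V[c[has] - 1]
        ev = st.event_rows
        log_inc[ev] = np.log(np.maximum(increments[s][geom.ev_pos[ev]], 1e-300))
    return Vrow, log_inc


def estep(
    design: DesignBundle,
    blocks: _lmm.SubjectBlocks,
    grid: QuadratureGrid,
    geom: HazardGeometry,
    params: JointParams,
    risksets: RiskSets,
) -> EStepMoments:
    """Posterior moments of the random effects on the quadrature grid."""
    data = design.data
    n, K = data.n, data.K
    q3 = grid.B3.shape[2]
    S = grid.S
    ks = data.subj_study

    # longitudinal residual pieces
    r = data.y - design.X1 @ params.beta1
    Ztr = np.stack(
        [
            np.add.reduceat(r, blocks.starts),
            np.add.reduceat(r * design.Z2[:, 1], blocks.starts),
        ],
        axis=1,
    )
    rr = np.add.reduceat(r * r, blocks.starts)
    sig2 = params.sigma_e2

    B2, B3 = grid.B2, grid.B3
    B3s = B3[ks]  # (n, S, q3)
    v = np.einsum("ni,nsi->ns", design.Z3_subj, B3s) if q3 else np.zeros((n, S))
    u1 = np.einsum("nmi,ni->nm", B2, blocks.Zt1)  # b2' Z2'1
    t22 = np.einsum("nmi,nij,nmj->nm", B2, blocks.ZtZ, B2)
    h2b = np.einsum("nmi,ni->nm", B2, Ztr)
    one_r = Ztr[:, 0]

    SSR = (
        rr[:, None, None]
        - 2.0 * (h2b[:, None, :] + (one_r[:, None] * v)[:, :, None])
        + t22[:, None, :]
        + 2.0 * u1[:, None, :] * v[:, :, None]
        + (blocks.m[:, None] * v**2)[:, :, None]
    )
    loglong = -0.5 * blocks.m[:, None, None] * np.log(2 * np.pi * sig2) - SSR / (
        2 * sig2
    )

    Dinv = _lmm._safe_inv_psd(params.D)
    logdetD = _lmm._logdet_psd(params.D)
    lp2 = -0.5 * (
        2 * np.log(2 * np.pi) + logdetD + np.einsum("nmi,ij,nmj->nm", B2, Dinv, B2)
    )

    # survival factor: event density at T_S, cumulative hazard with the
    # time-varying association handled through the Chebyshev separation
    wT = B2[:, :, 0] + B2[:, :, 1] * data.T[:, None]
    Vrow, log_inc = _baseline_rows(risksets, geom, params.increments)
    a2 = params.alpha2
    a3 = params.alpha3 if params.alpha3 is not None else 0.0
    zc = a2 * B2[:, :, 1] * geom.h_of[:, None]
    C = _cheb_coefs(zc)  # (n, M, J)
    a_lin = np.clip(
        a2 * (B2[:, :, 0] + B2[:, :, 1] * geom.t0_of[:, None]), -_EXP_CLIP, _EXP_CLIP
    )
    q = np.maximum(np.einsum("nmj,nj->nm", C, Vrow), 0.0) * np.exp(a_lin)  # (n, M)

    xb2 = design.X2 @ params.beta2
    eta_T = np.clip(
        xb2[:, None, None] + a2 * wT[:, None, :] + a3 * v[:, :, None],
        -_EXP_CLIP,
        _EXP_CLIP,
    )
    exb_av = np.exp(np.clip(xb2[:, None] + a3 * v, -_EXP_CLIP, _EXP_CLIP))  # (n, S)
    lsurv = (
        data.delta[:, None, None] * (log_inc[:, None, None] + eta_T)
        - exb_av[:, :, None] * q[:, None, :]
    )

    lg = grid.logw2[:, None, :] + lp2[:, None, :] + loglong + lsurv  # (n, S, M)
    Li = logsumexp(lg, axis=2)  # (n, S)

    if q3:
        Ainv = _lmm._safe_inv_psd(params.A)
        logdetA = _lmm._logdet_psd(params.A)
        lp3 = -0.5 * (
            q3 * np.log(2 * np.pi)
            + logdetA
            + np.einsum("ksi,ij,ksj->ks", B3, Ainv, B3)
        )
    else:
        lp3 = np.zeros((K, 1))
    lstudy = grid.logw3 + lp3 + np.add.reduceat(Li, blocks.study_starts, axis=0)
    ll_k = logsumexp(lstudy, axis=1)
    loglik = float(ll_k.sum())
    if not np.isfinite(loglik):
        raise FloatingPointError("zero posterior mass in E-step")
    W = np.exp(lstudy - ll_k[:, None])  # (K, S)
    omega = np.exp(lg - Li[:, :, None])  # conditional inner weights
    P = omega * W[ks][:, :, None]

    Eb2 = np.einsum("nsm,nmi->ni", P, B2)
    Eb2b2 = np.einsum("nsm,nmi,nmj->nij", P, B2, B2)
    Ps = P.sum(axis=2)  # (n, S)
    Eb3 = np.einsum("ns,nsi->ni", Ps, B3s)
    Eb3b3_study = np.einsum("ks,ksi,ksj->kij", W, B3, B3)
    Eb2b3 = np.einsum("nsm,nmi,nsq->niq", P, B2, B3s)
    Ew = np.einsum("nsm,nm->n", P, wT)
    Ev = np.einsum("ns,ns->n", Ps, v)
    return EStepMoments(
        P=P,
        wT=wT,
        v=v,
        W=W,
        Eb2=Eb2,
        Eb2b2=Eb2b2,
        Eb3=Eb3,
        Eb3b3_study=Eb3b3_study,
        Eb2b3=Eb2b3,
        Ew=Ew,
        Ev=Ev,
        loglik=loglik,
    )


def _surv_profile_parts(design, grid, geom, mom, risksets, psi, p2, has_a3):
    """Expected profile (Breslow-plugged) survival objective and derivatives.

    The objective is the expected complete-data survival log-likelihood with
    the baseline increments profiled out; per subject the expectation of
    ``exp(alpha2 * (b0 + b1 * t_e) + alpha3 * v)`` over the posterior nodes
    is carried as Chebyshev coefficient vectors in the event time, so all
    risk-set sums reduce to suffix sums of coefficients.
    """
    beta2 = psi[:p2]
    alpha2 = psi[p2]
    alpha3 = psi[p2 + 1] if has_a3 else 0.0
    data = design.data
    X2 = design.X2
    b0 = grid.B2[:, :, 0]
    b1 = grid.B2[:, :, 1]

    if has_a3:
        eav = np.exp(np.clip(alpha3 * mom.v, -_EXP_CLIP, _EXP_CLIP))  # (n, S)
        kap = np.einsum("nsm,ns->nm", mom.P, eav)
        kapv = np.einsum("nsm,ns,ns->nm", mom.P, eav, mom.v)
        kapvv = np.einsum("nsm,ns,ns->nm", mom.P, eav, mom.v**2)
    else:
        kap = mom.P.sum(axis=1)
        kapv = kapvv = None

    xb = X2 @ beta2
    a_lin = np.clip(
        xb[:, None] + alpha2 * (b0 + b1 * geom.t0_of[:, None]), -_EXP_CLIP, _EXP_CLIP
    )
    eb = np.exp(a_lin)  # folds exp(x'beta2) and the time-centre shift
    W0 = kap * eb
    C = _cheb_coefs(alpha2 * b1 * geom.h_of[:, None])  # (n, M, J)

    fam = [W0, W0 * b0, W0 * b1, W0 * b0 * b0, W0 * b0 * b1, W0 * b1 * b1]
    if has_a3:
        Wv = kapv * eb
        fam += [Wv, Wv * b0, Wv * b1, kapvv * eb]
    F = len(fam)
    CF = np.einsum("fnm,nmj->fnj", np.stack(fam), C)  # (F, n, J)

    p = p2 + 1 + (1 if has_a3 else 0)
    delta = data.delta
    lin = xb + alpha2 * mom.Ew + (alpha3 * mom.Ev if has_a3 else 0.0)
    f = float((delta * lin).sum())
    grad = np.zeros(p)
    grad[:p2] = (delta[:, None] * X2).sum(axis=0)
    grad[p2] = (delta * mom.Ew).sum()
    if has_a3:
        grad[p2 + 1] = (delta * mom.Ev).sum()
    hess = np.zeros((p, p))
    increments = []

    xx = np.einsum("ni,nj->nij", X2, X2)
    for s, st in enumerate(risksets.strata):
        order = st.subjects
        rc = st.risk_count - 1
        Tb = geom.Tb[s]
        te = st.event_times
        d = st.d

        cums = np.cumsum(CF[:, order, :], axis=1)[:, rc, :]  # (F, E, J)
        SF = np.einsum("fej,ej->fe", cums, Tb)
        S0 = np.maximum(SF[0], 1e-300)
        G2 = SF[1] + te * SF[2]
        H22 = SF[3] + 2 * te * SF[4] + te**2 * SF[5]
        if has_a3:
            G3 = SF[6]
            H23 = SF[7] + te * SF[8]
            H33 = SF[9]

        # x2-weighted blocks
        xCF = np.cumsum(
            X2[order][:, :, None] * CF[0][order][:, None, :], axis=0
        )[rc]  # (E, p2, J)
        SX0 = np.einsum("epj,ej->ep", xCF, Tb)
        xCF1 = np.cumsum(
            X2[order][:, :, None] * CF[1][order][:, None, :], axis=0
        )[rc]
        xCF2 = np.cumsum(
            X2[order][:, :, None] * CF[2][order][:, None, :], axis=0
        )[rc]
        SX2 = np.einsum("epj,ej->ep", xCF1, Tb) + te[:, None] * np.einsum(
            "epj,ej->ep", xCF2, Tb
        )
        if has_a3:
            xCFv = np.cumsum(
                X2[order][:, :, None] * CF[6][order][:, None, :], axis=0
            )[rc]
            SX3 = np.einsum("epj,ej->ep", xCFv, Tb)

        # beta2 x beta2 block, accumulated per Chebyshev order to bound memory
        SXX = np.zeros((len(te), p2, p2))
        C0o = CF[0][order]
        xxo = xx[order]
        for j in range(_CHEB_J):
            SXX += np.cumsum(xxo * C0o[:, j, None, None], axis=0)[rc] * Tb[
                :, j, None, None
            ]

        f -= float(np.sum(d * np.log(S0)))
        g_e = np.zeros((len(te), p))
        g_e[:, :p2] = SX0
        g_e[:, p2] = G2
        if has_a3:
            g_e[:, p2 + 1] = G3
        gbar = g_e / S0[:, None]
        grad -= (d[:, None] * gbar).sum(axis=0)

        H_e = np.zeros((len(te), p, p))
        H_e[:, :p2, :p2] = SXX
        H_e[:, :p2, p2] = H_e[:, p2, :p2] = SX2
        H_e[:, p2, p2] = H22
        if has_a3:
            H_e[:, :p2, p2 + 1] = H_e[:, p2 + 1, :p2] = SX3
            H_e[:, p2, p2 + 1] = H_e[:, p2 + 1, p2] = H23
            H_e[:, p2 + 1, p2 + 1] = H33
        hess -= np.einsum("e,eij->ij", d, H_e / S0[:, None, None]) - np.einsum(
            "e,ei,ej->ij", d, gbar, gbar
        )
        increments.append(d / S0)
    return f, grad, hess, increments


def _mstep_survival(design, grid, geom, mom, risksets, params, control, p2, has_a3):
    """Damped Newton update of (beta2, alpha2[, alpha3]) with profiled baseline."""
    psi = np.concatenate(
        [params.beta2, [params.alpha2], [params.alpha3] if has_a3 else []]
    )
    f, grad, hess, incs = _surv_profile_parts(
        design, grid, geom, mom, risksets, psi, p2, has_a3
    )
    ok = True
    for _ in range(control.newton_max):
        if np.max(np.abs(grad)) < control.newton_tol * max(1.0, abs(f)):
            break
        try:
            step = np.linalg.solve(-hess + 1e-10 * np.eye(len(psi)), grad)
        except np.linalg.LinAlgError:
            ok = False
            break
        accepted = False
        for _ in range(30):
            cand = psi + step
            out = _surv_profile_parts(
                design, grid, geom, mom, risksets, cand, p2, has_a3
            )
            if np.isfinite(out[0]) and out[0] >= f - 1e-10:
                accepted = True
                break
            step = step / 2.0
        if not accepted:
            break
        psi, (f, grad, hess, incs) = cand, out
    return psi, incs, hess, ok


@dataclass
class JointFitResult:
    """Everything estimated by one joint-model fit."""

    spec: ModelGroupSpec
    beta1: np.ndarray
    beta2: np.ndarray
    alpha2: float
    alpha3: float | None
    D: np.ndarray
    A: np.ndarray
    sigma_e2: float
    hazard: BaselineHazard
    cov_beta1: np.ndarray
    cov_psi: np.ndarray  # model-based covariance of (beta2, alpha2[, alpha3])
    psi_names: list
    x1_names: list
    x2_names: list
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int
    failure: str | None = None
    se_method: str = "model"
    separate_long: object = None
    separate_surv: object = None

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1]) if len(self.loglik_trace) else np.nan

    @property
    def se_beta1(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_beta1))

    @property
    def se_psi(self) -> np.ndarray:
        return np.sqrt(np.abs(np.diag(self.cov_psi)))

    def to_dict(self) -> dict:
        """Machine-readable summary (used by the CLI JSON output)."""
        return {
            "group": self.spec.group,
            "beta1": dict(zip(self.x1_names, np.asarray(self.beta1).tolist())),
            "beta2": dict(zip(self.x2_names, np.asarray(self.beta2).tolist())),
            "alpha2": self.alpha2,
            "alpha3": self.alpha3,
            "D": np.asarray(self.D).tolist(),
            "A": np.asarray(self.A).tolist(),
            "sigma_e2": self.sigma_e2,
            "loglik": self.loglik,
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "se_beta1": dict(zip(self.x1_names, self.se_beta1.tolist())),
            "se_psi": dict(zip(self.psi_names, self.se_psi.tolist())),
            "failure": self.failure,
        }


def observed_loglik(design, blocks, grid, geom, params, risksets) -> float:
    """Quadrature-approximated marginal log-likelihood at ``params``."""
    return estep(design, blocks, grid, geom, params, risksets).loglik


def fit_joint(
    dataset: MetaJointDataset | DesignBundle,
    spec: ModelGroupSpec | None = None,
    control: EMControl | None = None,
) -> JointFitResult:
    """Fit the one-stage joint model for ``spec`` by EM.

    Starting values come from separate longitudinal (mixed-model) and
    survival (Cox) fits of the same sub-model specifications without the
    association term; the longitudinal fit also provides the pseudo-adaptive
    quadrature centring.  Association parameters start at zero.

    Non-convergence and numerical failures are reported through
    ``converged`` / ``failure`` on the result, never raised.
    """
    from .init_fits import fit_separate_longitudinal, fit_separate_survival

    control = control or EMControl()
    if isinstance(dataset, DesignBundle):
        design = dataset
    else:
        design = build_design(dataset, spec)
    spec = design.spec
    data = design.data
    has_a3 = spec.has_study_re and control.estimate_association
    p2 = design.X2.shape[1]

    try:
        long_fit = fit_separate_longitudinal(design)
        surv_fit = fit_separate_survival(design)
    except (ValueError, np.linalg.LinAlgError, FloatingPointError) as exc:
        return _failed_result(design, str(exc))

    blocks = _lmm.subject_blocks(design)
    grid = build_grid(long_fit, design, control)
    risksets = RiskSets.build(data.T, data.delta, design.strata)
    geom = build_hazard_geometry(design, risksets)

    A0 = long_fit.A if spec.has_study_re else np.zeros((0, 0))
    params = JointParams(
        beta1=long_fit.beta1.copy(),
        beta2=surv_fit.beta2.copy(),
        alpha2=0.0,
        alpha3=0.0 if spec.has_study_re else None,
        D=long_fit.D.copy(),
        A=A0,
        sigma_e2=long_fit.sigma_e2,
        increments=[inc.copy() for inc in surv_fit.hazard.increments],
    )

    X1, y = design.X1, data.y
    XtX_chol = np.linalg.cholesky(X1.T @ X1)
    trace = []
    converged = False
    failure = None
    hess = None
    n_iter = 0
    prev_flat = params.flat()
    try:
        for n_iter in range(1, control.max_iter + 1):
            mom = estep(design, blocks, grid, geom, params, risksets)
            trace.append(mom.loglik)

            # closed-form longitudinal updates
            fitted_re = (
                mom.Eb2[data.obs_subject, 0]
                + mom.Eb2[data.obs_subject, 1] * design.Z2[:, 1]
            )
            if spec.has_study_re:
                fitted_re = fitted_re + np.einsum(
                    "ni,ni->n", design.Z3_obs, mom.Eb3[data.obs_subject]
                )
            rhs = X1.T @ (y - fitted_re)
            beta1 = np.linalg.solve(XtX_chol.T, np.linalg.solve(XtX_chol, rhs))
            D = mom.Eb2b2.mean(axis=0)
            A = mom.Eb3b3_study.mean(axis=0) if spec.has_study_re else params.A

            r = y - X1 @ beta1
            rr = np.add.reduceat(r * r, blocks.starts)
            Ztr = np.stack(
                [
                    np.add.reduceat(r, blocks.starts),
                    np.add.reduceat(r * design.Z2[:, 1], blocks.starts),
                ],
                axis=1,
            )
            ess = (
                rr.sum()
                - 2 * np.einsum("ni,ni->", Ztr, mom.Eb2)
                + np.einsum("nij,nij->", blocks.ZtZ, mom.Eb2b2)
            )
            if spec.has_study_re:
                z3 = design.Z3_subj
                Eb3b3_subj = mom.Eb3b3_study[data.subj_study]
                ess += (
                    -2 * np.einsum("ni,ni->", z3 * Ztr[:, :1], mom.Eb3)
                    + 2 * np.einsum("ni,niq,nq->", blocks.Zt1, mom.Eb2b3, z3)
                    + np.einsum("n,ni,nij,nj->", blocks.m, z3, Eb3b3_subj, z3)
                )
            sigma_e2 = float(ess / len(y))

            if control.estimate_association:
                psi, increments, hess, newton_ok = _mstep_survival(
                    design, grid, geom, mom, risksets, params, control, p2, has_a3
                )
                if not newton_ok:
                    failure = "survival Newton update failed"
                    break
                beta2 = psi[:p2]
                alpha2 = float(psi[p2])
                alpha3 = float(psi[p2 + 1]) if has_a3 else params.alpha3
            else:
                # association fixed at zero: survival update is a plain Cox step
                cox = fit_cox(
                    design.X2, data.T, data.delta, design.strata, design.x2_names
                )
                beta2 = cox.beta2
                alpha2, alpha3 = 0.0, params.alpha3
                increments = cox.hazard.increments
                hess = -np.linalg.inv(cox.cov_beta2)

            params = JointParams(
                beta1=beta1,
                beta2=beta2,
                alpha2=alpha2,
                alpha3=alpha3,
                D=D,
                A=A,
                sigma_e2=sigma_e2,
                increments=increments,
            )
            flat = params.flat()
            rel = np.max(
                np.abs(flat - prev_flat) / np.maximum(np.abs(prev_flat), 0.1)
            )
            dll = (
                abs(trace[-1] - trace[-2]) / (abs(trace[-1]) + 1.0)
                if n_iter > 1
                else np.inf
            )
            prev_flat = flat
            if rel < control.tol_param and dll < control.tol_loglik:
                converged = True
                break
    except FloatingPointError as exc:
        failure = str(exc)

    if failure is None and not converged:
        failure = "maximum EM iterations reached"

    # model-based covariances at the final parameters
    cov_beta1 = _lmm._gls(design, blocks, params.D, params.A, params.sigma_e2)[1]
    psi_names = list(design.x2_names) + ["alpha2"] + (["alpha3"] if has_a3 else [])
    if hess is not None and control.estimate_association:
        try:
            cov_psi = np.linalg.inv(-hess + 1e-10 * np.eye(len(psi_names)))
        except np.linalg.LinAlgError:
            cov_psi = np.full((len(psi_names), len(psi_names)), np.nan)
    elif not control.estimate_association:
        cov_psi_b = (
            np.linalg.inv(-hess) if hess is not None else np.full((p2, p2), np.nan)
        )
        cov_psi = np.zeros((p2 + 1, p2 + 1))
        cov_psi[:p2, :p2] = cov_psi_b
        psi_names = list(design.x2_names) + ["alpha2"]
    else:
        cov_psi = np.full((len(psi_names), len(psi_names)), np.nan)

    hazard = BaselineHazard(
        strata_labels=(
            design.data.study_labels if spec.stratified_hazard else ["all"]
        ),
        event_times=[st.event_times.copy() for st in risksets.strata],
        increments=[np.asarray(i) for i in params.increments],
    )
    return JointFitResult(
        spec=spec,
        beta1=params.beta1,
        beta2=params.beta2,
        alpha2=params.alpha2,
        alpha3=params.alpha3,
        D=params.D,
        A=params.A,
        sigma_e2=params.sigma_e2,
        hazard=hazard,
        cov_beta1=cov_beta1,
        cov_psi=cov_psi,
        psi_names=psi_names,
        x1_names=design.x1_names,
        x2_names=design.x2_names,
        loglik_trace=np.asarray(trace),
        converged=converged,
        n_iter=n_iter,
        failure=failure,
        separate_long=long_fit,
        separate_surv=surv_fit,
    )


def _failed_result(design: DesignBundle, reason: str) -> JointFitResult:
    logger.warning("joint fit failed during initialization: %s", reason)
    p1 = design.X1.shape[1]
    p2 = design.X2.shape[1]
    return JointFitResult(
        spec=design.spec,
        beta1=np.full(p1, np.nan),
        beta2=np.full(p2, np.nan),
        alpha2=np.nan,
        alpha3=np.nan if design.spec.has_study_re else None,
        D=np.full((2, 2), np.nan),
        A=np.full((design.spec.q3, design.spec.q3), np.nan),
        sigma_e2=np.nan,
        hazard=BaselineHazard([], [], []),
        cov_beta1=np.full((p1, p1), np.nan),
        cov_psi=np.full((p2 + 1, p2 + 1), np.nan),
        psi_names=list(design.x2_names) + ["alpha2"],
        x1_names=design.x1_names,
        x2_names=design.x2_names,
        loglik_trace=np.asarray([]),
        converged=False,
        n_iter=0,
        failure=reason,
    )
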