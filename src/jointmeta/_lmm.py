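"""Maximum-likelihood linear mixed model fitting by EM with exact E-steps.

The longitudinal sub-model is a Gaussian LMM with correlated individual
random intercept + slope (covariance ``D``) and, optionally, correlated
study-level random effects (covariance ``A``) whose design is constant
within subject.  All conditional distributions are Gaussian, so the E-step
is closed form: conditional on the study effects, subjects are independent
with standard 2x2 posteriors, and the study-effect posterior follows by a
rank-``q3`` Woodbury identity.  ML (not REML) is used throughout because the
estimates seed an ML EM algorithm for the joint model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import DesignBundle

_JITTER = 1e-10


def _safe_inv_psd(M: np.ndarray) -> np.ndarray:
    """Inverse of a PSD matrix with an eigenvalue floor."""
    M = np.asarray(M, dtype=float)
    w, V = np.linalg.eigh(M)
    w = np.maximum(w, _JITTER)
    return (V / w) @ V.T


def _logdet_psd(M: np.ndarray) -> float:
    w = np.linalg.eigvalsh(M)
    return float(np.sum(np.log(np.maximum(w, _JITTER))))


@dataclass
class SubjectBlocks:
    """Per-subject sufficient statistics, constant across iterations."""

    starts: np.ndarray  # (n,) reduceat boundaries into longitudinal rows
    study_starts: np.ndarray  # (K,) reduceat boundaries into subjects
    m: np.ndarray  # (n,) measurements per subject
    ZtZ: np.ndarray  # (n, 2, 2)
    Zt1: np.ndarray  # (n, 2)
    ZtX: np.ndarray  # (n, 2, p1)
    Xt1: np.ndarray  # (n, p1)
    z3: np.ndarray  # (n, q3)


def subject_blocks(design: DesignBundle) -> SubjectBlocks:
    data = design.data
    n = data.n
    sub = data.obs_subject
    starts = np.searchsorted(sub, np.arange(n))
    Z2, X1 = design.Z2, design.X1
    m = np.bincount(sub, minlength=n).astype(float)
    ZtZ = np.empty((n, 2, 2))
    St = np.add.reduceat(Z2[:, 1], starts)
    St2 = np.add.reduceat(Z2[:, 1] ** 2, starts)
    ZtZ[:, 0, 0] = m
    ZtZ[:, 0, 1] = ZtZ[:, 1, 0] = St
    ZtZ[:, 1, 1] = St2
    Zt1 = np.column_stack([m, St])
    ZtX = np.stack(
        [
            np.add.reduceat(X1, starts, axis=0),
            np.add.reduceat(X1 * Z2[:, 1:2], starts, axis=0),
        ],
        axis=1,
    )
    return SubjectBlocks(
        starts=starts,
        study_starts=np.searchsorted(data.subj_study, np.arange(data.K)),
        m=m,
        ZtZ=ZtZ,
        Zt1=Zt1,
        ZtX=ZtX,
        Xt1=ZtX[:, 0, :],
        z3=design.Z3_subj,
    )


def _batch_inv2(M: np.ndarray) -> np.ndarray:
    """Batched inverse of (n, 2, 2) symmetric positive definite matrices."""
    a, b, d = M[:, 0, 0], M[:, 0, 1], M[:, 1, 1]
    det = a * d - b * b
    out = np.empty_like(M)
    out[:, 0, 0] = d / det
    out[:, 1, 1] = a / det
    out[:, 0, 1] = out[:, 1, 0] = -b / det
    return out


@dataclass
class LmmMoments:
    """Posterior moments of the random effects at the current parameters."""

    Eb2: np.ndarray  # (n, 2)
    Eb2b2: np.ndarray  # (n, 2, 2) second moments
    cond_cov2: np.ndarray  # (n, 2, 2) Cov(b2 | y, b3 = posterior mean)
    Eb3: np.ndarray  # (K, q3)
    cov3: np.ndarray  # (K, q3, q3) posterior covariances
    Eb2b3: np.ndarray  # (n, 2, q3) cross second moments
    loglik: float


@dataclass
class SeparateLongFit:
    """ML fit of the separate longitudinal mixed model."""

    beta1: np.ndarray
    cov_beta1: np.ndarray
    D: np.ndarray
    A: np.ndarray  # (q3, q3); empty when no study-level effects
    sigma_e2: float
    moments: LmmMoments
    loglik: float
    converged: bool
    n_iter: int
    x1_names: list

    @property
    def se_beta1(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_beta1))


def _estep(design, blocks, beta, D, A, sig2, with_beta_cov=False):
    """Exact Gaussian E-step; returns moments and the marginal log-likelihood."""
    data = design.data
    n, K = data.n, data.K
    q3 = blocks.z3.shape[1]
    r = design.data.y - design.X1 @ beta
    Ztr = np.stack(
        [
            np.add.reduceat(r, blocks.starts),
            np.add.reduceat(r * design.Z2[:, 1], blocks.starts),
        ],
        axis=1,
    )  # (n, 2)
    rr = np.add.reduceat(r * r, blocks.starts)

    Dinv = _safe_inv_psd(D)
    M = blocks.ZtZ / sig2 + Dinv  # (n, 2, 2)
    Minv = _batch_inv2(M)
    a = np.einsum("nij,nj->ni", Minv, Ztr) / sig2  # E[b2 | b3=0]
    c = np.einsum("nij,nj->ni", Minv, blocks.Zt1) / sig2

    # per-subject marginal (b2 integrated): logdet V_i and r' V^-1 r
    DZtZ = np.einsum("ij,njk->nik", D, blocks.ZtZ) / sig2
    DZtZ[:, 0, 0] += 1.0
    DZtZ[:, 1, 1] += 1.0
    logdetV = blocks.m * np.log(sig2) + np.log(
        DZtZ[:, 0, 0] * DZtZ[:, 1, 1] - DZtZ[:, 0, 1] * DZtZ[:, 1, 0]
    )
    quad = rr / sig2 - np.einsum("ni,nij,nj->n", Ztr, Minv, Ztr) / sig2**2
    ll_subj = -0.5 * (blocks.m * np.log(2 * np.pi) + logdetV + quad)
    loglik = float(ll_subj.sum())

    if q3 == 0:
        Eb2 = a
        Eb2b2 = Minv + np.einsum("ni,nj->nij", a, a)
        return LmmMoments(
            Eb2=Eb2,
            Eb2b2=Eb2b2,
            cond_cov2=Minv,
            Eb3=np.zeros((K, 0)),
            cov3=np.zeros((K, 0, 0)),
            Eb2b3=np.zeros((n, 2, 0)),
            loglik=loglik,
        )

    # study-effect posterior via 1'V^-1 1 and 1'V^-1 r
    s1 = blocks.m / sig2 - np.einsum("ni,nij,nj->n", blocks.Zt1, Minv, blocks.Zt1) / sig2**2
    s2 = Ztr[:, 0] / sig2 - np.einsum("ni,nij,nj->n", blocks.Zt1, Minv, Ztr) / sig2**2
    z3 = blocks.z3
    Ainv = _safe_inv_psd(A)
    Eb3 = np.zeros((K, q3))
    cov3 = np.zeros((K, q3, q3))
    ll3 = 0.0
    ks = data.subj_study
    for k in range(K):
        sel = ks == k
        P3 = Ainv + np.einsum("ni,nj,n->ij", z3[sel], z3[sel], s1[sel])
        rhs = np.einsum("ni,n->i", z3[sel], s2[sel])
        S3 = _safe_inv_psd(P3)
        mu3 = S3 @ rhs
        Eb3[k] = mu3
        cov3[k] = S3
        ll3 += 0.5 * (mu3 @ rhs) - 0.5 * (_logdet_psd(A) + _logdet_psd(P3))
    loglik += float(ll3)

    zmu = np.einsum("ni,ni->n", z3, Eb3[ks])  # z3' E[b3] per subject
    Eb2 = a - c * zmu[:, None]
    zSz = np.einsum("ni,nij,nj->n", z3, cov3[ks], z3)
    Eb2_cov = Minv + np.einsum("ni,nj,n->nij", c, c, zSz)
    Eb2b2 = Eb2_cov + np.einsum("ni,nj->nij", Eb2, Eb2)
    # Cov(b2, b3) = -c (z3' cov3)
    zS = np.einsum("ni,nij->nj", z3, cov3[ks])  # (n, q3)
    cross_cov = -np.einsum("ni,nq->niq", c, zS)
    Eb2b3 = cross_cov + np.einsum("ni,nq->niq", Eb2, Eb3[ks])
    return LmmMoments(
        Eb2=Eb2,
        Eb2b2=Eb2b2,
        cond_cov2=Minv,
        Eb3=Eb3,
        cov3=cov3,
        Eb2b3=Eb2b3,
        loglik=loglik,
    )


def _gls(design, blocks, D, A, sig2):
    """Exact GLS solve for the fixed effects at given variance components.

    Returns ``(beta, cov_beta)`` where the covariance is the inverse
    marginal information ``(X' Sigma^-1 X)^-1`` with the study-level
    random effects folded in by a rank-``q3`` Woodbury correction.
    """
    data = design.data
    y = data.y
    Dinv = _safe_inv_psd(D)
    M = blocks.ZtZ / sig2 + Dinv
    Minv = _batch_inv2(M)
    Zty = np.stack(
        [
            np.add.reduceat(y, blocks.starts),
            np.add.reduceat(y * design.Z2[:, 1], blocks.starts),
        ],
        axis=1,
    )
    Xty = np.stack(
        [
            np.add.reduceat(design.X1 * y[:, None], blocks.starts, axis=0)
        ],
        axis=1,
    )[:, 0, :]
    XtX = design.X1.T @ design.X1
    info = XtX / sig2 - np.einsum(
        "nip,nij,njq->pq", blocks.ZtX, Minv, blocks.ZtX
    ) / sig2**2
    rhs = Xty.sum(axis=0) / sig2 - np.einsum(
        "nip,nij,nj->p", blocks.ZtX, Minv, Zty
    ) / sig2**2
    q3 = blocks.z3.shape[1]
    if q3:
        Xv1 = blocks.Xt1 / sig2 - np.einsum(
            "nip,nij,nj->np", blocks.ZtX, Minv, blocks.Zt1
        ) / sig2**2  # X_i' V^-1 1
        s1 = blocks.m / sig2 - np.einsum(
            "ni,nij,nj->n", blocks.Zt1, Minv, blocks.Zt1
        ) / sig2**2
        sy = Zty[:, 0] / sig2 - np.einsum(
            "ni,nij,nj->n", blocks.Zt1, Minv, Zty
        ) / sig2**2  # 1' V^-1 y
        Ainv = _safe_inv_psd(A)
        ks = data.subj_study
        for k in range(data.K):
            sel = ks == k
            P3 = Ainv + np.einsum(
                "ni,nj,n->ij", blocks.z3[sel], blocks.z3[sel], s1[sel]
            )
            S3 = _safe_inv_psd(P3)
            F = np.einsum("np,nq->pq", Xv1[sel], blocks.z3[sel])  # (p1, q3)
            g = np.einsum("nq,n->q", blocks.z3[sel], sy[sel])
            info = info - F @ S3 @ F.T
            rhs = rhs - F @ S3 @ g
    cov = _safe_inv_psd(info)
    return cov @ rhs, cov


def fit_lmm(
    design: DesignBundle,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> SeparateLongFit:
    """Fit the separate longitudinal mixed model.

    Uses an ECME scheme: each iteration solves the fixed effects exactly by
    GLS at the current variance components (a conditional maximization of
    the observed likelihood, which avoids the slow EM trade-off between the
    fixed effects and the random-effect means), then applies one EM update
    to ``D``, ``A`` and ``sigma_e2`` from the exact posterior moments.

    Convergence: maximum relative parameter change below ``tol``.  A fit is
    flagged unconverged (but still returned) at ``max_iter``; variance
    estimates collapsing to the PSD boundary are kept, with inverses
    floored.
    """
    data = design.data
    blocks = subject_blocks(design)
    q3 = blocks.z3.shape[1]
    X1, y = design.X1, data.y
    XtX = X1.T @ X1
    beta = np.linalg.solve(XtX, X1.T @ y)
    resid = y - X1 @ beta
    sig2 = max(1e-4, 0.05 * float(np.var(resid)))
    D = np.eye(2)
    A = 0.2 * np.eye(q3) if q3 else np.zeros((0, 0))

    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        beta_new, _ = _gls(design, blocks, D, A, sig2)
        mom = _estep(design, blocks, beta_new, D, A, sig2)
        D_new = mom.Eb2b2.mean(axis=0)
        A_new = (
            mom.cov3.mean(axis=0)
            + np.einsum("ki,kj->kij", mom.Eb3, mom.Eb3).mean(axis=0)
            if q3
            else A
        )
        # expected residual sum of squares at the new beta
        r = y - X1 @ beta_new
        rr = np.add.reduceat(r * r, blocks.starts)
        Ztr = np.stack(
            [
                np.add.reduceat(r, blocks.starts),
                np.add.reduceat(r * design.Z2[:, 1], blocks.starts),
            ],
            axis=1,
        )
        ess = rr.sum() - 2 * np.einsum("ni,ni->", Ztr, mom.Eb2) + np.einsum(
            "nij,nij->", blocks.ZtZ, mom.Eb2b2
        )
        if q3:
            z3 = blocks.z3
            ks = data.subj_study
            Eb3_s = mom.Eb3[ks]
            Eb3b3_s = mom.cov3[ks] + np.einsum("ni,nj->nij", Eb3_s, Eb3_s)
            ess += (
                -2 * np.einsum("ni,ni->", z3 * Ztr[:, :1], Eb3_s)
                + 2 * np.einsum("ni,niq,nq->", blocks.Zt1, mom.Eb2b3, z3)
                + np.einsum("n,ni,nij,nj->", blocks.m, z3, Eb3b3_s, z3)
            )
        sig2_new = float(ess / len(y))

        delta = max(
            np.max(np.abs(beta_new - beta)) / max(1.0, np.max(np.abs(beta))),
            np.max(np.abs(D_new - D)) / max(0.1, np.max(np.abs(D))),
            abs(sig2_new - sig2) / max(1e-3, sig2),
        )
        if q3:
            delta = max(delta, np.max(np.abs(A_new - A)) / max(0.1, np.max(np.abs(A))))
        beta, D, A, sig2 = beta_new, D_new, A_new, sig2_new
        if delta < tol:
            converged = True
            break

    beta, cov_beta = _gls(design, blocks, D, A, sig2)
    mom = _estep(design, blocks, beta, D, A, sig2)
    return SeparateLongFit(
        beta1=beta,
        cov_beta1=cov_beta,
        D=D,
        A=A,
        sigma_e2=sig2,
        moments=mom,
        loglik=mom.loglik,
        converged=converged,
        n_iter=n_iter,
        x1_names=design.x1_names,
    )
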