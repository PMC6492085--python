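"""Proportional-hazards machinery: risk sets, Breslow baseline, Newton Cox.

The same risk-set structure serves the separate Cox comparator fit and the
survival part of the joint EM M-step, where each subject contributes an
expected (rather than plugged-in) exponentiated linear predictor.  Ties are
handled by the Breslow approximation, which matches the Breslow-type
baseline-hazard update profiled inside the EM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class StratumRiskSet:
    subjects: np.ndarray  # subject indices sorted by descending T
    T_sorted: np.ndarray  # descending observed times
    event_times: np.ndarray  # unique event times, ascending
    d: np.ndarray  # tied event counts per event time
    n_at_risk: np.ndarray  # number at risk at each event time
    risk_count: np.ndarray  # per event time: #subjects with T >= t (prefix len)
    event_rows: np.ndarray  # subject indices with delta == 1


@dataclass
class RiskSets:
    """Per-stratum risk-set index structure."""

    strata: list  # list of StratumRiskSet
    stratum_of: np.ndarray  # (n,) stratum code per subject

    @classmethod
    def build(cls, T, delta, stratum_of) -> "RiskSets":
        T = np.asarray(T, dtype=float)
        delta = np.asarray(delta)
        stratum_of = np.asarray(stratum_of, dtype=np.intp)
        out = []
        for s in range(int(stratum_of.max()) + 1):
            idx = np.flatnonzero(stratum_of == s)
            order = idx[np.argsort(-T[idx], kind="mergesort")]
            Ts = T[order]
            ev_mask = delta[idx] == 1
            if not ev_mask.any():
                raise ValueError(f"stratum {s} contains no events")
            te, d = np.unique(T[idx][ev_mask], return_counts=True)
            # number of sorted (descending) subjects with T >= te
            risk_count = np.searchsorted(-Ts, -te, side="right")
            out.append(
                StratumRiskSet(
                    subjects=order,
                    T_sorted=Ts,
                    event_times=te,
                    d=d.astype(float),
                    n_at_risk=risk_count.astype(float),
                    risk_count=risk_count,
                    event_rows=idx[ev_mask],
                )
            )
        return cls(strata=out, stratum_of=stratum_of)

    def event_sums(self, values: np.ndarray) -> np.ndarray:
        """Per-stratum risk-set sums of per-subject ``values``.

        Returns a list-aligned concatenation: for each stratum, for each
        unique event time (ascending), the sum of ``values`` over subjects
        still at risk.  ``values`` may be (n,) or (n, p); sums have matching
        trailing dimensions.
        """
        outs = []
        for st in self.strata:
            v = values[st.subjects]
            csum = np.cumsum(v, axis=0)
            outs.append(csum[st.risk_count - 1])
        return outs

    def cumhaz_at_T(self, increments: list, T: np.ndarray) -> np.ndarray:
        """Cumulative baseline hazard at each subject's own time."""
        out = np.zeros(len(T))
        for s, st in enumerate(self.strata):
            idx = st.subjects
            cum = np.cumsum(increments[s])
            pos = np.searchsorted(st.event_times, T[idx], side="right")
            out[idx] = np.where(pos > 0, cum[np.maximum(pos - 1, 0)], 0.0)
        return out


@dataclass
class BaselineHazard:
    """Nonparametric baseline hazard: increments at event times per stratum."""

    strata_labels: list
    event_times: list  # per stratum, ascending
    increments: list  # per stratum, nonnegative

    def cumulative(self, stratum: int, t: np.ndarray) -> np.ndarray:
        cum = np.cumsum(self.increments[stratum])
        pos = np.searchsorted(self.event_times[stratum], t, side="right")
        return np.where(pos > 0, cum[np.maximum(pos - 1, 0)], 0.0)


@dataclass
class SeparateSurvFit:
    """Breslow partial-likelihood Cox fit (the separate survival model)."""

    beta2: np.ndarray
    cov_beta2: np.ndarray
    hazard: BaselineHazard
    loglik: float  # partial log-likelihood
    converged: bool
    n_iter: int
    x2_names: list

    @property
    def se_beta2(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_beta2))


def cox_loglik_parts(risksets: RiskSets, X, beta, delta):
    """Breslow partial log-likelihood, score and information."""
    eta = X @ beta
    w = np.exp(eta - eta.max())
    logshift = eta.max()
    ll = 0.0
    p = X.shape[1]
    score = np.zeros(p)
    info = np.zeros((p, p))
    wX = X * w[:, None]
    wXX = np.einsum("ni,nj->nij", X, wX)
    S0s = risksets.event_sums(w)
    S1s = risksets.event_sums(wX)
    S2s = risksets.event_sums(wXX)
    for st, S0, S1, S2 in zip(risksets.strata, S0s, S1s, S2s):
        ev = st.event_rows
        ll += eta[ev].sum() - np.sum(st.d * (np.log(S0) + logshift))
        xbar = S1 / S0[:, None]
        score += X[ev].sum(axis=0) - (st.d[:, None] * xbar).sum(axis=0)
        info += np.einsum(
            "e,eij->ij", st.d, S2 / S0[:, None, None]
        ) - np.einsum("e,ei,ej->ij", st.d, xbar, xbar)
    return ll, score, info


def breslow_increments(risksets: RiskSets, w: np.ndarray) -> list:
    """Baseline-hazard increments ``d_e / sum_{risk set} w_i`` per stratum."""
    S0s = risksets.event_sums(w)
    return [st.d / S0 for st, S0 in zip(risksets.strata, S0s)]


def fit_cox(
    X2: np.ndarray,
    T: np.ndarray,
    delta: np.ndarray,
    stratum_of: np.ndarray,
    x2_names: list,
    strata_labels: list | None = None,
    tol: float = 1e-9,
    max_iter: int = 50,
) -> SeparateSurvFit:
    """Newton–Raphson Cox fit with Breslow ties and optional stratification."""
    if not np.any(np.asarray(delta) == 1):
        raise ValueError("all subjects censored; cannot fit a survival model")
    risksets = RiskSets.build(T, delta, stratum_of)
    p = X2.shape[1]
    beta = np.zeros(p)
    ll, score, info = cox_loglik_parts(risksets, X2, beta, delta)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        step = np.linalg.solve(info + 1e-12 * np.eye(p), score)
        # step-halving to guarantee ascent
        for _ in range(30):
            cand = beta + step
            ll_new, score_new, info_new = cox_loglik_parts(risksets, X2, cand, delta)
            if ll_new >= ll - 1e-12:
                break
            step = step / 2.0
        beta, ll, score, info = cand, ll_new, score_new, info_new
        if np.max(np.abs(score)) < tol * max(1.0, abs(ll)):
            converged = True
            break
    w = np.exp(X2 @ beta)
    incs = breslow_increments(risksets, w)
    hazard = BaselineHazard(
        strata_labels=strata_labels
        if strata_labels is not None
        else list(range(len(risksets.strata))),
        event_times=[st.event_times.copy() for st in risksets.strata],
        increments=incs,
    )
    cov = np.linalg.inv(info + 1e-12 * np.eye(p))
    return SeparateSurvFit(
        beta2=beta,
        cov_beta2=cov,
        hazard=hazard,
        loglik=ll,
        converged=converged,
        n_iter=n_iter,
        x2_names=x2_names,
    )
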