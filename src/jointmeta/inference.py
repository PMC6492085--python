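"""Standard errors, confidence intervals and study-effect pooling.

With an unspecified baseline hazard, model-based standard errors from joint
fits tend to be underestimated, so bootstrap resampling (subjects within
study) is provided as the preferred SE source.  Model groups with fixed
study-by-treatment interactions yield study-specific treatment effects;
these are combined by DerSimonian–Laird random-effects pooling, mirroring a
random-effects meta-analysis of study-level results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data import MetaJointDataset, validate
from .em import EMControl, fit_joint
from .groups import ModelGroupSpec


def wald_ci(estimate: float, se: float, gamma: float = 0.05):
    """Normal-theory interval ``estimate +/- z_{1-gamma/2} * se``."""
    z = norm.ppf(1 - gamma / 2)
    return estimate - z * se, estimate + z * se


@dataclass
class PooledEffect:
    """DerSimonian–Laird random-effects pooled estimate."""

    estimate: float
    se: float
    tau2: float | None
    k: int
    study_estimates: np.ndarray
    study_ses: np.ndarray
    single_study: bool = False


def pool_study_effects(estimates, ses) -> PooledEffect:
    """Random-effects pooling of study-specific coefficients.

    The between-study variance ``tau^2`` uses the DerSimonian–Laird moment
    estimator truncated at zero; the pooled estimate and SE follow the usual
    inverse-variance rules with weights ``1 / (se^2 + tau^2)``.  A single
    study is returned as-is with ``tau2 = None``.
    """
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    if est.shape != se.shape or est.ndim != 1:
        raise ValueError("estimates and ses must be equal-length 1-d arrays")
    if not np.all(np.isfinite(se)) or np.any(se < 0):
        raise ValueError("all standard errors must be finite and nonnegative")
    k = len(est)
    if k == 0:
        raise ValueError("no study estimates to pool")
    if k == 1:
        return PooledEffect(
            estimate=float(est[0]),
            se=float(se[0]),
            tau2=None,
            k=1,
            study_estimates=est,
            study_ses=se,
            single_study=True,
        )
    w = 1.0 / np.maximum(se**2, 1e-300)
    mu_fixed = np.sum(w * est) / np.sum(w)
    Q = float(np.sum(w * (est - mu_fixed) ** 2))
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (Q - (k - 1)) / max(denom, 1e-300))
    wr = 1.0 / (se**2 + tau2)
    mu = float(np.sum(wr * est) / np.sum(wr))
    return PooledEffect(
        estimate=mu,
        se=float(np.sqrt(1.0 / np.sum(wr))),
        tau2=tau2,
        k=k,
        study_estimates=est,
        study_ses=se,
    )


def study_treatment_effects(beta, cov, names):
    """Study-specific treatment effects from a fit with interactions.

    Returns ``(estimates, ses)`` over studies: the reference study's effect
    is the ``treat`` coefficient itself; a non-reference study's effect is
    ``treat + treat:study[s]``, with the SE from the coefficient covariance.
    """
    beta = np.asarray(beta, dtype=float)
    i0 = names.index("treat")
    idx = [i for i, nm in enumerate(names) if nm.startswith("treat:study[")]
    ests = [beta[i0]]
    ses = [np.sqrt(cov[i0, i0])]
    for i in idx:
        ests.append(beta[i0] + beta[i])
        ses.append(np.sqrt(max(cov[i0, i0] + cov[i, i] + 2 * cov[i0, i], 0.0)))
    return np.asarray(ests), np.asarray(ses)


@dataclass
class BootstrapResult:
    """Bootstrap SEs for joint-model parameters."""

    B: int
    n_failed: int
    estimates: pd.DataFrame  # one row per converged resample
    se: pd.Series  # SD across converged resamples
    ci_lower: pd.Series  # percentile interval
    ci_upper: pd.Series
    unreliable: bool = False


def _param_series(result) -> dict:
    out = {}
    for nm, val in zip(result.x1_names, result.beta1):
        out[f"long:{nm}"] = float(val)
    for nm, val in zip(result.x2_names, result.beta2):
        out[f"surv:{nm}"] = float(val)
    out["alpha2"] = float(result.alpha2)
    if result.alpha3 is not None:
        out["alpha3"] = float(result.alpha3)
    out["sigma_e2"] = float(result.sigma_e2)
    return out


def bootstrap_se(
    dataset: MetaJointDataset,
    spec: ModelGroupSpec,
    control: EMControl | None = None,
    B: int = 100,
    seed: int | None = None,
    resample_studies: bool = False,
) -> BootstrapResult:
    """Nonparametric bootstrap of the joint fit.

    Default resampling unit is the subject within each study — the study
    structure is held fixed, matching the fixed treatment of study
    membership — with ``resample_studies=True`` available as a sensitivity
    analysis (whole studies with replacement).  Failed resample fits are
    counted, not imputed; results are flagged unreliable when more than half
    the resamples fail.
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    dataset = validate(dataset)
    rng = np.random.default_rng(seed)
    rows = []
    n_failed = 0
    studies = dataset.studies
    surv_by_study = {s: g for s, g in dataset.surv.groupby("study")}
    long_ix = dataset.long.set_index(["study", "subject"]).sort_index()
    m_count = dataset.long.groupby(["study", "subject"]).size()
    for _ in range(B):
        chosen_studies = (
            [studies[i] for i in rng.integers(0, len(studies), len(studies))]
            if resample_studies
            else studies
        )
        surv_parts, long_parts = [], []
        for new_k, s in enumerate(chosen_studies):
            g = surv_by_study[s]
            take = rng.integers(0, len(g), len(g))
            new = g.iloc[take].copy()
            keys = list(zip(new["study"], new["subject"]))
            new["study"] = new_k
            new["subject"] = np.arange(len(new))
            surv_parts.append(new)
            lg = long_ix.loc[keys].reset_index()
            counts = [int(m_count[k]) for k in keys]
            lg["study"] = new_k
            lg["subject"] = np.repeat(np.arange(len(new)), counts)
            long_parts.append(lg)
        bs = MetaJointDataset(
            long=pd.concat(long_parts, ignore_index=True),
            surv=pd.concat(surv_parts, ignore_index=True),
        )
        try:
            res = fit_joint(validate(bs), spec, control)
        except Exception:  # structural failure counts as a failed resample
            n_failed += 1
            continue
        if not res.converged:
            n_failed += 1
            continue
        rows.append(_param_series(res))
    est = pd.DataFrame(rows)
    if len(est) == 0:
        raise RuntimeError("all bootstrap resamples failed")
    se = est.std(ddof=1)
    return BootstrapResult(
        B=B,
        n_failed=n_failed,
        estimates=est,
        se=se,
        ci_lower=est.quantile(0.025),
        ci_upper=est.quantile(0.975),
        unreliable=n_failed > B / 2,
    )
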