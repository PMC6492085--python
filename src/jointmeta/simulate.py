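"""Multi-study joint data simulator.

Generates datasets with a continuous longitudinal outcome following a linear
mixed model (individual random intercept + slope, study-level random
intercept and/or treatment effect) and an event time whose hazard is a
Gompertz baseline multiplied by ``exp(beta21*treat + alpha2*(b0 + b1*t) +
alpha3*z3'b3)``.  Because the individual random slope enters the log hazard
linearly in time, the cumulative hazard inverts in closed form, giving exact
event-time draws from a single uniform per subject.  Censoring is
exponential, and longitudinal measurements are truncated at the observed
survival time, so dropout is informative whenever the association parameters
are non-zero.

When the effective Gompertz shape ``theta1 + alpha2*b1`` is negative the
subject's hazard decays fast enough that the event may never occur; such
"cured" subjects receive an infinite latent event time and always resolve to
censoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .data import MetaJointDataset

EULER_GAMMA = float(np.euler_gamma)

#: measurement grid used by all shipped scenarios
DEFAULT_MEAS_TIMES = (0.0, 0.25, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)


@dataclass(frozen=True)
class GompertzParams:
    """Gompertz event-time parameters derived from target moments.

    ``theta1`` is the shape and ``exp(theta0)`` the scale of the baseline
    hazard ``lambda0(t) = exp(theta0 + theta1 * t)``.
    """

    mu0: float
    sigma0: float
    theta1: float
    theta0: float


def gompertz_from_moments(mu0: float, sigma0: float) -> GompertzParams:
    """Calibrate Gompertz parameters to a target event-time mean and SD.

    Uses the extreme-value (Gumbel) correspondence: ``theta1 =
    pi / (sigma0 * sqrt(6))`` and ``theta0 = log(theta1) - gamma -
    mu0 * theta1`` with Euler's constant ``gamma``.  The resulting
    distribution has mean ``mu0`` and standard deviation ``sigma0`` up to the
    (here negligible) mass the Gumbel approximation places at negative times.
    """
    if sigma0 <= 0:
        raise ValueError("sigma0 must be positive")
    theta1 = math.pi / (sigma0 * math.sqrt(6.0))
    theta0 = math.log(theta1) - EULER_GAMMA - mu0 * theta1
    return GompertzParams(mu0=mu0, sigma0=sigma0, theta1=theta1, theta0=theta0)


@dataclass
class SimulationScenario:
    """Full parameter set for one simulated multi-study joint dataset.

    Defaults are the shared constants of the simulation design: five studies
    of 500 subjects randomized 1:1, ten scheduled measurements on
    ``0..4``, fixed effects ``beta10=1, beta11=3, beta12=2, beta21=3``,
    individual random-effect covariance ``D = [[1, .5], [.5, 1.5]]``,
    residual variance 0.01, event times calibrated to mean 3 / SD 0.5 and
    exponential censoring with rate ``exp(-0.426)`` (tuned to a ~25% event
    rate).
    """

    K: int = 5
    n_per_study: int = 500
    meas_times: tuple = DEFAULT_MEAS_TIMES
    beta10: float = 1.0
    beta11: float = 3.0
    beta12: float = 2.0
    beta21: float = 3.0
    D: tuple = ((1.0, 0.5), (0.5, 1.5))
    A: tuple = ((1.0, 0.5), (0.5, 1.5))
    alpha2: float = 0.5
    alpha3: float = 0.5
    sigma_e2: float = 0.01
    mu0: float = 3.0
    sigma0: float = 0.5
    lambda_cens: float = math.exp(-0.426)
    cure_condition: str = "full"
    name: str = ""

    def __post_init__(self):
        D = np.asarray(self.D, dtype=float)
        A = np.asarray(self.A, dtype=float)
        for M, nm in ((D, "D"), (A, "A")):
            if M.shape != (2, 2) or not np.allclose(M, M.T):
                raise ValueError(f"{nm} must be a symmetric 2x2 matrix")
            if np.linalg.eigvalsh(M).min() < -1e-10:
                raise ValueError(f"{nm} must be positive semidefinite")
        t = np.asarray(self.meas_times, dtype=float)
        if t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValueError("meas_times must be strictly increasing from 0")
        if self.cure_condition not in ("full", "intercept-only"):
            raise ValueError("cure_condition must be 'full' or 'intercept-only'")

    @property
    def gompertz(self) -> GompertzParams:
        return gompertz_from_moments(self.mu0, self.sigma0)

    # -- YAML round trip ---------------------------------------------------
    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["D"] = np.asarray(self.D, dtype=float).tolist()
        d["A"] = np.asarray(self.A, dtype=float).tolist()
        d["meas_times"] = list(self.meas_times)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationScenario":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("D", "A"):
            if key in d:
                d[key] = tuple(tuple(row) for row in d[key])
        if "meas_times" in d:
            d["meas_times"] = tuple(d["meas_times"])
        return cls(**d)


def _psd_sqrt(M: np.ndarray) -> np.ndarray:
    """Symmetric square root of a PSD matrix (handles singular M)."""
    w, V = np.linalg.eigh(np.asarray(M, dtype=float))
    return (V * np.sqrt(np.maximum(w, 0.0))) @ V.T


def simulate_censoring(U, lambda_cens: float):
    """Exponential censoring times ``-log(U)/lambda_cens``."""
    U = np.asarray(U, dtype=float)
    if lambda_cens <= 0:
        raise ValueError("lambda_cens must be positive")
    if np.any((U <= 0) | (U >= 1)):
        raise ValueError("U must lie in (0, 1)")
    return -np.log(U) / lambda_cens


def simulate_event_time(
    U,
    treat,
    b2,
    b3_contrib,
    params: GompertzParams,
    beta21: float = 0.0,
    alpha2: float = 0.0,
    cure_condition: str = "full",
):
    """Invert the cumulative hazard to draw latent event times.

    Parameters
    ----------
    U : array (n,)
        Uniform(0, 1) draws, one per subject.
    treat : array (n,)
        Binary arm indicators.
    b2 : array (n, 2)
        Individual random intercepts and slopes.
    b3_contrib : array (n,)
        The study-level association offset ``alpha3 * z3'b3`` per subject
        (zero when no study-level random effects are shared).
    params : GompertzParams
    beta21, alpha2 : float
        Treatment log-hazard ratio and individual-level association.
    cure_condition : {"full", "intercept-only"}
        Linear predictor used inside the cure-probability check.  ``full``
        uses the entire time-constant log-hazard offset (internally
        consistent with the inversion formula and the default);
        ``intercept-only`` uses only ``theta0 + alpha2*b0``.

    Returns
    -------
    array (n,)
        Event times; cured subjects get ``numpy.inf``.
    """
    U = np.asarray(U, dtype=float)
    treat = np.asarray(treat, dtype=float)
    b2 = np.atleast_2d(np.asarray(b2, dtype=float))
    b3_contrib = np.broadcast_to(np.asarray(b3_contrib, dtype=float), U.shape)
    if np.any((U <= 0) | (U >= 1)):
        raise ValueError("U must lie in (0, 1)")

    c = params.theta1 + alpha2 * b2[:, 1]  # effective Gompertz shape
    eta = params.theta0 + beta21 * treat + alpha2 * b2[:, 0] + b3_contrib
    if cure_condition == "full":
        eta_cure = eta
    elif cure_condition == "intercept-only":
        eta_cure = params.theta0 + alpha2 * b2[:, 0]
    else:
        raise ValueError("cure_condition must be 'full' or 'intercept-only'")

    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        cured = (c < 0) & (U < np.exp(np.exp(eta_cure) / c))
        arg = 1.0 + c * (-np.log(U)) / np.exp(eta)
        T = np.where(np.abs(c) < 1e-12, -np.log(U) / np.exp(eta), np.log(arg) / c)
    T = np.where(cured, np.inf, T)
    bad = ~cured & ~np.isfinite(T)
    if np.any(bad):
        raise FloatingPointError(
            f"{int(bad.sum())} event time(s) undefined: the cure condition "
            "failed to flag a non-positive log argument"
        )
    return T


def simulate_dataset(
    scenario: SimulationScenario,
    seed=None,
    rng: np.random.Generator | None = None,
    return_truth: bool = False,
):
    """Simulate one multi-study joint dataset under ``scenario``.

    Per study ``k``: draw study random effects ``b3_k ~ N(0, A)`` (design
    ``[1, treat]``); per subject: ``b2 ~ N(0, D)``, an exact 1:1 randomized
    arm, latent event time from :func:`simulate_event_time`, exponential
    censoring from :func:`simulate_censoring`.  The observed survival time is
    the minimum, with ``status = 1`` iff the event came first, and
    longitudinal records are kept only at scheduled times ``<= survtime``.

    Returns the dataset, plus a per-subject truth table (drawn random
    effects, latent times) when ``return_truth`` is set.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    gomp = scenario.gompertz
    K, n = scenario.K, scenario.n_per_study
    D = np.asarray(scenario.D, dtype=float)
    A = np.asarray(scenario.A, dtype=float)
    times = np.asarray(scenario.meas_times, dtype=float)
    ntot = K * n

    b3 = rng.standard_normal((K, 2)) @ _psd_sqrt(A).T
    b2 = rng.standard_normal((ntot, 2)) @ _psd_sqrt(D).T

    # exact 1:1 allocation within each study, order randomized
    treat = np.empty(ntot)
    base = np.zeros(n)
    base[: n // 2] = 1.0
    if n % 2:
        base[n // 2] = rng.integers(0, 2)
    for k in range(K):
        treat[k * n : (k + 1) * n] = rng.permutation(base)

    study = np.repeat(np.arange(K), n)
    z3b3 = b3[study, 0] + b3[study, 1] * treat  # study-level linear predictor

    U_event = rng.uniform(size=ntot)
    U_cens = rng.uniform(size=ntot)
    TE = simulate_event_time(
        U_event,
        treat,
        b2,
        scenario.alpha3 * z3b3,
        gomp,
        beta21=scenario.beta21,
        alpha2=scenario.alpha2,
        cure_condition=scenario.cure_condition,
    )
    TC = simulate_censoring(U_cens, scenario.lambda_cens)
    TS = np.minimum(TE, TC)
    delta = (TE <= TC).astype(int)

    # longitudinal records at scheduled times up to the survival time
    keep = times[None, :] <= TS[:, None]  # (ntot, n_times)
    subj_rep, time_idx = np.nonzero(keep)
    t_long = times[time_idx]
    eps = rng.normal(scale=math.sqrt(scenario.sigma_e2), size=len(t_long))
    y = (
        scenario.beta10
        + scenario.beta11 * t_long
        + scenario.beta12 * treat[subj_rep]
        + b2[subj_rep, 0]
        + b2[subj_rep, 1] * t_long
        + z3b3[subj_rep]
        + eps
    )

    study_label = study + 1
    subject_label = np.tile(np.arange(1, n + 1), K)
    long = pd.DataFrame(
        {
            "study": study_label[subj_rep],
            "subject": subject_label[subj_rep],
            "time": t_long,
            "y": y,
            "treat": treat[subj_rep].astype(int),
        }
    )
    surv = pd.DataFrame(
        {
            "study": study_label,
            "subject": subject_label,
            "survtime": TS,
            "status": delta,
            "treat": treat.astype(int),
        }
    )
    dataset = MetaJointDataset(long=long, surv=surv, validated=True)
    if not return_truth:
        return dataset
    truth = pd.DataFrame(
        {
            "study": study_label,
            "subject": subject_label,
            "b0_subj": b2[:, 0],
            "b1_subj": b2[:, 1],
            "b0_study": b3[study, 0],
            "b1_study": b3[study, 1],
            "T_event": TE,
            "T_cens": TC,
        }
    )
    return dataset, truth
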