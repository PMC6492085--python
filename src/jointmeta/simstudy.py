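"""Simulation-study harness: scenario grids, repeated fits, summary tables.

Three scenario sets probe the model groups from different angles: Set 1
varies the association parameters (``alpha2, alpha3`` over {0, 0.5, 1}^2 at
five studies), Set 2 the number of studies (5, 10, 15 at ``alpha2 = alpha3
= 0.5``) and Set 3 the level of between-study heterogeneity (study
random-effect covariance ``A1 = 0``, ``A2``, ``A3`` at five studies).  All
other parameters are the shared constants of
:class:`~jointmeta.simulate.SimulationScenario`.

Results are summarised per scenario x model group x parameter as the mean
estimate across replicates, the empirical SE (SD of estimates between
replicates) and the coverage of nominal Wald intervals, rendered in the
``mean (SE) [coverage%]`` cell format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy.stats import norm

from .em import EMControl, fit_joint
from .groups import build_spec
from .inference import pool_study_effects, study_treatment_effects
from .simulate import SimulationScenario, simulate_dataset

#: heterogeneity matrices of the Set-3 scenarios
A_MATRICES = {
    "A1": ((0.0, 0.0), (0.0, 0.0)),
    "A2": ((1.0, 0.5), (0.5, 1.5)),
    "A3": ((2.0, 1.0), (1.0, 3.0)),
}


def coverage(estimates, ses, truth, gamma: float = 0.05) -> float:
    """Fraction of Wald intervals ``est +/- z * se`` containing ``truth``."""
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    if est.shape != se.shape:
        raise ValueError("estimates and ses must have equal length")
    z = norm.ppf(1 - gamma / 2)
    return float(np.mean(np.abs(est - truth) <= z * se))


@dataclass
class ScenarioGrid:
    """The scenarios of one simulation set."""

    set_id: int
    scenarios: list  # (name, SimulationScenario) pairs

    @classmethod
    def build(cls, set_id: int) -> "ScenarioGrid":
        if set_id == 1:
            scen = [
                (
                    f"set1_a2-{a2:g}_a3-{a3:g}",
                    SimulationScenario(
                        alpha2=a2, alpha3=a3, name=f"set1_a2-{a2:g}_a3-{a3:g}"
                    ),
                )
                for a2, a3 in product((0.0, 0.5, 1.0), repeat=2)
            ]
        elif set_id == 2:
            scen = [
                (f"set2_K-{K}", SimulationScenario(K=K, name=f"set2_K-{K}"))
                for K in (5, 10, 15)
            ]
        elif set_id == 3:
            scen = [
                (
                    f"set3_A-{nm}",
                    SimulationScenario(A=A, name=f"set3_A-{nm}"),
                )
                for nm, A in A_MATRICES.items()
            ]
        else:
            raise ValueError("set_id must be 1, 2 or 3")
        return cls(set_id=set_id, scenarios=scen)


def _truths(scenario: SimulationScenario) -> dict:
    return {
        "beta12": scenario.beta12,
        "beta21": scenario.beta21,
        "alpha2": scenario.alpha2,
        "alpha3": scenario.alpha3,
    }


def _replicate_records(scenario, name, rep, group, result) -> list:
    """Flat per-replicate estimate records for one fitted model group."""
    rows = []

    def add(param, model, est, se):
        rows.append(
            {
                "scenario": name,
                "rep": rep,
                "group": group,
                "param": param,
                "model": model,
                "estimate": float(est),
                "se": float(se),
            }
        )

    lf, sf = result.separate_long, result.separate_surv
    spec = result.spec

    # longitudinal treatment effect (study-specific -> DL-pooled)
    if spec.fixed_study_interact_long:
        e, s = study_treatment_effects(lf.beta1, lf.cov_beta1, lf.x1_names)
        pooled = pool_study_effects(e, s)
        add("beta12", "separate", pooled.estimate, pooled.se)
        e, s = study_treatment_effects(result.beta1, result.cov_beta1, result.x1_names)
        pooled = pool_study_effects(e, s)
        add("beta12", "joint", pooled.estimate, pooled.se)
    else:
        i = lf.x1_names.index("treat")
        add("beta12", "separate", lf.beta1[i], lf.se_beta1[i])
        add("beta12", "joint", result.beta1[i], result.se_beta1[i])

    # time-to-event treatment effect
    if spec.fixed_study_interact_surv:
        e, s = study_treatment_effects(sf.beta2, sf.cov_beta2, sf.x2_names)
        pooled = pool_study_effects(e, s)
        add("beta21", "separate", pooled.estimate, pooled.se)
        e, s = study_treatment_effects(
            result.beta2, result.cov_psi[: len(result.beta2), : len(result.beta2)],
            result.x2_names,
        )
        pooled = pool_study_effects(e, s)
        add("beta21", "joint", pooled.estimate, pooled.se)
    else:
        i = sf.x2_names.index("treat")
        add("beta21", "separate", sf.beta2[i], sf.se_beta2[i])
        add("beta21", "joint", result.beta2[i], result.se_psi[i])

    ia = result.psi_names.index("alpha2")
    add("alpha2", "joint", result.alpha2, result.se_psi[ia])
    if result.alpha3 is not None and "alpha3" in result.psi_names:
        ia3 = result.psi_names.index("alpha3")
        add("alpha3", "joint", result.alpha3, result.se_psi[ia3])
    return rows


def run_scenario(
    scenario: SimulationScenario,
    groups=(0, 1, 2, 3, 4, 5),
    n_replicates: int = 100,
    seed: int = 0,
    control: EMControl | None = None,
    name: str | None = None,
) -> pd.DataFrame:
    """Simulate ``n_replicates`` datasets and fit the requested model groups.

    Returns a tidy per-replicate table of estimates and model-based SEs;
    failed fits are recorded with ``NaN`` estimates and excluded from
    summaries (but counted).  Deterministic given ``seed``: per-replicate
    seeds are spawned from the master seed by a fixed rule.
    """
    name = name or scenario.name or "scenario"
    children = np.random.SeedSequence(seed).spawn(n_replicates)
    rows = []
    for rep, child in enumerate(children):
        ds = simulate_dataset(scenario, rng=np.random.default_rng(child))
        for g in groups:
            res = fit_joint(ds, build_spec(g), control)
            if res.converged:
                rows.extend(_replicate_records(scenario, name, rep, g, res))
            else:
                rows.append(
                    {
                        "scenario": name,
                        "rep": rep,
                        "group": g,
                        "param": "beta21",
                        "model": "joint",
                        "estimate": np.nan,
                        "se": np.nan,
                    }
                )
    df = pd.DataFrame(rows)
    df["truth"] = df["param"].map(_truths(scenario))
    return df


@dataclass
class SimSummaryRow:
    """One cell of a simulation summary table."""

    scenario: str
    group: int
    param: str
    model: str
    n_success: int
    mean: float
    emp_se: float
    coverage: float
    truth: float

    def render(self) -> str:
        if np.isnan(self.emp_se):
            return f"{self.mean:.2f} (NA) [{100 * self.coverage:.1f}]"
        return f"{self.mean:.2f} ({self.emp_se:.2f}) [{100 * self.coverage:.1f}]"


def summarize(records: pd.DataFrame, gamma: float = 0.05) -> pd.DataFrame:
    """Aggregate per-replicate records into mean / empirical-SE / coverage."""
    if len(records) == 0:
        return pd.DataFrame(
            columns=[
                "scenario",
                "group",
                "param",
                "model",
                "n_success",
                "mean",
                "emp_se",
                "coverage",
                "truth",
                "cell",
            ]
        )
    out = []
    for (scen, g, param, model), sub in records.groupby(
        ["scenario", "group", "param", "model"], sort=True
    ):
        ok = sub.dropna(subset=["estimate"])
        truth = float(sub["truth"].iloc[0]) if np.isfinite(sub["truth"].iloc[0]) else np.nan
        if len(ok) == 0:
            continue
        row = SimSummaryRow(
            scenario=scen,
            group=int(g),
            param=param,
            model=model,
            n_success=int(len(ok)),
            mean=float(ok["estimate"].mean()),
            emp_se=float(ok["estimate"].std(ddof=1)) if len(ok) > 1 else np.nan,
            coverage=coverage(ok["estimate"], ok["se"], truth, gamma),
            truth=truth,
        )
        out.append(
            {
                **row.__dict__,
                "cell": row.render(),
            }
        )
    return pd.DataFrame(out)


def parse_cell(cell: str):
    """Inverse of :meth:`SimSummaryRow.render` (2/2/1 decimal places)."""
    mean, rest = cell.split(" (", 1)
    se, cov = rest.split(") [", 1)
    return (
        float(mean),
        np.nan if se == "NA" else float(se),
        float(cov.rstrip("]")) / 100.0,
    )
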