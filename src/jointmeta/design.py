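"""Design matrices for the two sub-models and the association structure.

Fixed-effect columns are ordered: intercept, time, treatment, study dummies,
treat-by-study interactions, extra time bases (longitudinal); treatment,
study dummies, treat-by-study (survival).  Study dummies use
treatment-contrast (reference) coding with a configurable reference study.

The association design evaluates the individual random-effect basis at the
subject's observed survival time ``T_S`` (the time substitution that makes
the shared-random-effect hazard offset time-constant) and the study-level
basis per subject.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import IndexedData, MetaJointDataset, index_dataset
from .groups import ModelGroupSpec


@dataclass
class DesignBundle:
    """All matrices needed to fit one model group on one dataset."""

    spec: ModelGroupSpec
    data: IndexedData
    X1: np.ndarray  # (N, p1) longitudinal fixed effects
    Z2: np.ndarray  # (N, 2) individual RE design [1, t]
    X2: np.ndarray  # (n, p2) survival fixed effects
    Z2_T: np.ndarray  # (n, 2) individual RE basis at T_S
    Z3_subj: np.ndarray  # (n, q3) study-level RE design per subject
    strata: np.ndarray  # (n,) hazard stratum per subject (all 0 if common)
    x1_names: list
    x2_names: list
    z3_names: list
    reference_study: object

    @property
    def Z3_obs(self) -> np.ndarray:
        """Study-level RE design expanded to longitudinal rows."""
        return self.Z3_subj[self.data.obs_subject]

    @property
    def n_strata(self) -> int:
        return int(self.strata.max()) + 1 if len(self.strata) else 0


def dummy_code(study_codes: np.ndarray, K: int, ref: int):
    """Indicator columns for all non-reference studies.

    Columns follow sorted study order with the reference study skipped; row
    sums are 0 (reference membership) or 1.
    """
    cols = [k for k in range(K) if k != ref]
    out = np.zeros((len(study_codes), len(cols)))
    for j, k in enumerate(cols):
        out[:, j] = study_codes == k
    return out, cols


def build_design(
    dataset: MetaJointDataset | IndexedData, spec: ModelGroupSpec
) -> DesignBundle:
    """Build the :class:`DesignBundle` for ``spec`` on a validated dataset."""
    data = dataset if isinstance(dataset, IndexedData) else index_dataset(dataset)
    K = data.K
    labels = data.study_labels
    if spec.reference_study is None:
        ref = 0
    else:
        if spec.reference_study not in labels:
            raise ValueError(
                f"reference study {spec.reference_study!r} not present in data"
            )
        ref = labels.index(spec.reference_study)

    if np.bincount(data.subj_study, minlength=K).min() == 0:
        raise ValueError("every study must contain at least one subject")

    obs_study = data.subj_study[data.obs_subject]
    obs_treat = data.treat[data.obs_subject]
    nonref = [labels[k] for k in range(K) if k != ref]

    # longitudinal fixed effects
    cols = [np.ones_like(data.t_obs), data.t_obs, obs_treat]
    names = ["intercept", "time", "treat"]
    if spec.fixed_study_long and K > 1:
        dum, _ = dummy_code(obs_study, K, ref)
        cols.extend(dum.T)
        names.extend(f"study[{s}]" for s in nonref)
    if spec.fixed_study_interact_long and K > 1:
        dum, _ = dummy_code(obs_study, K, ref)
        cols.extend((dum * obs_treat[:, None]).T)
        names.extend(f"treat:study[{s}]" for s in nonref)
    for basis_name, fn in spec.extra_long_basis:
        cols.append(np.asarray(fn(data.t_obs), dtype=float))
        names.append(basis_name)
    X1 = np.column_stack(cols)

    Z2 = np.column_stack([np.ones_like(data.t_obs), data.t_obs])

    # survival fixed effects
    cols2 = [data.treat]
    names2 = ["treat"]
    if spec.fixed_study_surv and K > 1:
        dum, _ = dummy_code(data.subj_study, K, ref)
        cols2.extend(dum.T)
        names2.extend(f"study[{s}]" for s in nonref)
    if spec.fixed_study_interact_surv and K > 1:
        dum, _ = dummy_code(data.subj_study, K, ref)
        cols2.extend((dum * data.treat[:, None]).T)
        names2.extend(f"treat:study[{s}]" for s in nonref)
    X2 = np.column_stack(cols2)

    Z2_T = np.column_stack([np.ones_like(data.T), data.T])

    z3_cols = []
    z3_names = []
    if "intercept" in spec.study_re:
        z3_cols.append(np.ones_like(data.treat))
        z3_names.append("intercept")
    if "treatment" in spec.study_re:
        z3_cols.append(data.treat)
        z3_names.append("treatment")
    Z3_subj = (
        np.column_stack(z3_cols) if z3_cols else np.zeros((data.n, 0))
    )

    strata = (
        data.subj_study.copy() if spec.stratified_hazard else np.zeros(data.n, dtype=np.intp)
    )

    return DesignBundle(
        spec=spec,
        data=data,
        X1=X1,
        Z2=Z2,
        X2=X2,
        Z2_T=Z2_T,
        Z3_subj=Z3_subj,
        strata=strata,
        x1_names=names,
        x2_names=names2,
        z3_names=z3_names,
        reference_study=labels[ref],
    )
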