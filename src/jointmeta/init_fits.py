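"""Separate one-stage longitudinal and survival comparator fits.

These models have the same fixed- and random-effect specification as the
corresponding joint sub-models but omit the shared-random-effect association
term.  They serve two purposes: as standalone comparators (the "separate
model" columns of the simulation summaries) and as the source of EM starting
values and pseudo-adaptive quadrature centring for the joint fit.
"""

from __future__ import annotations

from ._lmm import SeparateLongFit, fit_lmm
from ._surv import SeparateSurvFit, fit_cox
from .data import MetaJointDataset
from .design import DesignBundle, build_design
from .groups import ModelGroupSpec

__all__ = [
    "SeparateLongFit",
    "SeparateSurvFit",
    "fit_separate_longitudinal",
    "fit_separate_survival",
]


def _as_design(dataset, spec) -> DesignBundle:
    if isinstance(dataset, DesignBundle):
        return dataset
    return build_design(dataset, spec)


def fit_separate_longitudinal(
    dataset: MetaJointDataset | DesignBundle,
    spec: ModelGroupSpec | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> SeparateLongFit:
    """ML fit of the separate longitudinal linear mixed model.

    Individual random effects are always intercept + slope with an
    unstructured 2x2 covariance ``D``; study-level random effects follow the
    spec.  Returns estimates together with the conditional modes and
    covariances of the random effects at every level (the pseudo-adaptive
    quadrature centring).  ML rather than REML, since the estimates seed an
    ML EM algorithm.
    """
    return fit_lmm(_as_design(dataset, spec), tol=tol, max_iter=max_iter)


def fit_separate_survival(
    dataset: MetaJointDataset | DesignBundle,
    spec: ModelGroupSpec | None = None,
) -> SeparateSurvFit:
    """Breslow partial-likelihood Cox fit of the separate survival model.

    Stratified by study when the spec says so.  Any study-level terms
    carried solely by the association structure in the joint model vanish
    here entirely.
    """
    design = _as_design(dataset, spec)
    return fit_cox(
        design.X2,
        design.data.T,
        design.data.delta,
        design.strata,
        design.x2_names,
        strata_labels=(
            design.data.study_labels if design.spec.stratified_hazard else ["all"]
        ),
    )
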