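"""Model-group specifications.

Six model groups are supported, differing only in how they account for
between-study heterogeneity:

====== ==============================================================
group  heterogeneity handling
====== ==============================================================
0      none (naive pooling)
1      fixed study + treat-by-study terms in both sub-models
2      fixed study main effects in both sub-models, study-level
       random treatment effect (shared through the association)
3      study-level random intercept + random treatment effect only
4      fixed study + treat-by-study in the longitudinal sub-model,
       baseline hazard stratified by study
5      fixed study main effect in the longitudinal sub-model,
       study-level random treatment effect, stratified hazard
====== ==============================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Sequence

#: allowed study-level random-effect terms, in design-column order
STUDY_RE_TERMS = ("intercept", "treatment")


@dataclass(frozen=True)
class ModelGroupSpec:
    """Declarative description of one model group.

    ``study_re`` lists the study-level random effects (subset of
    ``("intercept", "treatment")``) shared between the sub-models through the
    association structure.  ``extra_long_basis`` holds optional extra fixed
    longitudinal basis functions of time, given as ``(name, callable)``
    pairs (for example a decaying-exponential change-point term).
    """

    group: int
    fixed_study_long: bool = False
    fixed_study_interact_long: bool = False
    fixed_study_surv: bool = False
    fixed_study_interact_surv: bool = False
    study_re: tuple = ()
    stratified_hazard: bool = False
    reference_study: Hashable | None = None
    extra_long_basis: tuple = field(default_factory=tuple)

    @property
    def q3(self) -> int:
        """Dimension of the study-level random effects."""
        return len(self.study_re)

    @property
    def has_study_re(self) -> bool:
        return self.q3 > 0


_GROUP_FLAGS = {
    0: dict(),
    1: dict(
        fixed_study_long=True,
        fixed_study_interact_long=True,
        fixed_study_surv=True,
        fixed_study_interact_surv=True,
    ),
    2: dict(
        fixed_study_long=True,
        fixed_study_surv=True,
        study_re=("treatment",),
    ),
    3: dict(study_re=("intercept", "treatment")),
    4: dict(
        fixed_study_long=True,
        fixed_study_interact_long=True,
        stratified_hazard=True,
    ),
    5: dict(
        fixed_study_long=True,
        study_re=("treatment",),
        stratified_hazard=True,
    ),
}


def build_spec(
    group: int,
    reference_study: Hashable | None = None,
    extra_long_basis: Sequence = (),
) -> ModelGroupSpec:
    """Return the :class:`ModelGroupSpec` for ``group`` (0-5).

    ``reference_study`` names the study absorbed into the intercept when
    fixed study terms are present; it defaults (at design-build time) to the
    first study in sorted-label order.
    """
    if group not in _GROUP_FLAGS:
        raise ValueError(f"unknown model group {group!r}; expected 0..5")
    flags = dict(_GROUP_FLAGS[group])
    for term in flags.get("study_re", ()):
        if term not in STUDY_RE_TERMS:  # pragma: no cover - internal table
            raise ValueError(f"unknown study-level random effect {term!r}")
    return ModelGroupSpec(
        group=group,
        reference_study=reference_study,
        extra_long_basis=tuple(extra_long_basis),
        **flags,
    )
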