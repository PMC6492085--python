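"""Shared data model for multi-study joint longitudinal and time-to-event data.

A meta-analytic joint dataset has three nested levels: repeated longitudinal
measurements (level 1) within individuals (level 2) within studies (level 3).
The container pairs a long-format longitudinal table with a one-row-per-subject
survival table and enforces the consistency rules the models rely on, most
importantly that longitudinal records never extend past a subject's observed
survival time.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LONG_COLUMNS = ["study", "subject", "time", "y", "treat"]
SURV_COLUMNS = ["study", "subject", "survtime", "status", "treat"]


class DataError(ValueError):
    """Raised when a dataset violates a structural invariant."""


@dataclass
class MetaJointDataset:
    """Multi-study joint dataset.

    Parameters
    ----------
    long : pandas.DataFrame
        Long-format longitudinal table with columns
        ``study, subject, time, y, treat``. ``time`` is a nonnegative
        measurement time in the same unit as the survival times, ``y`` the
        continuous outcome and ``treat`` a binary (0/1) arm indicator.
    surv : pandas.DataFrame
        Per-subject survival table with columns
        ``study, subject, survtime, status, treat``; ``survtime`` is the
        observed time (minimum of event and censoring time) and ``status``
        the event indicator (1 = event, 0 = censored).
    validated : bool
        Set by :func:`validate`; fitting functions require a validated
        dataset.
    """

    long: pd.DataFrame
    surv: pd.DataFrame
    validated: bool = field(default=False, compare=False)

    # -- descriptive properties -------------------------------------------
    @property
    def studies(self) -> list:
        """Sorted study labels."""
        return sorted(self.surv["study"].unique().tolist())

    @property
    def K(self) -> int:
        """Number of studies."""
        return self.surv["study"].nunique()

    @property
    def n_k(self) -> pd.Series:
        """Number of subjects per study."""
        return self.surv.groupby("study").size()

    @property
    def n_subjects(self) -> int:
        return len(self.surv)

    @property
    def m_ki(self) -> pd.Series:
        """Number of longitudinal measurements per (study, subject)."""
        return self.long.groupby(["study", "subject"]).size()

    @property
    def event_rate(self) -> float:
        """Fraction of subjects experiencing the event."""
        return float(self.surv["status"].mean())

    # -- IO ----------------------------------------------------------------
    @classmethod
    def from_csv(cls, long_path, surv_path) -> "MetaJointDataset":
        """Read the two tables from CSV files (header row mandatory)."""
        long = pd.read_csv(long_path)
        surv = pd.read_csv(surv_path)
        return cls(long=long, surv=surv)

    def to_csv(self, long_path, surv_path) -> None:
        self.long.to_csv(long_path, index=False)
        self.surv.to_csv(surv_path, index=False)


def _require_columns(df: pd.DataFrame, cols, name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DataError(f"{name} table is missing columns {missing}")


def validate(dataset: MetaJointDataset) -> MetaJointDataset:
    """Validate a :class:`MetaJointDataset` and return a cleaned copy.

    Enforces all structural invariants:

    * both tables have the required columns; the longitudinal table is
      non-empty;
    * ``treat`` is 0/1 and constant within subject, measurement times are
      nonnegative, survival times nonnegative, ``status`` is 0/1;
    * exactly one survival record per (study, subject), and every subject in
      the longitudinal table appears in the survival table;
    * (study, subject, time) is unique.

    Longitudinal records with ``time`` strictly greater than the subject's
    survival time are dropped with a warning: only measurements recorded
    prior to (or at) the survival time carry information, because dropout at
    the event/censoring time is part of the model.

    The operation is idempotent: validating a validated dataset returns an
    equal dataset.
    """
    long = dataset.long.copy()
    surv = dataset.surv.copy()
    _require_columns(long, LONG_COLUMNS, "longitudinal")
    _require_columns(surv, SURV_COLUMNS, "survival")

    if len(long) == 0:
        raise DataError("longitudinal table is empty; nothing to fit")
    if len(surv) == 0:
        raise DataError("survival table is empty; nothing to fit")

    if surv.duplicated(["study", "subject"]).any():
        dups = surv[surv.duplicated(["study", "subject"], keep=False)]
        raise DataError(
            "duplicate survival records for "
            f"{dups[['study', 'subject']].drop_duplicates().values.tolist()}"
        )

    for df, name in ((long, "longitudinal"), (surv, "survival")):
        if not df["treat"].isin([0, 1]).all():
            raise DataError(f"{name} treat must be binary 0/1")
    if (long["time"] < 0).any():
        raise DataError("measurement times must be nonnegative")
    if (surv["survtime"] < 0).any():
        raise DataError("survival times must be nonnegative")
    if not surv["status"].isin([0, 1]).all():
        raise DataError("status must be binary 0/1")
    if long.duplicated(["study", "subject", "time"]).any():
        raise DataError("duplicate (study, subject, time) longitudinal records")

    # every longitudinal subject must have a survival record
    merged = long.merge(
        surv[["study", "subject", "survtime", "treat"]],
        on=["study", "subject"],
        how="left",
        suffixes=("", "_surv"),
    )
    if merged["survtime"].isna().any():
        orphans = (
            merged.loc[merged["survtime"].isna(), ["study", "subject"]]
            .drop_duplicates()
            .values.tolist()
        )
        raise DataError(f"longitudinal subjects missing from survival table: {orphans}")
    if (merged["treat"] != merged["treat_surv"]).any():
        raise DataError("treat differs between longitudinal and survival tables")

    # truncate longitudinal follow-up at the survival time
    keep = merged["time"].to_numpy() <= merged["survtime"].to_numpy()
    n_drop = int((~keep).sum())
    if n_drop:
        warnings.warn(
            f"dropping {n_drop} longitudinal record(s) observed after the "
            "subject's survival time",
            stacklevel=2,
        )
        long = long.loc[keep].reset_index(drop=True)
    if len(long) == 0:
        raise DataError("no longitudinal records remain after truncation")

    long = long.sort_values(["study", "subject", "time"], kind="mergesort").reset_index(
        drop=True
    )
    surv = surv.sort_values(["study", "subject"], kind="mergesort").reset_index(
        drop=True
    )
    return MetaJointDataset(long=long, surv=surv, validated=True)


@dataclass
class IndexedData:
    """Integer-coded view of a validated dataset used by the fitting code.

    Studies are recoded to ``0..K-1`` in sorted-label order and subjects to
    ``0..n-1`` (sorted by study then subject label); the original labels are
    kept for reporting.
    """

    study_labels: list
    subj_study: np.ndarray  # (n,) study code per subject
    t_obs: np.ndarray  # (N,) measurement times
    y: np.ndarray  # (N,)
    obs_subject: np.ndarray  # (N,) subject index per longitudinal row
    treat: np.ndarray  # (n,) arm indicator per subject
    T: np.ndarray  # (n,) observed survival times
    delta: np.ndarray  # (n,) event indicators
    subject_labels: list  # (study_label, subject_label) per subject index

    @property
    def K(self) -> int:
        return len(self.study_labels)

    @property
    def n(self) -> int:
        return len(self.T)


def index_dataset(dataset: MetaJointDataset) -> IndexedData:
    """Build the integer-coded arrays for a validated dataset."""
    if not dataset.validated:
        dataset = validate(dataset)
    surv = dataset.surv
    long = dataset.long
    study_labels = sorted(surv["study"].unique().tolist())
    study_code = {s: k for k, s in enumerate(study_labels)}

    surv = surv.assign(_k=surv["study"].map(study_code)).sort_values(
        ["_k", "subject"], kind="mergesort"
    )
    subj_index = {
        (row.study, row.subject): i for i, row in enumerate(surv.itertuples())
    }
    key = list(zip(long["study"], long["subject"]))
    obs_subject = np.array([subj_index[k] for k in key], dtype=np.intp)
    order = np.argsort(obs_subject, kind="mergesort")

    return IndexedData(
        study_labels=study_labels,
        subj_study=surv["_k"].to_numpy(dtype=np.intp),
        t_obs=long["time"].to_numpy(dtype=float)[order],
        y=long["y"].to_numpy(dtype=float)[order],
        obs_subject=obs_subject[order],
        treat=surv["treat"].to_numpy(dtype=float),
        T=surv["survtime"].to_numpy(dtype=float),
        delta=surv["status"].to_numpy(dtype=float),
        subject_labels=list(zip(surv["study"], surv["subject"])),
    )
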