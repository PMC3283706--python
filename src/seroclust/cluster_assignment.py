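"""Relative-ratio (RR) clustering of SLE patients.

Every SLE patient is segregated into exactly one of three groups:

* ``SERONEGATIVE`` — no seropositive call on any of the six core antigens
  (screened first; such patients are never ratio-assigned);
* ``SM_RNP`` — RR >= 1, where RR is the sum of the raw Sm-D3 + RNP-A +
  RNP-70k titers divided by the sum of the raw Ro52 + Ro60 + La titers;
* ``RO_LA`` — RR < 1.

RR uses raw titer sums (light units), not Z-scores. A patient is "pure"
when all of its seropositive calls fall inside a single trio. A zero Ro/La
denominator with a non-seronegative patient (possible only for synthetic
inputs; real LU are positive) is treated as RR = +inf, hence ``SM_RNP``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import (
    CLASS_LABELS,
    CORE_ANTIGENS,
    RO_LA,
    RO_LA_TRIO,
    SERONEGATIVE,
    SM_RNP,
    SM_RNP_TRIO,
    CohortTable,
)
from .serology_core import ControlStats, call_seropositive, round_half_away


class JoinError(KeyError):
    """Raised when patient ids of two tables fail to align."""


@dataclass(frozen=True)
class ClusterPrevalence:
    """Cluster counts and display percentages for one cohort."""

    n_total: int
    n_smrnp: int
    n_rola: int
    n_seroneg: int
    n_pure_smrnp: int
    n_pure_rola: int

    @property
    def pct_smrnp(self) -> int:
        return round_half_away(100.0 * self.n_smrnp / self.n_total)

    @property
    def pct_rola(self) -> int:
        return round_half_away(100.0 * self.n_rola / self.n_total)

    @property
    def pct_seroneg(self) -> int:
        return round_half_away(100.0 * self.n_seroneg / self.n_total)


def assign_clusters(
    cohort: CohortTable, stats: dict[str, ControlStats]
) -> pd.DataFrame:
    """RR cluster assignment for every SLE patient.

    Returns a table indexed by patient_id with columns ``sum_smrnp``,
    ``sum_rola``, ``rr``, ``label`` and ``pure``.
    """
    missing = [a for a in CORE_ANTIGENS if a not in cohort.antigens]
    if missing:
        raise KeyError(f"cohort lacks core antigens required for RR: {missing}")

    sle = cohort.sle
    titers = sle[CORE_ANTIGENS]
    calls = call_seropositive(cohort, stats).loc[sle.index, CORE_ANTIGENS]

    sum_sm = titers[SM_RNP_TRIO].sum(axis=1)
    sum_ro = titers[RO_LA_TRIO].sum(axis=1)
    with np.errstate(divide="ignore"):
        rr = np.where(sum_ro > 0, sum_sm / sum_ro, np.inf)

    any_pos = calls.any(axis=1)
    pos_sm = calls[SM_RNP_TRIO].any(axis=1)
    pos_ro = calls[RO_LA_TRIO].any(axis=1)

    label = np.where(rr >= 1.0, SM_RNP, RO_LA)
    label = np.where(any_pos, label, SERONEGATIVE)
    # pure: at least one positive call, all confined to a single trio
    pure = any_pos & (pos_sm ^ pos_ro)

    return pd.DataFrame(
        {
            "sum_smrnp": sum_sm,
            "sum_rola": sum_ro,
            "rr": rr,
            "label": label,
            "pure": pure,
        },
        index=sle.index,
    )


def cluster_prevalence(assignments: pd.DataFrame) -> ClusterPrevalence:
    """Exact counts per cluster with integer display percentages."""
    if len(assignments) == 0:
        raise ValueError("no assignments to summarize")
    label = assignments["label"]
    pure = assignments["pure"]
    return ClusterPrevalence(
        n_total=len(assignments),
        n_smrnp=int((label == SM_RNP).sum()),
        n_rola=int((label == RO_LA).sum()),
        n_seroneg=int((label == SERONEGATIVE).sum()),
        n_pure_smrnp=int((pure & (label == SM_RNP)).sum()),
        n_pure_rola=int((pure & (label == RO_LA)).sum()),
    )


def recover_latent_labels(
    assignments: pd.DataFrame, truth: pd.DataFrame
) -> tuple[pd.DataFrame, float]:
    """Confusion matrix (latent rows x assigned columns) and accuracy.

    Only meaningful for simulated cohorts, whose latent class is written to
    a separate truth table at generation time.
    """
    if not assignments.index.sort_values().equals(truth.index.sort_values()):
        raise JoinError("assignment and truth patient ids do not match")
    joined = assignments.join(truth, how="inner")
    confusion = pd.crosstab(joined["latent_class"], joined["label"])
    confusion = confusion.reindex(
        index=CLASS_LABELS, columns=CLASS_LABELS, fill_value=0
    )
    accuracy = float(np.trace(confusion.to_numpy())) / len(joined)
    return confusion, accuracy
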