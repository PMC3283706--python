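"""Six-antigen mixture assay model and comparison with summed titers.

A single-well LIPS test of all six core antigens is modeled additively: the
mixture signal is the sum of the six individual titers times a
multiplicative log-normal noise term with unit mean and a configurable
coefficient of variation. The comparison mirrors the published analysis:
Spearman rank correlation between mixture and sum, and the mixture's own
ROC-optimal diagnostic cutoff with its sensitivity/specificity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association_stats import spearman_rho
from .cohort import CORE_ANTIGENS, GROUP_CONTROL, GROUP_SLE, CohortTable
from .serology_core import DiagnosticPerformance, _roc_optimal_from_values


@dataclass(frozen=True)
class MixtureResult:
    """Cohort-level mixture-vs-sum comparison."""

    per_patient: pd.DataFrame  # mixture_lu, sum_individual_lu
    spearman_rho: float
    spearman_p: float
    roc_cutoff: float
    performance: DiagnosticPerformance


def simulate_mixture(cohort: CohortTable, noise_cv: float, seed: int) -> pd.Series:
    """Mixture LU per subject: sum of the six core titers x log-normal noise.

    The noise has unit mean and coefficient of variation ``noise_cv``; at
    ``noise_cv = 0`` the mixture equals the sum exactly. Deterministic given
    ``seed``.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    missing = [a for a in CORE_ANTIGENS if a not in cohort.antigens]
    if missing:
        raise KeyError(f"cohort lacks core antigens: {missing}")
    total = cohort.titers()[CORE_ANTIGENS].sum(axis=1)
    if noise_cv == 0:
        noise = np.ones(len(total))
    else:
        sigma2 = np.log1p(noise_cv**2)
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        noise = np.exp(rng.normal(-sigma2 / 2.0, np.sqrt(sigma2), size=len(total)))
    return pd.Series(total.to_numpy() * noise, index=total.index, name="mixture_lu")


def compare_mixture_to_sum(mixture: pd.Series, cohort: CohortTable) -> MixtureResult:
    """Spearman correlation with the summed titers plus mixture diagnostics."""
    total = cohort.titers()[CORE_ANTIGENS].sum(axis=1)
    mixture = mixture.loc[total.index]
    rho = spearman_rho(mixture.to_numpy(), total.to_numpy())
    sle = mixture[cohort.is_sle].to_numpy(dtype=float)
    ctrl = mixture[~cohort.is_sle].to_numpy(dtype=float)
    cutoff, perf = _roc_optimal_from_values("mixture", sle, ctrl)
    per_patient = pd.DataFrame(
        {"mixture_lu": mixture, "sum_individual_lu": total}
    )
    return MixtureResult(
        per_patient=per_patient,
        spearman_rho=rho.statistic,
        spearman_p=rho.p_two_sided,
        roc_cutoff=cutoff,
        performance=perf,
    )
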