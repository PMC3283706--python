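"""Cutoff calibration, seropositivity calls, Z-scores and diagnostics.

Two explicit cutoff policies are kept side by side, because they serve
different stages of the analysis:

* the mean + 3 SD control cutoff drives seropositivity calls, Z-scores and
  the heatmap pathway;
* the ROC-optimal cutoff (maximum Youden J) drives the per-antigen
  diagnostic sensitivity/specificity tables.

A Z-score is ``(titer - cutoff) / control_sd``; by construction a titer at
the cutoff maps to 0 and the control mean maps to -3. "Seropositive" means
strictly above the cutoff; a titer exactly at the cutoff is negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import GROUP_CONTROL, GROUP_SLE, CohortTable


class CalibrationError(ValueError):
    """Raised when controls are insufficient to calibrate a cutoff."""


class DegenerateControlError(CalibrationError):
    """Raised when control titers have zero variance (cutoff undefined)."""


class NoSeparationError(ValueError):
    """Raised when ROC optimization is attempted on identical titers."""


def round_half_away(x: float) -> int:
    """Round half away from zero (display convention for percents)."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


@dataclass(frozen=True)
class ControlStats:
    """Control calibration for one antigen (mean + 3 SD policy)."""

    antigen: str
    control_mean: float
    control_sd: float

    @property
    def cutoff(self) -> float:
        return self.control_mean + 3.0 * self.control_sd


@dataclass(frozen=True)
class DiagnosticPerformance:
    """Sensitivity/specificity of one threshold rule, in percent.

    ``sensitivity`` and ``specificity`` are kept unrounded; use
    :meth:`rounded` for the integer-percent display convention.
    """

    label: str
    cutoff_used: float
    sensitivity: float
    specificity: float
    n_sle: int
    n_control: int

    def rounded(self) -> tuple[int, int]:
        return round_half_away(self.sensitivity), round_half_away(self.specificity)

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 100.0


def fit_control_cutoffs(
    cohort: CohortTable, panel: list[str] | None = None
) -> dict[str, ControlStats]:
    """Per-antigen control mean, sample SD (n-1) and mean+3SD cutoff."""
    panel = list(panel) if panel is not None else list(cohort.antigens)
    controls = cohort.titers(GROUP_CONTROL)
    if len(controls) < 2:
        raise CalibrationError(
            f"need >= 2 controls to calibrate cutoffs, got {len(controls)}"
        )
    stats: dict[str, ControlStats] = {}
    for antigen in panel:
        values = controls[antigen].to_numpy(dtype=float)
        mean = float(values.mean())
        sd = float(values.std(ddof=1))
        if sd == 0.0:
            raise DegenerateControlError(
                f"control titers for {antigen!r} have zero variance"
            )
        stats[antigen] = ControlStats(antigen, mean, sd)
    return stats


def stats_frame(stats: dict[str, ControlStats]) -> pd.DataFrame:
    """ControlStats as a table (antigen, control_mean, control_sd, cutoff)."""
    return pd.DataFrame(
        {
            "control_mean": {a: s.control_mean for a, s in stats.items()},
            "control_sd": {a: s.control_sd for a, s in stats.items()},
            "cutoff": {a: s.cutoff for a, s in stats.items()},
        }
    ).rename_axis("antigen")


def stats_from_frame(df: pd.DataFrame) -> dict[str, ControlStats]:
    return {
        str(a): ControlStats(str(a), float(r["control_mean"]), float(r["control_sd"]))
        for a, r in df.iterrows()
    }


def _require_stats(cohort: CohortTable, stats: dict[str, ControlStats]) -> None:
    missing = [a for a in cohort.antigens if a not in stats]
    if missing:
        raise KeyError(f"control stats missing for antigens: {missing}")


def z_scores(cohort: CohortTable, stats: dict[str, ControlStats]) -> pd.DataFrame:
    """Z-score matrix (subjects x antigens); no clipping is applied here.

    Display clipping (negative Z shown as 0) is a rendering concern, handled
    by :mod:`seroclust.report`.
    """
    _require_stats(cohort, stats)
    titers = cohort.titers()
    out = {}
    for antigen in cohort.antigens:
        s = stats[antigen]
        out[antigen] = (titers[antigen] - s.cutoff) / s.control_sd
    return pd.DataFrame(out)[cohort.antigens]


def call_seropositive(
    cohort: CohortTable, stats: dict[str, ControlStats]
) -> pd.DataFrame:
    """Boolean matrix: titer strictly above the mean+3SD cutoff (z > 0)."""
    _require_stats(cohort, stats)
    titers = cohort.titers()
    out = {a: titers[a] > stats[a].cutoff for a in cohort.antigens}
    return pd.DataFrame(out)[cohort.antigens]


def _performance_from_values(
    label: str,
    sle_values: np.ndarray,
    control_values: np.ndarray,
    cutoff: float,
) -> DiagnosticPerformance:
    if len(sle_values) == 0 or len(control_values) == 0:
        raise ValueError("both SLE and control groups must be nonempty")
    sens = 100.0 * float((sle_values > cutoff).mean())
    spec = 100.0 * float((control_values <= cutoff).mean())
    return DiagnosticPerformance(
        label=label,
        cutoff_used=cutoff,
        sensitivity=sens,
        specificity=spec,
        n_sle=len(sle_values),
        n_control=len(control_values),
    )


def diagnostic_performance(
    cohort: CohortTable, antigen: str, cutoff: float
) -> DiagnosticPerformance:
    """Sensitivity/specificity of ``titer > cutoff`` for one antigen."""
    sle = cohort.titers(GROUP_SLE)[antigen].to_numpy(dtype=float)
    ctrl = cohort.titers(GROUP_CONTROL)[antigen].to_numpy(dtype=float)
    return _performance_from_values(antigen, sle, ctrl, cutoff)


def _roc_optimal_from_values(
    label: str, sle_values: np.ndarray, control_values: np.ndarray
) -> tuple[float, DiagnosticPerformance]:
    pooled = np.unique(np.concatenate([sle_values, control_values]))
    if len(pooled) < 2:
        raise NoSeparationError("all titers identical; no threshold separates groups")
    candidates = np.concatenate(
        [[-np.inf], (pooled[:-1] + pooled[1:]) / 2.0, [np.inf]]
    )
    best: DiagnosticPerformance | None = None
    for cut in candidates:
        perf = _performance_from_values(label, sle_values, control_values, float(cut))
        if (
            best is None
            or perf.youden_j > best.youden_j + 1e-12
            or (
                abs(perf.youden_j - best.youden_j) <= 1e-12
                and (
                    perf.specificity > best.specificity + 1e-12
                    or (
                        abs(perf.specificity - best.specificity) <= 1e-12
                        and perf.cutoff_used > best.cutoff_used
                    )
                )
            )
        ):
            best = perf
    assert best is not None
    return best.cutoff_used, best


def roc_optimal_cutoff(
    cohort: CohortTable, antigen: str
) -> tuple[float, DiagnosticPerformance]:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 100.

    Scans every midpoint between adjacent distinct pooled titers plus the
    two infinities. Ties are broken toward higher specificity, then toward
    the higher cutoff (the diagnostic tables emphasize specificity).
    """
    sle = cohort.titers(GROUP_SLE)[antigen].to_numpy(dtype=float)
    ctrl = cohort.titers(GROUP_CONTROL)[antigen].to_numpy(dtype=float)
    return _roc_optimal_from_values(antigen, sle, ctrl)


def panel_sensitivity(
    cohort: CohortTable,
    stats: dict[str, ControlStats],
    panel: list[str] | None = None,
) -> DiagnosticPerformance:
    """Union rule over a panel: positive iff positive for >= 1 panel antigen.

    Sensitivity is the percent of SLE patients that are panel-positive;
    specificity the percent of controls with zero positive calls.
    """
    panel = list(panel) if panel is not None else list(cohort.antigens)
    if not panel:
        raise ValueError("panel must be nonempty")
    calls = call_seropositive(cohort, stats)[panel]
    any_pos = calls.any(axis=1)
    sle_pos = any_pos[cohort.is_sle.to_numpy()]
    ctrl_pos = any_pos[~cohort.is_sle.to_numpy()]
    if len(sle_pos) == 0 or len(ctrl_pos) == 0:
        raise ValueError("both SLE and control groups must be nonempty")
    return DiagnosticPerformance(
        label="+".join(panel),
        cutoff_used=float("nan"),
        sensitivity=100.0 * float(sle_pos.mean()),
        specificity=100.0 * float((~ctrl_pos).mean()),
        n_sle=len(sle_pos),
        n_control=len(ctrl_pos),
    )


def performance_frame(perfs: list[DiagnosticPerformance]) -> pd.DataFrame:
    """Diagnostic performances as a display table with rounded percents."""
    rows = []
    for p in perfs:
        sens, spec = p.rounded()
        rows.append(
            {
                "label": p.label,
                "cutoff": p.cutoff_used,
                "sensitivity_pct": sens,
                "specificity_pct": spec,
                "sensitivity_raw": p.sensitivity,
                "specificity_raw": p.specificity,
                "n_sle": p.n_sle,
                "n_control": p.n_control,
            }
        )
    return pd.DataFrame(rows).set_index("label")
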