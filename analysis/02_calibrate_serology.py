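"""Calibrate cutoffs and evaluate per-antigen diagnostic performance.

Both cutoff policies are reported: the control mean+3SD rule (which feeds
seropositivity calls and Z-scores) and the ROC-optimal rule (which feeds
the sensitivity/specificity table), together with the six-antigen union
sensitivity.
"""

from pathlib import Path

from seroclust import (
    CORE_ANTIGENS,
    CohortTable,
    diagnostic_performance,
    fit_control_cutoffs,
    panel_sensitivity,
    roc_optimal_cutoff,
)
from seroclust.serology_core import performance_frame, stats_frame

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = CohortTable.read_csv(RESULTS / "cohort.csv")
    stats = fit_control_cutoffs(cohort)
    stats_frame(stats).to_csv(RESULTS / "control_stats.csv")

    perfs = []
    for antigen in cohort.antigens:
        perfs.append(diagnostic_performance(cohort, antigen, stats[antigen].cutoff))
    mean3sd = performance_frame(perfs)
    mean3sd.to_csv(RESULTS / "diagnostics_mean3sd.csv")

    roc_perfs = [roc_optimal_cutoff(cohort, a)[1] for a in cohort.antigens]
    roc = performance_frame(roc_perfs)
    roc.to_csv(RESULTS / "diagnostics_roc.csv")

    union = panel_sensitivity(cohort, stats, CORE_ANTIGENS)
    sens, spec = union.rounded()
    print("per-antigen sensitivity/specificity (mean+3SD policy):")
    print(mean3sd[["sensitivity_pct", "specificity_pct"]].to_string())
    print(f"\nsix-antigen union: {sens}% sensitivity, {spec}% specificity")
    print(f"wrote control_stats.csv, diagnostics_mean3sd.csv, diagnostics_roc.csv")


if __name__ == "__main__":
    main()
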