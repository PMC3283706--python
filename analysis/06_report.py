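"""Render the cluster-ordered Z-score heatmap and the summary tables."""

from pathlib import Path

import pandas as pd

from seroclust import (
    CohortTable,
    cluster_prevalence,
    fit_control_cutoffs,
    roc_optimal_cutoff,
    z_scores,
)
from seroclust.report import render_heatmap, summary_tables

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = CohortTable.read_csv(RESULTS / "cohort.csv")
    stats = fit_control_cutoffs(cohort)
    assignments = pd.read_csv(RESULTS / "clusters.csv", index_col="patient_id")
    associations = pd.read_csv(RESULTS / "associations_simulated.csv", index_col="feature")

    perfs = [roc_optimal_cutoff(cohort, a)[1] for a in cohort.antigens]
    prev = cluster_prevalence(assignments)
    out = RESULTS / "report"
    summary_tables(cohort, perfs, prev, associations, out)

    z = z_scores(cohort, stats).loc[cohort.is_sle]
    manifest = render_heatmap(z, assignments, out / "heatmap.png", out / "heatmap_rows.csv")
    pure = manifest["pure"].sum()
    print(f"heatmap: {len(manifest)} SLE patients in cluster blocks ({pure} pure)")
    print(f"summary tables and figure written under {out}")


if __name__ == "__main__":
    main()
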