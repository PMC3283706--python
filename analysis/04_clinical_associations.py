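"""Association testing: clusters and antigens vs clinical manifestations.

Two complementary analyses:

1. the Fisher screen on the simulated cohort (clinical flags vs the two RR
   clusters), with Benjamini-Hochberg adjusted values as a labeled extra;
2. the four headline associations of the reference cohorts, recomputed
   from contingency tables reconstructed out of the printed percentages
   and group sizes (serositis x cluster, anti-IFN-a x SACQ,
   anti-Sm x anti-IFN-w, anti-IFN-a x anti-IFN-w).
"""

from pathlib import Path

import pandas as pd

from seroclust import (
    CLINICAL_FLAGS,
    CohortTable,
    ContingencyTable2x2,
    association_screen,
    fisher_exact_two_sided,
    table_from_percents,
)
from seroclust import reference_cohorts as ref

RESULTS = Path(__file__).resolve().parents[1] / "results"


def printed_tables() -> dict[str, ContingencyTable2x2]:
    out = {}
    for name, spec in ref.HEADLINE_FISHER.items():
        if "counts" in spec:
            (a, b), (c, d) = spec["counts"]
            out[name] = ContingencyTable2x2(a, b, c, d)
        else:
            out[name] = table_from_percents(
                spec["pct1"], spec["n1"], spec["pct2"], spec["n2"]
            )
    return out


def main() -> None:
    cohort = CohortTable.read_csv(RESULTS / "cohort.csv")
    assignments = pd.read_csv(RESULTS / "clusters.csv", index_col="patient_id")

    screen = association_screen(cohort, assignments, CLINICAL_FLAGS)
    screen.to_csv(RESULTS / "associations_simulated.csv")
    print("simulated-cohort Fisher screen (clinical flag x cluster):")
    print(screen[["pct_smrnp", "pct_rola", "p", "p_bh"]].round(4).to_string())
    hits = screen.index[screen["p"] < 0.05].tolist()
    print(f"flags with raw p < 0.05: {hits or 'none'}")

    rows = []
    for name, tab in printed_tables().items():
        res = fisher_exact_two_sided(tab)
        rows.append(
            {
                "association": name,
                "a": tab.a, "b": tab.b, "c": tab.c, "d": tab.d,
                "odds_ratio": res.statistic,
                "p": res.p_two_sided,
                "p_printed": ref.HEADLINE_FISHER[name]["p_printed"],
            }
        )
    printed = pd.DataFrame(rows).set_index("association")
    printed.to_csv(RESULTS / "associations_printed.csv")
    print("\nreconstructed printed-table associations:")
    print(printed[["p", "p_printed"]].to_string(float_format=lambda v: f"{v:.4g}"))


if __name__ == "__main__":
    main()
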