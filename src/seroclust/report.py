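"""Rendering: the Z-score heatmap and the cohort summary tables.

Heatmap conventions follow the serology-profiling style: patients are rows,
grouped in cluster blocks (Sm/RNP, then Ro/La, then seronegative) and
ordered within each block by descending relative ratio; the color scale
runs black (at or below cutoff) to green (high Z), with Z clipped to
``[0, z_max]`` for display only — sub-cutoff magnitudes carry no display
meaning. The row order is also written to a CSV manifest so the figure is
auditable without pixel inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.colors import LinearSegmentedColormap

from .cluster_assignment import ClusterPrevalence, JoinError
from .cohort import RO_LA, SERONEGATIVE, SM_RNP
from .serology_core import DiagnosticPerformance

_BLACK_GREEN = LinearSegmentedColormap.from_list("lips", ["black", "#00c000"])


@dataclass(frozen=True)
class HeatmapSpec:
    """Display conventions for the Z-score heatmap."""

    z_max: float = 10.0
    block_order: tuple[str, ...] = (SM_RNP, RO_LA, SERONEGATIVE)
    cmap: object = field(default_factory=lambda: _BLACK_GREEN, compare=False)


def heatmap_row_order(assignments: pd.DataFrame, spec: HeatmapSpec | None = None) -> pd.DataFrame:
    """Cluster-blocked patient ordering (descending RR inside each block)."""
    spec = spec or HeatmapSpec()
    blocks = []
    for label in spec.block_order:
        block = assignments[assignments["label"] == label]
        blocks.append(block.sort_values("rr", ascending=False, kind="mergesort"))
    ordered = pd.concat(blocks)
    manifest = ordered[["label", "rr", "pure"]].copy()
    manifest.insert(0, "row", np.arange(len(manifest)))
    return manifest


def render_heatmap(
    zmatrix: pd.DataFrame,
    assignments: pd.DataFrame,
    out_image: str | Path,
    out_manifest: str | Path | None = None,
    spec: HeatmapSpec | None = None,
) -> pd.DataFrame:
    """Write the heatmap image and its row-order manifest; returns the manifest."""
    spec = spec or HeatmapSpec()
    if not set(assignments.index) <= set(zmatrix.index):
        raise JoinError("assignment patient ids missing from the Z matrix")
    manifest = heatmap_row_order(assignments, spec)
    z = zmatrix.loc[manifest.index].clip(lower=0.0, upper=spec.z_max)

    fig, ax = plt.subplots(
        figsize=(0.5 * len(zmatrix.columns) + 2, 0.08 * len(z) + 2)
    )
    ax.imshow(
        z.to_numpy(),
        aspect="auto",
        interpolation="nearest",
        cmap=spec.cmap,
        vmin=0.0,
        vmax=spec.z_max,
    )
    ax.set_xticks(range(len(zmatrix.columns)), zmatrix.columns, rotation=90, fontsize=7)
    ax.set_yticks([])
    # block separators
    boundaries = np.cumsum(
        [int((manifest["label"] == lab).sum()) for lab in spec.block_order[:-1]]
    )
    for b in boundaries:
        ax.axhline(b - 0.5, color="white", lw=1.0)
    ax.set_ylabel("patients (cluster blocks, descending RR)")
    fig.colorbar(ax.images[0], ax=ax, label="Z (clipped)")
    fig.tight_layout()
    fig.savefig(out_image, dpi=150)
    plt.close(fig)

    if out_manifest is not None:
        manifest.to_csv(out_manifest, index=True, index_label="patient_id")
    return manifest


def _mean_ci(values: np.ndarray) -> tuple[float, float, float]:
    """Arithmetic mean with a normal-theory 95% CI (may dip negative)."""
    mean = float(values.mean())
    half = 1.96 * float(values.std(ddof=1)) / np.sqrt(len(values))
    return mean, mean - half, mean + half


def antigen_summary_table(cohort, perfs: list[DiagnosticPerformance]) -> pd.DataFrame:
    """Per-antigen sensitivity/specificity and group mean titers (95% CI)."""
    rows = []
    for perf in perfs:
        antigen = perf.label
        hc = cohort.titers("CONTROL")[antigen].to_numpy(dtype=float)
        sle = cohort.titers("SLE")[antigen].to_numpy(dtype=float)
        m_hc, lo_hc, hi_hc = _mean_ci(hc)
        m_sle, lo_sle, hi_sle = _mean_ci(sle)
        sens, spec = perf.rounded()
        rows.append(
            {
                "antigen": antigen,
                "sensitivity_pct": sens,
                "specificity_pct": spec,
                "mean_hc": m_hc,
                "ci_lo_hc": lo_hc,
                "ci_hi_hc": hi_hc,
                "mean_sle": m_sle,
                "ci_lo_sle": lo_sle,
                "ci_hi_sle": hi_sle,
            }
        )
    return pd.DataFrame(rows).set_index("antigen")


def prevalence_table(prev: ClusterPrevalence) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"cluster": SM_RNP, "n": prev.n_smrnp, "pct": prev.pct_smrnp,
             "n_pure": prev.n_pure_smrnp},
            {"cluster": RO_LA, "n": prev.n_rola, "pct": prev.pct_rola,
             "n_pure": prev.n_pure_rola},
            {"cluster": SERONEGATIVE, "n": prev.n_seroneg, "pct": prev.pct_seroneg,
             "n_pure": 0},
        ]
    ).set_index("cluster")


def summary_tables(
    cohort,
    perfs: list[DiagnosticPerformance],
    prevalence: ClusterPrevalence,
    associations: pd.DataFrame,
    out_dir: str | Path,
) -> dict[str, pd.DataFrame]:
    """Emit the three summary tables as CSV and Markdown (identical numbers)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables = {
        "antigen_performance": antigen_summary_table(cohort, perfs),
        "cluster_prevalence": prevalence_table(prevalence),
        "cluster_associations": associations,
    }
    for name, df in tables.items():
        df.to_csv(out_dir / f"{name}.csv")
        (out_dir / f"{name}.md").write_text(frame_to_markdown(df))
    return tables


def frame_to_markdown(df: pd.DataFrame) -> str:
    """Render a DataFrame as a GitHub-style markdown table.

    Cell values use ``repr``-free ``str`` formatting identical to the CSV
    writer's, so the two emissions carry the same numbers.
    """
    cols = [str(df.index.name or "")] + [str(c) for c in df.columns]
    lines = ["| " + " | ".join(cols) + " |", "|" + "---|" * len(cols)]
    for idx, row in df.iterrows():
        cells = [str(idx)] + [str(v) for v in row.tolist()]
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"
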