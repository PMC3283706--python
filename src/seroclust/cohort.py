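"""Patient-by-antigen titer tables.

The universal input of the pipeline is a cohort: one row per subject, one
column per antigen carrying the LIPS titer in light units (LU), plus group
membership (SLE patient vs. healthy control), demographics, and — for SLE
patients — binary clinical-manifestation flags and anti-dsDNA status.

Titers are luminometer counts and therefore strictly positive; every subject
has a titer for every antigen in the panel (no missing cells).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: The three Sm/RNP-trio antigens (snRNP core and 70k/A proteins).
SM_RNP_TRIO = ["Sm-D3", "RNP-A", "RNP-70k"]
#: The three Ro/La-trio antigens (the SSA pair and SSB).
RO_LA_TRIO = ["Ro52", "Ro60", "La"]
#: The six core antigens used for clustering and the mixture assay.
CORE_ANTIGENS = SM_RNP_TRIO + RO_LA_TRIO
#: Additional antigens carried by the default panel (cytokine and neuronal).
EXTRA_ANTIGENS = ["IFN-a", "IFN-w", "TH", "AQP-4", "GAD65", "GFAP"]

#: Binary clinical manifestation flags recorded for SLE patients.
CLINICAL_FLAGS = [
    "cns",
    "musculoskeletal",
    "mucocutaneous",
    "nephritis",
    "serositis",
    "hematological",
    "sacq",
    "quiescent",
]

DEMOGRAPHIC_COLS = ["sex", "ethnicity", "age_group"]

GROUP_SLE = "SLE"
GROUP_CONTROL = "CONTROL"

#: Latent / assigned class labels.
SM_RNP = "SM_RNP"
RO_LA = "RO_LA"
SERONEGATIVE = "SERONEGATIVE"
CLASS_LABELS = [SM_RNP, RO_LA, SERONEGATIVE]


class CohortError(ValueError):
    """Raised when a cohort table violates its structural contract."""


@dataclass
class CohortTable:
    """A cohort of subjects with per-antigen LIPS titers.

    Parameters
    ----------
    data:
        One row per subject, indexed by ``patient_id``. Must contain a
        ``group`` column (``SLE``/``CONTROL``) and one numeric column per
        antigen in ``antigens``. Clinical flags, demographics and
        ``dsdna_pos`` are optional columns.
    antigens:
        Ordered antigen panel; the order is preserved in every output.
    """

    data: pd.DataFrame
    antigens: list[str] = field(default_factory=lambda: list(CORE_ANTIGENS))

    def __post_init__(self) -> None:
        missing = [a for a in self.antigens if a not in self.data.columns]
        if missing:
            raise CohortError(f"cohort is missing titer columns: {missing}")
        if "group" not in self.data.columns:
            raise CohortError("cohort needs a 'group' column")
        titers = self.data[self.antigens]
        if titers.isna().any().any():
            raise CohortError("missing titer cells are not allowed")
        if (titers <= 0).any().any():
            raise CohortError("titers must be strictly positive (LU counts)")

    # -- views -----------------------------------------------------------
    @property
    def is_sle(self) -> pd.Series:
        return self.data["group"] == GROUP_SLE

    @property
    def sle(self) -> pd.DataFrame:
        return self.data[self.is_sle]

    @property
    def controls(self) -> pd.DataFrame:
        return self.data[~self.is_sle]

    @property
    def n_sle(self) -> int:
        return int(self.is_sle.sum())

    @property
    def n_control(self) -> int:
        return int((~self.is_sle).sum())

    def titers(self, group: str | None = None) -> pd.DataFrame:
        """Titer matrix (subjects x antigens), optionally one group only."""
        if group is None:
            return self.data[self.antigens]
        return self.data.loc[self.data["group"] == group, self.antigens]

    # -- I/O --------------------------------------------------------------
    def write_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=True, index_label="patient_id")

    @classmethod
    def read_csv(cls, path: str | Path, antigens: list[str] | None = None) -> "CohortTable":
        df = pd.read_csv(path, index_col="patient_id")
        if antigens is None:
            known = CORE_ANTIGENS + EXTRA_ANTIGENS
            antigens = [c for c in known if c in df.columns]
            # any numeric column that is not a flag/demographic is a titer
            extra = [
                c
                for c in df.columns
                if c not in antigens
                and c not in ("group", "dsdna_pos", *CLINICAL_FLAGS, *DEMOGRAPHIC_COLS)
                and np.issubdtype(df[c].dtype, np.number)
            ]
            antigens = antigens + extra
        return cls(df, antigens)
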