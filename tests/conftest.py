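import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from seroclust import CohortTable, default_config_from_tables, generate_cohort
from seroclust.cohort import CLINICAL_FLAGS, GROUP_CONTROL, GROUP_SLE

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def make_cohort(
    control_titers: dict[str, list[float]],
    sle_titers: dict[str, list[float]],
    sle_flags: dict[str, list[int]] | None = None,
) -> CohortTable:
    """Hand-built cohort from per-antigen titer lists."""
    antigens = list(control_titers)
    n_ctrl = len(next(iter(control_titers.values())))
    n_sle = len(next(iter(sle_titers.values())))
    rows = []
    for i in range(n_ctrl):
        row = {"patient_id": f"C{i}", "group": GROUP_CONTROL}
        row.update({a: control_titers[a][i] for a in antigens})
        rows.append(row)
    for i in range(n_sle):
        row = {"patient_id": f"P{i}", "group": GROUP_SLE}
        row.update({a: sle_titers[a][i] for a in antigens})
        if sle_flags:
            row.update({f: sle_flags[f][i] for f in sle_flags})
        rows.append(row)
    return CohortTable(pd.DataFrame(rows).set_index("patient_id"), antigens)


@pytest.fixture(scope="session")
def table_config():
    """Generator configuration calibrated to the printed cohort summaries."""
    return default_config_from_tables(seed=11)


@pytest.fixture(scope="session")
def sim_cohort(table_config):
    """One simulated validation-sized cohort (129 SLE / 15 controls)."""
    return generate_cohort(table_config)


@pytest.fixture(scope="session")
def big_cohort():
    """A larger simulated cohort for Monte-Carlo checks."""
    cfg = default_config_from_tables(n_sle=1000, n_control=200, seed=101)
    return generate_cohort(cfg)
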