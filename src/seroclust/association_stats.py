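"""Hypothesis tests for cluster / antigen vs. clinical associations.

The workhorse is the two-sided Fisher's exact test on 2x2 tables, defined
by the minimum-likelihood convention: the p-value sums the probabilities of
all tables with the observed margins whose point (hypergeometric)
probability does not exceed that of the observed table. Mann-Whitney U
(titer comparisons), a pooled two-sample t-test on log10 titers (geometric
mean titer comparisons) and Spearman rank correlation complete the toolkit,
plus a helper that reconstructs integer contingency tables from printed
percentages and group sizes.

All p-values are two-sided. No multiplicity correction is applied to the
headline output; the screen additionally reports Benjamini-Hochberg
adjusted values as a clearly labeled extra column.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .cohort import RO_LA, SM_RNP, CohortTable
from .serology_core import round_half_away

_REL_TOL = 1e-7  # tie tolerance when comparing hypergeometric point masses


class AmbiguousPercentError(ValueError):
    """Raised when no integer count re-rounds to a printed percentage."""


class ConstantInputError(ValueError):
    """Raised when a correlation is requested on a constant series."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts ``[[a, b], [c, d]]``; rows = condition, columns = feature."""

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("group1", "group2")
    col_labels: tuple[str, str] = ("feature+", "feature-")

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in counts):
            raise ValueError("contingency counts must be nonnegative")
        if sum(counts) < 1:
            raise ValueError("contingency table must contain at least one count")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class AssocResult:
    """One two-group comparison: statistic, two-sided p, effect summary."""

    test: str  # FISHER | MANNWHITNEY | TTEST_LOG | SPEARMAN
    statistic: float
    p_two_sided: float
    effect: dict = field(default_factory=dict)
    n: tuple[int, ...] = ()


def fisher_exact_two_sided(table: ContingencyTable2x2) -> AssocResult:
    """Minimum-likelihood two-sided Fisher's exact test.

    The statistic is the sample odds ratio ``ad / bc`` (+inf when ``bc`` is
    zero with ``ad`` positive). A table with an empty margin carries no
    information: p is defined as 1.0 and a warning is emitted.
    """
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        warnings.warn("2x2 table has an empty margin; p-value defined as 1.0")
        odds = np.nan
        p = 1.0
    else:
        odds, p = sps.fisher_exact(arr, alternative="two-sided")
    return AssocResult(
        test="FISHER",
        statistic=float(odds),
        p_two_sided=float(p),
        effect={
            "pct_row1": 100.0 * table.a / max(table.a + table.b, 1),
            "pct_row2": 100.0 * table.c / max(table.c + table.d, 1),
        },
        n=(table.a + table.b, table.c + table.d),
    )


def _mannwhitney_exact_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumeration (handles ties).

    Enumerates every assignment of the pooled midranks to the x-group; the
    two-sided p is the probability of a U at least as far from its null mean
    n1*n2/2 as the observed U. Intended for combined n <= 20.
    """
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # midranks
    r_obs = ranks[:nx].sum()
    u_obs = r_obs - nx * (nx + 1) / 2.0
    mu = nx * ny / 2.0
    dev = abs(u_obs - mu)
    hits = 0
    total = 0
    for combo in itertools.combinations(range(nx + ny), nx):
        u = ranks[list(combo)].sum() - nx * (nx + 1) / 2.0
        if abs(u - mu) >= dev - 1e-9:
            hits += 1
        total += 1
    return float(u_obs), hits / total


def mann_whitney_u(x, y, exact_max_n: int = 20) -> AssocResult:
    """Two-sided Mann-Whitney U test with midrank ties.

    Exact by enumeration when the combined sample size is at most
    ``exact_max_n``; otherwise the tie-corrected normal approximation with
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    if len(x) + len(y) <= exact_max_n:
        u, p = _mannwhitney_exact_p(x, y)
    else:
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        u, p = float(res.statistic), float(res.pvalue)
    rank_biserial = 2.0 * u / (len(x) * len(y)) - 1.0
    return AssocResult(
        test="MANNWHITNEY",
        statistic=u,
        p_two_sided=min(p, 1.0),
        effect={"rank_biserial": rank_biserial},
        n=(len(x), len(y)),
    )


def ttest_log_titers(x, y) -> AssocResult:
    """Pooled two-sample t-test on log10 titers (geometric mean comparison)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    if (x <= 0).any() or (y <= 0).any():
        raise ValueError("titers must be strictly positive for log transform")
    lx, ly = np.log10(x), np.log10(y)
    res = sps.ttest_ind(lx, ly, equal_var=True)
    gmt_x = float(10.0 ** lx.mean())
    gmt_y = float(10.0 ** ly.mean())
    return AssocResult(
        test="TTEST_LOG",
        statistic=float(res.statistic),
        p_two_sided=float(res.pvalue),
        effect={"gmt_x": gmt_x, "gmt_y": gmt_y, "gmt_ratio": gmt_x / gmt_y},
        n=(len(x), len(y)),
    )


def _spearman_exact_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Exact permutation p for |rho| >= |rho_obs| (n <= 10)."""
    n = len(rx)
    mx, sx = rx.mean(), rx.std()
    my, sy = ry.mean(), ry.std()
    thresh = abs(rho_obs) - 1e-12
    hits = 0
    total = 0
    chunk: list[tuple] = []

    def flush(chunk):
        nonlocal hits, total
        perms = np.array(chunk, dtype=float)
        rhos = (perms @ ry / n - mx * my) / (sx * sy)
        hits += int((np.abs(rhos) >= thresh).sum())
        total += len(perms)

    for perm in itertools.permutations(rx):
        chunk.append(perm)
        if len(chunk) >= 100_000:
            flush(chunk)
            chunk = []
    if chunk:
        flush(chunk)
    return hits / total


def spearman_rho(x, y, exact_max_n: int = 10) -> AssocResult:
    """Spearman rank correlation (midranks), two-sided.

    Exact permutation p-value for n at most ``exact_max_n``; otherwise the
    t-approximation on ``rho * sqrt((n-2)/(1-rho^2))``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 3:
        raise ValueError("paired samples with n >= 3 required")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("correlation undefined for constant input")
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        p = _spearman_exact_p(rx, ry, rho)
    else:
        p = float(sps.spearmanr(x, y).pvalue)
    return AssocResult(
        test="SPEARMAN",
        statistic=rho,
        p_two_sided=min(p, 1.0),
        effect={"rho": rho},
        n=(n,),
    )


def counts_from_percent(pct: float, n: int) -> int:
    """Integer count behind a printed percentage of a known group size.

    Rounds half away from zero, then verifies the count re-rounds to the
    printed percent. If it does not, the nearest consistent integer is
    returned; if no integer is consistent the reconstruction is ambiguous
    and an error lists the closest candidates.
    """
    if not 0 <= pct <= 100:
        raise ValueError("pct must be in [0, 100]")
    if n < 1:
        raise ValueError("n must be >= 1")
    target = pct * n / 100.0
    k0 = round_half_away(target)
    consistent = [
        k for k in range(0, n + 1) if round_half_away(100.0 * k / n) == round_half_away(pct)
    ]
    if k0 in consistent:
        return k0
    if consistent:
        return min(consistent, key=lambda k: abs(k - target))
    near = sorted(range(0, n + 1), key=lambda k: abs(100.0 * k / n - pct))[:3]
    raise AmbiguousPercentError(
        f"no count in 0..{n} re-rounds to {pct}%; closest candidates "
        f"{[(k, 100.0 * k / n) for k in near]}"
    )


def table_from_percents(
    pct1: float, n1: int, pct2: float, n2: int, **labels
) -> ContingencyTable2x2:
    """2x2 table reconstructed from two printed percentages and group sizes."""
    return ContingencyTable2x2(
        a=counts_from_percent(pct1, n1),
        b=n1 - counts_from_percent(pct1, n1),
        c=counts_from_percent(pct2, n2),
        d=n2 - counts_from_percent(pct2, n2),
        **labels,
    )


def association_screen(
    cohort: CohortTable,
    assignments: pd.DataFrame,
    features: list[str] | None = None,
    feature_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Fisher screen of binary features against the two RR clusters.

    For every feature, builds the 2x2 table (Sm/RNP vs Ro/La) x (feature
    present/absent) over the clustered SLE patients and runs the two-sided
    Fisher test. Raw p-values are the headline output; Benjamini-Hochberg
    adjusted values are appended as a labeled extra column. Features may be
    named columns of the cohort (clinical flags, ``dsdna_pos``) or columns
    of an explicit boolean ``feature_table`` indexed by patient id (e.g.
    seropositivity calls). Strata with an empty cluster are skipped.
    """
    clustered = assignments[assignments["label"].isin([SM_RNP, RO_LA])]
    in_sm = clustered["label"] == SM_RNP
    rows = []
    if features is None and feature_table is not None:
        features = list(feature_table.columns)
    if features is None:
        raise ValueError("features must be given directly or via feature_table")
    for feat in features:
        if feature_table is not None and feat in feature_table.columns:
            series = feature_table.loc[clustered.index, feat]
        else:
            series = cohort.data.loc[clustered.index, feat]
        mask = series.notna()
        if mask.sum() == 0 or in_sm[mask].all() or (~in_sm[mask]).all():
            warnings.warn(f"feature {feat!r}: empty stratum, skipped")
            continue
        flag = series[mask].astype(bool)
        sm = in_sm[mask]
        tab = ContingencyTable2x2(
            a=int((sm & flag).sum()),
            b=int((sm & ~flag).sum()),
            c=int((~sm & flag).sum()),
            d=int((~sm & ~flag).sum()),
            row_labels=(SM_RNP, RO_LA),
            col_labels=(f"{feat}+", f"{feat}-"),
        )
        res = fisher_exact_two_sided(tab)
        rows.append(
            {
                "feature": feat,
                "a": tab.a,
                "b": tab.b,
                "c": tab.c,
                "d": tab.d,
                "pct_smrnp": res.effect["pct_row1"],
                "pct_rola": res.effect["pct_row2"],
                "odds_ratio": res.statistic,
                "p": res.p_two_sided,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_bh"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
        out = out.set_index("feature")
    return out
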