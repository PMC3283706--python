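"""Synthetic SLE/control cohort generator.

The analysis pipeline (cutoff calibration, Z-scores, relative-ratio
clustering, association screens, mixture assay) is exercised on simulated
cohorts with the statistical structure the method assumes:

* control titers are log-normal per antigen — LIPS titers are strictly
  positive luminometer counts whose patient/control means differ by one to
  two orders of magnitude, which a normal model cannot accommodate;
* each SLE patient carries one of three latent classes (``SM_RNP``,
  ``RO_LA``, ``SERONEGATIVE``); given the class, each antigen is
  seropositive with a class-specific probability, and a seropositive titer
  is the control log-normal shifted up by a class- and antigen-specific
  log10 offset;
* the ``SERONEGATIVE`` class is forced seronegative on all six core
  antigens;
* clinical manifestation flags are Bernoulli with class-specific rates,
  conditionally independent given the class.

The latent class of each simulated patient is written to a separate truth
table, never into the analysis input, so label-recovery checks cannot leak.

Reproducibility: one global seed feeds a root ``SeedSequence``; every
subject gets an independent child stream keyed by its position, so the
cohort is bit-reproducible and independent of generation order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from . import reference_cohorts as ref
from .cohort import (
    CLINICAL_FLAGS,
    CORE_ANTIGENS,
    EXTRA_ANTIGENS,
    GROUP_CONTROL,
    GROUP_SLE,
    RO_LA,
    RO_LA_TRIO,
    SERONEGATIVE,
    SM_RNP,
    SM_RNP_TRIO,
    CohortTable,
)

LATENT_CLASSES = (SM_RNP, RO_LA, SERONEGATIVE)


class ConfigError(ValueError):
    """Raised when a simulation configuration is invalid."""


@dataclass
class SimConfig:
    """Parameters of the cohort generator.

    Probabilities are per antigen x latent class (``seropos_prob``,
    ``pos_log_shift``) or per clinical flag x latent class
    (``clinical_rates``). Titer locations/scales are log10 light units.
    """

    n_sle: int
    n_control: int
    antigen_names: list[str]
    cluster_probs: tuple[float, float, float]  # SM_RNP, RO_LA, SERONEGATIVE
    seropos_prob: dict[str, dict[str, float]]
    control_log_mean: dict[str, float]
    control_log_sd: dict[str, float]
    pos_log_shift: dict[str, dict[str, float]]
    clinical_rates: dict[str, dict[str, float]]
    mixture_noise_cv: float = 0.2
    female_prob: float = ref.FEMALE_FRACTION
    ethnicity_probs: dict[str, float] = field(
        default_factory=lambda: {"C": 0.55, "AA": 0.40, "A": 0.05}
    )
    age_group_probs: dict[str, float] = field(
        default_factory=lambda: dict(ref.AGE_GROUP_PROBS)
    )
    dsdna_prob: float = ref.DSDNA_POSITIVE_FRACTION
    seed: int = 0

    def __post_init__(self) -> None:
        self.cluster_probs = tuple(float(p) for p in self.cluster_probs)
        self.validate()

    def validate(self) -> None:
        if self.n_sle < 1 or self.n_control < 1:
            raise ConfigError("n_sle and n_control must be >= 1")
        if len(self.cluster_probs) != 3:
            raise ConfigError("cluster_probs needs exactly three entries")
        if abs(sum(self.cluster_probs) - 1.0) > 1e-9:
            raise ConfigError(
                f"cluster_probs must sum to 1 (got {sum(self.cluster_probs)!r})"
            )
        for name, probs in [
            ("cluster_probs", dict(enumerate(self.cluster_probs))),
            ("female_prob", {"": self.female_prob}),
            ("dsdna_prob", {"": self.dsdna_prob}),
            ("ethnicity_probs", self.ethnicity_probs),
            ("age_group_probs", self.age_group_probs),
        ]:
            for key, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(f"{name}[{key!r}] = {p} is not in [0, 1]")
        for antigen in self.antigen_names:
            if antigen not in self.control_log_mean:
                raise ConfigError(f"control_log_mean missing antigen {antigen!r}")
            if antigen not in self.control_log_sd:
                raise ConfigError(f"control_log_sd missing antigen {antigen!r}")
            if self.control_log_sd[antigen] <= 0:
                raise ConfigError(f"control_log_sd[{antigen!r}] must be > 0")
            for cls, p in self.seropos_prob.get(antigen, {}).items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(
                        f"seropos_prob[{antigen!r}][{cls!r}] = {p} is not in [0, 1]"
                    )
        for flag, rates in self.clinical_rates.items():
            for cls, p in rates.items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(
                        f"clinical_rates[{flag!r}][{cls!r}] = {p} is not in [0, 1]"
                    )
        if self.mixture_noise_cv < 0:
            raise ConfigError("mixture_noise_cv must be >= 0")

    # -- YAML round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, np.floating):
                return float(obj)
            if isinstance(obj, np.integer):
                return int(obj)
            return obj

        d = plain(dataclasses.asdict(self))
        d["cluster_probs"] = [float(p) for p in self.cluster_probs]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _lognormal_params_from_mean_ci(mean: float, lo: float, hi: float, n: int) -> tuple[float, float]:
    """log10 location/scale matching an arithmetic mean and normal-theory 95% CI.

    The CI half-width is read as 1.96 * SD / sqrt(n); the log-normal with the
    same arithmetic mean and SD has sigma^2 = ln(1 + cv^2) and
    mu = ln(mean) - sigma^2 / 2 (natural log, converted to log10).
    """
    half = (hi - lo) / 2.0
    sd = half * np.sqrt(n) / 1.96
    cv = sd / mean
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    ln10 = np.log(10.0)
    return mu / ln10, np.sqrt(sigma2) / ln10


def _own_shift(
    sle_mean: float,
    control_mean: float,
    sens: float,
    own_mass: float,
    cross_mass: float,
    floor: float = 0.7,
) -> float:
    """Own-trio log10 titer shift reproducing a printed whole-cohort SLE mean.

    The whole-cohort SLE mean is approximately
    ``(1 - sens) * control_mean + control_mean * (own_mass * 10^s + cross_mass
    * 10^(s-1))`` when cross-trio positives sit one decade below own-trio
    positives. Solved for ``s``, floored so positives clear the mean+3SD
    cutoff by a wide margin.
    """
    numer = sle_mean - (1.0 - sens) * control_mean
    denom = control_mean * (own_mass + cross_mass / 10.0)
    if numer <= 0 or denom <= 0:
        return floor
    return max(float(np.log10(numer / denom)), floor)


def default_config_from_tables(
    n_sle: int = ref.VALIDATION_N_SLE,
    n_control: int = ref.VALIDATION_N_CONTROL,
    include_extras: bool = True,
    seed: int = 0,
) -> SimConfig:
    """Generator configuration calibrated to the validation-cohort summaries.

    Control log-normal parameters reproduce the printed control mean titers
    (e.g. Sm-D3 4,800 LU; RNP-70k 28,800 LU) with SDs back-computed from the
    95% CI half-widths at the printed control n of 15. Class-conditional
    seropositivity probabilities are solved so the marginal seropositive
    fraction per core antigen matches the printed sensitivity under the
    default class mix, with own-trio reactivity near-saturated (every
    clustered patient reacts to its own trio far more often than to the
    other). Own-trio titer shifts are one decade above cross-trio shifts and
    sized from the printed whole-cohort SLE mean titers.
    """
    pi_sm, pi_ro, _ = ref.VALIDATION_CLUSTER_PROBS

    # own-trio seropositivity chosen near saturation; cross-trio rate then
    # solves  sens = pi_own * q_own + pi_cross * q_cross
    own_rate = {
        "Sm-D3": 0.95,
        "RNP-A": 0.90,
        "RNP-70k": 1.00,
        "Ro52": 0.85,
        "Ro60": 0.85,
        "La": 0.95,
    }

    antigens = list(CORE_ANTIGENS) + (list(EXTRA_ANTIGENS) if include_extras else [])
    control_log_mean: dict[str, float] = {}
    control_log_sd: dict[str, float] = {}
    seropos: dict[str, dict[str, float]] = {}
    shifts: dict[str, dict[str, float]] = {}

    for antigen in CORE_ANTIGENS:
        mean, lo, hi = ref.VALIDATION_CONTROL_TITERS[antigen]
        mu, sd = _lognormal_params_from_mean_ci(mean, lo, hi, ref.VALIDATION_N_CONTROL)
        control_log_mean[antigen] = mu
        control_log_sd[antigen] = sd

        sens = ref.VALIDATION_SENSITIVITY[antigen] / 100.0
        own = SM_RNP if antigen in SM_RNP_TRIO else RO_LA
        pi_own = pi_sm if own == SM_RNP else pi_ro
        pi_cross = pi_ro if own == SM_RNP else pi_sm
        q_own = own_rate[antigen]
        q_cross = float(np.clip((sens - pi_own * q_own) / pi_cross, 0.0, 1.0))
        seropos[antigen] = {
            own: q_own,
            (RO_LA if own == SM_RNP else SM_RNP): q_cross,
            SERONEGATIVE: 0.0,
        }

        sle_means = {  # printed whole-cohort SLE mean titers (LU)
            "Ro52": 895_000, "Ro60": 1_200_000, "La": 464_000,
            "Sm-D3": 77_000, "RNP-A": 276_000, "RNP-70k": 559_000,
        }
        s = _own_shift(sle_means[antigen], mean, sens, pi_own * q_own, pi_cross * q_cross)
        shifts[antigen] = {
            own: s,
            (RO_LA if own == SM_RNP else SM_RNP): s - 1.0,
            SERONEGATIVE: 0.0,
        }

    if include_extras:
        extra_sle_means = {
            "IFN-a": 88_000, "IFN-w": 7_800, "AQP-4": 27_000,
            "GAD65": 4_200, "GFAP": 21_000, "TH": 15_000,
        }
        for antigen in EXTRA_ANTIGENS:
            mean, lo, hi = ref.VALIDATION_EXTRA_TITERS[antigen]
            mu, sd = _lognormal_params_from_mean_ci(mean, lo, hi, ref.VALIDATION_N_CONTROL)
            control_log_mean[antigen] = mu
            control_log_sd[antigen] = sd
            sens = ref.VALIDATION_EXTRA_SENSITIVITY[antigen] / 100.0
            ro_pct, sm_pct = ref.CLUSTER_ANTIBODY_PCT[antigen]
            seropos[antigen] = {
                SM_RNP: sm_pct / 100.0,
                RO_LA: ro_pct / 100.0,
                SERONEGATIVE: 0.0,
            }
            s = _own_shift(extra_sle_means[antigen], mean, sens, sens, 0.0)
            shifts[antigen] = {SM_RNP: s, RO_LA: s, SERONEGATIVE: 0.0}

    # printed per-cluster clinical rates; the (rare) seronegative class gets
    # the mean of the two cluster rates — no printed value exists for it.
    clinical_rates: dict[str, dict[str, float]] = {}
    for flag in CLINICAL_FLAGS:
        ro_pct, sm_pct = ref.CLUSTER_CLINICAL_PCT[flag]
        clinical_rates[flag] = {
            SM_RNP: sm_pct / 100.0,
            RO_LA: ro_pct / 100.0,
            SERONEGATIVE: (sm_pct + ro_pct) / 200.0,
        }

    return SimConfig(
        n_sle=n_sle,
        n_control=n_control,
        antigen_names=antigens,
        cluster_probs=ref.VALIDATION_CLUSTER_PROBS,
        seropos_prob=seropos,
        control_log_mean=control_log_mean,
        control_log_sd=control_log_sd,
        pos_log_shift=shifts,
        clinical_rates=clinical_rates,
        seed=seed,
    )


def true_control_moments(config: SimConfig, antigen: str) -> tuple[float, float]:
    """Analytic arithmetic mean and SD of the control titer log-normal."""
    ln10 = np.log(10.0)
    mu = config.control_log_mean[antigen] * ln10
    sigma = config.control_log_sd[antigen] * ln10
    mean = float(np.exp(mu + sigma**2 / 2.0))
    sd = float(mean * np.sqrt(np.expm1(sigma**2)))
    return mean, sd


def true_cutoff(config: SimConfig, antigen: str) -> float:
    """Generating-distribution mean + 3 SD cutoff for one antigen."""
    mean, sd = true_control_moments(config, antigen)
    return mean + 3.0 * sd


def expected_seropositive_fraction(config: SimConfig, antigen: str) -> float:
    """P(titer > true generating cutoff) for a random SLE patient.

    Accounts for both latent positives falling below the cutoff and control
    draws exceeding it (log-normal tail), so Monte-Carlo checks of the
    marginal seropositive frequency have an exact expectation.
    """
    cut = true_cutoff(config, antigen)
    mu, sd = config.control_log_mean[antigen], config.control_log_sd[antigen]
    zcut = (np.log10(cut) - mu) / sd
    p_ctrl_above = float(norm.sf(zcut))
    total = 0.0
    for cls, pi in zip(LATENT_CLASSES, config.cluster_probs):
        if cls == SERONEGATIVE and antigen in CORE_ANTIGENS:
            continue  # truncated below the cutoff by construction
        q = config.seropos_prob.get(antigen, {}).get(cls, 0.0)
        shift = config.pos_log_shift.get(antigen, {}).get(cls, 0.0)
        p_pos_above = float(norm.sf(zcut - shift / sd))
        total += pi * (q * p_pos_above + (1.0 - q) * p_ctrl_above)
    return total


def _draw_titer(z: float, config: SimConfig, antigen: str, shift: float) -> float:
    return 10.0 ** (
        config.control_log_mean[antigen] + config.control_log_sd[antigen] * z + shift
    )


def _categorical(u: float, probs: dict[str, float]) -> str:
    acc = 0.0
    keys = list(probs)
    for key in keys:
        acc += probs[key]
        if u < acc:
            return key
    return keys[-1]


def generate_cohort(config: SimConfig) -> tuple[CohortTable, pd.DataFrame]:
    """Simulate one cohort; returns the cohort and the latent-class truth.

    The truth table (``patient_id``, ``latent_class``; SLE patients only) is
    kept out of the cohort table so downstream analyses cannot see it.
    Deterministic given ``config.seed``.
    """
    config.validate()
    panel = config.antigen_names
    n_total = config.n_control + config.n_sle
    children = np.random.SeedSequence(config.seed).spawn(n_total)

    rows: list[dict] = []
    truth_rows: list[dict] = []

    for i in range(config.n_control):
        rng = np.random.default_rng(children[i])
        z = rng.standard_normal(len(panel))
        row = {"patient_id": f"CTRL-{i + 1:04d}", "group": GROUP_CONTROL}
        for j, antigen in enumerate(panel):
            row[antigen] = _draw_titer(z[j], config, antigen, 0.0)
        u = rng.random(3)
        row["sex"] = "F" if u[0] < config.female_prob else "M"
        row["ethnicity"] = _categorical(u[1], config.ethnicity_probs)
        row["age_group"] = _categorical(u[2], config.age_group_probs)
        rows.append(row)

    for i in range(config.n_sle):
        rng = np.random.default_rng(children[config.n_control + i])
        pid = f"SLE-{i + 1:04d}"
        u_class = rng.random()
        acc = 0.0
        latent = LATENT_CLASSES[-1]
        for cls, pi in zip(LATENT_CLASSES, config.cluster_probs):
            acc += pi
            if u_class < acc:
                latent = cls
                break
        u_pos = rng.random(len(panel))
        z = rng.standard_normal(len(panel))
        row = {"patient_id": pid, "group": GROUP_SLE}
        for j, antigen in enumerate(panel):
            if latent == SERONEGATIVE and antigen in CORE_ANTIGENS:
                # the seronegative class never reacts to the core panel: its
                # control-level draw is truncated below the generating cutoff
                # so the contract holds surely, not just with high probability
                mu = config.control_log_mean[antigen]
                sd = config.control_log_sd[antigen]
                zcut = (np.log10(true_cutoff(config, antigen)) - mu) / sd
                zt = norm.ppf(norm.cdf(z[j]) * norm.cdf(zcut))
                row[antigen] = _draw_titer(float(zt), config, antigen, 0.0)
                continue
            q = config.seropos_prob.get(antigen, {}).get(latent, 0.0)
            positive = u_pos[j] < q
            shift = config.pos_log_shift.get(antigen, {}).get(latent, 0.0) if positive else 0.0
            row[antigen] = _draw_titer(z[j], config, antigen, shift)
        u_flags = rng.random(len(CLINICAL_FLAGS))
        for k, flag in enumerate(CLINICAL_FLAGS):
            rate = config.clinical_rates.get(flag, {}).get(latent, 0.0)
            row[flag] = int(u_flags[k] < rate)
        u = rng.random(4)
        row["sex"] = "F" if u[0] < config.female_prob else "M"
        row["ethnicity"] = _categorical(u[1], config.ethnicity_probs)
        row["age_group"] = _categorical(u[2], config.age_group_probs)
        row["dsdna_pos"] = int(u[3] < config.dsdna_prob)
        rows.append(row)
        truth_rows.append({"patient_id": pid, "latent_class": latent})

    data = pd.DataFrame(rows).set_index("patient_id")
    truth = pd.DataFrame(truth_rows).set_index("patient_id")
    return CohortTable(data, list(panel)), truth


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, index=True, index_label="patient_id")


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="patient_id")
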