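"""Synthetic serum-biomarker cohorts with known ground truth.

Generates multiplex-immunoassay-style cohorts — samples by analytes, with
plate batch effects, limit-of-quantitation censoring and low-volume dropout —
whose statistical structure mirrors a two-cohort (discovery/validation)
epidemiological biomarker study of sex and female hormonal status.  Every
planted effect is retained in the :class:`EffectSpec`, so downstream
preprocessing, modeling, simulation and classification stages can be tested
for parameter recovery and error control without access to real study data.

Concentrations are log-normal: on the log2 scale each analyte is

    log2(conc) = baseline + group_shift[group] + sum_c loading[c] * (x_c - center_c) + eps

with ``eps ~ Normal(0, residual_sd)``.  Group shifts are expressed relative
to the mean of the follicular and luteal groups ("cycling females"), so the
follicular and luteal shifts of every analyte average to zero.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Labels, covariates, status codes
# ---------------------------------------------------------------------------

#: The five analysis groups.  Females on non-OC sex hormones, pregnant or
#: breastfeeding females, hysterectomized females and females of unknown
#: hormonal status are never analysis groups; they are carried as exclusion
#: flags on otherwise ordinary samples.
GROUPS = ("male", "follicular", "luteal", "oc_user", "postmenopausal")

FEMALE_GROUPS = ("follicular", "luteal", "oc_user", "postmenopausal")
CYCLING_GROUPS = ("follicular", "luteal")

STATUS_MEASURED = "measured"
STATUS_BELOW = "below_loq"
STATUS_ABOVE = "above_loq"
STATUS_LOW_VOLUME = "low_volume_missing"
STATUS_CODES = (STATUS_MEASURED, STATUS_BELOW, STATUS_ABOVE, STATUS_LOW_VOLUME)

EXCLUSION_FLAGS = (
    "pregnant_breastfeeding",
    "non_oc_hormones",
    "hysterectomy",
    "unknown_status",
)

#: Covariates available to the per-analyte linear models (16).
MODEL_COVARIATES = (
    "collection_site",
    "recruitment",
    "chronic_disease",
    "lipid_agents",
    "anti_inflammatory",
    "antihypertensive",
    "ancestry",
    "education",
    "physical_activity",
    "bmi",
    "age",
    "alcohol",
    "smoking",
    "drug_use",
    "partner",
    "ids_score",
)

#: Covariates available to the classifier (18): the model covariates minus
#: recruitment method, plus waist circumference and blood pressures.
CLASSIFIER_COVARIATES = tuple(
    c for c in MODEL_COVARIATES if c != "recruitment"
) + ("waist", "systolic_bp", "diastolic_bp")

ALL_COVARIATES = MODEL_COVARIATES + ("waist", "systolic_bp", "diastolic_bp")

CONTINUOUS_COVARIATES = (
    "education",
    "physical_activity",
    "bmi",
    "age",
    "alcohol",
    "ids_score",
    "waist",
    "systolic_bp",
    "diastolic_bp",
)

CATEGORICAL_COVARIATES = tuple(
    c for c in ALL_COVARIATES if c not in CONTINUOUS_COVARIATES
)

#: Centering constants used when applying covariate loadings on the log2
#: scale, so that per-analyte baselines stay interpretable.
_COVARIATE_CENTERS = {"age": 40.0, "bmi": 25.0}


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the field."""


def stage_rng(seed: int, *keys) -> np.random.Generator:
    """Child random generator for a named pipeline stage.

    A single user-facing seed fans out to independent per-stage streams via
    ``SeedSequence`` keyed on the stage labels (strings hashed with crc32),
    so each stage can be re-run in isolation without perturbing the others.
    """
    entropy = [int(seed) & 0x7FFFFFFF]
    for k in keys:
        if isinstance(k, str):
            entropy.append(zlib.crc32(k.encode()))
        else:
            entropy.append(int(k) & 0xFFFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(entropy))


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class AnalyteMatrix:
    """Samples-by-analytes concentrations with per-cell status codes.

    ``values`` holds positive concentrations (arbitrary per-analyte units)
    where the status is ``measured`` and NaN elsewhere; ``status`` holds one
    of the four status codes per cell.  ``truth`` optionally retains the
    pre-degradation concentrations for parameter-recovery tests.
    """

    values: pd.DataFrame
    status: pd.DataFrame
    truth: pd.DataFrame | None = None

    def __post_init__(self):
        if self.values.shape != self.status.shape:
            raise ValueError("values and status dimensions differ")
        if not self.values.index.equals(self.status.index) or not (
            self.values.columns.equals(self.status.columns)
        ):
            raise ValueError("values and status must share index and columns")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_analytes(self) -> int:
        return self.values.shape[1]

    @property
    def analyte_ids(self) -> list[str]:
        return list(self.values.columns)

    def measured_mask(self) -> pd.DataFrame:
        return self.status == STATUS_MEASURED

    def copy(self) -> "AnalyteMatrix":
        return AnalyteMatrix(
            self.values.copy(),
            self.status.copy(),
            None if self.truth is None else self.truth.copy(),
        )


@dataclass
class EffectSpec:
    """Ground truth of a generated cohort.

    ``group_shift`` rows are log2 shifts relative to the cycling-female
    reference (mean of follicular and luteal); rows of analytes unaffected
    by sex and hormonal status are identically zero.
    """

    analyte_ids: list[str]
    baseline_log2: pd.Series
    group_shift: pd.DataFrame            # analytes x GROUPS, log2 units
    covariate_loading: pd.DataFrame      # analytes x continuous covariates
    residual_sd: pd.Series               # log2 units, > 0
    batch_additive: pd.Series            # per plate, log2 units
    batch_scale: pd.Series               # per plate, > 0 (scales log2 residuals)
    loq_lower_quantile: float
    loq_upper_quantile: float
    low_volume_rate: float
    fraction_sex_affected: float
    fraction_hormone_affected: float
    sex_affected: list[str] = field(default_factory=list)
    hormone_affected: list[str] = field(default_factory=list)

    def __post_init__(self):
        if (self.residual_sd <= 0).any():
            raise ConfigError("residual_sd must be > 0 for every analyte")
        if (self.batch_scale <= 0).any():
            raise ConfigError("batch_scale must be > 0 for every plate")
        for name in ("loq_lower_quantile", "loq_upper_quantile",
                     "low_volume_rate", "fraction_sex_affected",
                     "fraction_hormone_affected"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")

    @property
    def n_plates(self) -> int:
        return len(self.batch_additive)

    def to_json(self) -> str:
        payload = {
            "analyte_ids": self.analyte_ids,
            "baseline_log2": self.baseline_log2.to_dict(),
            "group_shift": self.group_shift.to_dict(orient="index"),
            "covariate_loading": self.covariate_loading.to_dict(orient="index"),
            "residual_sd": self.residual_sd.to_dict(),
            "batch_additive": self.batch_additive.to_dict(),
            "batch_scale": self.batch_scale.to_dict(),
            "loq_lower_quantile": self.loq_lower_quantile,
            "loq_upper_quantile": self.loq_upper_quantile,
            "low_volume_rate": self.low_volume_rate,
            "fraction_sex_affected": self.fraction_sex_affected,
            "fraction_hormone_affected": self.fraction_hormone_affected,
            "sex_affected": self.sex_affected,
            "hormone_affected": self.hormone_affected,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "EffectSpec":
        d = json.loads(text)
        ids = d["analyte_ids"]
        return cls(
            analyte_ids=ids,
            baseline_log2=pd.Series(d["baseline_log2"]).loc[ids],
            group_shift=pd.DataFrame.from_dict(
                d["group_shift"], orient="index"
            ).loc[ids, list(GROUPS)],
            covariate_loading=pd.DataFrame.from_dict(
                d["covariate_loading"], orient="index"
            ).loc[ids],
            residual_sd=pd.Series(d["residual_sd"]).loc[ids],
            batch_additive=pd.Series(
                {int(k): v for k, v in d["batch_additive"].items()}
            ).sort_index(),
            batch_scale=pd.Series(
                {int(k): v for k, v in d["batch_scale"].items()}
            ).sort_index(),
            loq_lower_quantile=d["loq_lower_quantile"],
            loq_upper_quantile=d["loq_upper_quantile"],
            low_volume_rate=d["low_volume_rate"],
            fraction_sex_affected=d["fraction_sex_affected"],
            fraction_hormone_affected=d["fraction_hormone_affected"],
            sex_affected=d["sex_affected"],
            hormone_affected=d["hormone_affected"],
        )


# ---------------------------------------------------------------------------
# Generator configuration
# ---------------------------------------------------------------------------


@dataclass
class GeneratorConfig:
    """Settings of the cohort generator.

    Defaults emulate the published study conditions: a 171-analyte panel in
    which 96/171 analytes differ by sex and 66/171 vary with female hormonal
    status (45 of those overlapping the sex-affected set, for 117 affected
    in total), 26 assay plates, between-plate additive shifts of SD 0.15
    log2 and multiplicative residual scaling consistent with the reported
    inter-assay CV of ~10.6%.
    """

    n_analytes: int = 171
    fraction_sex_affected: float = 96 / 171
    fraction_hormone_affected: float = 66 / 171
    #: fraction of hormone-affected analytes drawn from the sex-affected set
    hormone_sex_overlap: float = 45 / 66
    #: fraction of hormone-affected analytes with a follicular/luteal shift
    cycle_phase_fraction: float = 5 / 66
    effect_low: float = 0.1
    effect_high: float = 1.5
    baseline_low: float = 2.0
    baseline_high: float = 10.0
    residual_sd_low: float = 0.2
    residual_sd_high: float = 0.8
    fraction_covariate_affected: float = 0.5
    age_loading_max: float = 0.02     # log2 per year
    bmi_loading_max: float = 0.04     # log2 per kg/m^2
    n_plates: int = 26
    batch_additive_sd: float = 0.15   # log2
    batch_scale_sigma: float = 0.10   # SD of log batch scale
    loq_lower_quantile: float = 0.01
    loq_upper_quantile: float = 0.005
    low_volume_rate: float = 0.005
    #: covariate-group confounding (older postmenopausal group etc.)
    confound_covariates: bool = True

    def validate(self) -> None:
        for name in ("fraction_sex_affected", "fraction_hormone_affected",
                     "hormone_sex_overlap", "cycle_phase_fraction",
                     "fraction_covariate_affected", "loq_lower_quantile",
                     "loq_upper_quantile", "low_volume_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_analytes", "n_plates"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in ("residual_sd_low", "residual_sd_high",
                     "batch_scale_sigma"):
            if getattr(self, name) < 0 or (
                name.startswith("residual") and getattr(self, name) <= 0
            ):
                raise ConfigError(f"{name} must be positive")


def default_sizes() -> dict[str, dict[str, int]]:
    """Per-group sample counts of the study's discovery and validation cohorts."""
    return {
        "discovery": {
            "male": 140, "follicular": 34, "luteal": 37,
            "oc_user": 79, "postmenopausal": 57,
        },
        "validation": {
            "male": 445, "follicular": 149, "luteal": 211,
            "oc_user": 263, "postmenopausal": 261,
        },
    }


# ---------------------------------------------------------------------------
# Effect spec construction
# ---------------------------------------------------------------------------


def build_effect_spec(config: GeneratorConfig | None = None,
                      seed: int = 0) -> EffectSpec:
    """Draw a fully populated ground-truth :class:`EffectSpec`.

    The sex-affected set has exactly ``round(fraction_sex_affected *
    n_analytes)`` members; the hormone-affected set overlaps it by
    ``round(hormone_sex_overlap * n_hormone)`` members.  Deterministic given
    the seed.
    """
    config = config or GeneratorConfig()
    config.validate()
    rng = stage_rng(seed, "effect_spec")
    n = config.n_analytes
    ids = [f"A{i:03d}" for i in range(1, n + 1)]

    baseline = pd.Series(
        rng.uniform(config.baseline_low, config.baseline_high, n), index=ids
    )
    residual_sd = pd.Series(
        rng.uniform(config.residual_sd_low, config.residual_sd_high, n),
        index=ids,
    )

    n_sex = int(round(config.fraction_sex_affected * n))
    n_horm = int(round(config.fraction_hormone_affected * n))
    sex_set = list(rng.choice(ids, size=n_sex, replace=False))
    n_overlap = min(int(round(config.hormone_sex_overlap * n_horm)), n_sex)
    n_outside = min(n_horm - n_overlap, n - n_sex)
    horm_set = list(rng.choice(sex_set, size=n_overlap, replace=False)) + list(
        rng.choice([a for a in ids if a not in sex_set],
                   size=n_outside, replace=False)
    )

    shift = pd.DataFrame(0.0, index=ids, columns=list(GROUPS))

    def _draw(k):
        return rng.choice([-1.0, 1.0], k) * rng.uniform(
            config.effect_low, config.effect_high, k
        )

    shift.loc[sex_set, "male"] = _draw(len(sex_set))
    if horm_set:
        shift.loc[horm_set, "oc_user"] = _draw(len(horm_set))
        # postmenopausal levels tend toward male levels for sex-affected
        # analytes; random direction otherwise
        pm = rng.uniform(config.effect_low, min(1.0, config.effect_high),
                         len(horm_set))
        sign = np.where(
            [a in sex_set for a in horm_set],
            np.sign(shift.loc[horm_set, "male"].to_numpy()),
            rng.choice([-1.0, 1.0], len(horm_set)),
        )
        sign = np.where(sign == 0, 1.0, sign)
        shift.loc[horm_set, "postmenopausal"] = sign * pm
        n_cycle = int(round(config.cycle_phase_fraction * len(horm_set)))
        if n_cycle:
            cyc = rng.choice(horm_set, size=n_cycle, replace=False)
            d = rng.choice([-1.0, 1.0], n_cycle) * rng.uniform(
                0.1, 0.5, n_cycle
            )
            # keep the cycling-female reference (mean of phases) at zero
            shift.loc[cyc, "follicular"] = d / 2.0
            shift.loc[cyc, "luteal"] = -d / 2.0

    loading = pd.DataFrame(0.0, index=ids, columns=["age", "bmi"])
    n_cov = int(round(config.fraction_covariate_affected * n))
    cov_set = rng.choice(ids, size=n_cov, replace=False)
    loading.loc[cov_set, "age"] = rng.uniform(
        -config.age_loading_max, config.age_loading_max, n_cov
    )
    loading.loc[cov_set, "bmi"] = rng.uniform(
        -config.bmi_loading_max, config.bmi_loading_max, n_cov
    )

    plates = list(range(1, config.n_plates + 1))
    batch_additive = pd.Series(
        rng.normal(0.0, config.batch_additive_sd, config.n_plates),
        index=plates,
    )
    batch_scale = pd.Series(
        np.exp(rng.normal(0.0, config.batch_scale_sigma, config.n_plates)),
        index=plates,
    )

    return EffectSpec(
        analyte_ids=ids,
        baseline_log2=baseline,
        group_shift=shift,
        covariate_loading=loading,
        residual_sd=residual_sd,
        batch_additive=batch_additive,
        batch_scale=batch_scale,
        loq_lower_quantile=config.loq_lower_quantile,
        loq_upper_quantile=config.loq_upper_quantile,
        low_volume_rate=config.low_volume_rate,
        fraction_sex_affected=config.fraction_sex_affected,
        fraction_hormone_affected=config.fraction_hormone_affected,
        sex_affected=sorted(sex_set),
        hormone_affected=sorted(horm_set),
    )


# ---------------------------------------------------------------------------
# Covariate generation
# ---------------------------------------------------------------------------

# group-conditional age distributions (mean, sd); chosen so that the
# postmenopausal group is markedly older, reproducing realistic
# covariate-group confounding
_AGE_PARAMS = {
    "male": (42.0, 12.0),
    "follicular": (32.0, 8.0),
    "luteal": (32.0, 8.0),
    "oc_user": (28.0, 6.0),
    "postmenopausal": (56.0, 4.0),
}


def _draw_covariates(rng: np.random.Generator, group: str, cohort: str,
                     n: int, confound: bool) -> pd.DataFrame:
    if confound:
        mu, sd = _AGE_PARAMS[group]
    else:
        mu, sd = 40.0, 12.0
    age = np.clip(rng.normal(mu, sd, n), 18.0, 65.0)
    bmi_mu = 26.0 if (confound and group == "postmenopausal") else 24.5
    bmi = np.clip(rng.normal(bmi_mu, 3.8, n), 16.0, 45.0)
    waist = np.clip(2.4 * bmi + rng.normal(25.0, 6.0, n), 55.0, 160.0)
    systolic = np.clip(100.0 + 0.5 * age + rng.normal(0.0, 12.0, n),
                       85.0, 210.0)
    diastolic = np.clip(60.0 + 0.3 * age + rng.normal(0.0, 8.0, n),
                        45.0, 130.0)
    ids_mu = 8.0 if cohort == "discovery" else 24.0
    ids_score = np.clip(rng.normal(ids_mu, 6.0, n), 0.0, 84.0)
    p_chronic = np.clip(0.05 + 0.004 * (age - 18.0), 0.0, 1.0)
    p_antihyp = np.clip(0.01 + 0.005 * (age - 18.0), 0.0, 1.0)
    return pd.DataFrame({
        "collection_site": rng.choice(["site1", "site2", "site3"], n),
        "recruitment": rng.choice(
            ["community", "general_practice", "mental_health_care"],
            n, p=[0.19, 0.54, 0.27],
        ),
        "chronic_disease": (rng.random(n) < p_chronic).astype(int),
        "lipid_agents": (rng.random(n) < 0.08).astype(int),
        "anti_inflammatory": (rng.random(n) < 0.05).astype(int),
        "antihypertensive": (rng.random(n) < p_antihyp).astype(int),
        "ancestry": rng.choice(["european", "other"], n, p=[0.95, 0.05]),
        "education": np.clip(rng.normal(12.0, 3.0, n), 5.0, 22.0),
        "physical_activity": np.clip(
            rng.normal(7000.0, 3000.0, n), 0.0, None
        ),
        "bmi": bmi,
        "age": age,
        "alcohol": np.clip(rng.normal(5.0, 4.5, n), 0.0, None),
        "smoking": rng.choice(["never", "former", "current"],
                              n, p=[0.45, 0.3, 0.25]),
        "drug_use": (rng.random(n) < 0.05).astype(int),
        "partner": (rng.random(n) < 0.7).astype(int),
        "ids_score": ids_score,
        "waist": waist,
        "systolic_bp": systolic,
        "diastolic_bp": diastolic,
    })


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def generate_cohort(spec: EffectSpec,
                    sizes: Mapping[str, Mapping[str, int]] | Mapping[str, int] | None = None,
                    seed: int = 0,
                    confound_covariates: bool = True,
                    ) -> tuple[AnalyteMatrix, pd.DataFrame]:
    """Simulate a cohort from a ground-truth spec.

    ``sizes`` maps cohort name to per-group counts (a flat group->count
    mapping is treated as a single ``discovery`` cohort); defaults to the
    study's discovery + validation layout.  All cells start ``measured``;
    plate assignment, batch effects and censoring are applied by
    :func:`degrade`.
    """
    if sizes is None:
        sizes = default_sizes()
    elif sizes and all(k in GROUPS for k in sizes):
        sizes = {"discovery": dict(sizes)}
    total = sum(int(v) for coh in sizes.values() for v in coh.values())
    if total <= 0:
        raise ConfigError("total sample count must be positive")
    for coh, counts in sizes.items():
        for g, v in counts.items():
            if g not in GROUPS:
                raise ConfigError(f"unknown group label {g!r}")
            if v < 0:
                raise ConfigError(f"negative count for {coh}/{g}")

    rng = stage_rng(seed, "cohort")
    meta_parts = []
    for cohort in sizes:
        for group in GROUPS:
            n = int(sizes[cohort].get(group, 0))
            if n == 0:
                continue
            cov = _draw_covariates(rng, group, cohort, n,
                                   confound_covariates)
            cov.insert(0, "cohort", cohort)
            cov.insert(1, "group", group)
            meta_parts.append(cov)
    meta = pd.concat(meta_parts, ignore_index=True)
    meta.insert(0, "sample_id", [f"S{i:05d}" for i in range(1, len(meta) + 1)])
    meta["plate"] = 0
    meta["fasting"] = 1
    meta["exclusion_flags"] = ""
    meta = meta.set_index("sample_id")

    ids = spec.analyte_ids
    shift = spec.group_shift.loc[ids].to_numpy()          # analytes x groups
    gidx = np.array([GROUPS.index(g) for g in meta["group"]])
    log2 = (
        spec.baseline_log2.loc[ids].to_numpy()[None, :]
        + shift.T[gidx]
    )
    for cov_name in spec.covariate_loading.columns:
        center = _COVARIATE_CENTERS.get(cov_name, 0.0)
        x = meta[cov_name].to_numpy(dtype=float) - center
        log2 = log2 + np.outer(x, spec.covariate_loading[cov_name].loc[ids])
    eps = rng.normal(0.0, 1.0, log2.shape) * (
        spec.residual_sd.loc[ids].to_numpy()[None, :]
    )
    values = pd.DataFrame(np.exp2(log2 + eps), index=meta.index, columns=ids)
    status = pd.DataFrame(STATUS_MEASURED, index=meta.index, columns=ids)
    return AnalyteMatrix(values, status), meta


def _stratified_plates(meta: pd.DataFrame, n_plates: int,
                       rng: np.random.Generator) -> pd.Series:
    """Stratified randomization of samples to plates, balanced on group."""
    order = []
    for group in GROUPS:
        members = meta.index[meta["group"] == group].to_numpy()
        rng.shuffle(members)
        order.extend(members)
    plates = np.arange(1, n_plates + 1)
    start = rng.integers(0, n_plates)
    assign = plates[(start + np.arange(len(order))) % n_plates]
    return pd.Series(assign, index=pd.Index(order)).loc[meta.index]


def degrade(matrix: AnalyteMatrix, meta: pd.DataFrame, spec: EffectSpec,
            n_plates: int | None = None, seed: int = 0,
            ) -> tuple[AnalyteMatrix, pd.DataFrame]:
    """Apply plate assignment, batch effects and missingness to a clean cohort.

    Samples are assigned to plates by stratified randomization on group; on
    the log2 scale each plate's values get the spec's additive shift and a
    multiplicative scaling of their deviation from the per-analyte mean.
    Cells below / above the per-analyte LOQ quantiles are censored and a
    random fraction is marked as lost to low sample volume.  Pre-degradation
    concentrations are retained on the returned matrix's ``truth``.
    """
    if n_plates is None:
        n_plates = spec.n_plates
    if n_plates < 1:
        raise ConfigError("n_plates must be >= 1")
    if n_plates > spec.n_plates:
        raise ConfigError(
            f"n_plates={n_plates} exceeds the {spec.n_plates} plates "
            "parameterized in the spec"
        )
    rng = stage_rng(seed, "degrade")
    meta = meta.copy()
    meta["plate"] = _stratified_plates(meta, n_plates, rng)

    log2 = np.log2(matrix.values.to_numpy(dtype=float))
    center = log2.mean(axis=0, keepdims=True)
    add = spec.batch_additive.loc[meta["plate"]].to_numpy()[:, None]
    scale = spec.batch_scale.loc[meta["plate"]].to_numpy()[:, None]
    log2 = center + scale * (log2 - center) + add
    values = np.exp2(log2)

    status = np.full(values.shape, STATUS_MEASURED, dtype=object)
    if spec.loq_lower_quantile > 0:
        lo = np.quantile(values, spec.loq_lower_quantile, axis=0,
                         keepdims=True)
        status[values < lo] = STATUS_BELOW
    if spec.loq_upper_quantile > 0:
        hi = np.quantile(values, 1.0 - spec.loq_upper_quantile, axis=0,
                         keepdims=True)
        status[values > hi] = STATUS_ABOVE
    if spec.low_volume_rate > 0:
        lv = rng.random(values.shape) < spec.low_volume_rate
        status[lv] = STATUS_LOW_VOLUME

    out_values = pd.DataFrame(values, index=matrix.values.index,
                              columns=matrix.values.columns)
    truth = out_values.copy()
    out_status = pd.DataFrame(status, index=matrix.values.index,
                              columns=matrix.values.columns)
    out_values[out_status != STATUS_MEASURED] = np.nan
    return AnalyteMatrix(out_values, out_status, truth=truth), meta


# ---------------------------------------------------------------------------
# Exclusion-cascade metadata fixture
# ---------------------------------------------------------------------------


def make_exclusion_metadata(n_total: int,
                            n_non_fasted: int = 56,
                            flag_counts: Mapping[str, int] | None = None,
                            seed: int = 0) -> pd.DataFrame:
    """Metadata-only fixture exercising the ordered sample-exclusion cascade.

    Produces ``n_total`` samples of which ``n_non_fasted`` are flagged as
    non-fasted and, disjointly, ``flag_counts`` samples carry each exclusion
    flag (defaults follow the study's printed counts: 10 pregnant or
    breastfeeding, 18 on non-OC sex hormones, 61 hysterectomized, 11 with
    unknown hormonal status).
    """
    if flag_counts is None:
        flag_counts = {
            "pregnant_breastfeeding": 10,
            "non_oc_hormones": 18,
            "hysterectomy": 61,
            "unknown_status": 11,
        }
    need = n_non_fasted + sum(flag_counts.values())
    if need > n_total:
        raise ConfigError("flag counts exceed n_total")
    rng = stage_rng(seed, "exclusion_meta")
    groups = rng.choice(GROUPS, n_total)
    meta = pd.DataFrame({
        "cohort": "discovery",
        "group": groups,
        "plate": 1,
        "fasting": 1,
        "exclusion_flags": "",
    }, index=pd.Index([f"S{i:05d}" for i in range(1, n_total + 1)],
                      name="sample_id"))
    picks = rng.permutation(n_total)
    pos = 0
    meta.iloc[picks[pos:pos + n_non_fasted],
              meta.columns.get_loc("fasting")] = 0
    pos += n_non_fasted
    for flag in EXCLUSION_FLAGS:
        k = int(flag_counts.get(flag, 0))
        meta.iloc[picks[pos:pos + k],
                  meta.columns.get_loc("exclusion_flags")] = flag
        pos += k
    return meta
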