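"""Cohort preprocessing: exclusion, filtering, imputation, batch adjustment.

The pipeline order is fixed: assay/sample missingness filters -> value and
covariate imputation -> log2 transform + empirical-Bayes batch adjustment ->
robust multivariate outlier removal -> ordered sample-exclusion cascade.
Every stage is a pure function of its inputs and configuration, and the
:class:`PreprocessReport` keeps consistent in/removed/out bookkeeping.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.covariance import MinCovDet

from .synthetic import (
    AnalyteMatrix,
    EXCLUSION_FLAGS,
    STATUS_MEASURED,
    STATUS_BELOW,
    STATUS_ABOVE,
    STATUS_LOW_VOLUME,
    CONTINUOUS_COVARIATES,
    CATEGORICAL_COVARIATES,
)

log = logging.getLogger(__name__)

#: ordered exclusion cascade: (reason, predicate column semantics)
EXCLUSION_ORDER = ("non_fasted",) + EXCLUSION_FLAGS


@dataclass
class PreprocessReport:
    """Bookkeeping of every preprocessing stage."""

    n_assays_in: int = 0
    n_assays_out: int = 0
    n_samples_in: int = 0
    n_samples_out: int = 0
    removals: list[dict] = field(default_factory=list)
    imputation_counts: dict = field(default_factory=dict)
    outlier_samples: list[str] = field(default_factory=list)
    batch_diagnostics: dict = field(default_factory=dict)

    def record(self, stage: str, kind: str, n_in: int, removed: int,
               reason: str = "", items: list | None = None) -> None:
        entry = {
            "stage": stage, "kind": kind, "n_in": n_in,
            "n_removed": removed, "n_out": n_in - removed, "reason": reason,
        }
        if items is not None:
            entry["items"] = list(items)
        self.removals.append(entry)

    def validate(self) -> None:
        for e in self.removals:
            assert e["n_in"] - e["n_removed"] == e["n_out"]

    def to_json(self) -> str:
        self.validate()
        return json.dumps(self.__dict__, indent=1, default=str)


# ---------------------------------------------------------------------------
# Sample exclusion cascade
# ---------------------------------------------------------------------------


def exclude_samples(meta: pd.DataFrame,
                    report: PreprocessReport | None = None,
                    ) -> tuple[list[str], PreprocessReport]:
    """Apply the ordered sample-exclusion cascade; return kept sample ids.

    Removal order: non-fasted samples first, then females who were pregnant
    or breastfeeding, used sex hormones other than the oral contraceptive
    pill, had a hysterectomy, or had unknown hormonal status.  A sample
    matching several rules is removed once, attributed to the first rule.
    """
    report = report or PreprocessReport()
    missing = [c for c in ("fasting", "exclusion_flags") if c not in meta]
    if missing:
        raise ValueError(f"metadata lacks required columns: {missing}")
    if meta["fasting"].isna().any():
        bad = meta.index[meta["fasting"].isna()].tolist()
        raise ValueError(f"samples with missing fasting flag: {bad}")

    flags = meta["exclusion_flags"].fillna("").astype(str)
    flag_sets = flags.apply(lambda s: set(f for f in s.split(";") if f))
    remaining = meta.index.to_numpy()
    for reason in EXCLUSION_ORDER:
        if reason == "non_fasted":
            hit = meta.loc[remaining, "fasting"].astype(int) == 0
        else:
            hit = flag_sets.loc[remaining].apply(lambda s: reason in s)
        removed = remaining[hit.to_numpy()]
        report.record("exclude_samples", "samples", len(remaining),
                      len(removed), reason=reason)
        remaining = remaining[~hit.to_numpy()]
    return list(remaining), report


# ---------------------------------------------------------------------------
# Missingness filters
# ---------------------------------------------------------------------------


def apply_missingness_filters(matrix: AnalyteMatrix,
                              assay_threshold: float = 0.30,
                              sample_threshold: float = 0.30,
                              report: PreprocessReport | None = None,
                              ) -> tuple[AnalyteMatrix, PreprocessReport]:
    """Drop assays, then samples, with too many missing cells.

    A cell is missing when its status is anything but ``measured`` (below-
    and above-LOQ cells count as missing here because this filter precedes
    the LOQ imputation).  Assays with missing fraction strictly greater than
    ``assay_threshold`` are dropped first; then samples with strictly more
    than ``sample_threshold`` missing among the retained assays.
    """
    if not (0 < assay_threshold < 1 and 0 < sample_threshold < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    report = report or PreprocessReport()
    report.n_assays_in = matrix.n_analytes
    report.n_samples_in = matrix.n_samples

    missing = ~matrix.measured_mask()
    assay_frac = missing.mean(axis=0)
    keep_assays = assay_frac.index[assay_frac <= assay_threshold]
    report.record("missingness_filter", "assays", matrix.n_analytes,
                  matrix.n_analytes - len(keep_assays),
                  reason=f"missing fraction > {assay_threshold}",
                  items=list(assay_frac.index[assay_frac > assay_threshold]))
    if len(keep_assays) == 0:
        raise ValueError("all assays filtered out")

    sample_frac = missing[keep_assays].mean(axis=1)
    keep_samples = sample_frac.index[sample_frac <= sample_threshold]
    report.record("missingness_filter", "samples", matrix.n_samples,
                  matrix.n_samples - len(keep_samples),
                  reason=f"missing fraction > {sample_threshold}",
                  items=list(sample_frac.index[sample_frac > sample_threshold]))
    if len(keep_samples) == 0:
        raise ValueError("all samples filtered out")

    out = AnalyteMatrix(
        matrix.values.loc[keep_samples, keep_assays].copy(),
        matrix.status.loc[keep_samples, keep_assays].copy(),
        truth=None if matrix.truth is None
        else matrix.truth.loc[keep_samples, keep_assays].copy(),
    )
    report.n_assays_out = out.n_analytes
    report.n_samples_out = out.n_samples
    return out, report


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------


def impute_values(matrix: AnalyteMatrix, meta: pd.DataFrame | None = None,
                  report: PreprocessReport | None = None,
                  ) -> tuple[AnalyteMatrix, pd.DataFrame | None, PreprocessReport]:
    """Impute censored and missing cells, and missing covariates.

    Per analyte, on the raw concentration scale: below-LOQ cells get the
    minimum of the measured values, above-LOQ cells the maximum, low-volume
    cells the mean.  Continuous covariates are imputed with the mean,
    discrete covariates with the most frequent value.  Measured cells are
    never altered.
    """
    report = report or PreprocessReport()
    values = matrix.values.copy()
    status = matrix.status
    counts = {STATUS_BELOW: 0, STATUS_ABOVE: 0, STATUS_LOW_VOLUME: 0}
    for aid in values.columns:
        col_status = status[aid]
        measured = values.loc[col_status == STATUS_MEASURED, aid]
        nonmeasured = col_status != STATUS_MEASURED
        if not nonmeasured.any():
            continue
        if measured.empty:
            raise ValueError(f"analyte {aid} has no measured values to impute from")
        fills = {
            STATUS_BELOW: measured.min(),
            STATUS_ABOVE: measured.max(),
            STATUS_LOW_VOLUME: measured.mean(),
        }
        for code, fill in fills.items():
            mask = col_status == code
            n = int(mask.sum())
            if n:
                values.loc[mask, aid] = fill
                counts[code] += n
    report.imputation_counts.update({k: int(v) for k, v in counts.items()})

    out_meta = None
    if meta is not None:
        out_meta = meta.copy()
        cov_imputed = {}
        for col in out_meta.columns:
            if col in ("cohort", "group", "plate", "fasting",
                       "exclusion_flags"):
                continue
            miss = out_meta[col].isna()
            if not miss.any():
                continue
            if col in CONTINUOUS_COVARIATES:
                fill = out_meta.loc[~miss, col].astype(float).mean()
            else:
                fill = out_meta.loc[~miss, col].mode().iloc[0]
            out_meta.loc[miss, col] = fill
            cov_imputed[col] = int(miss.sum())
        if cov_imputed:
            report.imputation_counts["covariates"] = cov_imputed

    status_out = status.copy()
    status_out[:] = STATUS_MEASURED
    return AnalyteMatrix(values, status_out, truth=matrix.truth), out_meta, report


# ---------------------------------------------------------------------------
# log2 + empirical-Bayes batch adjustment
# ---------------------------------------------------------------------------


def _eb_iterate(s_data: np.ndarray, g_hat: np.ndarray, d_hat: np.ndarray,
                g_bar: float, t2: float, a: float, b: float,
                conv: float = 1e-4) -> tuple[np.ndarray, np.ndarray]:
    """Iterative posterior solution for one batch's location/scale parameters."""
    n = s_data.shape[1]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(200):
        g_new = (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)
        sum2 = ((s_data - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
            np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def log2_and_batch_adjust(matrix: AnalyteMatrix, plates: pd.Series,
                          report: PreprocessReport | None = None,
                          ) -> tuple[pd.DataFrame, PreprocessReport]:
    """Log2-transform and remove per-plate location/scale batch effects.

    Implements the parametric empirical-Bayes adjustment for additive and
    multiplicative batch effects: per-analyte standardization against the
    pooled mean and variance, per-batch location and scale estimates shrunk
    toward normal / inverse-gamma hyper-priors fitted across analytes, then
    adjustment and de-standardization.  With a single plate the result is
    plain ``log2`` of the input.
    """
    report = report or PreprocessReport()
    vals = matrix.values.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
        raise ValueError("batch adjustment requires finite positive values")
    log2 = np.log2(vals)
    plates = plates.loc[matrix.values.index]
    batches = pd.unique(plates)
    if len(batches) == 1:
        out = pd.DataFrame(log2, index=matrix.values.index,
                           columns=matrix.values.columns)
        report.batch_diagnostics["n_batches"] = 1
        return out, report

    counts = plates.value_counts()
    if (counts < 2).any():
        bad = counts.index[counts < 2].tolist()
        raise ValueError(f"plates with fewer than 2 samples: {bad}")

    # analytes x samples, as in the reference empirical-Bayes formulation
    dat = log2.T
    n_array = dat.shape[1]
    masks = [np.asarray(plates == b) for b in batches]
    n_batches = np.array([m.sum() for m in masks], dtype=float)

    design = np.stack([m.astype(float) for m in masks], axis=1)
    b_hat = np.linalg.solve(design.T @ design, design.T @ dat.T)  # batch x analyte
    grand_mean = (n_batches / n_array) @ b_hat
    resid = dat - (design @ b_hat).T
    var_pooled = (resid ** 2).mean(axis=1)
    var_pooled = np.maximum(var_pooled, 1e-18)
    stand_mean = grand_mean[:, None]
    s_data = (dat - stand_mean) / np.sqrt(var_pooled)[:, None]

    gamma_star = np.empty((len(batches), dat.shape[0]))
    delta_star = np.empty_like(gamma_star)
    for i, m in enumerate(masks):
        sd = s_data[:, m]
        g_hat = sd.mean(axis=1)
        d_hat = sd.var(axis=1, ddof=1)
        g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
        dm, dv = d_hat.mean(), d_hat.var(ddof=1)
        a = (2.0 * dv + dm ** 2) / dv
        b = (dm * dv + dm ** 3) / dv
        gamma_star[i], delta_star[i] = _eb_iterate(sd, g_hat, d_hat,
                                                   g_bar, t2, a, b)

    bayes = s_data.copy()
    for i, m in enumerate(masks):
        bayes[:, m] = (bayes[:, m] - gamma_star[i][:, None]) / np.sqrt(
            delta_star[i]
        )[:, None]
    bayes = bayes * np.sqrt(var_pooled)[:, None] + stand_mean

    report.batch_diagnostics.update({
        "n_batches": int(len(batches)),
        "location_shrunk_range": [float(gamma_star.min()),
                                  float(gamma_star.max())],
        "scale_shrunk_range": [float(delta_star.min()),
                               float(delta_star.max())],
    })
    out = pd.DataFrame(bayes.T, index=matrix.values.index,
                       columns=matrix.values.columns)
    return out, report


# ---------------------------------------------------------------------------
# Robust multivariate outliers
# ---------------------------------------------------------------------------


def flag_multivariate_outliers(data: pd.DataFrame,
                               cutoff_quantile: float = 0.999,
                               max_components: int = 10,
                               seed: int = 0,
                               report: PreprocessReport | None = None,
                               ) -> tuple[list[str], PreprocessReport]:
    """Flag samples with extreme robust Mahalanobis distances.

    Location and scatter come from a high-breakdown minimum-covariance-
    determinant fit with subset size ``h = ceil((n + d + 1) / 2)``; samples
    whose squared robust distance exceeds the chi-square(d) quantile
    ``cutoff_quantile`` are flagged.  When the analyte count approaches the
    sample count the distance is computed on the leading principal-component
    scores (at most ``max_components``) instead of raw analytes.
    """
    report = report or PreprocessReport()
    X = data.to_numpy(dtype=float)
    n, d = X.shape
    if n < 3:
        raise ValueError("need at least 3 samples for a robust scatter")
    used = "analytes"
    if d >= n // 2 or d > max_components:
        k = min(max_components, n // 2 - 1, d)
        scores, _ = pca_scores(data, k=k)
        X = scores.to_numpy()
        d = X.shape[1]
        used = f"pca_scores_{d}"
    h = int(np.ceil((n + d + 1) / 2.0))
    mcd = MinCovDet(support_fraction=min(h / n, 1.0), random_state=seed)
    try:
        mcd.fit(X)
        dist2 = mcd.mahalanobis(X)
    except (np.linalg.LinAlgError, ValueError) as err:
        raise ValueError(
            "singular robust scatter; reduce dimension before outlier "
            "detection"
        ) from err
    if not np.all(np.isfinite(dist2)):
        raise ValueError(
            "singular robust scatter; reduce dimension before outlier "
            "detection"
        )
    cutoff = stats.chi2.ppf(cutoff_quantile, df=d)
    flagged = list(data.index[dist2 > cutoff])
    report.outlier_samples = flagged
    report.record("outlier_removal", "samples", n, len(flagged),
                  reason=f"robust distance > chi2({d}) {cutoff_quantile} "
                         f"quantile on {used}", items=flagged)
    return flagged, report


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def pca_scores(data: pd.DataFrame, k: int = 2, scale: bool = False,
               ) -> tuple[pd.DataFrame, np.ndarray]:
    """First ``k`` principal-component scores and variance fractions.

    Columns are centered (optionally standardized); the sign convention
    makes each component's largest-magnitude loading positive.
    """
    if data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 analytes")
    X = data.to_numpy(dtype=float)
    X = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = X.std(axis=0, ddof=1, keepdims=True)
        X = X / np.where(sd == 0, 1.0, sd)
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size and s[0] > 0 else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds data rank {rank}")
    # fix signs: largest-magnitude loading of each component positive
    for j in range(k):
        i_max = np.argmax(np.abs(vt[j]))
        if vt[j, i_max] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    var = s ** 2
    frac = var / var.sum()
    scores = pd.DataFrame(
        u[:, :k] * s[:k], index=data.index,
        columns=[f"PC{j + 1}" for j in range(k)],
    )
    return scores, frac[:k]


# ---------------------------------------------------------------------------
# Convenience pipeline
# ---------------------------------------------------------------------------


def preprocess_pipeline(matrix: AnalyteMatrix, meta: pd.DataFrame,
                        assay_threshold: float = 0.30,
                        sample_threshold: float = 0.30,
                        outlier_quantile: float = 0.999,
                        seed: int = 0,
                        ) -> tuple[pd.DataFrame, pd.DataFrame, PreprocessReport]:
    """Run the full preprocessing chain; returns (log2 matrix, meta, report)."""
    report = PreprocessReport()
    filtered, report = apply_missingness_filters(
        matrix, assay_threshold, sample_threshold, report
    )
    meta = meta.loc[filtered.values.index]
    complete, meta, report = impute_values(filtered, meta, report)
    adjusted, report = log2_and_batch_adjust(complete, meta["plate"], report)
    # outlier distances are computed on group-centered data: the cohort has
    # genuine biological clusters (five sex/hormonal groups), and a
    # high-breakdown scatter fit on the raw matrix would flag whole groups
    # rather than aberrant samples
    centered = adjusted - adjusted.groupby(meta["group"]).transform("median")
    outliers, report = flag_multivariate_outliers(
        centered, cutoff_quantile=outlier_quantile, seed=seed, report=report
    )
    keep = [s for s in adjusted.index if s not in set(outliers)]
    adjusted, meta = adjusted.loc[keep], meta.loc[keep]
    kept, report = exclude_samples(meta, report)
    adjusted, meta = adjusted.loc[kept], meta.loc[kept]
    report.n_samples_out = len(kept)
    report.n_assays_out = adjusted.shape[1]
    return adjusted, meta, report
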