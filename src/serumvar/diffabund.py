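"""Per-analyte modeling of sex and hormonal-status effects.

For each analyte (log2 scale, preprocessed) the pipeline: selects adjustment
covariates by bidirectional stepwise search under BIC with the sex term
forced; fits the sex model by OLS, switching to a high-breakdown MM
regression when a Bonferroni outlier test on the externally studentized
residuals is significant; tests the 5-level group factor (male, follicular,
luteal, OC user, postmenopausal) against the 2-level sex model with a 3-df
F-test (OLS) or robust Wald test (MM); computes four named contrasts against
the cycling-female reference (the unweighted mean of the follicular and
luteal coefficients); and controls the FDR per family with the
Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .robustreg import fit_mm
from .synthetic import GROUPS, MODEL_COVARIATES, CONTINUOUS_COVARIATES

log = logging.getLogger(__name__)

CONTRAST_NAMES = ("oc_vs_cycle", "postmeno_vs_cycle", "male_vs_cycle",
                  "follicular_vs_luteal")

#: contrast weights over the five group means; every row sums to zero
CONTRAST_WEIGHTS = pd.DataFrame(
    [
        [0.0, -0.5, -0.5, 1.0, 0.0],   # OC users vs cycling females
        [0.0, -0.5, -0.5, 0.0, 1.0],   # postmenopausal vs cycling females
        [1.0, -0.5, -0.5, 0.0, 0.0],   # males vs cycling females
        [0.0, 1.0, -1.0, 0.0, 0.0],    # follicular vs luteal phase
    ],
    index=list(CONTRAST_NAMES), columns=list(GROUPS),
)

#: dummy-coded female subgroups of the full model (reference: follicular)
_FULL_LEVELS = ("luteal", "oc_user", "postmenopausal", "male")


# ---------------------------------------------------------------------------
# Design-matrix helpers
# ---------------------------------------------------------------------------


def _covariate_block(meta: pd.DataFrame, name: str
                     ) -> tuple[np.ndarray, list[str]]:
    col = meta[name]
    if name in CONTINUOUS_COVARIATES:
        return col.to_numpy(dtype=float)[:, None], [name]
    levels = sorted(pd.unique(col.astype(str)))
    cols, names = [], []
    for lv in levels[1:]:
        cols.append((col.astype(str) == lv).to_numpy(dtype=float))
        names.append(f"{name}[{lv}]")
    if not cols:  # single-level factor carries no information
        return np.empty((len(col), 0)), []
    return np.stack(cols, axis=1), names


def _sex_column(meta: pd.DataFrame) -> np.ndarray:
    return (meta["group"] == "male").to_numpy(dtype=float)[:, None]


def _group_columns(meta: pd.DataFrame) -> np.ndarray:
    return np.stack(
        [(meta["group"] == g).to_numpy(dtype=float) for g in _FULL_LEVELS],
        axis=1,
    )


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float, int]:
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(res[0]) if res.size else float(((y - X @ beta) ** 2).sum())
    return beta, rss, int(rank)


def _bic(y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    n = len(y)
    _, rss, rank = _ols(y, X)
    if rank < X.shape[1]:
        return np.inf, rank
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + rank * np.log(n), rank


# ---------------------------------------------------------------------------
# Stepwise covariate selection
# ---------------------------------------------------------------------------


def stepwise_select(y: np.ndarray | pd.Series, meta: pd.DataFrame,
                    candidates: tuple[str, ...] = MODEL_COVARIATES,
                    forced: str = "sex") -> list[str]:
    """Bidirectional stepwise covariate search under BIC.

    Starts from the forced-only model (intercept + sex or group term, never
    removable) and at each step takes the single addition or deletion that
    most lowers ``BIC = -2 loglik + k ln n``, stopping when no move lowers
    it.  Ties prefer deletion, then lexicographic covariate order.
    Rank-deficient candidate additions are skipped with a warning.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if forced == "sex":
        base = np.hstack([np.ones((n, 1)), _sex_column(meta)])
    elif forced == "group":
        base = np.hstack([np.ones((n, 1)), _group_columns(meta)])
    else:
        raise ValueError(f"unknown forced term {forced!r}")
    blocks = {c: _covariate_block(meta, c)[0] for c in candidates}
    blocks = {c: b for c, b in blocks.items() if b.shape[1] > 0}

    selected: list[str] = []

    def design(sel):
        return np.hstack([base] + [blocks[c] for c in sel])

    current_bic, _ = _bic(y, design(selected))
    while True:
        moves = []  # (bic, kind_rank, name, new_selection)
        for c in sorted(selected):
            sel = [s for s in selected if s != c]
            b, _ = _bic(y, design(sel))
            moves.append((b, 0, c, sel))
        for c in sorted(blocks):
            if c in selected:
                continue
            sel = selected + [c]
            b, rank = _bic(y, design(sel))
            if not np.isfinite(b):
                log.warning("stepwise: candidate %s is rank-deficient; skipped", c)
                continue
            moves.append((b, 1, c, sel))
        if not moves:
            break
        moves.sort(key=lambda t: (t[0], t[1], t[2]))
        best = moves[0]
        if best[0] < current_bic - 1e-10:
            current_bic = best[0]
            selected = best[3]
        else:
            break
    return sorted(selected)


# ---------------------------------------------------------------------------
# Per-analyte fitting
# ---------------------------------------------------------------------------


@dataclass
class AnalyteFit:
    """Fit of one analyte's sex model plus the hormonal-status extension."""

    analyte_id: str
    model_kind: str                      # "ols" | "mm_robust"
    selected_covariates: list[str]
    sex_log2_ratio: float
    sex_se: float
    sex_p: float
    hormonal_anova_p: float
    contrasts: pd.DataFrame              # name x {estimate, ci_low, ci_high, p}
    outlier_bonferroni_p: float
    flags: list[str] = field(default_factory=list)


def _studentized_outlier_p(y: np.ndarray, X: np.ndarray) -> float:
    """Smallest Bonferroni-corrected p of the externally studentized residuals."""
    n, p = X.shape
    q, _ = np.linalg.qr(X)
    h = np.minimum((q ** 2).sum(axis=1), 1.0 - 1e-10)
    beta, rss, _ = _ols(y, X)
    e = y - X @ beta
    df = n - p - 1
    if df <= 0:
        return 1.0
    denom = rss * (1.0 - h) - e ** 2
    denom = np.maximum(denom, 1e-300)
    r_ext = e * np.sqrt(df / denom)
    p_raw = 2.0 * stats.t.sf(np.abs(r_ext), df)
    return float(min(1.0, n * p_raw.min()))


def fit_analyte_model(y: np.ndarray | pd.Series, meta: pd.DataFrame,
                      selected: list[str], forced: str = "sex",
                      outlier_alpha: float = 0.05, seed: int = 0,
                      ) -> tuple[dict, str, float, list[str]]:
    """Fit the sex (or group) model, with robust fallback on outliers.

    Returns ``(fit, model_kind, outlier_p, flags)`` where ``fit`` holds
    ``params``, ``cov``, ``names``, ``df_resid``.  The robust branch fires
    when the smallest Bonferroni-corrected externally-studentized-residual
    p-value is below ``outlier_alpha``; the MM fit uses a 50%-breakdown
    S-scale and a 95%-efficiency bisquare M-step.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    names = ["intercept"]
    parts = [np.ones((n, 1))]
    if forced == "sex":
        parts.append(_sex_column(meta))
        names.append("sex[male]")
    elif forced == "group":
        parts.append(_group_columns(meta))
        names.extend(f"group[{g}]" for g in _FULL_LEVELS)
    else:
        raise ValueError(f"unknown forced term {forced!r}")
    for c in selected:
        block, bnames = _covariate_block(meta, c)
        parts.append(block)
        names.extend(bnames)
    X = np.hstack(parts)
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")

    outlier_p = _studentized_outlier_p(y, X)
    flags: list[str] = []
    if outlier_p < outlier_alpha:
        model_kind = "mm_robust"
        try:
            mm = fit_mm(X, y, seed=seed)
            if not mm.converged:
                flags.append("mm_nonconvergence_fallback_ols")
        except np.linalg.LinAlgError:
            mm = None
            flags.append("mm_failure_fallback_ols")
        if mm is not None and mm.scale > 0:
            fit = {"params": mm.params, "cov": mm.cov_params,
                   "names": names, "df_resid": n - p}
            return fit, model_kind, outlier_p, flags
        model_kind = "ols"
        flags.append("mm_degenerate_fallback_ols")
    else:
        model_kind = "ols"

    beta, rss, _ = _ols(y, X)
    sigma2 = rss / (n - p)
    cov = sigma2 * np.linalg.pinv(X.T @ X)
    fit = {"params": beta, "cov": cov, "names": names, "df_resid": n - p}
    return fit, model_kind, outlier_p, flags


def test_hormonal_status(y: np.ndarray | pd.Series, meta: pd.DataFrame,
                         selected: list[str], model_kind: str = "ols",
                         seed: int = 0) -> tuple[float, pd.DataFrame]:
    """Hormonal-status ANOVA and the four named contrasts.

    The full model replaces the 2-level sex term with the 5-level group
    factor (same covariates).  The nested comparison has 3 added degrees of
    freedom: an F-test for OLS fits and a Wald chi-square on the added
    female-subgroup coefficients (robust covariance) for MM fits.  Contrasts
    are linear combinations of group coefficients with the cycling-female
    reference (follicular + luteal) / 2 and 95% confidence intervals from
    the fit's covariance.
    """
    y = np.asarray(y, dtype=float)
    present = set(meta["group"])
    missing = [g for g in GROUPS if g not in present]
    if missing:
        raise ValueError(f"empty group level(s): {missing}")
    n = len(y)

    cov_parts, cov_names = [], []
    for c in selected:
        block, bnames = _covariate_block(meta, c)
        cov_parts.append(block)
        cov_names.extend(bnames)
    X_base = np.hstack([np.ones((n, 1)), _sex_column(meta)] + cov_parts)
    X_full = np.hstack([np.ones((n, 1)), _group_columns(meta)] + cov_parts)
    p_full = X_full.shape[1]
    full_names = ["intercept"] + [f"group[{g}]" for g in _FULL_LEVELS] + cov_names

    if model_kind == "mm_robust":
        mm = fit_mm(X_full, y, seed=seed)
        beta, cov, df = mm.params, mm.cov_params, n - p_full
        # the 2-level sex model is the constraint luteal = oc = postmeno = 0
        idx = [full_names.index(f"group[{g}]")
               for g in ("luteal", "oc_user", "postmenopausal")]
        bsub = beta[idx]
        vsub = cov[np.ix_(idx, idx)]
        w = float(bsub @ np.linalg.solve(vsub, bsub))
        anova_p = float(stats.chi2.sf(w, 3))
    else:
        _, rss0, _ = _ols(y, X_base)
        beta, rss1, _ = _ols(y, X_full)
        df = n - p_full
        f = ((rss0 - rss1) / 3.0) / (rss1 / df)
        anova_p = float(stats.f.sf(max(f, 0.0), 3, df))
        sigma2 = rss1 / df
        cov = sigma2 * np.linalg.pinv(X_full.T @ X_full)

    # map contrast weights over group means to coefficient space:
    # mean(g) = intercept + beta_g (beta_follicular = 0), covariates fixed
    rows = []
    tcrit = stats.t.ppf(0.975, df)
    for name in CONTRAST_NAMES:
        w_groups = CONTRAST_WEIGHTS.loc[name]
        L = np.zeros(p_full)
        for g in _FULL_LEVELS:
            L[full_names.index(f"group[{g}]")] = w_groups[g]
        est = float(L @ beta)
        se = float(np.sqrt(L @ cov @ L))
        tval = est / se if se > 0 else 0.0
        rows.append({
            "contrast": name, "estimate": est,
            "ci_low": est - tcrit * se, "ci_high": est + tcrit * se,
            "p": float(2.0 * stats.t.sf(abs(tval), df)),
        })
    return anova_p, pd.DataFrame(rows).set_index("contrast")


# ---------------------------------------------------------------------------
# Benjamini-Hochberg FDR
# ---------------------------------------------------------------------------


def adjust_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    ``q_(i) = min_{j >= i} p_(j) * m / j``, capped at 1 and mapped back to
    the input order.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# Panel runner and cohort comparison
# ---------------------------------------------------------------------------


def run_panel(data: pd.DataFrame, meta: pd.DataFrame,
              candidates: tuple[str, ...] = MODEL_COVARIATES,
              q_threshold: float = 0.05, seed: int = 0) -> pd.DataFrame:
    """Per-analyte modeling over a preprocessed (log2) matrix.

    Applies covariate selection, the sex model with robust fallback, and the
    hormonal-status ANOVA + contrasts to every analyte; then adjusts three
    p-value families (sex, ANOVA, each contrast) with Benjamini-Hochberg.
    Per-analyte failures are returned as flagged rows, never raised.
    """
    meta = meta.loc[data.index]
    rows = []
    for aid in data.columns:
        y = data[aid].to_numpy(dtype=float)
        aseed = (seed + zlib.crc32(aid.encode())) % (2 ** 31)
        try:
            selected = stepwise_select(y, meta, candidates=candidates)
            fit, kind, outlier_p, flags = fit_analyte_model(
                y, meta, selected, seed=aseed
            )
            i_sex = fit["names"].index("sex[male]")
            se = float(np.sqrt(fit["cov"][i_sex, i_sex]))
            coef = float(fit["params"][i_sex])
            tval = coef / se if se > 0 else 0.0
            sex_p = float(2.0 * stats.t.sf(abs(tval), fit["df_resid"]))
            anova_p, contrasts = test_hormonal_status(
                y, meta, selected, model_kind=kind, seed=aseed
            )
            row = {
                "analyte_id": aid, "model_kind": kind,
                "selected_covariates": ";".join(selected),
                "sex_log2_ratio": coef, "sex_se": se, "sex_p": sex_p,
                "hormonal_anova_p": anova_p,
                "outlier_bonferroni_p": outlier_p,
                "flags": ";".join(flags),
            }
            for name in CONTRAST_NAMES:
                c = contrasts.loc[name]
                row.update({
                    f"{name}_estimate": c["estimate"],
                    f"{name}_ci_low": c["ci_low"],
                    f"{name}_ci_high": c["ci_high"],
                    f"{name}_p": c["p"],
                })
        except Exception as err:  # noqa: BLE001 - panel must not abort
            log.warning("analyte %s failed: %s", aid, err)
            row = {"analyte_id": aid, "model_kind": "failed",
                   "flags": f"error:{err}"}
        rows.append(row)
    table = pd.DataFrame(rows).set_index("analyte_id")

    ok = table["model_kind"] != "failed"
    families = ["sex", "hormonal_anova"] + list(CONTRAST_NAMES)
    for fam in families:
        pcol = f"{fam}_p"
        qcol = f"{fam}_q"
        table[qcol] = np.nan
        if pcol in table.columns and ok.any():
            table.loc[ok, qcol] = adjust_fdr(table.loc[ok, pcol])
    table["sex_significant"] = table["sex_q"] < q_threshold
    table["hormonal_significant"] = table["hormonal_anova_q"] < q_threshold
    return table


REPLICATION_FAMILIES = {
    "sex": ("sex_q", "sex_log2_ratio"),
    "hormonal_status": ("hormonal_anova_q", None),
    **{name: (f"{name}_q", f"{name}_estimate") for name in CONTRAST_NAMES},
}


def compare_cohorts(discovery: pd.DataFrame, validation: pd.DataFrame,
                    q_threshold: float = 0.05) -> pd.DataFrame:
    """Replication of discovery findings in an independent validation cohort.

    A finding (q < threshold in the discovery cohort) replicates when the
    validation q is below the threshold and, for signed families, the effect
    direction agrees.
    """
    sd = set(discovery.index)
    sv = set(validation.index)
    if sd != sv:
        raise ValueError(
            f"analyte universes differ; symmetric difference: {sorted(sd ^ sv)}"
        )
    validation = validation.loc[discovery.index]
    rows = []
    for family, (qcol, effcol) in REPLICATION_FAMILIES.items():
        found = discovery.index[discovery[qcol] < q_threshold]
        rep = 0
        for aid in found:
            if not validation.loc[aid, qcol] < q_threshold:
                continue
            if effcol is not None and (
                np.sign(discovery.loc[aid, effcol])
                != np.sign(validation.loc[aid, effcol])
            ):
                continue
            rep += 1
        rows.append({
            "family": family, "n_discovered": len(found),
            "n_replicated": rep,
            "fraction_replicated": rep / len(found) if len(found) else np.nan,
        })
    return pd.DataFrame(rows).set_index("family")
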