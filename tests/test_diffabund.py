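"""Stepwise selection, robust fallback, hormonal ANOVA, contrasts, BH FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import serumvar as sv
from serumvar.diffabund import CONTRAST_NAMES, CONTRAST_WEIGHTS
from serumvar.robustreg import fit_mm
from serumvar.synthetic import GROUPS


def _meta(n_per_group=40, seed=0, covariates=True):
    rng = np.random.default_rng(seed)
    rows = []
    for g in GROUPS:
        for _ in range(n_per_group):
            rows.append({"group": g, "cohort": "discovery"})
    meta = pd.DataFrame(rows)
    meta.index = pd.Index([f"S{i:04d}" for i in range(len(meta))])
    if covariates:
        n = len(meta)
        meta["age"] = rng.uniform(20, 60, n)
        meta["bmi"] = rng.uniform(18, 35, n)
        meta["alcohol"] = rng.uniform(0, 20, n)
        meta["smoking"] = rng.choice(["never", "former", "current"], n)
        meta["partner"] = rng.integers(0, 2, n)
        meta["ids_score"] = rng.uniform(0, 40, n)
    return meta


class TestStepwiseSelect:
    def test_true_predictor_selected_noise_rejected(self):
        meta = _meta(40, seed=1)
        rng = np.random.default_rng(1)
        y = 2.0 * meta["bmi"].to_numpy() + rng.normal(0, 0.1, len(meta))
        sel = sv.stepwise_select(y, meta, candidates=("bmi", "age"))
        assert sel == ["bmi"]

    def test_pure_noise_candidates_rarely_selected(self):
        """BIC consistency: with no signal, the forced-only model nearly
        always wins.  At n = 200 a noise covariate enters when its chi-square
        improvement exceeds ln(n), probability ~2% per candidate, so with six
        candidates ~90% of panels should select nothing."""
        meta = _meta(40, seed=2)
        cands = ("age", "bmi", "alcohol", "smoking", "partner", "ids_score")
        empty = 0
        for s in range(100):
            y = np.random.default_rng(1000 + s).normal(0, 1, len(meta))
            if sv.stepwise_select(y, meta, candidates=cands) == []:
                empty += 1
        assert empty >= 90

    def test_forced_sex_term_never_deleted(self):
        meta = _meta(30, seed=3)
        y = np.random.default_rng(3).normal(0, 1, len(meta))
        fit, _, _, _ = sv.fit_analyte_model(
            y, meta, sv.stepwise_select(y, meta, candidates=("age",))
        )
        assert "sex[male]" in fit["names"]

    def test_deterministic(self):
        meta = _meta(40, seed=4)
        rng = np.random.default_rng(4)
        y = 0.3 * meta["age"].to_numpy() + rng.normal(0, 1, len(meta))
        cands = ("age", "bmi", "smoking")
        assert sv.stepwise_select(y, meta, candidates=cands) == \
            sv.stepwise_select(y, meta, candidates=cands)


class TestFitAnalyteModel:
    def test_clean_data_stays_ols_and_matches_reference(self):
        import statsmodels.api as sm

        meta = _meta(40, seed=5)
        rng = np.random.default_rng(5)
        y = (0.8 * (meta["group"] == "male").to_numpy()
             + 0.02 * meta["age"].to_numpy() + rng.normal(0, 0.5, len(meta)))
        fit, kind, _, _ = sv.fit_analyte_model(y, meta, ["age"])
        assert kind == "ols"
        X = np.column_stack([
            np.ones(len(meta)), (meta["group"] == "male").astype(float),
            meta["age"],
        ])
        ref = sm.OLS(y, X).fit()
        assert np.allclose(fit["params"], ref.params)
        i = fit["names"].index("sex[male]")
        assert np.isclose(np.sqrt(fit["cov"][i, i]), ref.bse[1])

    def test_gross_outlier_triggers_robust_fit(self):
        meta = _meta(40, seed=6)
        rng = np.random.default_rng(6)
        sigma = 0.2
        y = (1.0 * (meta["group"] == "male").to_numpy()
             + rng.normal(0, sigma, len(meta)))
        y[0] += 20 * sigma
        fit, kind, outlier_p, _ = sv.fit_analyte_model(y, meta, [])
        assert kind == "mm_robust"
        assert outlier_p < 0.05
        i = fit["names"].index("sex[male]")
        assert abs(fit["params"][i] - 1.0) < 0.1
        ols = np.linalg.lstsq(
            np.column_stack([np.ones(len(meta)),
                             (meta["group"] == "male").astype(float)]),
            y, rcond=None,
        )[0]
        assert abs(ols[1] - 1.0) > abs(fit["params"][i] - 1.0)

    def test_trigger_consistent_with_bonferroni_threshold(self):
        """model_kind is mm_robust exactly when the outlier p drops below 5%."""
        meta = _meta(20, seed=7)
        rng = np.random.default_rng(7)
        base = rng.normal(0, 0.5, len(meta))
        for bump in (0.0, 1.0, 1.5, 2.0, 3.0, 5.0):
            y = base.copy()
            y[3] += bump
            _, kind, outlier_p, _ = sv.fit_analyte_model(y, meta, [])
            assert (kind == "mm_robust") == (outlier_p < 0.05)

    def test_false_trigger_rate_on_clean_gaussian(self):
        """The Bonferroni outlier test fires on at most ~5% of clean analytes."""
        meta = _meta(20, seed=8)
        fired = 0
        n_panels = 200
        for s in range(n_panels):
            y = np.random.default_rng(2000 + s).normal(0, 1, len(meta))
            _, kind, _, _ = sv.fit_analyte_model(y, meta, [])
            fired += kind == "mm_robust"
        # size <= 0.05; allow 3 binomial SEs above the nominal level
        assert fired <= n_panels * 0.05 + 3 * np.sqrt(n_panels * 0.05 * 0.95)


class TestMMRegression:
    def test_contaminated_slope_recovery_beats_ols(self):
        rng = np.random.default_rng(9)
        n = 100
        x = rng.uniform(-2, 2, n)
        X = np.column_stack([np.ones(n), x])
        sigma = 0.3
        y = 1.0 * x + rng.normal(0, sigma, n)
        y[:5] += 20 * sigma          # 5% gross contamination
        mm = fit_mm(X, y, seed=0)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert abs(mm.params[1] - 1.0) < 0.1
        assert abs(ols[1] - 1.0) > abs(mm.params[1] - 1.0)

    def test_matches_reference_mm_estimator(self, tmp_path):
        """Independent oracle: MASS::rlm(method='MM') — S-init + bisquare."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable; the reference oracle cannot run")
        rng = np.random.default_rng(10)
        n = 150
        x1, x2 = rng.normal(0, 1, n), rng.normal(0, 1, n)
        y = 0.5 + 1.2 * x1 - 0.7 * x2 + rng.normal(0, 0.4, n)
        y[:8] += 6.0
        df = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
        df.to_csv(tmp_path / "d.csv", index=False)
        script = tmp_path / "mm.R"
        script.write_text(
            "suppressMessages(library(MASS))\n"
            f"d <- read.csv('{tmp_path}/d.csv')\n"
            "f <- rlm(y ~ x1 + x2, data=d, method='MM')\n"
            f"write.csv(data.frame(coef=coef(f)), '{tmp_path}/ref.csv')\n"
        )
        subprocess.run(["Rscript", str(script)], check=True,
                       capture_output=True)
        ref = pd.read_csv(tmp_path / "ref.csv")["coef"].to_numpy()
        X = np.column_stack([np.ones(n), x1, x2])
        mm = fit_mm(X, y, seed=0)
        assert np.abs(mm.params - ref).max() < 0.02

    def test_clean_data_close_to_ols(self):
        rng = np.random.default_rng(11)
        n = 500
        X = np.column_stack([np.ones(n), rng.normal(0, 1, n)])
        y = 2.0 + 0.5 * X[:, 1] + rng.normal(0, 1, n)
        mm = fit_mm(X, y, seed=0)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.abs(mm.params - ols).max() < 0.05


class TestHormonalStatus:
    def test_null_anova_p_uniform(self):
        meta = _meta(30, seed=12, covariates=False)
        ps = []
        for s in range(1000):
            y = np.random.default_rng(3000 + s).normal(0, 1, len(meta))
            p, _ = sv.test_hormonal_status(y, meta, [])
            ps.append(p)
        _, ks_p = stats.kstest(ps, "uniform")
        assert ks_p > 0.01

    def test_planted_oc_shift_recovered_in_contrasts(self):
        meta = _meta(60, seed=13, covariates=False)
        rng = np.random.default_rng(13)
        y = 1.0 * (meta["group"] == "oc_user").to_numpy() + rng.normal(
            0, 0.5, len(meta)
        )
        _, contrasts = sv.test_hormonal_status(y, meta, [])
        oc = contrasts.loc["oc_vs_cycle"]
        se = (oc["ci_high"] - oc["ci_low"]) / (2 * 1.96)
        assert abs(oc["estimate"] - 1.0) < 3 * se
        for name in ("male_vs_cycle", "follicular_vs_luteal"):
            c = contrasts.loc[name]
            se = (c["ci_high"] - c["ci_low"]) / (2 * 1.96)
            assert abs(c["estimate"]) < 3 * se

    def test_contrast_weights_sum_to_zero(self):
        assert np.allclose(CONTRAST_WEIGHTS.sum(axis=1), 0.0)

    def test_ci_brackets_estimate(self):
        meta = _meta(25, seed=14)
        y = np.random.default_rng(14).normal(0, 1, len(meta))
        _, contrasts = sv.test_hormonal_status(y, meta, ["age"])
        assert (contrasts["ci_low"] <= contrasts["estimate"]).all()
        assert (contrasts["estimate"] <= contrasts["ci_high"]).all()

    def test_empty_group_level_rejected(self):
        meta = _meta(10, seed=15)
        meta = meta[meta["group"] != "oc_user"]
        y = np.zeros(len(meta))
        with pytest.raises(ValueError, match="oc_user"):
            sv.test_hormonal_status(y, meta, [])


def _bh_bruteforce(p):
    """Literal BH definition: q_i = min over thresholds t >= p_i of t*m/R(t)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    q = np.empty(m)
    for i in range(m):
        candidates = []
        for t in p[p >= p[i] - 1e-300]:
            r = (p <= t).sum()
            candidates.append(t * m / r)
        q[i] = min(1.0, min(candidates))
    return q


class TestAdjustFdr:
    @pytest.mark.parametrize("p,expected", [
        ([0.005, 0.04, 0.05], [0.015, 0.05, 0.05]),
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.33], [0.33]),
    ])
    def test_hand_computed_examples(self, p, expected):
        assert np.allclose(sv.adjust_fdr(p), expected)

    def test_matches_bruteforce_definition(self):
        rng = np.random.default_rng(16)
        for _ in range(50):
            m = rng.integers(1, 30)
            p = rng.uniform(0, 1, m)
            assert np.abs(sv.adjust_fdr(p) - _bh_bruteforce(p)).max() < 1e-12

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(17)
        p = rng.uniform(0, 1, 500)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        assert np.abs(sv.adjust_fdr(p) - ref).max() < 1e-12

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=50))
    @settings(deadline=None, derandomize=True)
    def test_q_dominates_p_and_is_monotone(self, p):
        q = sv.adjust_fdr(p)
        assert (q >= np.asarray(p) - 1e-15).all()
        assert (q <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sv.adjust_fdr([0.1, 1.2])


class TestRunPanelAndReplication:
    def test_single_analyte_panel_matches_manual_stages(self):
        meta = _meta(40, seed=18)
        rng = np.random.default_rng(18)
        y = 0.7 * (meta["group"] == "male").to_numpy() + rng.normal(
            0, 0.6, len(meta)
        )
        data = pd.DataFrame({"A1": y}, index=meta.index)
        cands = ("age", "bmi")
        table = sv.run_panel(data, meta, candidates=cands, seed=0)
        sel = sv.stepwise_select(y, meta, candidates=cands)
        fit, kind, _, _ = sv.fit_analyte_model(y, meta, sel,
                                               seed=table.index.size)
        anova_p, contrasts = sv.test_hormonal_status(y, meta, sel,
                                                     model_kind=kind)
        row = table.loc["A1"]
        i = fit["names"].index("sex[male]")
        assert row["model_kind"] == kind
        assert np.isclose(row["sex_log2_ratio"], fit["params"][i])
        assert np.isclose(row["hormonal_anova_p"], anova_p)
        assert np.isclose(row["oc_vs_cycle_estimate"],
                          contrasts.loc["oc_vs_cycle", "estimate"])
        assert np.isclose(row["sex_q"], row["sex_p"])  # m = 1

    def test_null_panel_rarely_finds_anything(self):
        """FDR control: with no planted effects, q<0.05 findings are rare."""
        meta = _meta(30, seed=19, covariates=False)
        rng = np.random.default_rng(19)
        hits = 0
        n_panels = 40
        for s in range(n_panels):
            data = pd.DataFrame(
                rng.normal(0, 1, (len(meta), 20)),
                index=meta.index,
                columns=[f"A{j}" for j in range(20)],
            )
            table = sv.run_panel(data, meta, candidates=(), seed=s)
            hits += int(table["sex_significant"].any())
        assert hits <= max(4, 0.05 * n_panels + 3 * np.sqrt(n_panels * 0.05))

    def test_replication_identity_and_sign_rule(self):
        meta = _meta(50, seed=20)
        rng = np.random.default_rng(20)
        male = (meta["group"] == "male").to_numpy()
        data = pd.DataFrame(
            {f"A{j}": (1.0 if j < 3 else 0.0) * male
             + rng.normal(0, 0.4, len(meta)) for j in range(6)},
            index=meta.index,
        )
        table = sv.run_panel(data, meta, candidates=(), seed=0)
        rep = sv.compare_cohorts(table, table)
        assert rep.loc["sex", "fraction_replicated"] == 1.0
        flipped = table.copy()
        flipped["sex_log2_ratio"] = -flipped["sex_log2_ratio"]
        rep2 = sv.compare_cohorts(table, flipped)
        assert rep2.loc["sex", "n_replicated"] == 0

    def test_replication_requires_matching_analytes(self):
        meta = _meta(20, seed=21)
        data = pd.DataFrame(
            np.random.default_rng(21).normal(0, 1, (len(meta), 2)),
            index=meta.index, columns=["A1", "A2"],
        )
        t1 = sv.run_panel(data, meta, candidates=(), seed=0)
        t2 = t1.rename(index={"A2": "A3"})
        with pytest.raises(ValueError, match="A2"):
            sv.compare_cohorts(t1, t2)

    def test_two_cohort_replication_of_strong_effects(self, default_spec):
        """Strong planted effects found in discovery mostly replicate."""
        sizes = sv.default_sizes()
        matrix, meta = sv.generate_cohort(default_spec, sizes, seed=22)
        data = np.log2(matrix.values)
        disc = meta.index[meta["cohort"] == "discovery"]
        val = meta.index[meta["cohort"] == "validation"]
        cands = ("age", "bmi")
        t_disc = sv.run_panel(data.loc[disc], meta.loc[disc],
                              candidates=cands, seed=0)
        t_val = sv.run_panel(data.loc[val], meta.loc[val],
                             candidates=cands, seed=0)
        rep = sv.compare_cohorts(t_disc, t_val)
        assert rep.loc["sex", "n_discovered"] >= 50
        assert rep.loc["sex", "fraction_replicated"] >= 0.9
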