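"""Association statistics: OR conventions, exact tests, conditional scans."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from conftest import genotype_frame
from dqmotif.motifs import CASE, CONTROL, attach_motifs
from dqmotif.stats import (OR_CASE_ONLY, StatsError, antibody_count_group,
                           autoantibody_association,
                           autoantibody_count_contrast, conditional_scan,
                           drdq_haplotype_analysis, fisher_two_sided,
                           genotype_group_analysis, motif_design,
                           one_vs_rest_subject, one_vs_rest_test,
                           residue_scan, trans_scan, virtual_or_clustered,
                           virtual_reference_or)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def fisher_oracle(a, b, c, d):
    """Exhaustive hypergeometric enumeration: two-sided p sums probabilities
    of all tables (fixed margins) no more probable than the observed."""
    N, r1, c1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, r1 + c1 - N), min(r1, c1)
    k = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(k, N, r1, c1)
    pobs = sps.hypergeom.pmf(a, N, r1, c1)
    return float(pmf[pmf <= pobs * (1 + 1e-7)].sum())


def newton_logistic(X, y, tol=1e-12, max_iter=100):
    """Independent Newton-Raphson logistic ML oracle."""
    X, y = np.asarray(X, float), np.asarray(y, float)
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        p = 1 / (1 + np.exp(-X @ beta))
        W = p * (1 - p)
        H = X.T @ (X * W[:, None])
        step = np.linalg.solve(H, X.T @ (y - p))
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    se = np.sqrt(np.diag(np.linalg.inv(H)))
    return beta, se


class TestVirtualReferenceOr:
    def test_published_counts_give_point_35(self):
        # DQA1*02:01-B1*02:02: 41 of 1921 patient copies vs 78 of 1266 controls
        res = virtual_reference_or(41, 1921, 78, 1266)
        assert round(res.or_virtual, 2) == 0.35

    def test_equal_frequencies_give_unity(self):
        assert virtual_reference_or(10, 100, 10, 100).or_virtual == pytest.approx(1.0)

    def test_case_only_motif_sentinel_and_frequency(self):
        res = virtual_reference_or(6, 1921, 0, 1266)
        assert res.or_virtual == OR_CASE_ONLY
        assert round(100 * res.case_freq, 2) == 0.31

    def test_control_only_motif_sentinel(self):
        assert virtual_reference_or(0, 1921, 5, 1266).or_virtual == 0.0

    def test_unobserved_unit_rejected(self):
        with pytest.raises(StatsError, match="neither group"):
            virtual_reference_or(0, 100, 0, 100)

    def test_or_equals_ratio_of_reported_percentages(self):
        res = virtual_reference_or(321, 1921, 266, 1266)
        pct_ratio = (100 * res.case_freq) / (100 * res.control_freq)
        assert res.or_virtual == pytest.approx(pct_ratio, rel=1e-12)


class TestOneVsRest:
    def test_identical_proportions_or_one_p_one(self):
        res = one_vs_rest_test(10, 10, 100, 100, mode="fisher")
        assert res.odds_ratio == pytest.approx(1.0, abs=1e-9)
        assert res.p == pytest.approx(1.0)

    def test_exact_p_matches_enumeration_on_example(self):
        res = one_vs_rest_test(8, 3, 10, 10, mode="fisher")
        assert res.p == pytest.approx(fisher_oracle(8, 2, 3, 7), rel=1e-12)

    def test_exact_p_matches_enumeration_on_random_tables(self):
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 200:
            a, b, c, d = (int(x) for x in rng.integers(0, 16, 4))
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            res = one_vs_rest_test(a, c, a + b, c + d, mode="fisher")
            assert res.p == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-10)
            checked += 1

    def test_offset_logistic_reproduces_frequency_ratio(self):
        res = one_vs_rest_test(50, 30, 500, 400, mode="logistic_offset")
        expected = math.log((50 / 500) / (30 / 400))
        assert res.coef == pytest.approx(expected, rel=1e-12)

    def test_offset_logistic_matches_statsmodels_glm(self):
        """The closed-form offset-logistic MLE agrees with an actual GLM fit
        with the same offset."""
        import statsmodels.api as sm
        a, c, case_total, control_total = 37, 22, 300, 250
        y = np.r_[np.ones(case_total), np.zeros(control_total)]
        x = np.r_[np.ones(a), np.zeros(case_total - a),
                  np.ones(c), np.zeros(control_total - c)]
        offset = np.full_like(y, math.log(case_total / control_total))
        fit = sm.GLM(y, x[:, None], family=sm.families.Binomial(),
                     offset=offset).fit()
        res = one_vs_rest_test(a, c, case_total, control_total,
                               mode="logistic_offset")
        assert res.coef == pytest.approx(float(fit.params[0]), abs=1e-6)
        assert res.se == pytest.approx(float(fit.bse[0]), abs=1e-6)

    def test_separation_falls_back_to_exact(self):
        res = one_vs_rest_test(0, 8, 100, 100, mode="logistic_offset")
        assert res.method == "fisher(separation)"
        assert res.odds_ratio == 0.0

    def test_modes_agree_on_classification_away_from_alpha(self):
        """The exact test and the offset-logistic Wald test give the same
        verdict at alpha = 0.05 whenever both p-values sit clear of the
        threshold (the conventions can disagree right at the boundary)."""
        rng = np.random.default_rng(19)
        for _ in range(50):
            a, c = int(rng.integers(1, 40)), int(rng.integers(1, 40))
            fis = one_vs_rest_test(a, c, 80, 80, mode="fisher")
            off = one_vs_rest_test(a, c, 80, 80, mode="logistic_offset")
            if max(fis.p, off.p) < 0.04 or min(fis.p, off.p) > 0.07:
                assert (fis.p < 0.05) == (off.p < 0.05)


class TestLogisticAgainstNewtonOracle:
    def test_subject_level_fit_matches_oracle(self):
        a, c, n_cases, n_controls = 30, 12, 200, 150
        res = one_vs_rest_subject(a, c, n_cases, n_controls)
        y = np.r_[np.ones(n_cases), np.zeros(n_controls)]
        x = np.r_[np.ones(a), np.zeros(n_cases - a),
                  np.ones(c), np.zeros(n_controls - c)]
        X = np.column_stack([np.ones_like(x), x])
        beta, se = newton_logistic(X, y)
        assert res.coef == pytest.approx(beta[1], abs=1e-6)
        assert res.se == pytest.approx(se[1], abs=1e-6)

    def test_glm_engine_matches_oracle_on_multicolumn_design(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(5)
        n = 400
        X = np.column_stack([np.ones(n), rng.binomial(2, 0.3, n),
                             rng.binomial(2, 0.4, n)]).astype(float)
        y = (rng.random(n) < 1 / (1 + np.exp(-(X @ [-0.4, 0.7, -0.5])))).astype(float)
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        beta, se = newton_logistic(X, y)
        assert np.allclose(fit.params, beta, atol=1e-6)
        assert np.allclose(fit.bse, se, atol=1e-6)

    def test_highly_resistant_classification(self):
        res = one_vs_rest_subject(0, 9, 100, 100)
        assert res.classification == "highly_resistant"


def multiplicative_cohort(rng, n_cases=1500, n_controls=1500):
    """Subjects with motifs N/R1/R2, disease multiplicative on the logit."""
    motifs = np.array(["N", "R1", "R2"])
    beta = {"N": 0.0, "R1": math.log(2.5), "R2": math.log(4.0)}
    probs = [0.9, 0.05, 0.05]
    cases, controls = [], []
    while len(cases) < n_cases or len(controls) < n_controls:
        m1 = rng.choice(motifs, 20_000, p=probs)
        m2 = rng.choice(motifs, 20_000, p=probs)
        logit = -3.0 + np.array([beta[m] for m in m1]) + np.array([beta[m] for m in m2])
        dis = rng.random(20_000) < 1 / (1 + np.exp(-logit))
        for i in np.nonzero(dis)[0][: n_cases - len(cases)]:
            cases.append((m1[i], m2[i]))
        for i in np.nonzero(~dis)[0][: n_controls - len(controls)]:
            controls.append((m1[i], m2[i]))
    status = [CASE] * n_cases + [CONTROL] * n_controls
    pairs = cases + controls
    return genotype_frame(status, [p[0] for p in pairs], [p[1] for p in pairs])


class TestGenotypeGroupAnalysis:
    # exact one-vs-rest ORs for the simulation above, from enumeration over
    # genotype classes (frozen from the closed-form computation)
    EXACT = {"R1/neutral": 1.8723, "R2/neutral": 3.3034, "R1/R2": 7.1204}

    def test_doubly_heterozygous_or_matches_multiplicative_expectation(self):
        rng = np.random.default_rng(99)
        df = multiplicative_cohort(rng)
        classes = {"N": "neutral", "R1": "risk", "R2": "risk"}
        table = genotype_group_analysis(df, classes).set_index("label")
        for label, exact in self.EXACT.items():
            row = table.loc[label]
            assert abs(row["coef"] - math.log(exact)) < 3.5 * row["se"]
        # product diagnostic: under this model the exact ratio is 1.151
        from dqmotif.summaries import or_product_check
        chk = or_product_check(table.loc["R1/neutral", "odds_ratio"],
                               table.loc["R2/neutral", "odds_ratio"],
                               table.loc["R1/R2", "odds_ratio"])
        assert 0.8 < chk["ratio"] < 1.6

    def test_empty_class_rows_omitted(self):
        df = genotype_frame([CASE, CONTROL, CASE, CONTROL],
                            ["R1", "R1", "N", "N"], ["N", "N", "N", "N"])
        table = genotype_group_analysis(df, {"R1": "risk", "N": "neutral"})
        assert "R1/R1" not in set(table["label"])  # no homozygotes present

    def test_requires_a_risk_motif(self):
        df = genotype_frame([CASE, CONTROL], ["N", "N"], ["N", "N"])
        with pytest.raises(StatsError):
            genotype_group_analysis(df, {"N": "neutral"})


class TestConditionalScan:
    @staticmethod
    def _data(rng, n=500):
        X1 = rng.binomial(2, 0.3, n).astype(float)
        X2 = rng.binomial(2, 0.2, n).astype(float)
        logit = -0.5 + 0.8 * X1 - 0.6 * X2
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
        return y, pd.DataFrame({"x1": X1, "x2": X2})

    def test_independent_term_marginal_close_to_adjusted(self):
        rng = np.random.default_rng(21)
        y, X = self._data(rng, n=4000)
        Z = rng.binomial(2, 0.4, len(y)).astype(float)  # independent of X and y
        res = conditional_scan(y, X, {"z": pd.Series(Z)})
        row = res.iloc[0]
        assert row["status"] == "ok"
        # both tests see the same (null) signal: z-scores agree within noise
        z_marg = sps.norm.isf(row["p_marginal"] / 2)
        z_adj = sps.norm.isf(row["p_adjusted"] / 2)
        assert abs(z_adj - z_marg) < 1.0

    def test_deterministic_function_of_adjustment_is_confounded(self):
        rng = np.random.default_rng(22)
        n = 500
        X1 = rng.binomial(2, 0.3, n).astype(float)
        X2 = rng.binomial(2, 0.2, n).astype(float)
        logit = -0.5 + 0.9 * X1 + 0.5 * X2  # same-sign effects
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
        X = pd.DataFrame({"x1": X1, "x2": X2})
        res = conditional_scan(y, X, {"combo": X["x1"] + 2 * X["x2"]})
        row = res.iloc[0]
        assert row["status"] == "confounded"
        assert row["coef"] == 0.0 and np.isnan(row["p_adjusted"])
        assert row["p_marginal"] < 0.05  # marginally associated via x1/x2

    def test_type_one_error_calibrated_with_correlated_null_term(self):
        """Score test holding the adjustment fixed rejects at ~alpha under the
        null even when the test term is correlated with the adjustment."""
        rng = np.random.default_rng(123)
        rejections = 0
        reps = 300
        for _ in range(reps):
            y, X = self._data(rng, n=400)
            flip = rng.random(len(y)) < 0.5
            Z = np.where(flip, X["x1"], rng.binomial(2, 0.3, len(y))).astype(float)
            res = conditional_scan(y, X, {"z": pd.Series(Z)})
            rejections += res.iloc[0]["p_adjusted"] < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.03)

    def test_low_copy_terms_skipped(self):
        rng = np.random.default_rng(23)
        y, X = self._data(rng)
        Z = np.zeros(len(y))
        Z[:3] = 1
        res = conditional_scan(y, X, {"rare": pd.Series(Z)}, min_copies=5)
        assert res.iloc[0]["status"] == "skipped(<min_copies)"


class TestResidueAndTransScans:
    def test_trans_motifs_lose_significance_after_cis_adjustment(
            self, study_cohort_motifs, registry, panel):
        """Trans motifs are recombinations of cis alleles; once every cis
        motif is adjusted for, few trans motifs should stay significant."""
        res = trans_scan(study_cohort_motifs, registry, panel)
        ok = res[res["status"] == "ok"]
        assert len(ok) >= 5
        frac_sig = (ok["p_adjusted"] < 0.05).mean()
        assert frac_sig <= 0.2
        # while marginally, LD with cis motifs makes many look associated
        assert (ok["p_marginal"] < 0.05).mean() > frac_sig

    def test_residue_scan_reports_marginal_signal(self, study_cohort_motifs,
                                                  registry, panel):
        res = residue_scan(study_cohort_motifs, registry, panel=panel)
        # panel residues are linear functions of the motif counts: with the
        # default one-pair-per-motif pool every residue is confounded, and
        # each still shows strong marginal association
        beta57 = res[res["term"] == "β57"].iloc[0]
        assert beta57["status"] == "confounded"
        assert beta57["p_marginal"] < 1e-10


def _antibody_truth(base, effect, f):
    """Exact per-copy 2x2 OR for a motif-conditional antibody effect, from
    enumeration over carriage classes (0/1/2 copies, Hardy-Weinberg)."""
    cells = np.zeros((2, 2))  # rows: motif copy yes/no; cols: pos/neg
    for k, pk in ((0, (1 - f) ** 2), (1, 2 * f * (1 - f)), (2, f ** 2)):
        ppos = 1 / (1 + math.exp(-(math.log(base / (1 - base)) + k * effect)))
        cells[0] += pk * np.array([k * ppos, k * (1 - ppos)])
        cells[1] += pk * np.array([(2 - k) * ppos, (2 - k) * (1 - ppos)])
    return (cells[0, 0] * cells[1, 1]) / (cells[0, 1] * cells[1, 0])


class TestAutoantibody:
    @staticmethod
    def _patients(rng, n, base, effect, f):
        m1 = np.where(rng.random(n) < f, "M", "O")
        m2 = np.where(rng.random(n) < f, "M", "O")
        k = (m1 == "M").astype(int) + (m2 == "M").astype(int)
        logit = math.log(base / (1 - base)) + effect * k
        pos = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
        return genotype_frame([CASE] * n, m1, m2, gada=pos)

    def test_null_effect_gives_or_near_one(self):
        rng = np.random.default_rng(31)
        df = self._patients(rng, 4000, base=0.6, effect=0.0, f=0.2)
        res = autoantibody_association(df, "gada").set_index("motif")
        assert res.loc["M", "odds_ratio"] == pytest.approx(1.0, abs=0.2)
        assert res.loc["M", "p"] > 0.001

    def test_recovers_injected_effect_within_ci(self):
        rng = np.random.default_rng(32)
        base, effect, f = 0.6, 0.45, 0.15
        truth = _antibody_truth(base, effect, f)
        df = self._patients(rng, 1000, base, effect, f)
        res = autoantibody_association(df, "gada").set_index("motif")
        row = res.loc["M"]
        # Wald CI on the log cross-product OR
        a = row["positive_copies"]
        b = row["copies"] - a
        pos_all = df["gada"].repeat(2).sum()
        c, d = pos_all - a, 2 * len(df) - row["copies"] - (pos_all - a)
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        assert abs(math.log(row["odds_ratio"]) - math.log(truth)) < 1.96 * se

    def test_absent_antibody_column_skipped(self):
        df = genotype_frame([CASE], ["M"], ["O"])
        assert autoantibody_association(df, "gada") is None

    def test_all_positive_is_degenerate(self):
        df = genotype_frame([CASE] * 30, ["M"] * 30, ["O"] * 30,
                            gada=[1.0] * 30)
        res = autoantibody_association(df, "gada", min_copies=10)
        assert res["p"].isna().all()

    def test_missing_calls_excluded_not_negative(self):
        df = genotype_frame([CASE] * 40, ["M"] * 40, ["O"] * 40,
                            gada=[1.0] * 20 + [float("nan")] * 20)
        res = autoantibody_association(df, "gada", min_copies=10)
        assert (res["copies"] == 20).all()  # only informative copies counted

    @pytest.mark.parametrize("calls,expected", [
        ([1, 1, 0, 0, 0, 0], "2-4"),
        ([1, 0, 0, 0, 0, 0], "0-1"),
        ([None] * 6, None),
        ([1, None, 1, None, None, None], "2-4"),
    ])
    def test_antibody_count_grouping(self, calls, expected):
        assert antibody_count_group(calls) == expected

    def test_count_contrast_detects_count_dependent_effect(self):
        rng = np.random.default_rng(33)
        n = 2000
        m1 = np.where(rng.random(n) < 0.2, "M", "O")
        m2 = np.where(rng.random(n) < 0.2, "M", "O")
        k = (m1 == "M").astype(int) + (m2 == "M").astype(int)
        # carrying M raises the chance of multiple autoantibodies
        p_multi = 1 / (1 + np.exp(-(-0.5 + 0.8 * k)))
        multi = rng.random(n) < p_multi
        iaa = multi.astype(float)
        gada = multi.astype(float)
        df = genotype_frame([CASE] * n, m1, m2, iaa=iaa, gada=gada)
        res = autoantibody_count_contrast(df).set_index("motif")
        assert res.loc["M", "odds_ratio"] > 1
        assert res.loc["M", "p"] < 0.01


class TestDrDqHaplotypes:
    def test_complete_ld_joint_haplotype_matches_motif_or(self, registry, panel):
        from dqmotif.simulate import SynthConfig, simulate_cohort
        from dqmotif.pipeline import motif_association_table
        cfg = SynthConfig(seed=61)  # default map: DR3 uniquely on DQ2.5
        cohort = attach_motifs(simulate_cohort(cfg, registry, panel),
                               registry, panel)
        drdq = drdq_haplotype_analysis(cohort).set_index("label")
        motif_table, _ = motif_association_table(cohort)
        motif_or = motif_table.set_index("label").loc["DCAA-YSARD", "or_virtual"]
        joint = drdq.loc["DRB1*03:01~DCAA-YSARD"]
        # complete LD: identical copy counts up to rare-exclusion totals
        assert joint["or_virtual"] == pytest.approx(motif_or, rel=0.01)

    def test_low_copy_haplotypes_excluded(self):
        df = genotype_frame(
            [CASE] * 50 + [CONTROL] * 50,
            ["A"] * 100, ["A"] * 100,
            drb1_1=["DR1"] * 99 + ["DRX"], drb1_2=["DR1"] * 100)
        out = drdq_haplotype_analysis(df, min_copies=5)
        assert "DRX" not in set(out["drb1"])

    def test_missing_drb1_returns_none(self):
        df = genotype_frame([CASE], ["A"], ["A"])
        assert drdq_haplotype_analysis(df) is None


class TestClusteredVirtualOr:
    def test_matches_plain_estimate_and_widens_se(self, study_cohort_motifs):
        from dqmotif.motifs import motif_copy_counts
        counts = motif_copy_counts(study_cohort_motifs)
        m = "DCAA-YSARD"
        n_cases = (study_cohort_motifs["status"] == CASE).sum()
        n_controls = (study_cohort_motifs["status"] == CONTROL).sum()
        plain = virtual_reference_or(int(counts.loc[m, CASE]), 2 * n_cases,
                                     int(counts.loc[m, CONTROL]), 2 * n_controls)
        clustered = virtual_or_clustered(study_cohort_motifs, m)
        assert clustered.or_virtual == pytest.approx(plain.or_virtual, rel=1e-12)
        assert clustered.method == "virtual_reference_clustered"
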