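import numpy as np
import pandas as pd
import pytest
from scipy import stats

from glycoreg.oncogenomics import (
    SurvivalRecord,
    alteration_prevalence,
    cna_expression_concordance,
    log2_cpm,
    logrank_test,
    paired_de,
    rank_oncoprint,
    survival_records,
    survival_scan,
    tmm_factors,
)
from glycoreg.simulate import simulate_tumor_cohort


def tmm_oracle(counts: np.ndarray, ref_col: int) -> np.ndarray:
    """Independent TMM re-implementation: sort-based trimming, explicit loops."""
    lib = counts.sum(axis=0)
    factors = []
    for j in range(counts.shape[1]):
        obs, ref = counts[:, j], counts[:, ref_col]
        keep = (obs > 0) & (ref > 0)
        o, r = obs[keep] / lib[j], ref[keep] / lib[ref_col]
        M = np.log2(o / r)
        A = 0.5 * np.log2(o * r)
        w = (lib[j] - obs[keep]) / (lib[j] * obs[keep]) + \
            (lib[ref_col] - ref[keep]) / (lib[ref_col] * ref[keep])
        if M.size == 0 or np.max(np.abs(M)) < 1e-6:
            factors.append(1.0)
            continue
        n = M.size
        lo_m = int(np.floor(n * 0.3) + 1)
        lo_a = int(np.floor(n * 0.05) + 1)
        rank_m = stats.rankdata(M)
        rank_a = stats.rankdata(A)
        sel = [i for i in range(n)
               if lo_m <= rank_m[i] <= n + 1 - lo_m
               and lo_a <= rank_a[i] <= n + 1 - lo_a]
        num = sum(M[i] / w[i] for i in sel)
        den = sum(1.0 / w[i] for i in sel)
        factors.append(2.0 ** (num / den) if sel and den > 0 else 1.0)
    f = np.array(factors)
    return f / np.exp(np.mean(np.log(f)))


@pytest.fixture(scope="module")
def planted_cohort():
    genes = [f"G{i:03d}" for i in range(10)]
    cohort, truth = simulate_tumor_cohort(
        500, genes,
        mut_rates={"G000": 0.3}, cna_rates={"G001": 0.2, "G002": 0.1},
        lfc_truth={"G003": 2.0, "G004": -1.5},
        hazard_model={"G001": 3.0}, seed=11)
    return cohort, truth


class TestAlterationPrevalence:
    def test_small_hand_case(self):
        cohort, _ = simulate_tumor_cohort(10, ["G"], seed=0)
        cohort.cna.iloc[:3, 0] = 2
        prev = alteration_prevalence(cohort)
        assert prev.loc["G", "pct_amplified"] == pytest.approx(30.0)
        assert prev.loc["G", "pct_any"] == pytest.approx(30.0)

    def test_patient_with_snv_and_amp_counted_once(self):
        cohort, _ = simulate_tumor_cohort(10, ["G"], seed=0)
        cohort.snv.iloc[0, 0] = True
        cohort.cna.iloc[0, 0] = 2
        prev = alteration_prevalence(cohort)
        assert prev.loc["G", "pct_any"] == pytest.approx(10.0)

    def test_matches_brute_force_patient_loop(self, planted_cohort):
        cohort, _ = planted_cohort
        prev = alteration_prevalence(cohort)
        for g in cohort.snv.columns:
            n_any = sum(
                bool(cohort.snv.loc[p, g]) or abs(cohort.cna.loc[p, g]) >= 1
                for p in cohort.patients)
            assert prev.loc[g, "pct_any"] == pytest.approx(
                100.0 * n_any / len(cohort.patients))

    def test_planted_rates_recovered(self, planted_cohort):
        cohort, _ = planted_cohort
        prev = alteration_prevalence(cohort)
        assert prev.loc["G000", "pct_mutated"] == pytest.approx(30.0, abs=6.0)
        assert prev.loc["G001", "pct_amplified"] + prev.loc[
            "G001", "pct_deleted"] == pytest.approx(20.0, abs=5.0)

    def test_strict_threshold_mode(self, planted_cohort):
        cohort, _ = planted_cohort
        strict = alteration_prevalence(cohort, cna_threshold=2)
        loose = alteration_prevalence(cohort, cna_threshold=1)
        assert (strict["pct_amplified"] <= loose["pct_amplified"]).all()


class TestRankOncoprint:
    def test_single_gene_rank_one(self):
        df = pd.DataFrame({"pct_mutated": [1.0], "pct_amplified": [0.0],
                           "pct_deleted": [0.0], "pct_any": [1.0],
                           "cancer_type": ["X"]}, index=pd.Index(["G"], name="gene"))
        ranked = rank_oncoprint(df)
        assert ranked.index[0] == 1 and ranked.iloc[0]["gene"] == "G"

    def test_ties_broken_lexicographically(self):
        df = pd.DataFrame({"pct_mutated": [0, 0], "pct_amplified": [0, 0],
                           "pct_deleted": [0, 0], "pct_any": [5.0, 5.0],
                           "cancer_type": ["X", "X"]},
                          index=pd.Index(["B", "A"], name="gene"))
        assert list(rank_oncoprint(df)["gene"]) == ["A", "B"]

    def test_planted_top_gene_recovered(self):
        genes = [f"G{i:03d}" for i in range(20)]
        rates = {g: 0.01 for g in genes}
        rates["G007"] = 0.15
        cohort, _ = simulate_tumor_cohort(800, genes, mut_rates=rates, seed=3)
        ranked = rank_oncoprint(alteration_prevalence(cohort))
        assert ranked.iloc[0]["gene"] == "G007"


class TestTMM:
    def test_identical_columns_unit_factors(self):
        col = np.arange(1, 101, dtype=float)
        m = pd.DataFrame({"a": col, "b": col, "c": col})
        assert np.allclose(tmm_factors(m), 1.0)

    def test_pure_depth_scaling_removed(self):
        rng = np.random.default_rng(4)
        col = rng.negative_binomial(5, 0.02, 400).astype(float) + 1
        m = pd.DataFrame({"a": col, "b": col * 2.0})
        assert np.allclose(tmm_factors(m), 1.0, atol=1e-6)

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            counts = rng.negative_binomial(5, 0.01, size=(300, 5)).astype(float)
            counts[rng.random(counts.shape) < 0.1] = 0
            counts[counts.sum(axis=1) == 0, 0] = 1  # avoid all-zero rows only
            m = pd.DataFrame(counts)
            lib = counts.sum(axis=0)
            q75 = np.array([np.quantile(counts[:, j] / lib[j], 0.75)
                            for j in range(5)])
            ref = int(np.argmin(np.abs(q75 - q75.mean())))
            assert np.allclose(tmm_factors(m).to_numpy(),
                               tmm_oracle(counts, ref), atol=1e-6)

    def test_all_zero_library_rejected(self):
        m = pd.DataFrame({"a": [1.0, 2.0], "b": [0.0, 0.0]})
        with pytest.raises(ValueError, match="all-zero"):
            tmm_factors(m)

    def test_factors_multiply_to_one(self):
        rng = np.random.default_rng(6)
        m = pd.DataFrame(rng.negative_binomial(5, 0.01, size=(200, 4)).astype(float))
        f = tmm_factors(m)
        assert np.prod(f) == pytest.approx(1.0, abs=1e-9)


class TestPairedDE:
    def test_planted_lfc_recovered(self, planted_cohort):
        cohort, _ = planted_cohort
        de = paired_de(cohort)
        assert de.loc["G003", "log2_fc"] == pytest.approx(2.0, abs=0.3)
        assert de.loc["G003", "q"] < 0.05
        assert de.loc["G004", "log2_fc"] == pytest.approx(-1.5, abs=0.3)

    def test_direction_matches_planted_sign(self, planted_cohort):
        cohort, truth = planted_cohort
        de = paired_de(cohort)
        for g, lfc in truth.tumor_lfc.items():
            if abs(lfc) >= 1:
                assert np.sign(de.loc[g, "log2_fc"]) == np.sign(lfc)

    def test_tumor_equals_normal_null(self):
        cohort, _ = simulate_tumor_cohort(20, ["A", "B"], seed=7)
        normal_cols = [c for c in cohort.expression.columns
                       if c.endswith("_normal")]
        for nc in normal_cols:
            cohort.expression[nc.replace("_normal", "_tumor")] = \
                cohort.expression[nc]
        de = paired_de(cohort)
        assert np.allclose(de["log2_fc"], 0.0)
        assert np.allclose(de["p"], 1.0)

    def test_null_type_one_error_controlled(self):
        flags = []
        for seed in range(30):
            cohort, _ = simulate_tumor_cohort(20, [f"G{i}" for i in range(20)],
                                              seed=100 + seed)
            de = paired_de(cohort)
            flags.append((de["p"] < 0.05).mean())
        # raw p at 5%: mean false-positive rate within binomial noise
        assert np.mean(flags) <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / (30 * 20))

    def test_too_few_pairs_rejected(self):
        cohort, _ = simulate_tumor_cohort(10, ["A"], seed=0)
        cohort.expression = cohort.expression.iloc[:, :4]
        with pytest.raises(ValueError, match="pairs"):
            paired_de(cohort)


class TestConcordance:
    def test_identical_vectors_r_one(self):
        v = pd.Series(np.arange(10.0), index=[f"g{i}" for i in range(10)])
        r, _ = cna_expression_concordance(v, v)
        assert r == pytest.approx(1.0)

    def test_planted_coupling_recovered(self):
        rng = np.random.default_rng(8)
        cna = pd.Series(rng.uniform(0, 20, 100))
        lfc = 0.1 * cna + rng.normal(0, 0.3, 100)
        r, p = cna_expression_concordance(cna, lfc.abs())
        assert r > 0.3 and p < 0.01

    def test_null_p_uniform(self):
        rng = np.random.default_rng(9)
        ps = []
        for _ in range(200):
            a = pd.Series(rng.normal(size=30))
            b = pd.Series(rng.normal(size=30))
            ps.append(cna_expression_concordance(a, b)[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_too_few_genes_rejected(self):
        v = pd.Series(np.arange(5.0))
        with pytest.raises(ValueError, match="10"):
            cna_expression_concordance(v, v)


class TestLogrank:
    @staticmethod
    def _records(times_a, times_u, events_a=None, events_u=None):
        events_a = events_a or [True] * len(times_a)
        events_u = events_u or [True] * len(times_u)
        recs = [SurvivalRecord(f"a{i}", t, e, "altered")
                for i, (t, e) in enumerate(zip(times_a, events_a))]
        recs += [SurvivalRecord(f"u{i}", t, e, "unaltered")
                 for i, (t, e) in enumerate(zip(times_u, events_u))]
        return recs

    def test_identical_groups_statistic_zero(self):
        times = [10.0, 20.0, 30.0, 40.0]
        stat, p = logrank_test(self._records(times, times))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_one_group_missing_rejected(self):
        recs = [SurvivalRecord("a", 10.0, True, "altered")]
        with pytest.raises(ValueError, match="both groups"):
            logrank_test(recs)

    def test_time_unit_rescaling_invariant(self):
        rng = np.random.default_rng(10)
        ta = rng.exponential(100, 30)
        tu = rng.exponential(300, 30)
        s1, _ = logrank_test(self._records(list(ta), list(tu)))
        s2, _ = logrank_test(self._records(list(ta * 365), list(tu * 365)))
        assert s1 == pytest.approx(s2, rel=1e-9)

    def test_planted_hazard_detected(self, planted_cohort):
        cohort, _ = planted_cohort
        stat, p = logrank_test(survival_records(cohort, "G001"))
        assert p < 0.01

    def test_survival_scan_flags_planted_gene(self, planted_cohort):
        cohort, _ = planted_cohort
        scan = survival_scan(cohort).set_index("gene")
        assert scan.loc["G001", "q"] < 0.05
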