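"""Clinical groupings, Fisher/t tests, HMG-LMG, exclusivity, driver consensus."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from mutscape import (
    Cohort, KMeans1D, kmeans1d_split, build_groupings, gene_group_fisher,
    gene_numeric_ttest, hmg_lmg_classify, pairwise_interactions,
    driver_consensus,
)


def cohort_from_status(status: pd.DataFrame, clinical=None) -> Cohort:
    """Build a Cohort whose mutation table realises a sample x gene matrix."""
    rows = []
    for sample in status.index:
        for gene in status.columns:
            if status.loc[sample, gene]:
                rows.append((sample, "c", gene, "1", 1, "C", "T", "SNP",
                             "missense", "", "A", "G"))
    muts = pd.DataFrame(rows, columns=[
        "sample_id", "cohort", "gene", "chrom", "pos", "ref_allele",
        "alt_allele", "variant_type", "variant_class", "protein_change",
        "context5", "context3"])
    clin = clinical if clinical is not None else pd.DataFrame(
        index=pd.Index(status.index, name="sample_id"))
    return Cohort(mutations=muts, clinical=clin)


class TestKMeans1D:
    def test_hand_example_against_exhaustive_split(self):
        ages = [50, 55, 58, 62, 65, 70]
        labels, boundary = kmeans1d_split(ages)
        assert list(labels) == [0, 0, 0, 1, 1, 1]
        assert 58 < boundary < 62

    def test_perfectly_separated(self):
        labels, boundary = kmeans1d_split([40, 40, 40, 80, 80, 80])
        assert list(labels) == [0, 0, 0, 1, 1, 1]
        assert 40 < boundary < 80

    def test_constant_values_rejected(self):
        with pytest.raises(ValueError):
            kmeans1d_split([5, 5, 5, 5])

    def test_equals_exhaustive_contiguous_search(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            x = np.sort(rng.normal(60, 12, rng.integers(8, 120)).round(1))
            if np.unique(x).size < 2:
                continue
            model = KMeans1D(2).fit(x)
            # oracle: try every contiguous split of the sorted values
            best_ss, best_i = np.inf, None
            for i in range(1, len(x)):
                if x[i - 1] == x[i]:
                    continue  # identical values cannot straddle a boundary
                left, right = x[:i], x[i:]
                ss = ((left - left.mean()) ** 2).sum() + ((right - right.mean()) ** 2).sum()
                if ss < best_ss:
                    best_ss, best_i = ss, i
            assert model.inertia_ == pytest.approx(best_ss, abs=1e-9)

    def test_unsorted_input_labels_align(self):
        labels, _ = kmeans1d_split([70, 50, 65, 55])
        assert list(labels) == [1, 0, 1, 0]


class TestGroupings:
    @pytest.fixture
    def clinical(self):
        return pd.DataFrame({
            "age": [45, 50, 66, 70],
            "gender": ["male", "female", "male", "male"],
            "smoking": ["yes", "no", "yes", "unknown"],
            "drinking": ["no", "no", "yes", "yes"],
            "t_stage": ["T2", "T1", "T3", "T4"],
            "n_lymph": ["yes", "no", "yes", "no"],
            "tnm_stage": ["S1", "S2", "S3", "S4"],
            "grade": ["G1", "G2", "G3", "G4"],
            "location": ["upper", "middle", "lower", "middle"],
        }, index=pd.Index(["P1", "P2", "P3", "P4"], name="sample_id"))

    def test_convention_assignments(self, clinical):
        g = build_groupings(clinical)
        assert g["t_stage"].loc["P1"] == "A"      # T2 -> T1-T2 arm
        assert g["t_stage"].loc["P3"] == "B"
        assert g["tnm_stage"].loc["P3"] == "B"    # S3 -> S3-S4 arm
        assert g["lymph_metastasis"].loc["P1"] == "A"
        assert g["grade"].loc["P4"] == "B"
        assert set(g["location"].unique()) <= {"upper", "middle", "lower"}

    def test_unknowns_excluded(self, clinical):
        g = build_groupings(clinical)
        assert "P4" not in g["smoking"].index

    def test_both_age_groupings_emitted(self, clinical):
        g = build_groupings(clinical)
        assert g["age_60"].loc["P1"] == "A" and g["age_60"].loc["P3"] == "B"
        assert set(g["age_kmeans"]) == {"A", "B"}

    def test_m_stage_never_emitted_and_missing_column_warns(self, clinical):
        g = build_groupings(clinical.drop(columns=["grade"]))
        assert "grade" not in g
        assert "m_stage" not in g  # distant metastasis is never tested


class TestGeneGroupFisher:
    def test_balanced_gene_or_1_p_1(self):
        status = pd.DataFrame(False, index=[f"P{i}" for i in range(100)],
                              columns=["G1"])
        status.iloc[:10] = True    # 10/50 mutated in arm A
        status.iloc[50:60] = True  # 10/50 mutated in arm B
        cohort = cohort_from_status(status)
        grouping = pd.Series(["A"] * 50 + ["B"] * 50, index=status.index)
        res = gene_group_fisher(cohort, grouping).set_index("gene")
        assert res.loc["G1", "odds_ratio"] == pytest.approx(1.0)
        assert res.loc["G1", "p"] == pytest.approx(1.0)

    def test_p_matches_hypergeometric_enumeration(self):
        # toy table [[8,2],[2,8]]
        status = pd.DataFrame(False, index=[f"P{i}" for i in range(20)],
                              columns=["G1"])
        status.iloc[:8] = True     # 8 of 10 in arm A mutated
        status.iloc[10:12] = True  # 2 of 10 in arm B mutated
        cohort = cohort_from_status(status)
        grouping = pd.Series(["A"] * 10 + ["B"] * 10, index=status.index)
        res = gene_group_fisher(cohort, grouping).set_index("gene")
        rv = hypergeom(20, 10, 10)  # N, K (mutated), n (arm A)
        p_obs = rv.pmf(8)
        p_enum = sum(rv.pmf(k) for k in range(0, 11) if rv.pmf(k) <= p_obs * (1 + 1e-9))
        assert res.loc["G1", "p"] == pytest.approx(p_enum, rel=1e-9)
        assert res.loc["G1", "direction"] == "higher_in_A"

    def test_min_mutated_floor(self):
        status = pd.DataFrame(False, index=[f"P{i}" for i in range(20)],
                              columns=["G1", "G2"])
        status.loc["P0", "G1"] = True  # only 1 mutated sample
        status.iloc[:5, 1] = True
        cohort = cohort_from_status(status)
        grouping = pd.Series(["A"] * 10 + ["B"] * 10, index=status.index)
        res = gene_group_fisher(cohort, grouping, min_mutated=3)
        assert set(res["gene"]) == {"G2"}

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(5)
        status = pd.DataFrame(rng.random((40, 3)) < 0.4,
                              index=[f"P{i}" for i in range(40)],
                              columns=["G1", "G2", "G3"])
        cohort = cohort_from_status(status)
        grouping = pd.Series(rng.choice(["A", "B"], 40), index=status.index)
        swapped = grouping.map({"A": "B", "B": "A"})
        p1 = gene_group_fisher(cohort, grouping).set_index("gene")["p"]
        p2 = gene_group_fisher(cohort, swapped).set_index("gene")["p"]
        assert np.allclose(p1.sort_index(), p2.sort_index())

    def test_bh_fdr_monotone_and_above_p(self):
        rng = np.random.default_rng(6)
        status = pd.DataFrame(rng.random((60, 20)) < 0.3,
                              index=[f"P{i}" for i in range(60)],
                              columns=[f"G{i}" for i in range(20)])
        cohort = cohort_from_status(status)
        grouping = pd.Series(rng.choice(["A", "B"], 60), index=status.index)
        res = gene_group_fisher(cohort, grouping)
        assert (res["fdr"] >= res["p"] - 1e-12).all()
        srt = res.sort_values("p")
        assert (np.diff(srt["fdr"]) >= -1e-12).all()

    def test_empty_arm_rejected(self):
        status = pd.DataFrame(True, index=["P1", "P2"], columns=["G1"])
        cohort = cohort_from_status(status)
        with pytest.raises(ValueError, match="empty arm"):
            gene_group_fisher(cohort, pd.Series(["A", "A"], index=status.index))


class TestGeneNumericTTest:
    def test_welch_formula_hand_case(self):
        status = pd.DataFrame({"G1": [True, True, True, False, False, False]},
                              index=[f"P{i}" for i in range(6)])
        cohort = cohort_from_status(status)
        values = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], index=status.index)
        res = gene_numeric_ttest(cohort, values, min_mutated=1).set_index("gene")
        # Welch t by hand: means 2 and 5, s^2 = 1 each, n = 3 each
        t_hand = (2 - 5) / np.sqrt(1 / 3 + 1 / 3)
        assert res.loc["G1", "t"] == pytest.approx(t_hand, abs=1e-12)

    def test_equal_means_t_zero(self):
        status = pd.DataFrame({"G1": [True, True, False, False]},
                              index=[f"P{i}" for i in range(4)])
        cohort = cohort_from_status(status)
        values = pd.Series([3.0, 5.0, 3.0, 5.0], index=status.index)
        res = gene_numeric_ttest(cohort, values, min_mutated=1).set_index("gene")
        assert res.loc["G1", "t"] == pytest.approx(0.0, abs=1e-12)

    def test_single_sample_arm_skipped(self):
        status = pd.DataFrame({"G1": [True, False, False, False]},
                              index=[f"P{i}" for i in range(4)])
        cohort = cohort_from_status(status)
        values = pd.Series([1.0, 2.0, 3.0, 4.0], index=status.index)
        res = gene_numeric_ttest(cohort, values, min_mutated=1).set_index("gene")
        assert bool(res.loc["G1", "skipped"])


class TestHmgLmg:
    def make_assoc(self, rows):
        return pd.DataFrame(rows, columns=["gene", "rate_A", "rate_B", "p"])

    def test_rule_application(self):
        assoc = self.make_assoc([
            ("G_up", 0.30, 0.10, 0.01),
            ("G_down", 0.05, 0.20, 0.01),
            ("G_ns", 0.30, 0.10, 0.20),
        ])
        out = hmg_lmg_classify(assoc)
        assert out["G_up"] == "HMG"
        assert out["G_down"] == "LMG"
        assert out["G_ns"] == "none"

    def test_partition_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(1)
        assoc = self.make_assoc([
            (f"G{i}", rng.random(), rng.random(), rng.random()) for i in range(50)])
        out = hmg_lmg_classify(assoc)
        assert len(out) == 50
        assert set(out.unique()) <= {"HMG", "LMG", "none"}


class TestInteractions:
    def test_perfect_exclusivity(self):
        status = pd.DataFrame(False, index=[f"P{i}" for i in range(20)],
                              columns=["GA", "GB"])
        status.iloc[:10, 0] = True
        status.iloc[10:, 1] = True
        res = pairwise_interactions(cohort_from_status(status), top_n=2)
        row = res.iloc[0]
        assert row["odds_ratio"] == 0.0
        assert row["classification"] == "mutually_exclusive"

    def test_perfect_cooccurrence(self):
        status = pd.DataFrame(False, index=[f"P{i}" for i in range(20)],
                              columns=["GA", "GB"])
        status.iloc[:10] = True
        res = pairwise_interactions(cohort_from_status(status), top_n=2)
        row = res.iloc[0]
        assert np.isinf(row["odds_ratio"])
        assert row["classification"] == "co_occurring"

    def test_independent_pair_usually_unclassified(self):
        rng = np.random.default_rng(11)
        status = pd.DataFrame(rng.random((100, 2)) < 0.4,
                              index=[f"P{i}" for i in range(100)],
                              columns=["GA", "GB"])
        res = pairwise_interactions(cohort_from_status(status), top_n=2)
        assert res.iloc[0]["classification"] == "independent"


class TestDriverConsensus:
    def test_two_tool_support_makes_driver(self):
        tables = {
            "mutsigcv": pd.DataFrame({"gene": ["TP53"], "fdr": [0.01]}),
            "driverml": pd.DataFrame({"gene": ["TP53"], "p": [0.005]}),
        }
        out = driver_consensus(tables).set_index("gene")
        assert bool(out.loc["TP53", "is_driver"])
        assert out.loc["TP53", "n_tools_supporting"] == 2

    def test_single_tool_not_driver(self):
        tables = {"oncodrivefml": pd.DataFrame({"gene": ["KRAS"], "fdr": [0.001]})}
        out = driver_consensus(tables).set_index("gene")
        assert not bool(out.loc["KRAS", "is_driver"])

    def test_thresholds_respected(self):
        tables = {
            "mutsigcv": pd.DataFrame({"gene": ["G1"], "fdr": [0.06]}),   # miss
            "driverml": pd.DataFrame({"gene": ["G1"], "p": [0.02]}),     # miss (p >= 0.01)
            "oncodriveclustl": pd.DataFrame({"gene": ["G1"], "fdr": [0.04]}),  # hit
        }
        out = driver_consensus(tables).set_index("gene")
        assert out.loc["G1", "n_tools_supporting"] == 1
        assert not bool(out.loc["G1", "is_driver"])

    def test_empty_inputs_empty_table(self):
        assert len(driver_consensus({})) == 0

    def test_unknown_tool_rejected(self):
        with pytest.raises(ValueError, match="unknown driver tool"):
            driver_consensus({"dndscv": pd.DataFrame({"gene": [], "p": []})})
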