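"""Signature extraction: NMF behaviour, k selection, annotation, exposures."""

import numpy as np
import pandas as pd
import pytest

from mutscape import (
    Cohort, SignatureNMF, build_catalog, extract_signatures, select_k,
    cosine_annotate, attribute_exposures, signature_clinical_tests,
    default_signatures,
)
from mutscape.signatures import SBS96_CHANNELS


def cosine(u, v):
    return float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))


def test_build_catalog_counts_channels():
    rows = [("G1", "1", i, "C", "A", "missense", "SNP", "P1", "A", "A")
            for i in range(3)]
    muts = pd.DataFrame(rows, columns=["gene", "chrom", "pos", "ref_allele",
                                       "alt_allele", "variant_class",
                                       "variant_type", "sample_id",
                                       "context5", "context3"])
    muts["cohort"] = "c"
    muts["protein_change"] = ""
    cat = build_catalog(Cohort(mutations=muts), "SBS96")
    assert cat.loc["P1", "A[C>A]A"] == 3
    assert cat.loc["P1"].sum() == 3


def test_catalog_all_zero_row_for_indel_only_sample():
    muts = pd.DataFrame([("G1", "1", 5, "AC", "-", "frame_shift_del", "DEL",
                          "P1", "TTT", "GGG")],
                        columns=["gene", "chrom", "pos", "ref_allele",
                                 "alt_allele", "variant_class", "variant_type",
                                 "sample_id", "context5", "context3"])
    muts["cohort"] = "c"
    muts["protein_change"] = ""
    cat = build_catalog(Cohort(mutations=muts), "SBS96")
    assert cat.loc["P1"].sum() == 0


def test_catalog_row_sums_equal_generated_counts(sim_small):
    cat = build_catalog(sim_small["cohort"], "SBS96")
    muts = sim_small["cohort"].mutations
    snv_counts = muts[muts["variant_type"] == "SNP"].groupby("sample_id").size()
    # every generated SNP carries context, so nothing is skipped
    assert cat.attrs["n_skipped"] == 0
    for sample, n in snv_counts.items():
        assert cat.loc[sample].sum() == n


def test_nmf_rank1_recovers_common_profile():
    profile = np.zeros(96)
    profile[:4] = [0.4, 0.3, 0.2, 0.1]
    X = np.outer([100, 200, 50], profile)
    cat = pd.DataFrame(X, columns=list(SBS96_CHANNELS))
    sigs, expo = extract_signatures(cat, 1, n_restarts=3, seed=0)
    assert cosine(sigs["S1"].to_numpy(), profile) > 0.99999
    assert np.allclose(sigs["S1"].sum(), 1.0)


def test_nmf_deterministic_given_seed(planted_catalog):
    cat = planted_catalog["catalog"]
    s1, e1 = extract_signatures(cat, 2, n_restarts=3, seed=123)
    s2, e2 = extract_signatures(cat, 2, n_restarts=3, seed=123)
    assert np.array_equal(s1.to_numpy(), s2.to_numpy())
    assert np.array_equal(e1.drop(columns="dominant_signature").to_numpy(),
                          e2.drop(columns="dominant_signature").to_numpy())


def test_nmf_objective_non_increasing(planted_catalog):
    model = SignatureNMF(n_signatures=2, n_restarts=2, random_state=5)
    model.fit(planted_catalog["catalog"])
    diffs = np.diff(model.objective_history_)
    assert (diffs <= 1e-8 * model.objective_history_[0]).all()


def test_nmf_signatures_column_stochastic(planted_catalog):
    model = SignatureNMF(n_signatures=2, n_restarts=2, random_state=5)
    model.fit(planted_catalog["catalog"])
    assert np.allclose(model.signatures_.sum(axis=0), 1.0, atol=1e-8)
    assert (model.signatures_ >= 0).all()
    assert (model.exposures_ >= 0).all()


def test_planted_signature_recovery(planted_catalog):
    cat, truth = planted_catalog["catalog"], planted_catalog["signatures"]
    sigs, expo = extract_signatures(cat, 2, n_restarts=10, seed=7)
    ann = cosine_annotate(sigs, truth)
    assert set(ann["best_match"]) == {"SigA", "SigB"}
    assert (ann["similarity"] >= 0.95).all()


def test_exposure_row_sums_track_catalog_row_sums(planted_catalog):
    cat = planted_catalog["catalog"]
    sigs, expo = extract_signatures(cat, 2, n_restarts=10, seed=7)
    total_expo = expo[["S1", "S2"]].sum(axis=1).to_numpy()
    total_counts = cat.sum(axis=1).to_numpy()
    assert np.all(np.abs(total_expo - total_counts) <= 0.05 * total_counts)


def test_nmf_matches_sklearn_objective(planted_catalog):
    # independent cross-check: our multiplicative-update fit reaches the same
    # reconstruction error as sklearn's NMF (mu solver) within 1%
    from sklearn.decomposition import NMF as SkNMF
    X = planted_catalog["catalog"].to_numpy(float)
    ours = SignatureNMF(n_signatures=2, n_restarts=5, random_state=0).fit(X)
    sk = SkNMF(n_components=2, solver="mu", beta_loss="frobenius", init="random",
               max_iter=2000, tol=1e-6, random_state=0).fit(X)
    sk_err = np.linalg.norm(X - sk.transform(X) @ sk.components_)
    assert ours.reconstruction_err_ <= sk_err * 1.01


def test_nmf_input_validation(planted_catalog):
    cat = planted_catalog["catalog"]
    with pytest.raises(ValueError):
        SignatureNMF(n_signatures=0).fit(cat)
    with pytest.raises(ValueError):
        SignatureNMF(n_signatures=97).fit(cat)
    with pytest.raises(ValueError):
        SignatureNMF(n_signatures=1).fit(np.zeros((3, 96)))


class TestSelectK:
    def test_two_signature_catalog_selects_2(self, planted_catalog):
        sel = select_k(planted_catalog["catalog"], range(1, 5), seed=7)
        assert sel["k"] == 2

    def test_rank1_catalog_selects_1(self):
        rng = np.random.default_rng(3)
        profile = default_signatures()["SigA"].to_numpy()
        X = np.vstack([rng.multinomial(500, profile) for _ in range(20)])
        cat = pd.DataFrame(X, columns=list(SBS96_CHANNELS))
        assert select_k(cat, range(1, 4), seed=5)["k"] == 1

    def test_single_candidate_returned_with_diagnostics(self, planted_catalog):
        sel = select_k(planted_catalog["catalog"], [3], seed=1)
        assert sel["k"] == 3
        assert list(sel["table"].index) == [3]
        assert "reconstruction_err" in sel["table"].columns

    def test_empty_range_rejected(self, planted_catalog):
        with pytest.raises(ValueError):
            select_k(planted_catalog["catalog"], [], seed=0)


class TestCosineAnnotate:
    def test_exact_match_similarity_1(self):
        ref = default_signatures()
        ann = cosine_annotate(ref[["SigA"]].rename(columns={"SigA": "X"}), ref)
        assert ann.loc["X", "best_match"] == "SigA"
        assert ann.loc["X", "similarity"] == pytest.approx(1.0)

    def test_orthogonal_flagged_novel(self):
        ref = default_signatures()
        other = pd.DataFrame(0.0, index=ref.index, columns=["X"])
        cg = [c for c in ref.index if "[C>G]" in c]  # disjoint from both refs
        other.loc[cg, "X"] = 1.0 / len(cg)
        ann = cosine_annotate(other, ref)
        assert ann.loc["X", "similarity"] == pytest.approx(0.0)
        assert ann.loc["X", "best_match"] == "novel"

    def test_perturbed_reference_recovered_brute_force(self):
        ref = default_signatures()
        v = ref["SigB"].to_numpy() * 0.95 + 0.05 / 96
        v = v / v.sum()
        query = pd.DataFrame({"Q": v}, index=ref.index)
        ann = cosine_annotate(query, ref)
        # brute-force cosine against every reference column
        best = max(ref.columns, key=lambda c: cosine(v, ref[c].to_numpy()))
        assert ann.loc["Q", "best_match"] == best == "SigB"

    def test_channel_mismatch_rejected(self):
        ref = default_signatures()
        bad = ref.iloc[:95]
        with pytest.raises(ValueError):
            cosine_annotate(bad, ref)


class TestAttributeExposures:
    def test_pure_sample_gets_full_exposure(self):
        ref = default_signatures()
        cat = pd.DataFrame([ref["SigA"].to_numpy() * 100], columns=ref.index,
                           index=["P1"])
        expo = attribute_exposures(cat, ref)
        assert expo.loc["P1", "SigA"] == pytest.approx(100, rel=1e-6)
        assert expo.loc["P1", "SigB"] == pytest.approx(0, abs=1e-8)
        assert expo.loc["P1", "dominant_signature"] == "SigA"

    def test_all_zero_sample_zero_exposure(self):
        ref = default_signatures()
        cat = pd.DataFrame(0.0, index=["P1"], columns=ref.index)
        expo = attribute_exposures(cat, ref)
        assert expo.loc["P1", ["SigA", "SigB"]].sum() == 0
        assert expo.loc["P1", "dominant_signature"] == "none"

    def test_nnls_matches_grid_search_oracle(self):
        ref = default_signatures()
        rng = np.random.default_rng(8)
        true = np.array([37.0, 83.0])
        counts = true @ ref.to_numpy().T + rng.normal(0, 0.5, 96).clip(-0.2)
        counts = np.clip(counts, 0, None)
        cat = pd.DataFrame([counts], columns=ref.index, index=["P1"])
        expo = attribute_exposures(cat, ref)
        # exhaustive grid over (a, b) exposures
        grid = np.linspace(0, 150, 301)
        S = ref.to_numpy()
        best, best_err = None, np.inf
        for a in grid:
            r = counts - a * S[:, 0]
            b = np.clip((r @ S[:, 1]) / (S[:, 1] @ S[:, 1]), 0, None)
            err = np.linalg.norm(counts - a * S[:, 0] - b * S[:, 1])
            if err < best_err:
                best, best_err = (a, b), err
        assert expo.loc["P1", "SigA"] == pytest.approx(best[0], abs=0.5)
        assert expo.loc["P1", "SigB"] == pytest.approx(best[1], abs=0.5)


class TestSignatureClinicalTests:
    def test_independent_membership_gives_or_1_p_1(self):
        dom = pd.Series(["S1"] * 10 + ["S2"] * 10 + ["S1"] * 10 + ["S2"] * 10,
                        index=[f"P{i}" for i in range(40)])
        lab = pd.Series(["A"] * 20 + ["B"] * 20, index=dom.index)
        res = signature_clinical_tests(dom, {"g": lab})
        assert (res["odds_ratio"] == 1.0).all()
        assert (res["p"] == 1.0).all()

    def test_perfect_separation_p_by_enumeration(self):
        from scipy.stats import hypergeom
        dom = pd.Series(["S1"] * 20 + ["S2"] * 20,
                        index=[f"P{i}" for i in range(40)])
        lab = pd.Series(["A"] * 20 + ["B"] * 20, index=dom.index)
        res = signature_clinical_tests(dom, {"g": lab}).set_index("signature")
        # two-sided Fisher p for [[20,0],[0,20]] via hypergeometric enumeration
        rv = hypergeom(40, 20, 20)
        p_obs = rv.pmf(20)
        p_enum = sum(rv.pmf(k) for k in range(0, 21) if rv.pmf(k) <= p_obs * (1 + 1e-9))
        assert res.loc["S1", "p"] == pytest.approx(p_enum, rel=1e-9)

    def test_empty_arm_skipped_and_flagged(self):
        dom = pd.Series(["S1", "S2"], index=["P1", "P2"])
        lab = pd.Series(["A", "A"], index=dom.index)
        res = signature_clinical_tests(dom, {"g": lab})
        assert res["skipped"].all()
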