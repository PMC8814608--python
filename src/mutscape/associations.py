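"""Gene-clinical association, mutual exclusivity and driver consensus.

Samples are dichotomised by the cohort's clinical grouping conventions
(T1-T2 vs T3-T4, TNM S1-S2 vs S3-S4, gender, lymph-node metastasis,
smoking, drinking, grade G1-G2 vs G3-G4, plus an age split both at the
fixed 60-year threshold and by exact 1-D k-means; tumor location stays
3-level; M stage is never tested). Per-gene mutation status is compared
across arms by two-sided Fisher exact tests with Benjamini-Hochberg FDR,
numeric covariates by Welch t-tests, and genes significantly enriched /
depleted in the metastasis arm are labelled HMG / LMG. Pairwise
co-mutation patterns among the most-mutated genes are classified as
mutually exclusive or co-occurring, and per-tool driver-gene tables are
aggregated into a consensus call (a gene is a driver when >= 2 tools
support it at their thresholds).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .io import Cohort

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# 1-D k-means

class KMeans1D(BaseEstimator):
    """Exact 1-D k-means by dynamic programming over contiguous splits.

    Optimal 1-D clusters are contiguous in sorted order, so the global
    optimum is found by minimising within-cluster sum of squares over all
    contiguous partitions.

    Attributes
    ----------
    boundaries_ : ndarray (k-1,)
        Midpoints between adjacent clusters, ascending.
    labels_ : ndarray
        Cluster index (0 = lowest values) per input point.
    inertia_ : float
        Total within-cluster sum of squares.
    """

    def __init__(self, n_clusters: int = 2):
        self.n_clusters = n_clusters

    def fit(self, values):
        x = np.asarray(values, dtype=float).ravel()
        k = self.n_clusters
        if np.unique(x).size < k:
            raise ValueError(f"need at least {k} distinct values for k={k}")
        order = np.argsort(x, kind="stable")
        xs = x[order]
        n = len(xs)
        # prefix sums -> O(1) within-SS of any contiguous segment
        c1 = np.concatenate([[0.0], np.cumsum(xs)])
        c2 = np.concatenate([[0.0], np.cumsum(xs**2)])

        def seg_ss(i, j):  # points i..j-1
            s, s2, m = c1[j] - c1[i], c2[j] - c2[i], j - i
            return s2 - s * s / m

        INF = np.inf
        cost = np.full((k + 1, n + 1), INF)
        split = np.zeros((k + 1, n + 1), dtype=int)
        cost[0, 0] = 0.0
        for kk in range(1, k + 1):
            for j in range(kk, n + 1):
                best, arg = INF, kk - 1
                for i in range(kk - 1, j):
                    c = cost[kk - 1, i] + seg_ss(i, j)
                    if c < best:
                        best, arg = c, i
                cost[kk, j] = best
                split[kk, j] = arg
        # backtrack segment boundaries
        cuts = []
        j = n
        for kk in range(k, 0, -1):
            i = split[kk, j]
            cuts.append(i)
            j = i
        cuts = sorted(cuts[:-1])  # drop the leading 0
        labels_sorted = np.zeros(n, dtype=int)
        for ci, cut in enumerate(cuts, start=1):
            labels_sorted[cut:] = ci
        labels = np.empty(n, dtype=int)
        labels[order] = labels_sorted
        self.labels_ = labels
        self.boundaries_ = np.array([(xs[c - 1] + xs[c]) / 2.0 for c in cuts])
        self.inertia_ = float(cost[k, n])
        return self


def kmeans1d_split(values, k: int = 2) -> tuple[np.ndarray, float]:
    """Exact 1-D k-means labels and (for k=2) the boundary between clusters."""
    model = KMeans1D(n_clusters=k).fit(values)
    boundary = float(model.boundaries_[0]) if k == 2 else model.boundaries_
    return model.labels_, boundary


# ---------------------------------------------------------------------------
# Clinical groupings

def build_groupings(clinical: pd.DataFrame) -> dict[str, pd.Series]:
    """The cohort's standard sample groupings as label Series.

    Binary groupings use labels ``A``/``B`` (A listed first in the
    convention, e.g. T1-T2 = A); tumor location keeps its three levels.
    Age is emitted twice: split at 60 years and by 1-D k-means. Unknown
    values are left out. Missing columns drop the grouping with a warning;
    M stage is never emitted.
    """
    groupings: dict[str, pd.Series] = {}

    def binary(col, a_levels, name):
        if col not in clinical.columns:
            logger.warning("clinical table lacks %r: grouping %s omitted", col, name)
            return
        v = clinical[col]
        lab = pd.Series(np.where(v.isin(a_levels), "A", "B"), index=clinical.index)
        lab[~v.isin(a_levels) & (v.isin(["unknown"]) | v.isna())] = np.nan
        groupings[name] = lab.dropna()

    binary("t_stage", ["T1", "T2"], "t_stage")
    binary("tnm_stage", ["S1", "S2"], "tnm_stage")
    binary("gender", ["male"], "gender")
    binary("n_lymph", ["yes"], "lymph_metastasis")
    binary("smoking", ["yes"], "smoking")
    binary("drinking", ["yes"], "drinking")
    binary("grade", ["G1", "G2"], "grade")

    if "location" in clinical.columns:
        loc = clinical["location"]
        groupings["location"] = loc[loc.isin(["upper", "middle", "lower"])]
    else:
        logger.warning("clinical table lacks 'location': grouping omitted")

    if "age" in clinical.columns:
        age = clinical["age"].dropna()
        groupings["age_60"] = pd.Series(
            np.where(age < 60, "A", "B"), index=age.index
        )
        if np.unique(age).size >= 2:
            labels, boundary = kmeans1d_split(age.to_numpy(), k=2)
            km = pd.Series(np.where(labels == 0, "A", "B"), index=age.index)
            km.attrs = {"boundary": boundary}
            groupings["age_kmeans"] = km
    else:
        logger.warning("clinical table lacks 'age': age groupings omitted")
    return groupings


# ---------------------------------------------------------------------------
# Per-gene tests

def _mutation_status(cohort: Cohort, samples: pd.Index) -> pd.DataFrame:
    """Boolean samples x genes mutation-status matrix."""
    muts = cohort.mutations[cohort.mutations["sample_id"].isin(samples)]
    status = (
        muts.assign(mutated=True)
        .pivot_table(index="sample_id", columns="gene", values="mutated",
                     aggfunc="any", fill_value=False)
        .reindex(samples, fill_value=False)
    )
    return status.astype(bool)


def gene_group_fisher(cohort: Cohort, grouping: pd.Series,
                      min_mutated: int = 3) -> pd.DataFrame:
    """Two-sided Fisher exact test of mutation status vs a binary grouping.

    Genes mutated in fewer than ``min_mutated`` tested samples are skipped.
    Returns per-gene odds ratio, mutation rates per arm, direction, raw p
    and BH FDR across the tested genes.
    """
    lab = grouping[grouping.isin(["A", "B"])]
    n_a, n_b = int((lab == "A").sum()), int((lab == "B").sum())
    if n_a == 0 or n_b == 0:
        raise ValueError("grouping has an empty arm")
    status = _mutation_status(cohort, lab.index)
    rows = []
    a_mask = (lab == "A").to_numpy()
    for gene in status.columns:
        mut = status[gene].to_numpy()
        if mut.sum() < min_mutated:
            continue
        ma = int((mut & a_mask).sum())
        mb = int((mut & ~a_mask).sum())
        table = [[ma, mb], [n_a - ma, n_b - mb]]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        rate_a, rate_b = ma / n_a, mb / n_b
        rows.append({
            "gene": gene, "mut_A": ma, "mut_B": mb, "wild_A": n_a - ma,
            "wild_B": n_b - mb, "rate_A": rate_a, "rate_B": rate_b,
            "odds_ratio": float(odds), "p": float(p),
            "direction": "higher_in_A" if rate_a >= rate_b else "higher_in_B",
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
        out = out.sort_values("p").reset_index(drop=True)
    return out


def gene_numeric_ttest(cohort: Cohort, values: pd.Series,
                       min_mutated: int = 3, min_per_arm: int = 2) -> pd.DataFrame:
    """Welch two-sample t-test of a numeric covariate, mutated vs wild-type.

    Genes whose mutated or wild arm has fewer than ``min_per_arm`` values
    are skipped and flagged.
    """
    vals = values.dropna()
    status = _mutation_status(cohort, vals.index)
    rows = []
    v = vals.to_numpy(float)
    for gene in status.columns:
        mut = status[gene].to_numpy()
        if mut.sum() < min_mutated:
            continue
        x, y = v[mut], v[~mut]
        if len(x) < min_per_arm or len(y) < min_per_arm:
            rows.append({"gene": gene, "n_mut": len(x), "n_wild": len(y),
                         "skipped": True, "t": np.nan, "p": np.nan,
                         "mean_mut": np.nan, "mean_wild": np.nan})
            continue
        t, p = stats.ttest_ind(x, y, equal_var=False)
        rows.append({"gene": gene, "n_mut": len(x), "n_wild": len(y),
                     "skipped": False, "t": float(t), "p": float(p),
                     "mean_mut": float(np.mean(x)), "mean_wild": float(np.mean(y))})
    out = pd.DataFrame(rows)
    tested = out.index[~out["skipped"]] if len(out) else []
    out["fdr"] = np.nan
    if len(tested):
        out.loc[tested, "fdr"] = multipletests(out.loc[tested, "p"], method="fdr_bh")[1]
    return out


def hmg_lmg_classify(lymph_association: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """Classify genes by mutation rate in the lymph-node-metastasis arm.

    Expects the association table of the ``lymph_metastasis`` grouping
    (arm A = metastasis). Genes with p < alpha and a higher mutation rate
    in the metastasis arm are HMG, lower are LMG, everything else none.
    """
    out = pd.Series("none", index=lymph_association["gene"], name="class")
    sig = lymph_association["p"] < alpha
    higher = lymph_association["rate_A"] > lymph_association["rate_B"]
    out[(sig & higher).to_numpy()] = "HMG"
    out[(sig & ~higher).to_numpy()] = "LMG"
    return out


# ---------------------------------------------------------------------------
# Mutual exclusivity / co-occurrence

def pairwise_interactions(cohort: Cohort, top_n: int = 25,
                          alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise co-mutation tests among the ``top_n`` most-mutated genes.

    For each gene pair a two-sided Fisher exact test on the 2x2 joint
    mutation-status table; at p < alpha the pair is classified by odds
    ratio (< 1 mutually exclusive, > 1 co-occurring).
    """
    samples = pd.Index(cohort.sample_ids, name="sample_id")
    status = _mutation_status(cohort, samples)
    freq = status.sum().sort_values(ascending=False)
    genes = list(freq.index[:top_n])
    rows = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            g1, g2 = genes[i], genes[j]
            m1, m2 = status[g1].to_numpy(), status[g2].to_numpy()
            both = int((m1 & m2).sum())
            only1 = int((m1 & ~m2).sum())
            only2 = int((~m1 & m2).sum())
            neither = int((~m1 & ~m2).sum())
            odds, p = stats.fisher_exact([[both, only1], [only2, neither]],
                                         alternative="two-sided")
            if p < alpha:
                cls = "mutually_exclusive" if odds < 1 else "co_occurring"
            else:
                cls = "independent"
            rows.append({"gene1": g1, "gene2": g2, "both": both, "only1": only1,
                         "only2": only2, "neither": neither,
                         "odds_ratio": float(odds), "p": float(p),
                         "classification": cls})
    return pd.DataFrame(rows).sort_values("p").reset_index(drop=True) if rows else pd.DataFrame(
        columns=["gene1", "gene2", "both", "only1", "only2", "neither",
                 "odds_ratio", "p", "classification"])


# ---------------------------------------------------------------------------
# Driver consensus

#: Per-tool significance rules: (statistic column semantics, threshold).
DRIVER_TOOL_THRESHOLDS = {
    "mutsigcv": ("fdr", 0.05),
    "driverml": ("p", 0.01),
    "oncodrivefml": ("fdr", 0.05),
    "oncodriveclustl": ("fdr", 0.05),
}


def driver_consensus(tool_tables: dict[str, pd.DataFrame],
                     min_tools: int = 2) -> pd.DataFrame:
    """Aggregate per-tool driver results into a consensus call.

    ``tool_tables`` maps a tool name to a table with a ``gene`` column and
    a ``p`` or ``fdr`` column; each tool flags genes passing its threshold
    (driverml p < 0.01; the others FDR < 0.05) and a gene is a consensus
    driver when at least ``min_tools`` tools flag it.
    """
    flags: dict[str, dict[str, bool]] = {}
    for tool, table in tool_tables.items():
        key = tool.lower()
        if key not in DRIVER_TOOL_THRESHOLDS:
            raise ValueError(
                f"unknown driver tool {tool!r}; expected one of "
                f"{sorted(DRIVER_TOOL_THRESHOLDS)}"
            )
        stat_col, threshold = DRIVER_TOOL_THRESHOLDS[key]
        if "gene" not in table.columns:
            raise ValueError(f"{tool}: results table lacks a 'gene' column")
        if stat_col not in table.columns:
            raise ValueError(f"{tool}: results table lacks its {stat_col!r} column")
        for _, row in table.iterrows():
            flags.setdefault(row["gene"], {})[key] = bool(row[stat_col] < threshold)
    rows = []
    for gene in sorted(flags):
        support = {t: flags[gene].get(t, False) for t in DRIVER_TOOL_THRESHOLDS}
        n_support = sum(support.values())
        rows.append({"gene": gene, **{f"{t}_hit": v for t, v in support.items()},
                     "n_tools_supporting": n_support,
                     "is_driver": n_support >= min_tools})
    cols = ["gene"] + [f"{t}_hit" for t in DRIVER_TOOL_THRESHOLDS] + [
        "n_tools_supporting", "is_driver"]
    return pd.DataFrame(rows, columns=cols)
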