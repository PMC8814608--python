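"""Neoantigen burden and scoring from MHC-binding prediction tables.

Input is a pVACtools-style per-peptide table: each row is one mutant
peptide with its predicted binding score ``M`` (IC50-like, lower =
stronger), the matched wild-type peptide score ``W`` when one exists
(frameshift products have none) and a binder level (SB strong / WB weak /
NB non-binder, derivable from percent rank). Candidate neoantigens are the
SB and WB peptides. Per sample:

* ``TNB`` (tumor neoantigen burden) — the number of candidate peptides.
* ``AAscore`` — log2(W/M) per peptide; unpaired peptides use a fixed
  wild/mutant ratio of 15, i.e. log2(15).
* ``Gscore`` — sum of AAscores over a gene's candidate peptides.
* ``TNS`` (tumor neoantigen score) — sum of Gscores over genes.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

#: Default percent-rank thresholds for strong / weak binders (NetMHC convention).
SB_RANK = 0.5
WB_RANK = 2.0

#: Default wild/mutant binding ratio imputed for unpaired (frameshift) peptides.
UNPAIRED_RATIO = 15.0

PEPTIDE_COLUMNS = (
    "sample_id", "gene", "mutant_peptide", "wild_peptide",
    "mutant_score", "wild_score", "percent_rank", "bind_level",
)


def read_binding_table(path) -> pd.DataFrame:
    """Read a peptide binding TSV (pVACtools-style export)."""
    tbl = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "gene": str},
                      keep_default_na=True)
    missing = [c for c in ("sample_id", "gene", "mutant_peptide", "mutant_score")
               if c not in tbl.columns]
    if missing:
        raise ValueError(f"binding table missing column(s): {missing}")
    for c in PEPTIDE_COLUMNS:
        if c not in tbl.columns:
            tbl[c] = np.nan
    return tbl


def bind_level_from_rank(percent_rank: float, sb_rank: float = SB_RANK,
                         wb_rank: float = WB_RANK) -> str:
    if percent_rank <= sb_rank:
        return "SB"
    if percent_rank <= wb_rank:
        return "WB"
    return "NB"


def filter_candidates(peptides: pd.DataFrame, sb_rank: float = SB_RANK,
                      wb_rank: float = WB_RANK) -> pd.DataFrame:
    """Keep SB and WB peptides (the candidate neoantigens).

    ``bind_level`` is used where present and otherwise derived from
    ``percent_rank``; records with neither raise, listing the offenders.
    """
    pep = peptides.copy()
    level = pep["bind_level"].astype("string")
    no_level = level.isna() | ~level.isin(["SB", "WB", "NB"])
    has_rank = pep["percent_rank"].notna()
    derivable = no_level & has_rank
    if derivable.any():
        level.loc[derivable] = pd.Series(
            [bind_level_from_rank(r, sb_rank, wb_rank)
             for r in pep.loc[derivable, "percent_rank"]],
            index=pep.index[derivable], dtype="string",
        )
    bad = no_level & ~has_rank
    if bad.any():
        raise ValueError(
            "records with neither bind_level nor percent_rank at rows: "
            f"{list(pep.index[bad])}"
        )
    pep["bind_level"] = level.astype(str)
    return pep[pep["bind_level"].isin(["SB", "WB"])].copy()


def aascore(wild_score: float | None, mutant_score: float,
            unpaired_ratio: float = UNPAIRED_RATIO,
            unpaired_mode: str = "log_ratio") -> float:
    """Binding-improvement score of one mutant peptide.

    ``log2(W/M)`` when a wild-type partner exists. Unpaired peptides (e.g.
    frameshift products) default to ``log2(unpaired_ratio)``; with
    ``unpaired_mode="literal15"`` the raw ratio value itself is returned,
    the alternative reading of the imputation rule.
    """
    if mutant_score is None or not mutant_score > 0:
        raise ValueError(f"mutant binding score must be > 0, got {mutant_score!r}")
    unpaired = wild_score is None or (isinstance(wild_score, float) and math.isnan(wild_score))
    if unpaired:
        if unpaired_mode == "literal15":
            return float(unpaired_ratio)
        return math.log2(unpaired_ratio)
    if not wild_score > 0:
        raise ValueError(f"wild-type binding score must be > 0, got {wild_score!r}")
    return math.log2(wild_score / mutant_score)


def gscore(candidates: pd.DataFrame, **aascore_kwargs) -> float:
    """Sum of AAscores over one gene's candidate peptides in one sample."""
    return float(sum(
        aascore(row.wild_score, row.mutant_score, **aascore_kwargs)
        for row in candidates.itertuples(index=False)
    ))


def sample_scores(peptides: pd.DataFrame, sb_rank: float = SB_RANK,
                  wb_rank: float = WB_RANK, **aascore_kwargs) -> pd.DataFrame:
    """Per-sample TNB and TNS from a (possibly unfiltered) peptide table.

    Returns a DataFrame indexed by sample_id with columns ``TNB`` (candidate
    count) and ``TNS`` (sum over genes of the Gscore, equivalently the sum
    of AAscores over all candidate peptides).
    """
    cand = filter_candidates(peptides, sb_rank, wb_rank)
    if cand.empty:
        samples = pd.Index(sorted(peptides["sample_id"].unique()), name="sample_id")
        return pd.DataFrame({"TNB": 0, "TNS": 0.0}, index=samples)
    cand = cand.assign(
        aascore=[
            aascore(row.wild_score, row.mutant_score, **aascore_kwargs)
            for row in cand.itertuples(index=False)
        ]
    )
    out = cand.groupby("sample_id").agg(TNB=("aascore", "size"), TNS=("aascore", "sum"))
    missing = set(peptides["sample_id"].unique()) - set(out.index)
    if missing:
        pad = pd.DataFrame({"TNB": 0, "TNS": 0.0}, index=sorted(missing))
        out = pd.concat([out, pad]).sort_index()
    out.index.name = "sample_id"
    out["TNB"] = out["TNB"].astype(int)
    return out


def gene_scores(peptides: pd.DataFrame, sb_rank: float = SB_RANK,
                wb_rank: float = WB_RANK, **aascore_kwargs) -> pd.DataFrame:
    """Per (sample, gene) Gscore table for the candidate peptides."""
    cand = filter_candidates(peptides, sb_rank, wb_rank)
    if cand.empty:
        return pd.DataFrame(columns=["sample_id", "gene", "Gscore", "n_peptides"])
    cand = cand.assign(
        aascore=[
            aascore(row.wild_score, row.mutant_score, **aascore_kwargs)
            for row in cand.itertuples(index=False)
        ]
    )
    out = (cand.groupby(["sample_id", "gene"])["aascore"]
           .agg(Gscore="sum", n_peptides="size").reset_index())
    out["n_peptides"] = out["n_peptides"].astype(int)
    return out


def sharing_spectrum(candidates: pd.DataFrame) -> pd.DataFrame:
    """How many patients share each distinct candidate peptide.

    Groups distinct mutant-peptide strings by the number of patients
    carrying them. Returns a DataFrame indexed by patient multiplicity with
    ``n_peptides`` and ``fraction`` columns (fractions sum to 1). Peptide
    identity ignores the HLA allele.
    """
    if candidates.empty:
        return pd.DataFrame(columns=["n_peptides", "fraction"],
                            index=pd.Index([], name="n_patients"))
    per_pep = candidates.groupby("mutant_peptide")["sample_id"].nunique()
    spec = per_pep.value_counts().sort_index()
    out = pd.DataFrame({"n_peptides": spec})
    out["fraction"] = out["n_peptides"] / out["n_peptides"].sum()
    out.index.name = "n_patients"
    return out
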