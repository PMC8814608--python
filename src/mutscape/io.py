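"""Reading, validating and merging MAF-format mutation tables and clinical tables.

A cohort is represented by two pandas DataFrames: a long-format mutation
table (one row per somatic variant call) and a clinical table indexed by
sample. Multiple cohorts are merged into a single analysis-ready
:class:`Cohort` with cross-cohort sample-identity checks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

#: Columns required in every input MAF (GDC v1.0 names).
REQUIRED_MAF_COLUMNS = (
    "Hugo_Symbol",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Classification",
    "Variant_Type",
    "Tumor_Sample_Barcode",
)

#: Optional flanking-context columns (reference bases 5' / 3' of the variant).
CONTEXT_COLUMNS = ("Context_5prime", "Context_3prime")

VARIANT_TYPES = ("SNP", "DNP", "INS", "DEL")

#: GDC Variant_Classification values -> internal variant-class vocabulary.
CLASSIFICATION_MAP = {
    "Missense_Mutation": "missense",
    "Nonsense_Mutation": "nonsense",
    "Silent": "silent",
    "Splice_Site": "splice_site",
    "Frame_Shift_Ins": "frame_shift_ins",
    "Frame_Shift_Del": "frame_shift_del",
    "In_Frame_Ins": "in_frame_ins",
    "In_Frame_Del": "in_frame_del",
}

#: Variant classes counted as coding (enter TMB denominators).
CODING_CLASSES = frozenset(
    {
        "missense",
        "nonsense",
        "silent",
        "splice_site",
        "frame_shift_ins",
        "frame_shift_del",
        "in_frame_ins",
        "in_frame_del",
        "other",
    }
)

#: Nonsynonymous = every coding class except silent (splice sites included).
NONSYNONYMOUS_CLASSES = frozenset(CODING_CLASSES - {"silent"})

CLINICAL_VOCABULARIES = {
    "gender": {"male", "female"},
    "smoking": {"yes", "no"},
    "drinking": {"yes", "no"},
    "t_stage": {"T1", "T2", "T3", "T4"},
    "n_lymph": {"yes", "no"},
    "tnm_stage": {"S1", "S2", "S3", "S4"},
    "grade": {"G1", "G2", "G3", "G4"},
    "location": {"upper", "middle", "lower"},
}

_YES = {"yes", "y", "true", "1", "positive", "pos"}
_NO = {"no", "n", "false", "0", "negative", "neg"}


class MafFormatError(ValueError):
    """Raised when a MAF or clinical file violates its format contract."""


@dataclass
class Cohort:
    """A merged, analysis-ready cohort.

    Attributes
    ----------
    mutations : pandas.DataFrame
        Long-format mutation table with internal column names
        (``sample_id, cohort, gene, chrom, pos, ref_allele, alt_allele,
        variant_type, variant_class, protein_change, context5, context3``).
    clinical : pandas.DataFrame
        One row per sample, indexed by ``sample_id``.
    """

    mutations: pd.DataFrame
    clinical: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def sample_ids(self) -> list[str]:
        muts = set(self.mutations["sample_id"].unique())
        if len(self.clinical):
            muts |= set(self.clinical.index)
        return sorted(muts)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def mutations_of(self, sample_id: str) -> pd.DataFrame:
        return self.mutations[self.mutations["sample_id"] == sample_id]


_INTERNAL_FROM_MAF = {
    "Hugo_Symbol": "gene",
    "Chromosome": "chrom",
    "Start_Position": "pos",
    "Reference_Allele": "ref_allele",
    "Tumor_Seq_Allele2": "alt_allele",
    "Variant_Classification": "variant_class",
    "Variant_Type": "variant_type",
    "Tumor_Sample_Barcode": "sample_id",
    "Protein_Change": "protein_change",
    "HGVSp_Short": "protein_change",
    "Context_5prime": "context5",
    "Context_3prime": "context3",
}


def read_maf(path: str | Path, cohort_label: str = "cohort") -> pd.DataFrame:
    """Read a tab-separated MAF file into the internal mutation-table layout.

    Unknown ``Variant_Classification`` values are mapped to ``"other"`` with a
    warning; duplicate identical records are dropped. Comment lines starting
    with ``#`` are ignored.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise MafFormatError(f"{path}: empty MAF file") from exc
    missing = [c for c in REQUIRED_MAF_COLUMNS if c not in raw.columns]
    if missing:
        raise MafFormatError(f"{path}: missing required MAF column(s): {', '.join(missing)}")
    if raw.empty:
        raise MafFormatError(f"{path}: MAF has a header but no records")

    cols = {}
    for maf_col, internal in _INTERNAL_FROM_MAF.items():
        if maf_col in raw.columns and internal not in cols:
            cols[internal] = raw[maf_col]
    tbl = pd.DataFrame(cols)
    for optional in ("protein_change", "context5", "context3"):
        if optional not in tbl.columns:
            tbl[optional] = ""

    tbl["pos"] = pd.to_numeric(tbl["pos"], errors="raise").astype(int)
    if (tbl["pos"] < 1).any():
        raise MafFormatError(f"{path}: Start_Position must be >= 1 (1-based MAF coordinates)")

    unknown = ~tbl["variant_class"].isin(CLASSIFICATION_MAP)
    if unknown.any():
        labels = sorted(tbl.loc[unknown, "variant_class"].unique())
        warnings.warn(
            f"{path}: {int(unknown.sum())} record(s) with unmapped "
            f"Variant_Classification {labels} mapped to 'other'",
            stacklevel=2,
        )
    tbl["variant_class"] = tbl["variant_class"].map(CLASSIFICATION_MAP).fillna("other")

    bad_type = ~tbl["variant_type"].isin(VARIANT_TYPES)
    if bad_type.any():
        # TNP and longer ONP records are rare; fold them into DNP-like handling
        # only when two bases actually change, otherwise drop to 'SNP' semantics
        # is unsafe — keep the verbatim type and let catalog builders skip them.
        logger.info("%s: %d record(s) with non-standard Variant_Type kept verbatim", path, int(bad_type.sum()))

    # MAF insertion convention: Reference_Allele "-" ; normalize empties to "-"
    tbl.loc[tbl["variant_type"] == "INS", "ref_allele"] = (
        tbl.loc[tbl["variant_type"] == "INS", "ref_allele"].replace("", "-")
    )
    tbl.loc[tbl["variant_type"] == "DEL", "alt_allele"] = (
        tbl.loc[tbl["variant_type"] == "DEL", "alt_allele"].replace("", "-")
    )

    snp = tbl["variant_type"] == "SNP"
    if (tbl.loc[snp, "ref_allele"] == tbl.loc[snp, "alt_allele"]).any():
        raise MafFormatError(f"{path}: SNP record with identical ref and alt allele")

    tbl.insert(1, "cohort", cohort_label)
    before = len(tbl)
    tbl = tbl.drop_duplicates().reset_index(drop=True)
    if len(tbl) < before:
        logger.info("%s: dropped %d duplicate record(s)", path, before - len(tbl))
    order = [
        "sample_id", "cohort", "gene", "chrom", "pos", "ref_allele", "alt_allele",
        "variant_type", "variant_class", "protein_change", "context5", "context3",
    ]
    return tbl[order]


_MAF_FROM_INTERNAL = {
    "gene": "Hugo_Symbol",
    "chrom": "Chromosome",
    "pos": "Start_Position",
    "ref_allele": "Reference_Allele",
    "alt_allele": "Tumor_Seq_Allele2",
    "variant_class": "Variant_Classification",
    "variant_type": "Variant_Type",
    "sample_id": "Tumor_Sample_Barcode",
    "protein_change": "Protein_Change",
    "context5": "Context_5prime",
    "context3": "Context_3prime",
}

_CLASS_TO_MAF = {v: k for k, v in CLASSIFICATION_MAP.items()}


def write_maf(mutations: pd.DataFrame, path: str | Path) -> None:
    """Write an internal mutation table back to GDC-style MAF columns."""
    out = mutations.rename(columns=_MAF_FROM_INTERNAL)
    out["Variant_Classification"] = (
        mutations["variant_class"].map(_CLASS_TO_MAF).fillna("Other").values
    )
    cols = [c for c in _MAF_FROM_INTERNAL.values() if c in out.columns]
    out[cols].to_csv(path, sep="\t", index=False)


def _norm_yesno(value: str) -> str:
    v = str(value).strip().lower()
    if v in _YES:
        return "yes"
    if v in _NO:
        return "no"
    return "unknown"


def _norm_level(value: str, prefix: str, levels: set[str]) -> str:
    v = str(value).strip().upper().replace(" ", "")
    if not v or v in {"NA", "NAN", "NONE", "UNKNOWN", "UNK", "."}:
        return "unknown"
    if not v.startswith(prefix):
        v = prefix + v
    return v if v in levels else "unknown"


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a clinical TSV, normalising vocabularies; unparseable cells -> unknown.

    Requires a ``sample_id`` column; duplicate sample ids are an error.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sample_id" not in raw.columns:
        raise MafFormatError(f"{path}: clinical table lacks a 'sample_id' column")
    dupes = raw["sample_id"][raw["sample_id"].duplicated()].unique().tolist()
    if dupes:
        raise MafFormatError(f"{path}: duplicate sample_id(s) in clinical table: {dupes}")
    return normalize_clinical(raw)


def normalize_clinical(raw: pd.DataFrame) -> pd.DataFrame:
    """Vocabulary-normalise an in-memory clinical table (see :func:`read_clinical`)."""
    out = pd.DataFrame(index=pd.Index(raw["sample_id"].astype(str), name="sample_id"))
    if "age" in raw.columns:
        out["age"] = pd.to_numeric(raw["age"].values, errors="coerce")
    if "gender" in raw.columns:
        g = raw["gender"].astype(str).str.strip().str.lower()
        out["gender"] = g.where(g.isin(CLINICAL_VOCABULARIES["gender"]), "unknown").values
    for col in ("smoking", "drinking", "n_lymph"):
        if col in raw.columns:
            out[col] = [_norm_yesno(v) for v in raw[col]]
    for col, prefix in (("t_stage", "T"), ("tnm_stage", "S"), ("grade", "G")):
        if col in raw.columns:
            levels = CLINICAL_VOCABULARIES[col]
            out[col] = [_norm_level(v, prefix, levels) for v in raw[col]]
    if "location" in raw.columns:
        loc = raw["location"].astype(str).str.strip().str.lower()
        out["location"] = loc.where(loc.isin(CLINICAL_VOCABULARIES["location"]), "unknown").values
    if "os_time" in raw.columns:
        out["os_time"] = pd.to_numeric(raw["os_time"].values, errors="coerce")
        if (out["os_time"].dropna() < 0).any():
            raise MafFormatError("clinical table: os_time must be >= 0")
    if "os_event" in raw.columns:
        ev = pd.Series(pd.to_numeric(raw["os_event"].values, errors="coerce"))
        if not ev.dropna().isin([0, 1]).all():
            raise MafFormatError("clinical table: os_event must be 0/1")
        out["os_event"] = ev.values
    return out


def merge_cohorts(
    mutation_tables: list[pd.DataFrame],
    clinical_tables: list[pd.DataFrame] | None = None,
) -> Cohort:
    """Concatenate per-cohort tables into one :class:`Cohort`.

    The same sample id appearing in two different cohorts is an identity
    collision and raises; within a cohort, mutation and clinical rows are
    simply pooled.
    """
    if not mutation_tables:
        raise ValueError("merge_cohorts requires at least one mutation table")
    labels = [t["cohort"].iloc[0] for t in mutation_tables if len(t)]
    if len(labels) != len(set(labels)):
        raise ValueError("cohort labels must be distinct across mutation tables")
    per_cohort = {}
    for t in mutation_tables:
        for label, samples in t.groupby("cohort")["sample_id"]:
            per_cohort.setdefault(label, set()).update(samples)
    seen: dict[str, str] = {}
    for label, samples in per_cohort.items():
        for s in samples:
            if s in seen and seen[s] != label:
                raise ValueError(
                    f"sample_id {s!r} appears in cohorts {seen[s]!r} and {label!r}"
                )
            seen[s] = label
    mutations = pd.concat(mutation_tables, ignore_index=True)
    if clinical_tables:
        clin = pd.concat(clinical_tables)
        dup = clin.index[clin.index.duplicated()].unique().tolist()
        if dup:
            raise ValueError(f"duplicate sample_id(s) across clinical tables: {dup}")
    else:
        clin = pd.DataFrame(index=pd.Index([], name="sample_id"))
    orphans = set(mutations["sample_id"]) - set(clin.index) if len(clin) else set()
    if orphans and len(clin):
        logger.warning("%d mutated sample(s) missing from clinical table", len(orphans))
    return Cohort(mutations=mutations, clinical=clin)
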