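"""Synthetic cohort generator with known ground truth.

Produces download-free inputs with the statistical structure the analysis
modules assume: somatic mutations drawn from known signature mixtures with
flanking sequence context (written as MAF), clinically structured
covariates with survival times from an exponential model, and
neoantigen-binding tables with wild-type-paired missense peptides and
unpaired frameshift peptides. Every latent quantity (true signature of
each mutation, planted HMG/LMG genes, the survival hazard threshold,
planted shared peptides) is returned in a truth record so recovery tests
can score the pipeline against it.

Default scales echo an esophageal squamous-cell carcinoma exome cohort:
overdispersed per-sample mutation counts with a median around 108 coding
mutations (median aTMB near 3.6/Mb), roughly a quarter synonymous, a small
indel fraction, male-skewed demographics, and smoking-dependent lymph-node
metastasis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .io import Cohort, normalize_clinical
from .signatures import SBS96_CHANNELS, _COMPLEMENT

_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Recurrently mutated genes used at the head of the synthetic gene pool.
_KNOWN_GENES = [
    "TP53", "TTN", "MUC16", "NOTCH1", "KMT2D", "CDKN2A", "ZNF750", "NFE2L2",
    "PIK3CA", "RB1", "FAT1", "EP300", "FBXW7", "AP3S1", "RPS15", "FSIP2",
    "FAT2", "PTEN", "CUL3", "CREBBP",
]


def default_signatures() -> pd.DataFrame:
    """Two disjoint-support SBS-96 ground-truth signatures.

    ``SigA`` lives on the 16 C>A channels and ``SigB`` on the 16 T>C
    channels, with non-uniform context weights, so recovered signatures can
    be matched to truth unambiguously.
    """
    sig = pd.DataFrame(0.0, index=list(SBS96_CHANNELS), columns=["SigA", "SigB"])
    ca = [c for c in SBS96_CHANNELS if "[C>A]" in c]
    tc = [c for c in SBS96_CHANNELS if "[T>C]" in c]
    wa = np.arange(1, len(ca) + 1, dtype=float)
    wb = np.arange(len(tc), 0, -1, dtype=float)
    sig.loc[ca, "SigA"] = wa / wa.sum()
    sig.loc[tc, "SigB"] = wb / wb.sum()
    return sig


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults are the study conditions."""

    n_samples: int = 120
    seed: int = 0
    # mutation load: negative binomial (overdispersed, like real TMB)
    mean_mutations: float = 120.0
    dispersion: float = 3.0
    silent_fraction: float = 0.24
    indel_fraction: float = 0.08
    frameshift_fraction: float = 0.7
    # signature mixture; None -> default_signatures()
    signature_weights_alpha: tuple = (1.0, 1.0)
    # gene-level planted clinical effects: gene -> (p_met, p_nonmet)
    hmg_genes: dict = field(default_factory=lambda: {
        "ZNF750": (0.35, 0.10), "NOTCH1": (0.30, 0.10)})
    lmg_genes: dict = field(default_factory=lambda: {"CREBBP": (0.05, 0.25)})
    n_background_genes: int = 60
    # clinical marginals
    male_fraction: float = 0.8
    smoking_fraction: float = 0.55
    drinking_given_smoking: float = 0.75
    drinking_given_nonsmoking: float = 0.40
    lymph_given_smoking: float = 0.63
    lymph_given_nonsmoking: float = 0.43
    # survival: exponential baseline, administrative censoring
    baseline_hazard: float = np.log(2) / 730.0  # median OS two years
    lymph_hazard_ratio: float = 1.8
    burden_hazard_ratio: float = 1.0
    burden_threshold_quantile: float = 0.6
    censoring_horizon: float = 1825.0  # five years
    # neoantigen model
    candidate_rate: float = 0.35  # peptides per nonsynonymous mutation
    shared_peptide_patients: int = 3

    def __post_init__(self):
        for name in ("silent_fraction", "indel_fraction", "frameshift_fraction",
                     "male_fraction", "smoking_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("hmg_genes", "lmg_genes"):
            if key in data:
                data[key] = {g: tuple(v) for g, v in data[key].items()}
        if "signature_weights_alpha" in data:
            data["signature_weights_alpha"] = tuple(data["signature_weights_alpha"])
        return cls(**data)


def _random_flank(rng, length=2) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _channel_to_variant(channel: str, rng) -> tuple[str, str, str, str]:
    """Ref/alt/flanks realising an SBS-96 channel, on a random strand."""
    five, rest = channel[0], channel[2:]
    ref, alt, three = rest[0], rest[2], rest[4]
    c5 = _random_flank(rng, 1) + five
    c3 = three + _random_flank(rng, 1)
    if rng.random() < 0.5:  # report on the purine strand half the time
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        c5, c3 = ("".join(_COMPLEMENT[b] for b in reversed(c3)),
                  "".join(_COMPLEMENT[b] for b in reversed(c5)))
    return ref, alt, c5, c3


def simulate_cohort(config: SimulationConfig,
                    signatures: pd.DataFrame | None = None):
    """Generate one synthetic cohort.

    Returns ``(maf, clinical, truth)``: a GDC-style MAF DataFrame with
    flanking-context columns, a raw clinical table (TSV layout, one row per
    sample) and a truth dict with every latent quantity.
    """
    rng = np.random.default_rng(config.seed)
    if signatures is None:
        signatures = default_signatures()
    sig_probs = signatures.to_numpy(float).T  # k x channels
    sig_names = list(signatures.columns)
    channels = list(signatures.index)
    if not np.allclose(sig_probs.sum(axis=1), 1.0):
        raise ValueError("signature channel distributions must each sum to 1")

    samples = [f"S{i + 1:04d}" for i in range(config.n_samples)]
    # planted genes are governed solely by their per-group probabilities, so
    # they are kept out of the background pool
    planted_names = set(config.hmg_genes) | set(config.lmg_genes)
    genes = [g for g in _KNOWN_GENES if g not in planted_names]
    genes += [f"GENE{i:03d}" for i in range(1, config.n_background_genes + 1)]
    gene_w = 1.0 / np.arange(2, len(genes) + 2)
    gene_w /= gene_w.sum()

    # --- clinical covariates ------------------------------------------------
    age = np.clip(rng.normal(60, 9, config.n_samples).round(), 30, 88).astype(int)
    gender = np.where(rng.random(config.n_samples) < config.male_fraction, "male", "female")
    smoking = rng.random(config.n_samples) < config.smoking_fraction
    p_drink = np.where(smoking, config.drinking_given_smoking, config.drinking_given_nonsmoking)
    drinking = rng.random(config.n_samples) < p_drink
    p_lymph = np.where(smoking, config.lymph_given_smoking, config.lymph_given_nonsmoking)
    lymph = rng.random(config.n_samples) < p_lymph
    t_stage = rng.choice(["T1", "T2", "T3", "T4"], config.n_samples, p=[0.1, 0.3, 0.45, 0.15])
    tnm = rng.choice(["S1", "S2", "S3", "S4"], config.n_samples, p=[0.15, 0.35, 0.4, 0.1])
    grade = rng.choice(["G1", "G2", "G3", "G4"], config.n_samples, p=[0.15, 0.5, 0.3, 0.05])
    location = rng.choice(["upper", "middle", "lower"], config.n_samples, p=[0.15, 0.5, 0.35])

    # --- mutations ----------------------------------------------------------
    p_nb = config.dispersion / (config.dispersion + config.mean_mutations)
    counts = rng.negative_binomial(config.dispersion, p_nb, config.n_samples)
    mixture = rng.dirichlet(config.signature_weights_alpha, config.n_samples)

    rows = []
    mut_signature = []  # truth: generating signature per MAF row ("" = indel)
    for si, sample in enumerate(samples):
        n_mut = int(counts[si])
        for _ in range(n_mut):
            gene = genes[rng.choice(len(genes), p=gene_w)]
            chrom = str(rng.integers(1, 23))
            pos = int(rng.integers(1, 1_000_000))
            if rng.random() < config.indel_fraction:
                is_del = rng.random() < 0.5
                frameshift = rng.random() < config.frameshift_fraction
                length = int(rng.integers(1, 3)) if frameshift else 3
                seq = "".join(rng.choice(list("ACGT"), size=length))
                c5, c3 = _random_flank(rng, 5), _random_flank(rng, 5)
                if is_del:
                    vt, ref, alt = "DEL", seq, "-"
                    vc = "Frame_Shift_Del" if frameshift else "In_Frame_Del"
                else:
                    vt, ref, alt = "INS", "-", seq
                    vc = "Frame_Shift_Ins" if frameshift else "In_Frame_Ins"
                mut_signature.append("")
            else:
                k = rng.choice(len(sig_names), p=mixture[si])
                ch = channels[rng.choice(len(channels), p=sig_probs[k])]
                ref, alt, c5, c3 = _channel_to_variant(ch, rng)
                vt = "SNP"
                if rng.random() < config.silent_fraction:
                    vc = "Silent"
                else:
                    vc = rng.choice(["Missense_Mutation", "Nonsense_Mutation", "Splice_Site"],
                                    p=[0.85, 0.10, 0.05])
                mut_signature.append(sig_names[k])
            rows.append((gene, chrom, pos, ref, alt, vc, vt, sample, c5, c3))

    # planted group-dependent genes (one extra missense per hit)
    planted = {"HMG": sorted(config.hmg_genes), "LMG": sorted(config.lmg_genes)}
    for gene, (p_met, p_non) in {**config.hmg_genes, **config.lmg_genes}.items():
        for si, sample in enumerate(samples):
            p = p_met if lymph[si] else p_non
            if rng.random() < p:
                ref, alt, c5, c3 = _channel_to_variant(
                    channels[rng.choice(len(channels))], rng)
                rows.append((gene, "1", int(rng.integers(1, 1_000_000)), ref, alt,
                             "Missense_Mutation", "SNP", sample, c5, c3))
                mut_signature.append("planted")

    maf = pd.DataFrame(rows, columns=[
        "Hugo_Symbol", "Chromosome", "Start_Position", "Reference_Allele",
        "Tumor_Seq_Allele2", "Variant_Classification", "Variant_Type",
        "Tumor_Sample_Barcode", "Context_5prime", "Context_3prime"])

    # --- survival -----------------------------------------------------------
    burden = maf.groupby("Tumor_Sample_Barcode").size().reindex(samples, fill_value=0)
    threshold = float(np.quantile(burden, config.burden_threshold_quantile))
    high_burden = burden.to_numpy() > threshold
    hazard = config.baseline_hazard * np.where(lymph, config.lymph_hazard_ratio, 1.0)
    hazard = hazard * np.where(high_burden, config.burden_hazard_ratio, 1.0)
    latent = rng.exponential(1.0 / hazard)
    os_time = np.minimum(latent, config.censoring_horizon)
    os_event = (latent <= config.censoring_horizon).astype(int)
    os_time = np.maximum(os_time.round(), 1).astype(int)

    clinical = pd.DataFrame({
        "sample_id": samples,
        "age": age,
        "gender": gender,
        "smoking": np.where(smoking, "yes", "no"),
        "drinking": np.where(drinking, "yes", "no"),
        "t_stage": t_stage,
        "n_lymph": np.where(lymph, "yes", "no"),
        "tnm_stage": tnm,
        "grade": grade,
        "location": location,
        "os_time": os_time,
        "os_event": os_event,
    })

    truth = {
        "seed": config.seed,
        "signatures": signatures,
        "mixture_weights": pd.DataFrame(mixture, index=samples, columns=sig_names),
        "mutation_signature": mut_signature,
        "planted_genes": planted,
        "hmg_probs": dict(config.hmg_genes),
        "lmg_probs": dict(config.lmg_genes),
        "burden_threshold": threshold,
        "burden_hazard_ratio": config.burden_hazard_ratio,
        "lymph_hazard_ratio": config.lymph_hazard_ratio,
        "config": asdict(config),
    }
    return maf, clinical, truth


def simulate_binding_table(config: SimulationConfig, cohort: Cohort,
                           seed_offset: int = 1):
    """Peptide binding table for a cohort's nonsynonymous mutations.

    Each nonsynonymous mutation yields a Poisson number of candidate
    peptides; percent ranks drive the SB/WB/NB level, missense peptides get
    a matched wild-type partner, frameshift products are unpaired, and one
    planted peptide is shared across ``shared_peptide_patients`` samples.
    Returns ``(table, truth)``.
    """
    rng = np.random.default_rng(config.seed + seed_offset)
    muts = cohort.mutations
    nonsyn = muts[(muts["variant_class"] != "silent")
                  & muts["variant_class"].isin(
                      ["missense", "nonsense", "splice_site", "frame_shift_ins",
                       "frame_shift_del", "in_frame_ins", "in_frame_del"])]
    if nonsyn.empty:
        import warnings
        warnings.warn("cohort has no nonsynonymous mutations: empty binding table",
                      stacklevel=2)
        return pd.DataFrame(columns=["sample_id", "gene", "mutant_peptide",
                                     "wild_peptide", "mutant_score", "wild_score",
                                     "percent_rank", "bind_level"]), {}
    rows = []
    for row in nonsyn.itertuples(index=False):
        n_pep = rng.poisson(config.candidate_rate)
        frameshift = row.variant_class in ("frame_shift_ins", "frame_shift_del")
        for _ in range(n_pep):
            pep = "".join(rng.choice(list(_AA), size=9))
            rank = float(np.exp(rng.normal(np.log(1.5), 1.1)))
            level = "SB" if rank <= 0.5 else ("WB" if rank <= 2.0 else "NB")
            m_score = float(np.exp(rng.normal(np.log(300), 1.0)))
            if frameshift:
                wild_pep, w_score = "", np.nan
            else:
                wild_pep = pep[:4] + rng.choice(list(_AA)) + pep[5:]
                w_score = float(m_score * 2 ** rng.normal(0.8, 1.0))
            rows.append((row.sample_id, row.gene, pep, wild_pep, m_score,
                         w_score, round(rank, 4), level))
    table = pd.DataFrame(rows, columns=[
        "sample_id", "gene", "mutant_peptide", "wild_peptide", "mutant_score",
        "wild_score", "percent_rank", "bind_level"])

    shared_pep, shared_samples = "", []
    all_samples = sorted(set(cohort.mutations["sample_id"]))
    k = min(config.shared_peptide_patients, len(all_samples))
    if k >= 2:
        shared_pep = "".join(rng.choice(list(_AA), size=9))
        shared_samples = list(rng.choice(all_samples, size=k, replace=False))
        for s in shared_samples:
            rows_s = pd.DataFrame([{
                "sample_id": s, "gene": "TP53", "mutant_peptide": shared_pep,
                "wild_peptide": shared_pep[:4] + "A" + shared_pep[5:],
                "mutant_score": 50.0, "wild_score": 500.0,
                "percent_rank": 0.2, "bind_level": "SB"}])
            table = pd.concat([table, rows_s], ignore_index=True)
    truth = {"shared_peptide": shared_pep, "shared_samples": shared_samples,
             "candidate_rate": config.candidate_rate}
    return table, truth


def cohort_from_simulation(maf: pd.DataFrame, clinical: pd.DataFrame,
                           label: str = "synthetic") -> Cohort:
    """Wrap simulator output into an analysis-ready :class:`Cohort`."""
    muts = maf.rename(columns={
        "Hugo_Symbol": "gene", "Chromosome": "chrom", "Start_Position": "pos",
        "Reference_Allele": "ref_allele", "Tumor_Seq_Allele2": "alt_allele",
        "Variant_Classification": "variant_class", "Variant_Type": "variant_type",
        "Tumor_Sample_Barcode": "sample_id", "Context_5prime": "context5",
        "Context_3prime": "context3"})
    from .io import CLASSIFICATION_MAP
    muts["variant_class"] = muts["variant_class"].map(CLASSIFICATION_MAP).fillna("other")
    muts.insert(1, "cohort", label)
    muts["protein_change"] = ""
    return Cohort(mutations=muts, clinical=normalize_clinical(clinical))
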