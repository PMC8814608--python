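"""End-to-end orchestration: ingest -> signatures -> burden -> neoantigen ->
survival -> associations, driven by a single run configuration.

Each stage writes plain TSV/JSON files into the output directory plus a
manifest recording the package version, seed and parameters, so a rerun
with the same configuration reproduces identical analytic outputs
(timestamps are deliberately excluded).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .io import read_maf, read_clinical, merge_cohorts, Cohort
from .burden import compute_burden, burden_concordance
from .neoantigen import read_binding_table, filter_candidates, sample_scores, \
    gene_scores, sharing_spectrum
from .signatures import build_catalog, extract_signatures, select_k, \
    signature_clinical_tests
from .survival import optimal_cutpoint
from .associations import build_groupings, gene_group_fisher, hmg_lmg_classify, \
    pairwise_interactions, driver_consensus

logger = logging.getLogger(__name__)

ALL_STAGES = ("ingest", "signatures", "burden", "neoantigen", "survival", "associations")


class PipelineError(RuntimeError):
    """A stage could not run; the message names the stage and the cause."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run (see the YAML schema in the docs)."""

    maf: list[str] = field(default_factory=list)
    clinical: str | None = None
    binding: str | None = None
    driver_tables: dict[str, str] = field(default_factory=dict)
    outdir: str = "mutscape_out"
    seed: int = 17
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    signature_kind: str = "SBS96"
    n_signatures: int | str = "auto"
    k_range: list[int] = field(default_factory=lambda: [1, 2, 3, 4])
    n_restarts: int = 20
    sb_rank: float = 0.5
    wb_rank: float = 2.0
    unpaired_mode: str = "log_ratio"
    minprop: float = 0.1
    alpha: float = 0.05
    min_mutated: int = 3
    top_n_interactions: int = 25

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _write_tsv(df: pd.DataFrame, path: Path, index=True):
    df.to_csv(path, sep="\t", index=index)


def run_pipeline(config: RunConfig, cohort: Cohort | None = None) -> dict:
    """Execute the enabled stages in dependency order.

    ``cohort`` may be supplied directly (e.g. from the simulator); otherwise
    the ``maf``/``clinical`` paths in the config are ingested. Returns a
    results dict mirroring what was written to ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    manifest = {"package": "mutscape", "version": __version__,
                "seed": config.seed, "stages": [], "parameters": asdict(config)}

    # --- ingest -------------------------------------------------------------
    if cohort is None:
        if "ingest" not in config.stages:
            raise PipelineError("ingest: stage disabled but no in-memory cohort supplied")
        if not config.maf:
            raise PipelineError("ingest: no MAF inputs configured")
        tables = [read_maf(p, cohort_label=f"cohort{i + 1}")
                  for i, p in enumerate(config.maf)]
        clin = [read_clinical(config.clinical)] if config.clinical else None
        cohort = merge_cohorts(tables, clin)
    results["cohort"] = cohort
    _write_tsv(cohort.mutations, outdir / "mutations.tsv", index=False)
    if len(cohort.clinical):
        _write_tsv(cohort.clinical, outdir / "clinical.tsv")
    manifest["stages"].append("ingest")
    manifest["n_samples"] = cohort.n_samples
    manifest["n_mutations"] = int(len(cohort.mutations))

    groupings = build_groupings(cohort.clinical) if len(cohort.clinical) else {}

    # --- signatures ---------------------------------------------------------
    if "signatures" in config.stages:
        catalog = build_catalog(cohort, kind=config.signature_kind)
        if not catalog.to_numpy().any():
            raise PipelineError("signatures: catalog is all-zero for kind "
                                f"{config.signature_kind}")
        if config.n_signatures == "auto":
            sel = select_k(catalog, config.k_range, seed=config.seed)
            k = sel["k"]
            _write_tsv(sel["table"], outdir / "signature_k_selection.tsv")
        else:
            k = int(config.n_signatures)
        signatures, exposures = extract_signatures(
            catalog, k, n_restarts=config.n_restarts, seed=config.seed)
        _write_tsv(catalog.T, outdir / "catalog.tsv")  # channels as rows
        _write_tsv(signatures, outdir / "signatures.tsv")
        _write_tsv(exposures, outdir / "exposures.tsv")
        results.update(catalog=catalog, signatures=signatures, exposures=exposures, k=k)
        if groupings:
            binary = {n: g for n, g in groupings.items()
                      if set(g.unique()) <= {"A", "B"}}
            sig_tests = signature_clinical_tests(exposures["dominant_signature"], binary)
            _write_tsv(sig_tests, outdir / "signature_clinical_tests.tsv", index=False)
            results["signature_clinical_tests"] = sig_tests
        manifest["stages"].append("signatures")
        manifest["n_signatures"] = int(k)

    # --- burden -------------------------------------------------------------
    burdens = None
    if "burden" in config.stages:
        burdens = compute_burden(cohort)
        _write_tsv(burdens, outdir / "tmb.tsv")
        results["burden"] = burdens
        if len(burdens) >= 3:
            results["burden_concordance"] = burden_concordance(burdens)
            (outdir / "tmb_concordance.json").write_text(
                json.dumps(results["burden_concordance"], indent=2))
        manifest["stages"].append("burden")

    # --- neoantigen ---------------------------------------------------------
    neo = None
    if "neoantigen" in config.stages:
        if config.binding is None:
            logger.info("neoantigen stage enabled but no binding table: skipped")
        else:
            peptides = read_binding_table(config.binding)
            neo = sample_scores(peptides, config.sb_rank, config.wb_rank,
                                unpaired_mode=config.unpaired_mode)
            _write_tsv(neo, outdir / "neoantigen_scores.tsv")
            _write_tsv(gene_scores(peptides, config.sb_rank, config.wb_rank,
                                   unpaired_mode=config.unpaired_mode),
                       outdir / "gene_scores.tsv", index=False)
            spectrum = sharing_spectrum(
                filter_candidates(peptides, config.sb_rank, config.wb_rank))
            _write_tsv(spectrum, outdir / "sharing_spectrum.tsv")
            results.update(neoantigen=neo, sharing_spectrum=spectrum)
            manifest["stages"].append("neoantigen")

    # --- survival -----------------------------------------------------------
    if "survival" in config.stages:
        clin = cohort.clinical
        if not {"os_time", "os_event"} <= set(clin.columns):
            logger.info("survival stage: clinical table lacks os_time/os_event, skipped")
        else:
            surv = clin[["os_time", "os_event"]].dropna()
            scores = {}
            if burdens is not None:
                scores["aTMB"] = burdens["aTMB"]
                scores["fTMB"] = burdens["fTMB"]
            if neo is not None:
                scores["TNB"] = neo["TNB"].astype(float)
                scores["TNS"] = neo["TNS"]
            cut_results = {}
            for name, score in scores.items():
                common = surv.index.intersection(score.index)
                s = score.loc[common]
                if s.nunique() < 2 or len(common) < 2 / config.minprop:
                    continue
                cp = optimal_cutpoint(s.to_numpy(),
                                      surv.loc[common, "os_time"].to_numpy(),
                                      surv.loc[common, "os_event"].to_numpy(),
                                      minprop=config.minprop)
                cut_results[name] = {
                    "cutpoint": cp.cutpoint_, "statistic": cp.statistic_,
                    "p": cp.p_, "p_adjusted": cp.p_adjusted_,
                    "n_high": cp.n_high_, "n_low": cp.n_low_,
                }
            (outdir / "survival_cutpoints.json").write_text(
                json.dumps(cut_results, indent=2))
            results["cutpoints"] = cut_results
            manifest["stages"].append("survival")

    # --- associations -------------------------------------------------------
    if "associations" in config.stages:
        if not groupings:
            logger.info("associations stage: no clinical groupings available, skipped")
        else:
            assoc = {}
            for name, grouping in groupings.items():
                if set(grouping.unique()) - {"A", "B"}:
                    continue  # location (3-level) is reported but not Fisher-tested
                try:
                    assoc[name] = gene_group_fisher(cohort, grouping,
                                                    min_mutated=config.min_mutated)
                except ValueError as exc:
                    logger.warning("grouping %s skipped: %s", name, exc)
                    continue
                _write_tsv(assoc[name], outdir / f"association_{name}.tsv", index=False)
            results["associations"] = assoc
            if "lymph_metastasis" in assoc and len(assoc["lymph_metastasis"]):
                hmg = hmg_lmg_classify(assoc["lymph_metastasis"], alpha=config.alpha)
                hmg.to_frame().to_csv(outdir / "hmg_lmg.tsv", sep="\t")
                results["hmg_lmg"] = hmg
            inter = pairwise_interactions(cohort, top_n=config.top_n_interactions,
                                          alpha=config.alpha)
            _write_tsv(inter, outdir / "interactions.tsv", index=False)
            results["interactions"] = inter
            manifest["stages"].append("associations")
        if config.driver_tables:
            tables = {tool: pd.read_csv(path, sep="\t")
                      for tool, path in config.driver_tables.items()}
            drivers = driver_consensus(tables)
            _write_tsv(drivers, outdir / "driver_consensus.tsv", index=False)
            results["drivers"] = drivers
            if "associations" not in manifest["stages"]:
                manifest["stages"].append("associations")

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    results["manifest"] = manifest
    return results
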