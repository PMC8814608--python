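# Methods

`mutscape` re-implements, as a tested library, the integrative
somatic-mutation analysis used for large esophageal squamous-cell carcinoma
(ESCC) cohort studies: mutational-signature extraction, two tumor-mutation-
burden definitions, neoantigen burden/score statistics, survival
dichotomisation by maximally selected rank statistics, gene–clinical
association with HMG/LMG classification, mutual-exclusivity testing and
driver-gene consensus. This note records the models, the defaults and the
design decisions, and what the synthetic-data tests do and do not show.

## Data model

Input mutations are GDC-style MAF tables (tab-separated, 1-based inclusive
coordinates, dash convention for indel alleles). Only eight columns are
required — `Hugo_Symbol, Chromosome, Start_Position, Reference_Allele,
Tumor_Seq_Allele2, Variant_Classification, Variant_Type,
Tumor_Sample_Barcode` — because multi-cohort inputs rarely share the full
column superset. Unknown `Variant_Classification` values map to `other`
with a warning; `Tumor_Sample_Barcode` is taken verbatim (no truncation),
and the same sample id appearing in two cohorts is treated as an identity
collision rather than silently merged. Synonymous = `Silent`;
nonsynonymous = every other coding class, including splice sites; indel =
`Variant_Type` INS or DEL regardless of frame.

Flanking sequence context comes from optional `Context_5prime` /
`Context_3prime` columns (written by the simulator, or by any upstream
annotation). The package never fetches a reference genome; real-genome
context extraction is an extension point, not a dependency.

## Tumor mutational burden

Two statistics per sample, both over coding records with a fixed 30-Mb
exome denominator:

* `aTMB = (all coding SNVs + indels) / 30` — synonymous included;
* `fTMB = (nonsynonymous SNVs + indels) / 30` — synonymous excluded.

fTMB is deliberately the *synonymous-free* burden; the alternative literal
reading ("exclude the nonsynonymous SNVs") is available as
`ftmb_mode="literal"` for comparison but is not the default, since the
definitional intent of fTMB is a burden restricted to protein-changing
events. By construction `aTMB >= fTMB >= 0`, duplicating every record
doubles both, and a silent SNV moves only aTMB — these invariants are
asserted in the tests.

## Mutational signatures

**Channels.** Single-base substitutions are classified into the 96
trinucleotide channels on the pyrimidine strand (purine-reference calls are
reverse-complemented, so classification is strand-invariant). Doublet
substitutions use the canonical 78 DBS channels with reverse-complement
pairs collapsed. Indels use the 83 ID channels with SigProfiler-style
labels `size:Del|Ins:C|T|R|M:bin`: for 1-bp events the base is reported on
the pyrimidine strand and the bin is the homopolymer repeat-unit count
(minus one for deletions, capped at 5); longer indels are binned by length
(5 = 5+) and adjacent whole-copy count; deletions with no adjacent copy but
partial flank identity go to the microhomology branch, with homology length
capped at `min(length - 1, 5)`. Ties between repeat and microhomology
classification resolve repeat-first. A 1-bp T deletion inside a TTTTT run
is therefore `1:Del:T:4`.

**Extraction.** Catalogs (samples × channels counts) are factorised by NMF
with the Frobenius objective and multiplicative updates: defaults 20
random restarts, at most 2000 iterations, relative-improvement tolerance
1e-6, best restart kept. The per-iteration objective is recorded and must
be non-increasing (asserted in the tests, and cross-checked against
scikit-learn's `mu` solver). Signatures are column-normalised to sum to 1
with the scale pushed into the exposures, so exposure rows live on the
mutation-count scale; on well-fit synthetic catalogs the exposure row sums
track the catalog row sums within 5%.

**Rank selection.** For each candidate `k`, eight factorisations are run,
each on a multinomial bootstrap of the catalog (per-sample counts resampled
from the observed channel profile). The pooled restart signatures are
clustered into `k` groups and stability is the *minimum* per-cluster mean
cosine silhouette: a signature set only counts as reproducible when every
component is. Without the bootstrap, an overfit extra component reappears
deterministically across restarts and inflates stability; with it, spurious
components wander and their cluster silhouette collapses. The chosen `k`
is the largest candidate with stability ≥ 0.8 (`k = 1` is defined as
perfectly stable). Both the threshold and the restart count are arguments.

**Annotation and attribution.** Extracted signatures are matched to a
reference set (COSMIC-format TSV, channels as rows) by cosine similarity;
best matches below 0.75 are reported as `novel`. Per-sample exposures onto
fixed signatures are non-negative least squares with the residual norm
reported. "Enrichment" of a sample in a signature means the argmax of its
relative exposure (`dominant_signature`); samples with no classifiable
mutations are `none`. Dominant-signature membership is tested against each
binary clinical grouping with a two-sided Fisher exact test and
Benjamini–Hochberg FDR across all signature × grouping tests.

## Neoantigen scoring

Input is a pVACtools-style peptide table. Candidate neoantigens are the SB
and WB binders; where only a percent rank is present, levels default to the
NetMHC convention SB ≤ 0.5, WB ≤ 2.0 (both configurable). Per peptide,
`AAscore = log2(W/M)` with `W`/`M` the wild-type/mutant binding scores
(IC50-like, lower = stronger, so positive AAscore means the mutation
improved binding). Unpaired peptides — frameshift products with no
wild-type partner — use a fixed wild/mutant ratio of 15, i.e.
`log2(15) ≈ 3.907`; the alternative reading where the score itself is 15 is
available as `unpaired_mode="literal15"`. `Gscore` is the per-gene sum of
AAscores, `TNB` the per-sample candidate count, and `TNS` the per-sample
sum of Gscores over genes, which is identically the sum of AAscores over
all candidate peptides — summation is the only aggregation consistent with
treating Gscore as "the score of the gene in the sample", and the equality
of the two computation paths is asserted. Peptide identity for the sharing
spectrum is the exact mutant peptide string, ignoring the HLA allele;
the spectrum maps patient multiplicity to the count and fraction of
distinct peptides.

## Survival analysis

Kaplan–Meier estimation wraps lifelines (`S(0) = 1`, right-continuous).
The log-rank machinery is implemented in-package because the cutpoint scan
needs the per-candidate standardized statistic: at each distinct event time
the observed events per group are compared with their hypergeometric
expectation, with the standard tie-corrected variance
`d (n-d)/(n-1) · n_g/n · (1 - n_g/n)`; two groups give
`z = (O-E)/sqrt(V)` and `chi² = z²` on 1 df, g groups use the covariance
matrix with a pseudo-inverse. The implementation agrees with lifelines to
machine precision in the tests and is invariant under monotone time
transformations.

The optimal cutpoint (the `surv_cutpoint` procedure) scans every observed
score value whose split keeps at least `minprop = 0.1` of samples on each
side, computes the standardized two-group log-rank statistic for
`high = score > c` (strictly greater, matching the "high > threshold"
convention of the survival figures this reproduces), and returns the
candidate maximising `|z|`, smaller value on ties. The reported p-value at
the selected cutpoint is the *unadjusted* log-rank p, as is conventional in
studies using this procedure; because the cutpoint maximises the statistic
this p is anti-conservative under the null (the test suite demonstrates
the inflation), so the Lausen–Schumacher approximation for the maximally
selected statistic is reported alongside as `p_adjusted_`. The
per-candidate table is exposed for inspection.

## Gene–clinical association

Grouping conventions: T1-T2 vs T3-T4, TNM S1-S2 vs S3-S4 (reading the
stated "S1-S2 vs S3-S3" convention as a typo for S3-S4), male vs female,
lymph-node metastasis yes/no, smoking yes/no, drinking yes/no, grade G1-G2
vs G3-G4; tumor location stays three-level; distant-metastasis (M) stage is
never tested (too few M1 samples in the motivating cohorts to support it).
Age is dichotomised twice — at the fixed 60-year threshold and by exact
1-D k-means (dynamic programming over contiguous splits, provably optimal,
equal to exhaustive search in the tests) — and both groupings are emitted.

Per gene, mutated/wild status is tested against each binary grouping with a
two-sided Fisher exact test; genes mutated in fewer than `min_mutated = 3`
tested samples are skipped to avoid degenerate tables (no floor is inherent
to the method; the value is configurable). Raw p and BH FDR within the
grouping are both reported: the HMG/LMG classification gates on raw
p < 0.05, labelling genes with a higher mutation rate in the metastasis arm
HMG and lower LMG, a partition that is exhaustive and exclusive over tested
genes. Numeric covariates (age, aTMB, fTMB, TNS, …) use Welch two-sample
t-tests, mutated vs wild, with arms under two values skipped and flagged.

Pairwise interactions among the `top_n = 25` most-mutated genes use the
2×2 joint-status table with a two-sided Fisher test at p < 0.05; direction
is by odds ratio (< 1 mutually exclusive, > 1 co-occurring), matching the
semantics of the somatic-interaction analyses in maftools.

Driver consensus ingests per-tool result tables (gene + p or FDR column);
a tool flags a gene at its threshold — driverml p < 0.01; MutSigCV,
OncodriveFML and OncodriveCLUSTL FDR < 0.05 — and a gene is a consensus
driver when at least two tools flag it. Running the driver tools themselves
is out of scope; their tables are inputs.

## Synthetic cohort generator

The generator produces MAF + clinical + binding tables with known ground
truth, at the statistical scale of an ESCC exome cohort:

* per-sample mutation counts are negative binomial (mean 120, dispersion
  3) so the median aTMB lands near 3.6/Mb with realistic overdispersion;
* substitutions are drawn from a mixture of two disjoint-support SBS-96
  signatures (C>A-based and T>C-based, non-uniform context weights) with
  per-sample Dirichlet(1,1) weights; each mutation's generating signature
  and channel-consistent flanking context are recorded, and the strand is
  randomised so classifiers must reverse-complement;
* roughly 24% of SNVs are silent and 8% of records are indels (70%
  frameshift), echoing the aTMB/fTMB ratio of coding cohorts;
* clinical covariates are male-skewed (80%) with smoking-dependent
  drinking and lymph-node metastasis (63% vs 43% by smoking status);
* planted HMG/LMG genes are governed *only* by their per-group mutation
  probabilities (they are excluded from the background gene pool), so
  their arm-specific rates equal the configured values;
* survival is exponential with administrative censoring at five years,
  hazard ratio 1.8 for lymph-node metastasis and an optional
  burden-threshold effect for cutpoint-recovery experiments;
* each nonsynonymous mutation yields a Poisson(0.35) number of peptides
  with lognormal percent ranks and binding scores; frameshift products are
  unpaired; one peptide is planted in three patients so the sharing
  spectrum has a known multiplicity-3 entry.

Same seed, same bytes: generation is fully reproducible.

What the simulator does **not** emulate: real genomic coordinates and gene
footprints (so burden is not confounded with gene length), germline
contamination, subclonal structure, copy number, signature flat/background
components, HLA restriction of peptides, or inter-cohort batch structure.
Passing recovery tests therefore demonstrates correctness of the
algorithms under their stated models, not robustness to the full messiness
of real cohorts.

## Numerical choices and problem sizes

Degenerate inputs fail loudly: all-zero catalogs, constant scores, empty
grouping arms and nonpositive binding scores raise; samples without
mutations get zero burdens and `none` dominant signatures rather than
errors. NMF uses an epsilon of 1e-12 in the update denominators; cutpoint
candidates with zero log-rank variance score z = 0.

Test and verification scales were chosen to exercise each statistical
property at desk scale: signature recovery on 50 samples × 2000 mutations
(cosine ≥ 0.95 against planted truth, automatic rank = 2), cutpoint
recovery on 100 replicates of n = 300 at hazard ratio 3 (recovered within
the central 10% quantile band ≥ 90% of the time), log-rank type-I error
and Fisher null false-positive rate on 1000 simulations each, and the
association screen on a 500-sample cohort. The full suite runs in a few
minutes on one CPU.

## Known limitations

* Context comes from input columns, not a reference genome; MAFs without
  context columns can be burden/association-analysed but not
  signature-analysed.
* The DBS catalog requires explicit DNP records; adjacent SNV merging is
  not performed.
* The maximally-selected-statistic adjustment is the Lausen–Schumacher
  normal approximation, adequate for diagnostics but not exact at small n.
* BH FDR is computed within each grouping's gene family; a global
  correction across groupings is a caller decision.
* The unpaired-peptide constant (ratio 15) is a convention of the scoring
  scheme, not an estimate; both published readings are implemented.
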