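# Methods

## Scope and data flow

The package implements the downstream, model-level half of a
neoantigen-burden study: it consumes *annotated* somatic variants
(gene/transcript/protein position/reference and alternate residue),
protein sequences, per-sample HLA class I allele lists, peptide:MHC
dissociation constants from any predictor, an epitope reference set and
per-transcript RPKM tables. Read alignment, variant calling, annotation,
HLA typing, binding prediction and expression quantification are upstream
tools' jobs; their outputs are this package's inputs. A synthetic-cohort
generator produces all of these inputs with known ground truth so that
every stage is testable without access to patient sequence data.

## Peptide enumeration

Coordinates are 1-based throughout (genomic, protein, and window
positions); windows are closed intervals. Each nonsynonymous SNV yields a
window of up to 10 residues on either flank of the substituted position
(≤ 21 total, truncated at protein termini). Every contiguous 9-mer of that
window is a candidate — a full 21-mer yields 13, and all 13 are counted as
possible neoantigens and scored, including the up-to-4 windows that do not
overlap the substitution (their mutant and wild-type sequences are
identical; they can never show a mutant/wild-type binding contrast beyond
the wild-type Kd adjustment). Multiple variants in one window are treated
independently against the reference protein: no phasing information is
assumed. Indel calls are consumed (they matter for the proximity filter
and burden counts) but generate no peptides, since peptide construction is
defined only for single-residue substitutions. SNVs within 1 bp (default)
of an indel in the same sample and chromosome are discarded as probable
alignment artifacts before any peptide work.

## MHC binding and amplitude

For each 9-mer the dissociation constant is minimized over the sample's
alleles, independently for mutant and wild-type (the winning allele may
differ). The binding gate is strict: K_d^MT < 500 nM. The amplitude
A = K_d^WT / K_d^MT is computed for every scored window. A configurable
cap on K_d^WT (`wt_kd_cap_nM`, default off) is provided as a hook for the
correction some pipelines apply when predictors report constants far above
their trained range; only its monotone contract is fixed here, not a
specific functional form, because no single published form is canonical.

TCR recognition R (and therefore F = A·R) is computed for binding windows
only — those are the neoantigens the analysis considers; non-binding
windows carry missing R/F and can never be classified immunogenic or enter
the expression adjustment. This is also what keeps multi-seed simulation
studies fast, since the alignment step dominates runtime.

Classification: *binding* = K_d^MT below threshold; *immunogenic* =
binding with R > 0 (exact zero, which occurs only for an empty reference
with this arithmetic — consequently the immunogenic:binding ratio on
synthetic cohorts sits near 1, unlike pipelines that round small R to
zero); *stringent* = binding with R ≥ 0.01.

## TCR recognition potential

|s,e| is the maximum, over all equal-length contiguous substring pairs of
the candidate and the epitope (length ≥ 1, no gaps), of the summed
BLOSUM62 scores; the matrix is the canonical NCBI integer table (loaded
from Biopython and pinned by tests). R = S/(1+S) with
S = Σ_e exp[-k(a−|s,e|)], a = 26, k = 4.87. Exponents reach magnitude
~10², so S is accumulated with log-sum-exp and R evaluated as a sigmoid of
log S; R is clamped to the largest double below 1 so the strict R < 1
bound survives rounding when S is astronomically large (e.g. exact
self-matches). A brute-force substring-enumeration oracle pins the
alignment semantics in the tests.

## Expression adjustment and summaries

Within a sample, records with F > 0 share expression fractions
rpkm_i / Σ_j rpkm_j (transcript-level RPKM of the variant's annotated
transcript; RPKM is used for the denominator as well, since the same
normalization defines the quantity). Missing transcripts count as zero
RPKM and are logged; if every F > 0 record has zero RPKM the sample's
adjusted statistics are undefined rather than zero. Fractions sum to 1
within 1e-9 per sample by construction, and adjusted fitness never exceeds
unadjusted.

Per-sample means of K_d^MT, A, R and F are taken over the *immunogenic*
records by default (`averaging_set="binding"` switches to all binding
records); max F over immunogenic records; adjusted mean/max over records
with a defined adjustment. Duplicate 9-mer sequences from overlapping
windows or recurrent mutations are separate records — counts are window
counts. Samples enter between-group strength comparisons only with ≥ 2
immunogenic neoantigens. An optional, off-by-default rule additionally
drops eligible samples whose max F sits ≥ 100× below the mean of the other
eligible samples' max F, generalizing the ad-hoc exclusion of
extreme-magnitude outlier samples.

## Statistics

Group comparisons use the two-sided Wilcoxon rank-sum test. The exact
mode enumerates all C(n, n_x) assignments of the observed (mid)ranks and
doubles the smaller tail (capped at 1); `auto` uses it for combined n ≤ 12
without ties. The *normal* mode — the default for cohort comparisons —
uses the classical large-sample z with tie-corrected variance and **no
continuity correction**, matching the convention of mainstream statistics
packages for this test. The choice matters at these sample sizes: with 3
vs 4 samples the exact two-sided p can never fall below 2/35 ≈ 0.057,
whereas the normal approximation yields p = 0.034 at perfect separation,
which is the attainable significance the analysis design relies on.

Count metrics (somatic mutations, binding and immunogenic counts) are
compared across all samples; ratio/strength metrics across eligible
samples only. Association of mutation burden with neoantigen counts is
reported as tie-aware Spearman rho plus the OLS slope with a t-based 95%
CI. Families of regressions against cell-type scores are
Bonferroni-corrected (p → min(1, m·p)). Degenerate cases (all values
tied, too few eligible samples, constant predictors) produce "not
computed" entries or warnings, never crashes.

QC helpers: variants are flagged `in_coding`/`in_groove` against
user-supplied HLA exon intervals (BED on disk, converted to 1-based closed;
exons 2 and 3 encode the peptide-binding groove), and a gene's expression
in a mutated sample is tested against mean ± 2 sample standard deviations
(n−1 denominator, appropriate for small cohorts) of the cohort.

## Synthetic cohorts

`generate_cohort` produces a complete, byte-reproducible input bundle from
(config, seed): proteome FASTA, per-sample variant tables, allele list,
epitope FASTA, expression TSV, group labels, and a manifest of planted
ground truth (near-indel SNVs, suppressed transcripts).

Design choices, and why:

- **Residue composition.** Proteins and epitopes are drawn with
  vertebrate-proteome amino-acid frequencies. Uniform sampling would
  overweight rare, high-scoring residues (W, C), fattening the tail of
  chance BLOSUM62 matches and letting background similarity saturate the
  recognition sigmoid at a = 26 — which would swamp any planted biological
  structure with alignment noise (one BLOSUM unit is a factor e^k ≈ 130 in
  F below saturation).
- **Epitope reference.** Epitopes are the strongest-binding 9-mer windows
  of a small number of "immunodominant" source proteins (default 3),
  mirroring two properties of curated epitope databases: entries are
  peptides that were actually presented (strong MHC binders), and they
  cluster heavily on a few antigens. Somatic mutations landing in or
  beside these source windows yield high-similarity, frequently
  binding-competent neoantigens concentrated on few transcripts — the
  regime in which suppressing the expression of a sample's strongest
  neoantigens is a well-defined escape event. A composition-matched
  random-epitope mode remains available when no proteome/predictor is
  supplied.
- **Dissociation constants.** Kd is a pure function of (peptide, allele,
  role, seed): a 64-bit splitmix mix of the inputs mapped through the
  lognormal quantile (σ = 1.5 on log-nM by default). The location μ is
  calibrated so that the best-over-alleles binding fraction of random
  9-mers hits a target (default 3%, matching published
  binding:possible-9-mer ratios). A per-position hash component with
  weight 0.9 makes single-substitution neighbors strongly correlated, as
  neural predictors are for near-identical peptides. The wild-type role
  shifts log-Kd by −0.7, reproducing the reported regime in which
  wild-type counterparts usually out-bind mutants (amplitude mostly < 1);
  for mutation-free windows this makes A exactly e^−0.7 ≈ 0.5.
- **Burden.** Per-sample somatic burden is uniform over a configurable
  range (default 50–5,000, echoing the order-of-magnitude spread of
  published per-sample counts). A small fraction of indels, and SNVs
  planted 1 bp from them, exercise the proximity filter; the manifest
  records the planted keys.
- **Expression and the group effect.** Baseline RPKM is lognormal per
  (transcript, sample). In each group-B sample the distinct transcripts
  ranked by their best record's fitness — the 9-mer windows of one variant
  share a transcript, so the natural unit of expression escape is the
  transcript — have their RPKM multiplied by `suppression_effect`
  (default 0.05) for the top `suppression_top_k` (default 3) transcripts.
  Group A is untouched. With the effect set to 1.0 the groups are
  exchangeable, giving the null behavior used to check the test's size.

### What the generator does not emulate

Real read-level noise, annotation errors, phased multi-nucleotide
variants, indel-derived or frameshift peptides, clonal architecture,
allele-specific expression, and a trained binding predictor's sequence
motifs are all absent. Passing the recovery study therefore shows that the
*pipeline* detects a planted expression-escape effect of realistic shape
at realistic sizes — not that any particular biological cohort would show
it.

## Problem sizes and multi-seed studies

Multi-seed studies (`neofit.power`) run the full pipeline per seed at a
scaled-down size chosen so hundreds of simulations complete in minutes on
one CPU: burden 400–900 per sample, 30 proteins of 250–450 residues, 20
epitopes, 3 vs 4 samples. These sizes keep per-sample binding counts in
the hundreds and immunogenic-transcript counts in the handful range, the
same count structure as the eligible samples of the motivating study. At
the default effect (0.05 suppression of the top 3 transcripts) the
adjusted-max-fitness comparison rejects at 0.05 in roughly two-thirds of
seeds, the unadjusted comparison stays near the nominal level, and with no
suppression the rejection rate sits at the discrete attainable level
(2/35 ≈ 0.057) — numbers recomputed, not asserted, by
`scripts/acceptance.py` and the test suite.

## Known limitations

- Indel and frameshift neoepitopes are out of scope; indels participate
  only in counting and the proximity filter.
- The wild-type Kd correction is a cap hook, not a published curve.
- With exact arithmetic R > 0 for any non-empty reference, so
  "immunogenic" coincides with "binding" on synthetic data; the stringent
  subset (R ≥ 0.01) is the discriminating tier there.
- The expression adjustment assigns one transcript per variant (the
  annotated one); multi-transcript genes are not aggregated.
- Exact Wilcoxon enumeration is limited to combined n ≤ 12 by design;
  larger cohorts take the normal path.
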