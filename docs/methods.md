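# Methods

## Scope and data model

The pipeline operates strictly at the call level: annotated germline and
somatic small-variant calls, germline structural variants (SVs), purity- and
ploidy-adjusted copy-number segments, and sample metadata. Read-level
processing (alignment, SNV/SV calling, purity estimation) is assumed done by
an upstream WGS pipeline; annotations (gene, canonical coding effect, gnomAD
frequency, reference-cohort carrier count, recalibrated quality) are expected
pre-computed on the inputs. Coordinates are 0-based half-open internally;
VCF positions are converted on ingest. Formats: TSV with header for every
table, a minimal VCF 4.2 subset (annotations in INFO, read support in
`AD` with the ref,alt convention), BED3+1 for panel regions, COSMIC-layout
TSV for signature matrices, YAML/JSON for configuration.

## Germline filtering

Four predicates are applied to panel-scoped germline small variants, in a
fixed order so that removal ledgers are reproducible; the kept set is the
conjunction of the predicates and therefore order-invariant (asserted
against a brute-force oracle in the tests):

1. **Synonymous effects** removed (`drop_synonymous`, default true).
2. **Population variance**: gnomAD non-cancer cumulative frequency strictly
   above `gnomad_max` (default 0.01) removed. A missing gnomAD frequency is
   treated as rare — absence from gnomAD implies rarity, which matches the
   filter's intent.
3. **Recalibrated quality** below the cutoff removed. The cutoff is
   estimated from a Gaussian kernel density (Silverman bandwidth) of the
   cohort's recalibrated Phred scores, taking the deepest density minimum
   between the two largest modes on a 1024-point grid. The estimate is
   replaced by the fallback constant 235.6 when fewer than 50 scores are
   available or the density is unimodal (with a warning). The boundary is
   inclusive: a score exactly at the cutoff is kept.
4. **Reference-cohort frequency**: carrier counts at or above
   ⌈`cohort_max_fraction` · `reference_cohort_n`⌉ removed (defaults 0.05 and
   5778, giving the integer threshold 289). The count is carried as an
   integer plus cohort size — not a fraction — so the ≥ 5% rule reproduces
   integer threshold arithmetic exactly; the ceiling uses a 1e-9 guard
   against binary-float overshoot.

SVs pass only the cohort-count filter: gnomAD provides no non-cancer SV
frequencies. Patients whose tumors carry an IDH1/2 mutation are excluded
from the analysis set before prevalence statistics (they are astrocytoma
WHO grade 4, not IDH-wildtype glioblastoma); unknown IDH status is kept
with a warning by default.

## Pathogenicity and zygosity

Clinical significance arrives as a ClinVar-style class plus an optional
expert-curation override with free-text rationale; the override always wins
and is logged. This models manual curation as an explicit, auditable table
rather than hidden logic. Conflicting or absent ClinVar states resolve to
VUS-equivalent. Only class 4/5 variants become PGVs; no automated ACMG/AMP
criteria engine is included.

Zygosity is resolved per patient-gene group. Genes annotated
dominant-and-recessive are resolved as recessive-pattern per variant: a
single heterozygous variant does not by itself establish dominant risk.
Mismatch-repair genes are carried as dominant (Lynch-type) with the
recessive constitutional syndrome expressed through a `cmmrd_candidate`
flag set when a patient carries two or more PGVs in one MMR gene.

## LOH model

The lost-allele decision is a maximum-likelihood choice over mutant copy
number m ∈ {0, …, round(CN)} with expected tumor alt fraction

    f(m) = (purity·m + (1 − purity)·1) / (purity·CN + (1 − purity)·2),

i.e. the non-tumor fraction is modeled as diploid heterozygous. The
likelihood is binomial in the observed alt/total tumor reads, with f clamped
to [1e−9, 1 − 1e−9] to keep boundary hypotheses (f = 0 or 1) finite. LOH is
present when the segment's minor copy number is below
`minor_cn_threshold` = 0.5. The call is *undetermined* when LOH is absent,
when purity is below `min_purity` = 0.2 (the cohort-inclusion purity floor,
below which allele fractions barely separate), when the best m is interior,
or when the germline genotype is homozygous. Segments shorter than
`focal_max_mb` = 3 Mb are focal; segments of at least `arm_min_mb` = 10 Mb
carry an arm label. At depth 90 and purity uniform on [0.2, 1], the lost
allele is recovered in ≈ 99% of simulated loci; errors concentrate at the
purity floor, where f(0) and f(1) differ by ~0.11.

## Causality categories

`assign_category` is a pure, total rule cascade evaluated in order:

- **(a)** monoallelic PGV in a recessive-pattern gene → 3, even when a
  somatic second hit exists (the hit is preserved in the rationale);
  only biallelic germline inactivation confers risk in such genes.
- **(b)** MMR gene: 1 if the tumor is MSI (or MSI-elevated with a same-gene
  second hit), else 2 (MMR genes are brain-tumor-associated).
- **(c)** HRD gene: 1 with an SBS3-like signature match *and* biallelic
  inactivation, else 2.
- **(d)** other glioblastoma/medulloblastoma-associated gene: 1 with a
  demonstrated second hit (somatic small variant, focal deletion, or focal
  loss of the wild-type allele not explained by a common arm event), else 2.
- **(e)** non-associated gene: 2 with matching tumor findings or a
  demonstrated second hit, else 3.

Arm-level LOH on arms configured as near-universal for the tumor type
(default for glioblastoma: chr10 loss/LOH, chr7 gain) is deliberately weak
evidence — it removes one allele of hundreds of genes — so it yields
category 2, not 1; the `arm_loh_counts_as_hit` switch restores the looser
reading. Epigenetic second hits (e.g. promoter hypermethylation) are not
called — they are invisible to WGS — but the fixture marks the one
ambiguous methylation-suspect patient with an `uncertain` flag.

## Genome-wide phenotypes

**MSI.** Somatic indel *events* (not unique sites) at microsatellite tracts
per Mb. A tract scanner reports maximal perfect repeats with primitive
(smallest-period) units of 1–5 bp and ≥ 5 units; overlaps between candidate
tracts are resolved greedily by start position, shorter unit first. Status:
rate > 1.3 → elevated (exclusive), rate ≥ 4 → MSI (inclusive, the
diagnostic WGS cutoff). The denominator is the configurable
`genome_size_mb` (default 2900).

**Signatures.** SNV catalogs use the 96 pyrimidine-reference trinucleotide
channels in COSMIC order; purine-reference contexts are reverse-
complemented. Exposures are fitted by non-negative least squares —
deterministic, exact on noiseless mixtures (residual 0), and within 0.05 of
truth for 70/30 multinomial mixtures at n = 5000. No de-novo signature
extraction is attempted. The packaged six-column matrix (SBS1/3/6/11/15-like
plus flat noise) is a *synthetic* stand-in with disjoint supports chosen for
identifiability, not measured COSMIC profiles; any COSMIC-format matrix can
be supplied. A phenotype "matches" an MMR gene when the tumor is MSI or the
dMMR signature group (SBS6/14/15/20/21/26, optionally SBS9/10 with the POLE
flag) has relative exposure ≥ 0.1, and an HRD gene when SBS3 exposure
≥ 0.2; these two thresholds are package choices — no quantitative
definition of a "matching signature" exists to adopt.

## Cohort statistics

Prevalence of dominant PGVs in associated genes uses the post-IDH-exclusion
denominator (92 in the reference cohort); the MMR-carrier percentage uses
the full-cohort denominator (98). Both denominators are explicit
parameters, never inferred silently. Headline prevalences are rounded to
integer percent and the MMR percentage to one decimal, with unrounded
values and numerator/denominator stored alongside every figure. The
Mann-Whitney U statistic uses midranks; p-values come from full enumeration
of all C(n, n_a) labelings when n_a + n_b ≤ 12 (a permutation test, which
handles ties naturally and matches the exact distribution in the tie-free
case), otherwise from the normal approximation with tie-corrected variance
and continuity correction. The carrier-age comparison runs on synthetic
cohorts only: individual ages are not part of the packaged evidence table.

## Synthetic cohorts

The generator emulates the study conditions at the call level: tumor purity
uniform on [0.2, 1.0], tumor depth 90–110×, normal depth 30–35×, a ~6%
IDH-mutant fraction, ~24% PGV carriers with gene weights matching the
observed PGV spectrum, SV PGVs at 3/29, a 0.6 probability of biallelic
inactivation split evenly between somatic small hits and LOH, background
chr10 loss (0.8) and chr7 gain (0.7), ms-indel rates of 10/Mb
(MMR-deficient) vs 0.1/Mb, TMB 40/Mb vs 3/Mb, dMMR-heavy vs SBS3-heavy vs
clock-like signature mixtures, and a −9-year carrier age shift on a
truncated normal(61, 10) age model. Read counts are binomial at the
purity-mixed expected allele fraction. Per-Mb rates are kept at study
levels while the genome is represented by a 100 Mb footprint, which keeps a
200-patient simulation in seconds without changing any rate-based
statistic. Each patient also receives one decoy germline variant per filter
removal reason plus a rare benign passenger, so every filter and the
classification stage do live work in every simulated cohort.

Expected causality categories in the ground truth are derived by running
the category cascade on the *noise-free* planted evidence; comparing
pipeline output against them therefore isolates read-sampling noise, and
the residual mismatches (≈ 0–2% of planted PGVs) are LOH allele miscalls
near the purity floor. What the simulator does **not** model: real
trinucleotide sequence context, correlated segment structure, subclonality,
germline CNV mosaicism, panel-of-normals artifacts, or epigenetic
silencing — so passing recovery tests demonstrates internal consistency of
the estimators under the stated noise model, not robustness to every
property of real tumors.

## Numerical and degenerate-input conventions

Quality-cutoff estimation falls back to 235.6 on degenerate or unimodal
score sets; `sv_count_threshold` guards the ceiling against float
overshoot; binomial likelihoods clamp probabilities away from {0, 1};
NNLS normalisation returns all-zero relative exposures for empty catalogs;
zygosity ties (two PGVs in one gene) are biallelic only for
recessive-pattern genes; oncoprint inclusion is "PGV present and/or
ms-indel rate > 1.3". Rows failing an input schema are collected with row
numbers and reasons, never silently dropped; a missing required column is
an immediate error naming the column.

## Known limitations

- The packaged gene panel covers the genes named in the study (24 genes
  with inheritance, mechanism, association and phenotype-class
  annotations); the full reportable panel is an external artifact and its
  size is treated as metadata, not reproduced. Region coordinates are
  representative GRCh37 gene spans.
- The packaged evidence table is post-curation; pre-curation variant lists
  are not reconstructible from printed information and are exercised only
  synthetically.
- VCF support is a minimal 4.2 subset; rich annotation formats (VEP/SnpEff
  strings) are out of scope, as annotations are expected pre-computed.
- Signature matching thresholds (0.1 dMMR, 0.2 HRD) and the LOH thresholds
  (minor CN 0.5, purity 0.2, focal 3 Mb, arm 10 Mb) are package defaults,
  documented and configurable, and should be revisited for other tumor
  types or assay designs.
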