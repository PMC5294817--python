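# Methods

`cistrovar` integrates a transcription factor's genome-wide binding loci
(its *cistrome*, from ChIP-seq peak sets) with trait- and disease-associated
SNPs, asking which phenotypes have their variants concentrated under binding
sites and whether those variants plausibly change binding. This note records
the model, the conventions, the tunable parameters and the design choices,
and what the synthetic-data tests do and do not demonstrate.

## Coordinates and interval algebra

All internal coordinates are 0-based half-open (BED-native); VCF positions
(1-based) are converted on read, and chromosome names are normalized to the
`chr`-prefixed dialect. A SNP is a 1-bp interval at its position; for
insertion/deletion alleles only the anchor base position is used.

The consensus cistrome is the non-overlapping union of peaks across
datasets: two peaks merge iff they share at least one base pair. Abutting
intervals `[0,100)` and `[100,200)` share zero base pairs and do not merge —
"non-overlapping" means exactly that. Each merged locus carries the set of
dataset names contributing ≥ 1 bp of overlap, and the union of covered base
pairs is preserved exactly (property-tested against a naive O(n²) oracle).

Cistrome intersection uses a fractional-overlap criterion: a query locus
counts as shared when the total base pairs it overlaps with the subject
cistrome reach `min_fraction` of its own length (default 0.25, inclusive —
25 bp of a 100-bp locus passes at 0.25). Because "fraction of the peak"
does not say which peak, the default is the query-side (A) convention, with
a reciprocal mode requiring one subject locus to satisfy the fraction with
respect to both lengths. The two directions are not symmetric in general,
so the summary carries both counts (`n_shared` for A, `n_shared_b` for B);
each side's shared + only counts partition that side's loci. The convention
used is recorded in the run manifest.

## LD proxy expansion

Linkage disequilibrium is measured as the gametic r² from phased
haplotypes, r² = D²/(p q p′ q′) with D = f₁₁ − p p′, where f₁₁ is the
frequency of haplotypes carrying the alternate allele at both sites. r² is
undefined (a distinct error, never 0) when either site is monomorphic. A
squared-Pearson dosage correlation is available for unphased data.

A lead SNP's proxies are the panel sites within ± `window_bp` of the lead
(default 500 kb, i.e. a 1 Mb span — "surrounding" read as a half-window)
with r² ≥ `r2_min` (default 0.8, inclusive) and minor allele frequency
≥ `maf_min` (default 0.05). The MAF filter applies to proxies only: leads
come pre-vetted from the catalog and are kept regardless, including leads
absent from the panel (retained without proxies and reported). Multi-allelic
panel sites are split into one biallelic record per alternate allele on
read.

## Trait enrichment

For each phenotype and peak set a hypergeometric test is applied with:
population N = the deduplicated universe of catalog + proxy SNPs; successes
K = the SNPs associated with the trait; draws n = the SNPs under the peak
set; observed k = trait SNPs under the peak set. The enrichment p-value is
the inclusive upper tail P(X ≥ k) (computed through log-space survival
functions, stable to N ~ 10⁷); the lower tail is reported alongside for
under-representation, but ranking and significance use the upper tail. A
SNP counts once toward N and n no matter how many leads it proxies, and
once per trait toward K.

Bonferroni correction multiplies by m and caps at 1. By default
(`m_policy="tested"`) m is the number of phenotypes with at least one SNP
under the supplied peak sets; `m_policy="all"` uses every phenotype in the
catalog. The policy and the resulting m are recorded per result and in the
manifest.

A one-tailed Fisher exact test (enrichment direction, tail summation at
fixed margins) supports comparisons of "likely to affect binding" fractions
between a SNP set and its background.

Note on published full-scale tables: corrected p-values printed in the
analysis this package models (e.g. 0.0003 for a trait with N = 191,482,
K = 1,874, n = 78, k = 4) are not reproducible from the printed marginals
under this — or the swapped, equivalent — parameterization; the exact
big-integer tail for those marginals is 0.00735, frozen in the test suite.
The parameterization here is therefore exposed in configuration and the
package makes no attempt to match those printed values.

## DR3 motif model and allele scoring

The vitamin-D-receptor class of nuclear receptors binds a direct repeat of
two hexameric half-sites spaced by 3 bp (DR3). The model is one 4×6
half-site probability matrix applied to both hexamers; spacer columns carry
no weight, so motif width is 15 and a SNP in the spacer has zero allele
effect by construction. Scores are log2 odds against a background base
distribution (default uniform 0.25), summed over the 12 scored columns; a
pseudocount of 0.01 is added to every PWM cell (columns renormalized)
before taking logs so zero cells score finitely.

The packaged default half-site is built from the consensus RGKTSA: 0.85
probability on the consensus base(s), split evenly when degenerate, with
the remaining 0.15 spread over the other bases. It ships as an editable
JASPAR-style text file (`data/dr3_half_site.pwm`). The matrix behind the
published HOMER scores is not available, so scan scores here are analogous
to, not identical with, those scores; the hit threshold defaults to 80% of
the maximal window score and is fully configurable.

Scanning evaluates every window on both strands (windows containing N are
skipped; overlapping hits allowed); hit coordinates are + strand genomic
and a hit's sequence is reported in its reading orientation. In-motif SNP
positions are 1-based in the reading orientation — for a − strand hit,
position 1 is the end-most genomic base. The allele effect is
ΔLOD = LOD(alt) − LOD(ref) in bits: negative means the reference allele is
the better predicted binding site. The reference allele must match the
genome at the SNP position, or the annotation is rejected with the position
reported. By default motif scanning covers ± 100 bp around each consensus
locus midpoint (a summit-region stand-in); whole-locus scanning is a flag.

## Regulatory-score annotation

Variants carry ordinal regulatory-evidence categories 1a..6; the set
{1a..1f, 2a, 2b, 2c} is classified "likely to affect binding" — an explicit
category set, never numeric parsing of the labels. Score tables are always
consumed from TSV files, never fetched from a live service. TF
co-occurrence is tabulated with set semantics per SNP and emitted as a
ranked frequency table (the input a wordcloud would be drawn from; no
graphic is produced). Binding-by-genotype summaries report per-class
(ref-hom / het / alt-hom) n, mean and SD plus a monotonicity call; with
fewer than two observed classes the call is "undefined".

Published fractions of "likely affecting" SNPs in a 42-SNP significant set
are quoted in the source material as 33.3% and 35% for what is arithmetically
15/42 = 35.7%; this package reports exact fractions only.

## Synthetic data: what it emulates and what it does not

Generators are pure functions of `(SimConfig, seed)` with one named
substream per generator, so adding a generator never perturbs another's
output, and all fixtures are written in the pipeline's real input formats
(BED/VCF/TSV/FASTA) — the pipeline cannot distinguish fixtures from real
data. Ground-truth side files (coverage per SNP, motif plants, allele
overrides) are sufficient to compute every stage's expected output exactly.

* **Panel**: independent LD blocks; within a block every site copies a
  founder column (founder alternate-allele frequency uniform on
  `founder_freq_range`, default 0.02–0.5 so site MAFs straddle the 0.05
  filter) with per-site mutation probability `mutation_rate` (default
  0.02). This block-copy model gives provable control of within- and
  between-block r² with trivial code; it is deliberately not a coalescent
  and has no recombination gradient, hotspots or demography.
* **Catalog + peaks**: every panel site belongs to exactly one trait; one
  planted trait receives `planted_trait_snp_count` sites and its SNPs are
  covered by peaks at `enrichment_factor` × the background coverage
  probability; peaks are otherwise uniform, split into ≥ 2 sets so
  consensus merging is exercised. Real GWAS catalogs have LD-clustered,
  gene-dense SNPs and non-uniform peak placement; passing the calibration
  tests therefore shows correctness of the statistic under its own null,
  not robustness to LD-structured confounding (a GREGOR/GoShifter-style
  LD-matched permutation null is explicitly future work).
* **Sequences**: i.i.d. background with exact consensus DR3 15-mers
  planted at recorded positions/strands, preferentially over SNP positions
  near locus midpoints; panel reference alleles are written into the
  genome so allele-aware rescoring is exactly consistent.
* **Genotype/binding**: Hardy–Weinberg genotypes at a stated allele
  frequency; signal = base·(2 − dosage)/2 + Gaussian noise, so alternate
  homozygotes lose binding entirely up to noise.

## Simulation sizes and calibration results

The statistical checks run at sizes chosen to give tight Monte-Carlo bounds
with fast turnaround; these are the package's study conditions:

* Type-I error: uniform (factor 1) placement, universe 4,000 SNPs over 20
  traits, ~2.5% coverage; across 1,000 replicates in the test suite (500 in
  the acceptance script) the fraction of traits with p_raw < 0.05 must stay
  within two standard errors of 0.05 — the discrete test is conservative
  and lands near 0.03.
* Power: planted trait with K = 50 of N = 20,000 SNPs, background coverage
  ~2.5% (≈ 4,167 peaks of mean width 300 bp on a 50-Mb genome), factor 10;
  the planted trait must be top-ranked with Bonferroni p < 0.05 in ≥ 95% of
  200 replicates. Panel depth is 20 haplotypes here because haplotype
  content does not enter the enrichment statistic.
* LD recall: blocks with `mutation_rate = 0` (perfectly correlated sites,
  the planted-block construction that guarantees r² = 1) and founder
  frequencies 0.15–0.45 so empirical MAFs clear the filter; recall of
  within-block proxies is 100% with zero cross-block false proxies over 50
  seeds.
* Motif recovery: 100 sequences with one planted consensus DR3 each at the
  80%-of-maximum threshold; recall 1.0, with the background false-hit rate
  checked to stay below 10⁻³ per window.

## Numerical and degenerate-input choices

Hypergeometric tails go through `scipy.stats.hypergeom` survival/cdf
functions (log-space internally); the test suite pins them to an exact
`fractions.Fraction` big-integer enumeration to relative error 1e-12 on a
randomized grid. k = 0 returns exactly 1. Inconsistent count configurations
(k > K, k > n, n > N) are rejected, as are all-zero Fisher tables. Empty
peak sets and empty intersections return zero-count summaries, not errors.
Monomorphic sites raise a dedicated error wherever r² would be undefined.
Ties in TF frequency tables break lexicographically; consensus-base ties in
the PWM resolve in A,C,G,T order.

## Run manifest and reproducibility

Every pipeline run writes `manifest.json` with the tool version, every
effective threshold (r², MAF, window, overlap fraction, motif threshold,
correction policy, alpha), input checksums and headline counts. All
pipeline stages are deterministic given their inputs, so re-running from a
manifest reproduces outputs byte-identically; the driver re-executes a
stage only when one of its outputs is missing or an upstream stage ran.

## Known limitations

Peak calling, read alignment, de novo motif discovery and live annotation
services are out of scope; regulatory scores and peaks are consumed from
files. One haplotype panel per run (union across panels is by SNP id across
runs). The enrichment null ignores LD structure among catalog SNPs.
Dinucleotide background models and DR-n spacings other than the
parameterized spacer length are not modeled.
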