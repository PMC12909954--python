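# Methods

## Scope and data model

`svsieve` analyses per-sample SV callsets (VCF 4.2 with `SVTYPE`/`SVLEN`, or
sequence-explicit REF/ALT), a pedigree table (sample, family, role, sex,
population), control-cohort callsets, BED annotation tracks, PAF
assembly-to-reference alignments, and bedMethyl haplotype methylation tables.
Internally all coordinates are 0-based half-open; VCF emission is 1-based with
`END = POS + |SVLEN|` for deletions and the anchor base for insertions.
Genotypes are small integer codes (absent/het/hom/hemi/missing) so cohort
matrices stay `int8`. Pseudoautosomal regions (configurable; GRCh38 PAR1/PAR2
defaults packaged in `svsieve.config`) are treated as autosomal — diploid in
males — everywhere: ploidy, transmission, zygosity categories and MAF.

## SV matching and cohort collapse

Two records match when all hold: same type and chromosome; start distance
≤ `refdist` (default 500 bp); size ratio ≥ `pctsize` (0.90); sequence
similarity ≥ `pctseq` (0.90) where similarity is normalized edit similarity
`1 − editdistance/max(len)` (edlib); and reciprocal overlap ≥ `pctovl` when
that gate is enabled (insertions satisfy the overlap gate whenever they are
within `refdist`). Design choices where the underlying comparison tools leave
room:

- records lacking sequence fall back to size-only matching (flagged in the
  `MatchDecision`), since symbolic ALTs carry no sequence;
- inversions never use the sequence gate — comparing inverted sequence is not
  well defined here;
- collapse merges *exact connected components* of the match relation found
  within a window of sorted starts (complete because matching requires start
  distance ≤ `refdist`), rather than an order-dependent greedy sweep: the
  partition is reproducible and testable against a brute-force all-pairs
  union–find oracle;
- two heterozygous calls of the *same* sample never merge directly (they are
  two distinct alleles); the nonredundancy postcondition carries the same
  exception;
- the representative row is chosen by `keep`: `common` (allele identity
  carried by most samples), `maxqual`, or `first`; ties break leftmost then by
  lexicographic id. Per sample, the genotype of the highest-QUAL constituent
  wins.

Callerset validation keeps primary (assembly-based) records matched by at
least one record of at least one supporting (alignment-based) callset, and
annotates the supporting caller set. Blacklist exclusion removes any SV whose
footprint touches a masked interval (interval trees; insertions use a 1 bp
footprint at the insertion point).

## Rare-SV definition and trio classification

A collapsed row × child carrier pair is **rare** iff no control column
carries the allele; on non-PAR chrX/chrY only controls of the child's sex are
consulted. Missing control genotypes do not count as carriers. Each rare pair
receives one of six zygosity categories (autosomal het/hom, X het/hom, X/Y
hemizygous; males on non-PAR X/Y are always hemizygous, and a diploid male X
genotype is flagged, not fatal). Category tallies are reported both per
carrier pair and per unique SV, since either convention is defensible.

Mendelian confidence is sex-aware producibility: sons take their X from the
mother only and their Y from the father only, so the other parent's genotype
(often structurally missing) is not consulted; a genuinely missing
transmitting-parent genotype yields LC. Origin classes, in precedence order:

1. **DENOVO** — all transmitting parents genotyped reference (and neither
   parent a carrier). This is checked *before* the LC gate: a true de novo is
   by definition Mendelian-discordant.
2. **PRIVATE_BIALLELIC_HOM** — child homozygous, both parents heterozygous,
   and no other parent in the cohort carries.
3. **PRIVATE_INHERITED** — the allele is observed exactly once among *all*
   parents of the cohort (the transmitting parent is counted) and that copy
   sits in the child's own family.
4. **INHERITED_OTHER** otherwise; LC rows that are not the clean de novo
   pattern become **UNRESOLVED** and feed the curation cascade.

MAF is folded (≤ 0.5); hemizygous samples contribute one allele to the
denominator, diploid samples two, missing genotypes none.

## Curation cascade

Mendelian-discordant calls are resolved by the first decisive step of an
ordered cascade: (1) relaxed match (0.9/0.9, 500 bp) against the parents' raw
pre-validation callsets — a hit means the validated parental callset simply
dropped the allele, so the call is a confirmed transmission; (2) family
re-genotyping: Mendelian-compatible re-genotyped calls confirm transmission
when a parent carries, or a de novo when both parents re-genotype reference;
(3) parental read support — supported iff ≥ `min_reads` (1) reads deviate by
≤ 50% from the SV size within a dynamic window of `max(svlen, 500)` bp; a
sample queried with zero support in *both* parents supports a de novo, while
unqueried samples leave the step undecided; (4) tandem-repeat allele-length
outliers — a child allele is an expansion iff it exceeds the population mean
+ 3 SD *and* the maximum control allele, where the population excludes the
child's own family (the candidate transmitting parent must not mask the
expansion) and requires ≥ 20 genotyped samples; the origin is the family
parent whose allele lies within 10% relative difference. The read-support rule
replaces a trained callable-region classifier with a transparent rule-based
step; an external per-SV quality column can be supplied instead. Anything
undecided exports to a review sheet — the package never guesses.

## Annotation and prioritization

Track intersection uses any-overlap (≥ 1 bp) semantics; insertions intersect
as points. Functional classes partition every SV set with precedence
EXON (incl. UTR) > INTRON (within a gene span) > INTER. `annotation_gain`
reports how many SVs a new track class flags beyond a base class, as a
percentage of the base count (rounded half-up). Candidate rules: (A) de novo
and either exonic in an NDD-flagged gene or regulatory
(ENCODE/brain/TF-cluster) within 50 kbp of a risk gene — the flank is
configurable since no canonical distance exists for linking intergenic
regulatory SVs to genes; (B) private biallelic homozygous in a SFARI gene or
regulatory DNA; (C) any rare SV in a constrained (Gnocchi ≥ 4) predicted
promoter. Candidates carry their full rule trail, and adding a flag can only
add candidates.

## Burden statistics

The χ² burden comparison uses the 2×2 table `[[events_p, N_p], [events_s,
N_s]]` — events against group sample slots — because that construction
reproduces the direction and magnitude of published SV-burden odds ratios;
it is an interpretation, stated here prominently, and Yates continuity
correction is on by default (small counts; toggleable). Odds ratios apply the
Haldane–Anscombe 0.5 correction when any cell is zero. The Mann–Whitney U
comparison of per-sample counts uses average ranks, the tie-corrected normal
variance, no continuity correction (Z > 0 ⇒ probands higher), and an exact
enumeration p-value when the smaller group has ≤ 8 samples. Note that the χ²
construction is *not* a calibrated test under a per-sample Poisson null (it
is strongly conservative); the per-sample Mann–Whitney comparison is the
calibrated instrument, and the type-I-error check in the test suite targets
it. "Adjusted p" is Bonferroni — a published nominal 0.29 adjusting to 1
implies a multiplicative family correction. `filtering_efficiency_report`
rounds `100·(1 − rare/validated)` half-up to the nearest integer.

## Sex-chromosome contiguity and XCI skew

The reference sex chromosome is partitioned into 1 Mbp windows; windows
touching a mask (PAR, centromere, heterochromatin) leave the denominator. A
window qualifies iff the union of assembly alignment blocks covers ≥ 95% of
it and ≤ 3 distinct contigs touch it; the score is qualified/unmasked.
Coverage is union coverage in target space (identity-weighted coverage is not
used); secondary alignments are excluded by input contract.

XCI skew: per CpG island ± 5 kbp, the mean methylation per haplotype over
CpGs with coverage ≥ 5; islands lacking a qualifying CpG on either haplotype
are excluded and counted. The genome-wide haplotype mean is unweighted over
used islands (no CpG-count weighting). `skew_index = mean_mat − mean_pat`;
|skew| ≥ 0.20 classifies as skewed (this threshold is the package's default —
skew is usually shown qualitatively — and is configurable). Swapping the
haplotype inputs negates the index exactly. The bedMethyl reader accepts the
minimal 5-column layout or the modkit pileup layout and auto-detects the
percent scale.

## Synthetic cohort generator

The generator defines the conditions under which the pipeline is validated:

- **SV pool.** Sizes from a mixture of two lognormal components centred at
  300 bp (σ = 0.25, weight 0.55) and 6 kbp (σ = 0.25, weight 0.30) plus a
  uniform 50–20,000 bp tail (0.15), clipped at the 50 bp SV definition —
  realising the characteristic Alu/LINE bimodal spectrum; type mix
  INS/DEL/INV = 0.48/0.48/0.04. Allele frequencies per ancestry stratum:
  Beta(0.3, 1.5) for AFR and Beta(0.2, 2.0) for non-AFR, giving African
  samples higher diversity (their discovery curves dominate) and a heavy
  rare tail. Loci sit on a 1 kbp grid so distinct loci never fall within the
  500 bp match radius — truth stays unambiguous for collapse and recovery
  tests. Deletions carry a generated "deleted reference" sequence so emitted
  VCFs can be sequence-explicit.
- **Genotypes.** Founders draw haplotypes Bernoulli(AF) (Hardy–Weinberg by
  construction), with one allele on male non-PAR X and Y. Children take one
  allele per parent uniformly at random under sex-chromosome rules. De novo
  events are *fresh loci* (AF 0, ≥ 1 kbp from any existing locus, fresh ids)
  injected per child at Poisson(rate); default rate 0.3 per child — a free
  parameter chosen as a plausible per-genome de novo SV count, not a measured
  value. Genotyping errors flip only between adjacent zygosity states
  (hom↔het, het↔absent, hemi↔absent), mimicking caller error modes; every
  flip is recorded.
- **Files and evidence.** Per-family and control multi-sample VCFs (sorted,
  optionally bgzipped+indexed) plus per-sample "caller replicate" VCFs in
  which supporting callers drop records independently at a configurable
  probability — callerset validation then has the analytic survival rate
  `1 − dropout^k`. Read-support and TR allele-length tables are generated
  consistently with true genotypes; PAF alignments cover 1 Mbp windows except
  configurable gapped/fragmented windows; methylation for a female with
  maternal-inactive fraction `s` gives bulk island methylation
  `s·0.80 + (1−s)·0.10` on the maternal haplotype (binomial per CpG at the
  chosen coverage), so the expected skew index is `(2s−1)·0.70` in closed
  form. (`skew` is the fraction of cells with the maternal X inactive.)

What the simulator deliberately does *not* emulate: breakpoint jitter between
callers, repeat-context miscalling, reference bias, segmental-duplication
artifacts, read-level data, or realistic sequence content. Passing tests
therefore demonstrate the correctness of the *logic* (matching, collapse,
filtering, classification, statistics) under clean conditions and known
truth — not robustness to the full error structure of real long-read
callsets, which is what the curation cascade and manual-review terminal state
exist to absorb.

## Numerical and degenerate-input conventions

Zero-variance TR loci yield no outlier calls; empty burden groups flag the χ²
result undefined rather than raising; a chromosome whose windows are all
masked yields an undefined (NaN) coverage fraction; VCF records with neither
SVLEN nor sequence are skipped with a logged count; percentages round half-up
at their stated precision. All randomness flows from explicit integer seeds
(numpy `default_rng`), and identical seeds give byte-identical output files.

## Problem sizes used in validation

The test suite and acceptance script run on 2,000–20,000-locus pools with 5
quads and 20–400 controls, 889 CpG islands at coverage 20, and 500-replicate
null calibrations — sizes chosen so each property is measured with comfortable
statistical margin while the whole suite stays fast on one CPU.
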