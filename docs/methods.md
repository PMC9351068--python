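# Methods

## Scope and model

The package reproduces the *downstream* analysis of a multifocal tumor
cohort: it consumes per-sample somatic call sets (small variants,
copy-number segments, structural variants) and germline/tumor allelic
counts at SNP positions, and produces filtered call sets, parental-allele
assignments for copy-number events, within-patient clonality calls and
cohort recurrence summaries. Read alignment, variant calling and
annotation are out of scope; their outputs are the package's inputs.

All in-memory coordinates are 0-based half-open; VCF (1-based) and SEG
(1-based inclusive) convert at the I/O boundary. Chromosome-name matching
is exact string comparison — no "chr" normalization — so silent contig
mismatches fail loudly. A missing population allele frequency never
removes a variant: absence of evidence is not evidence of commonness.

## Filtering rules

Comparisons sit on the exact boundary side of each rule: variants are
removed at total depth ≤ 6 reads (kept at 7) or population AF > 0.001
(kept at exactly 0.001); CNAs are kept when median logR > 0.15 or
< −0.15, at length ≥ 10,000 bp (9,999 removed); intrachromosomal SVs need
span ≥ 10,000 bp. Copy-neutral LOH segments are exempt from the logR
magnitude rule only — they are logR-neutral by definition yet real
allelic events, and they must survive filtering to be mappable.

Segment breakpoints are taken as the first and last covered base. A
boundary lying exactly at a chromosome end is not an interior breakpoint:
whole-chromosome and arm-level segments therefore pass the
centromere/chromosome-end breakpoint exclusions, which target focal
artifacts with breakpoints in unreliable regions. An interior breakpoint
within 1 Mb of either chromosome end, or inside the centromere interval,
removes the segment. The original workflow's manual per-variant review is
not computable; an explicit exclusion-key list (`manual_exclusions`)
stands in for it. Each filter emits an audit: every input record is kept
or tagged with the *first* failing rule (depth before population AF).

## Chromosome mapping

Heterozygous germline SNPs are selected in the matched normal with read
depth strictly > 10 and VAF in the closed interval [0.4, 0.6]. For a
tumor segment, candidates are het SNPs inside the segment∩arm window with
tumor depth strictly > 10.

The two-sided binomial p-value under the Binomial(n, ½) null uses the
minimum-likelihood convention — sum P(k) over outcomes no more likely
than the observed one. For this symmetric unimodal null that set is
exactly the two mirror tails, giving the closed form
p = min(1, 2·CDF(min(ref, alt))), symmetric in its arguments; tests pin
it against exact rational-arithmetic enumeration (≤ 1e-12 for totals
≤ 30). Ties (ref = alt) give p = 1 and can never be informative, so the
major allele of an informative SNP is always defined.

Benjamini–Hochberg adjustment is computed per family, where a family is
the candidate set of one (tumor, arm-restricted segment). Segments are
split at the centromere *before* FDR correction because p and q arms can
carry independent events and must be interpreted separately (the
observed p/q-discordant chromosome-18 case requires per-arm inference).
SNPs failing the tumor depth filter are excluded before adjustment.

Informative SNPs have adjusted p < 0.05. For a tumor pair, the shared set
is the intersection of informative positions; when it holds fewer than
1000 SNPs, *both* tumors are re-called at the relaxed level 0.1 and the
shared set recomputed — the symmetric re-call keeps comparison results
invariant under argument order, and the level actually used is recorded.
Concordance is the fraction of shared SNPs whose major allele agrees;
verdicts use config-exposed cutoffs, same_allele at ≥ 0.9 and
different_allele at ≤ 0.1 (the source analyses report only qualitative
same/different calls, so explicit numeric cutoffs are a package choice),
ambiguous in between, and no_call for an empty shared set.

## Clonality

Variants match on the exact key (chrom, pos, ref, alt): two different
substitutions at one position are convergent, not shared. The shared
fraction uses the smaller tumor's set size as denominator (symmetric and
conservative; a union denominator is config-switchable). A primary pair
is independent when the shared fraction is < 0.01 *and* the shared count
is < 5; a metastasis is assigned the primary with maximal sharing when
that count is ≥ 5 and ≥ 2× the runner-up, otherwise it is unassigned
(tie/sub-threshold vs zero sharing are distinguished — the latter is
compatible with an unsequenced primary of origin). Dissemination over a
patient's assigned metastases: one distinct origin (≥ 2 assigned) is
clonal, ≥ 2 distinct origins independent, anything else undefined
(mixed_unassigned). The subclonal audit flags ≥ 2 ALT reads at a shared
variant's position in tumors where it was not called; promotion of
supported variants into a tumor's set is opt-in and can only increase
shared counts. Parental-allele concordance is reported alongside variant
sharing but never overrides it.

## Recurrence summaries

All recurrence flags count *patients* (≥ 2), never tumors. Nonsynonymous
means any annotated effect except silent. Mutation burden divides by the
full configured genome length; a callable-genome correction would shift
absolute burdens on real data. CNA events classify as whole-chromosome or
arm-level at ≥ 0.8 fractional coverage of the chromosome/arm
(config-exposed; the boundary between "whole-arm" and focal events is not
standardized), else focal. Minimally targeted regions are the
intersection intervals of *maximal* mutually-overlapping segment sets
(per direction) spanning ≥ 2 patients with intersection < 5 Mb; for
intervals, distinct maximal overlapping sets have disjoint intersections
(Helly property), so reported regions are automatically pairwise disjoint
and contained in every contributing segment. Pathway enrichment is the
upper-tail hypergeometric probability P(X ≥ k) for k of n mutated
universe genes landing in a K-gene pathway of an N-gene universe
(enrichment only, no depletion test), BH-corrected across pathways at
FDR 0.1.

## Synthetic cohort generator

The generator emulates the multifocal setting with known ground truth.
Defaults, chosen once as the study conditions:

| parameter | default | rationale |
|---|---|---|
| patients | 13 | cohort size of the setting emulated |
| primaries/patient | 2–18 (uniform) | observed multifocality range |
| metastases/patient | 0–4 | observed per-patient metastasis counts |
| mutation rate | 0.41 /Mb | mean primary-tumor burden |
| coding fraction | 0.012 | ≈ coding share of somatic calls |
| effect mix | 0.65 missense / 0.27 silent / 0.08 LoF | observed coding spectrum |
| purity | Uniform(0.2, 0.9) | 20% selection floor |
| tumor / normal depth | 60× / 30× | target sequencing depths |
| het SNPs/chromosome | 2000 | desk-scale mapping resolution |
| CNA events | chr18 loss p=0.57; chr2 gain p=0.13; chr1 cn-LOH p=0.08 | dominant event spectrum mapped onto the toy genome |
| met inherited fraction | 0.9 | metastases carry most of the parent clone |
| met burden factor | 1.0 | no generative link between met and primary burden is established; exposed, not tuned |
| overdispersion ρ | 0.01 | mild beta-binomial noise |
| logR noise sd | 0.01 | segment-level measurement noise |

The toy genome is three 10-Mb chromosomes with centromeres at 40–45% of
length ("chr18" names the loss-prone one); it is configurable up to
full-genome scale. Germline het SNPs get an independent fair-coin ALT
haplotype (emulating unphased heterozygosity — exactly the ambiguity the
mapping procedure resolves). Allelic counts follow a purity-mixture
model: at a SNP where tumor cells carry n_alt copies of the ALT-bearing
and n_ref of the REF-bearing haplotype,

    E[VAF] = (φ·n_alt + (1−φ)) / (φ·(n_alt + n_ref) + 2(1−φ)),

with depth Poisson(mean) and ALT counts beta-binomial (ρ = 0 degenerates
to binomial). Loss sets the affected haplotype to 0 copies, gain to 2,
cn-LOH to 2 with the other at 0 (logR ≈ 0, exercising the mapping path
without a logR signal). Primaries draw variants independently at uniform
random positions (chance pair-sharing ≪ 1e-3 on the toy genome);
metastases inherit each parent variant with probability 0.9, draw private
variants at the same rate, inherit the parent's CNA events on the same
haplotypes, and may add events on unaffected chromosomes (metastases
carry more CNAs than primaries in this setting). One normal per patient
is the purity-0, no-event case. Everything derives from one seed through
per-patient spawned streams, so outputs are byte-reproducible;
`include_allelic_counts=False` skips count generation for variant-only
analyses (a mode with its own deterministic stream).

What the generator does **not** emulate — and hence what passing tests do
not show about real data: trinucleotide mutation spectra and signatures,
subclonal copy-number mosaics and subclonal variant fractions, caller
artifacts (strand bias, repeats), germline contamination of somatic
calls, uneven coverage, and real gene/pathway structure (genes are a
100-kb grid over coding positions). Recovery rates here are upper bounds
for cohorts with low purity or subclonal events, a limitation the
mapping approach itself carries.

## Numerical and degenerate-input choices

- BH adjustment: vectorized step-up with reverse cumulative minimum,
  clipped to 1; empty input returns empty; p-values outside (0, 1]
  rejected.
- Depth-0 allelic rows: VAF undefined, skipped silently in het-SNP
  selection; (0, 0) binomial input is an error.
- Segments entirely inside the centromere produce no mapping reports.
- Purity-0 tumors yield no informative SNPs (the null is true).
- Origin ties break toward "unassigned_ambiguous", never lexically.
- SEG files are re-read with exact float round-tripping so threshold
  boundary values survive I/O; the VCF population-AF field is written as
  a string field because 32-bit float INFO storage would perturb the
  0.001 filter boundary.

## Problem sizes used in validation

The test suite and acceptance script run at desk scale, chosen as the
package's own validation conditions: mapping recovery uses 2000 het SNPs
per chromosome at purity 0.6, 60× depth, ρ = 0.01 (20 seeds in tests, 10
in the acceptance script); clonality recovery uses 100 (tests) / 20
(script) full default cohorts with variant-only generation; end-to-end
byte-determinism uses a 4-patient cohort with 800 SNPs/chromosome; oracle
comparisons enumerate totals ≤ 30 (binomial, exact rationals), all
hypergeometric tuples with N ≤ 25, and BH vectors up to length 10,000.
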