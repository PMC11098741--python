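# Methods

This note documents the models implemented in `scsnv`, the parameters
that matter, the synthetic-data generator's assumptions, and the design
choices made where the problem was genuinely open. It states no number
that the test suite or `scripts/acceptance.py` does not itself compute.

## 1. Genotype likelihoods (`scsnv.genolike`)

Reads with more than 4 alignment mismatches or mapping quality below 20
are discarded (both boundaries inclusive of 4 and 20; mismatches count
substitutions plus indel bases, a choice the pileup producer controls).
Any locus with ≥1 non-reference read is a candidate SNV; when several
non-reference bases occur, the most frequent one becomes the alternative
allele (alphabetical tie-break) and the rest are dropped, keeping every
site bi-allelic.

Per read, the error probability is `e = 10^(−min(BQ, MQ)/10)` and

```
P(ref | g=0) = 1 − e,   P(ref | g=1) = 1/2,   P(ref | g=2) = e,
```

with complements for the alternative allele; GL(g) is the product over
reads, kept in log space. Zero reads give a flat triplet. This is the
classical symmetric bi-allelic model; it is permutation-invariant in the
reads, and adding an alt read can never raise the normalised P(g = 0)
(both tested properties).

## 2. Panel refinement HMM (`scsnv.panel_refine`)

The sample's two chromosome copies are modelled as mosaics of the K
panel haplotypes. The HMM state space is the K² ordered haplotype pairs.
Transitions factorise over the chains: over an inter-site distance of
d bp each chain stays on its template with probability `exp(−d/ρ)` and
otherwise lands uniformly on one of the K templates. Emission at site m
for pair (h₁, h₂) sums the allele-pair mixture against the data:

```
E_m(h1, h2) = Σ_{a1,a2∈{0,1}} P(a1|h1) P(a2|h2) · GL_m(a1+a2),
P(a|h) = 1 − θ  if a equals the template allele, else θ.
```

Posterior genotype probabilities come from scaled forward–backward with
the per-state genotype distribution re-weighted by the site's GL; the
same pass yields the phase posterior P(alt on haplotype 1 | g = 1) that
orients the phased germline matrix for the somatic stage.

Two chains that are *a priori* independent become coupled once the
genotype likelihood (a function of a₁ + a₂) enters the emission, so the
refinement is implemented as the exact pair HMM rather than two haploid
chains combined after the fact; the factorised transition keeps the cost
at O(M·K²). Correctness is pinned by a test against an explicit
K²-state dynamic program written entry-by-entry from the definitions
(relative error < 1e-8 on panels up to 8 haplotypes × 6 sites), and by
closed forms: with a single site and flat GL the posterior is the
Hardy–Weinberg law of the panel allele frequency.

Defaults: `θ = 1e-3`, `ρ = 100 kb` (one expected switch per 100 kb).
Neither is sharply identified by desk-scale data; both are exposed.
Ties in argmax break toward the smaller genotype. Final calls keep
`argmax GP` when it equals `argmax GL`; het-by-GL loci refined to
hom-*reference* feed the error model; every other discordance is
excluded from all downstream sets.

## 3. Sequencing-error model (`scsnv.error_model`)

Het→hom-ref discordances fall in 12 categories (6 unordered base pairs ×
2 collapse directions). The per-category threshold is the median pooled
BAF of its discordant loci; empty categories fall back to the global
median (configured default 0.1 when no discordant loci exist at all,
with a warning). A de novo candidate passes iff pooled depth ≥ 100
(inclusive — "minimum acceptable depth") and BAF ≥ the max of its allele
pair's two thresholds. Raising any threshold can only shrink the passing
set (tested monotonicity).

## 4. SVM artifact filter (`scsnv.svm_filter`)

Features per candidate site: QS (phred-scaled `−10·log10 P(g=0)`,
capped at 99), RPB and BQB (signed tie-corrected rank-sum z comparing
alt- vs ref-supporting reads on read position / base quality; 0 when a
side is empty), MQSB (mean of |rank-sum z on mapping quality| and the
z-transformed two-sided Fisher exact statistic of the strand × allele
table), VDB (variance of alt read positions over the uniform-placement
expectation `span²/12`; neutral 1 below two alt reads), SGB (distinct
alt-supporting cells / alt reads), and BAF. The named metrics follow
widely used variant-calling annotations in spirit; the exact formulas
here are the package's own and are deliberately pluggable.

Training: positives are panel-overlapping germline calls; negatives are
de novo SNVs in fixed genomic chunks (default 50 kb) that contain no
germline SNV and hold a run of more than two consecutive de novo SNVs —
several "somatic" calls with not one germline variant nearby is the
signature of a mapping/amplification artifact, given realistic somatic
mutation rates. The classifier is an RBF-kernel SVC with internal
probability calibration behind a standardiser (probabilities therefore
invariant to affine feature rescaling); candidates with P(positive) <
0.5 are dropped, the boundary value 0.5 retained.

## 5. Cell-population LD refinement (`scsnv.ld_refine`)

Only *heterozygous phased* germline SNVs enter the cell × locus matrix
(homozygous sites carry no phase information). In cell j, covered loci
k < i with nothing covered between them form a two-locus neighbourhood;
the pair cosegregates when the same phased allele is seen at both
(`c¹ₖc¹ᵢ > 0 or c²ₖc²ᵢ > 0`). Chained neighbourhoods k < i < l with both
flanks showing the haplotype-1 allele form a three-locus neighbourhood,
cosegregating when the middle shows haplotype 1 too. Scores are
`1 − cosegregating fraction` per distance bin (13 bins: <100 bp up to
>500 kb, lower edge inclusive; the three-locus distance is upstream
flank → middle). Empty bins are flagged undefined, never 0/0; lookups
fall back to the nearest defined bin, preferring wider ones. For
*profile estimation* the haplotype-2 mirror of the three-locus sets is
pooled — unbiased for germline SNVs by phase symmetry, doubling the
data. The profile is exactly reproduced by a brute-force set-enumeration
oracle on >100 random small matrices (tested).

**Phasing de novo SNVs.** Per cell with reads at site s: the two-locus
term uses the nearer covered germline neighbour within 100 bp (DNA-like
default; 1 kb for RNA-like data) and the bin score at that distance; the
cell's observation either supports orientation A¹|A² (same-haplotype
allele pairing) or A²|A¹, ambiguous cells (both pairings supported) are
skipped. The three-locus term conditions the flanks on *one* haplotype
and votes by which allele of s the cell shows, with flank distances
capped at 10 kb (50 kb RNA-like). Terms combine per cell as
½(two-locus + three-locus) when both exist, else whichever exists. The
population average over informative cells gives p(A¹|A²), with
p(A²|A¹) = 1 − p(A¹|A²) by construction, orientation = argmax, and
`p_s = min` of the two, classified putative somatic iff `p_s > 0.25`.

**Haplotype channels.** The one-haplotype flank conditioning is what
lets p_s estimate a carrier fraction: among haplotype-1 fragments, the
fraction showing a new allele *is* the carrier fraction f of a somatic
SNV on haplotype 1, while a germline het always shows its haplotype-1
allele there. But a somatic allele may sit on either haplotype, and the
two natural fixes both fail: conditioning on haplotype 1 only misses
haplotype-2 somatic alleles entirely (they score ≈ 0), while pooling the
mirrored neighbourhoods into one vote set dilutes every somatic signal
to 0.5 − f/2, because fragments from the non-carrier haplotype always
display the reference allele and vote for the alt-on-carrier-haplotype
orientation regardless of the cell's carrier status. The implementation
therefore evaluates the three-locus term as two separate channels
(flanks on haplotype 1; mirrored flanks on haplotype 2), aggregates each
channel's cells independently, and reports the channel with the larger
p_s (ties toward channel 1). A germline het scores ≈ 0 in both channels;
a somatic SNV scores ≈ f in its carrier channel and ≈ 0 in the other.
The per-cell sums of both orientation hypotheses are accumulated
separately so that exchanging the two branch values of the per-cell term
swaps the sums exactly — p_s is bitwise invariant under the exchange
(tested), which is why no stance on the "intended" branch labelling is
needed: only orientation labels flip.

The per-cluster genotyper pools counts within each cell cluster and
takes argmax of the pooled genotype likelihood; clusters without reads
get a missing genotype.

## 6. Evaluation metrics (`scsnv.evaluate`)

Sensitivity |N∩W|/|W|, precision |N∩W|/|N|, genotype accuracy on the
intersection, overall accuracy = precision × genotype accuracy, with
call sets restricted to genotypes 1/2 keyed by (chrom, pos, ref, alt).
Array concordance counts matching alleles per locus minus the minimum
achievable (1 when either genotype is het) and by default normalises by
the attainable excess Σ(2 − min) so the score is a fraction of possible
agreement in [0, 1]; a flag switches to the raw per-locus mean, since
"normalised against the number of loci" admits both readings. Clone
concordance is |A∩B|/|A| per reference clone under best-Jaccard matching
(with an optional rank-sum enrichment pre-filter at p < 0.01 on per-cell
mutation indicators), averaged unweighted.

## 7. Ancestry projection (`scsnv.ancestry`)

GRM = R_c R_cᵀ with columns mean-centred (raw 0/1/2 lets allele
frequency offsets dominate PC1; centering is the conventional choice,
and both a disable flag and optional column standardisation are exposed
because reference implementations differ). Missing genotypes are
mean-imputed. PCA coordinates are top-K eigenvectors scaled by
√eigenvalue, sign-fixed. Projection Procrustes minimises
`‖ρ Ỹ A − Y‖²_F` over orthonormal-column A (K′ × K) and scalar ρ. With
K′ > K the quadratic term depends on A, so no single SVD solves it; a
majorisation–minimisation iteration (linearise the concave part at the
current A, solve the resulting orthogonal Procrustes subproblem by polar
decomposition, update ρ in closed form) is run from the rotation-case
optimum. A generic numerical minimiser confirms the objective to 1e-6 in
tests, and reference samples self-project close to their own map
coordinates.

## 8. Synthetic-data generator (`scsnv.simulate`)

*Panel*: haplotypes are mosaics of a small founder pool (default 8),
switching founders with probability `1 − exp(−recomb_intensity·d)` and
mutating at 1%; shared founder blocks produce r² that decays with
distance. Columns below the MAF floor are repaired by flipping randomly
chosen majority alleles. *Sample*: two mosaic haplotypes with
Poisson-distributed breakpoints. *Clones*: exact largest-remainder cell
allocation over a parent-pointer tree; a somatic allele is carried by
exactly the originating clone and its descendants, always as gain of
heterozygosity on one specified haplotype (a somatic site colliding with
a germline het is rejected — the model assumes two alleles per site in
the population).

*Per-cell reads.* Depth per cell-site is zero-inflated Poisson (mean
`mean_depth` including the zeros; zero-inflation default 0.3 emulates
expression/accessibility sparsity — real depth laws vary, so the whole
depth model is parameterised). Within a cell, reads sample a Markov
**haplotype field**: the active haplotype persists over distance with
probability `exp(−d/L)` and is redrawn fairly otherwise, with
`L = frag_corr_len` defaulting to 100 × read length. Loci within a read
length therefore share a haplotype draw except with probability ≤ 0.01
(fragment-level physical phasing), cell-sites are locally monoallelic,
and the correlation decays to independence at long range — the two-locus
cosegregation score runs from ≈ 0 below the read length to ≈ 0.5 beyond
~10 kb (tested). The long correlation length stands in for amplification
bias and allelic expression, the mechanisms that carry cosegregation
signal beyond the read length in real single-cell data; it is the
load-bearing assumption behind three-locus phasing, and data without any
such correlation would leave the three-locus model uninformative at long
range. Whole-allele dropout applies per cell-site and haplotype; each
read's allele flips with the base-error rate. Optional artifact sites
scatter alternative reads across cells with no haplotype linkage, low
base qualities, read-end positions and strand bias, to exercise the
depth/BAF and SVM filters.

What the generator does **not** emulate: read-level FASTQ/BAM output,
copy-number events and loss of heterozygosity, multi-allelic sites,
doublets, finite-library and UMI effects, or locus-specific error
profiles. Tests passing on this generator show the machinery recovers
the signals the model family assumes; they do not certify performance on
real data whose dropout and error structure differ.

## 9. Study designs and problem sizes (`scsnv.designs`)

The validation suite fixes four designs: (a) somatic recovery — 2,000
panel sites over 2 Mb (germline hets ≈ 1/kb), 40 panel haplotypes, 500
cells, mean depth 5, 0.1% errors, 10% dropout, 30 somatic SNVs placed in
the widest inter-site gaps alternating carrier haplotype, carrier
fractions 0.1–0.4; (b) germline p_s — the same conditions with true hets
probed as if de novo; (c) refinement benchmark — 800 sites with 20%
covered at pooled depth 1–2 and 1% errors, argmax GL vs argmax GP
against truth; (d) two-locus decay — 1,500 sites over 3 Mb, 400 cells.
These sizes keep any single design under a few seconds on one CPU while
leaving dozens of scored sites and thousands of neighbourhoods per bin.

## 10. Pipeline (`scsnv.pipeline`, `scsnv.cli`)

Stages: simulate → germline (GL, chunked HMM refinement, consensus,
error model) → de novo (depth/BAF filter, SVM) → somatic (profile,
phasing, classification) → evaluate. Genome chunks are refined together
with all panel sites inside an overlap margin (default 500 kb, the
largest profile bin edge and far beyond the 100 kb switching scale) and
only core results kept, making chunked and unchunked runs merge to
identical call sets (tested with 4 chunks). All randomness derives from
one seed; the manifest records the seed, a parameter hash and the full
configuration. When a simulated dataset yields no SVM negative set the
SVM stage logs a warning and passes survivors through unchanged rather
than aborting the run.

## Known limitations

* The SVM's named features approximate, but are not identical to, the
  upstream callers' annotations of the same names.
* p_s is biased upward slightly for very small carrier fractions (the
  reported channel is the max of two noisy estimates) and cannot
  separate truncal somatic SNVs with BAF ≈ 0.5 from germline hets — an
  intrinsic limit of cosegregation evidence.
* The haplotype-field correlation length is a single global parameter;
  real allelic imbalance is locus- and cell-type-specific.
* The refinement HMM refines only sites observed in the input set; it
  does not impute untyped panel sites, and panel construction itself is
  out of scope.
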