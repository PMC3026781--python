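# Methods

This note documents the models, decision rules and numerical choices behind
`mirclone`, what the synthetic-study generator does and does not emulate,
and the problem sizes used in validation.

## Read annotation

Reads are DNA-alphabet sequences (T for U, normalized at parse time) of
15–35 nt with a clone multiplicity. Classification walks the database
classes in a fixed priority — miRNA, piRNA, rRNA, tRNA, snRNA, snoRNA,
mRNA — and stops at the first class containing a valid hit; reads valid in
no database but occurring verbatim in the genome (either strand) form the
novel-candidate pool; everything else is `unmatched`. Priority is by class,
never by file order: within a class, entries are scanned in sorted-id order
and ties on identity go to the smaller id, so classifications are invariant
to how the databases were supplied.

A hit is a best ungapped sliding alignment with identity strictly greater
than 0.90. Identity is matches divided by the aligned-core length, where
the core is the read minus any 5′/3′ overhang beyond the reference ends;
each overhang may be at most 3 nt and is not penalized. When the read lies
inside the reference — the usual case for 18–24-nt reads against mature
miRNAs — the core is the whole read, so the denominator is read length.
Gaps are not modeled: small-RNA cloning produces end variation, not indels,
and at these read lengths an ungapped scan is exact and exhaustive. `N`
matches nothing.

Clone counts are normalized per 1 000 miRNA-annotated reads per sample, so
the total-form column of the expression matrix sums to exactly 1 000 in
every sample; the per-class composition of *all* reads is reported
separately. Each miRNA carries three row forms — nonmodified, modified,
total — with total = nonmodified + modified by construction.

## Hairpin folding and the precursor screen

The folder is a Nussinov-style dynamic program: maximum total pair weight
over nested pairings with G:C=3, A:U=2, G:U=1 and a minimum hairpin loop of
3 nt, O(n³) time via per-diagonal vectorization. Traceback is
deterministic: when several structures are optimal, the leftmost position
is paired rather than left single, and pairs with the rightmost admissible
partner. The score acts as a negative pseudo-energy ("lowest free energy"
maps to highest score). This is a deliberate surrogate for a thermodynamic
nearest-neighbour folder: the downstream criteria consume pairing topology
only, and the surrogate is verifiable against an exhaustive enumeration of
all nested pairings (`fold_bruteforce`), which the test suite does for 500
random sequences up to 12 nt.

Candidate loci are extended by 88 nt of genomic context per side and folded
in 110-nt windows stepped by 5 nt (the step is configurable; 5 nt ensures a
window always exists containing any plantable hairpin with both arms).
Only windows fully containing the mature locus are admissible; the
highest-scoring window wins, ties to the leftmost. Context is truncated at
genome edges rather than failing. Minus-strand loci are folded on the
reverse complement, with coordinates reported on the plus strand.

Before structural evaluation, helices with fewer than 3 stacked pairs are
pruned from the winning window's structure. Isolated pairs and 2-stacks are
thermodynamically unstable; under a pure maximum-pairing objective they
appear abundantly in random context, and pruning them plays the role of
RNAfold's no-lone-pair constraint.

The criteria are evaluated on the *stem-loop component housing the mature
span*: the anchor is the helix carrying most of the mature positions'
pairs, extended outward through single-child junctions small enough to be
precursor elements (internal loops below the internal-loop bound, bulges
below the bulge bound) and stopped at multiloops, larger junctions or the
window exterior. Without this, spurious context pairing would merge the
entire window into one component and the stem-loop test would be
meaningless under the surrogate. Within that component:

* (a) exactly one terminal loop;
* (b) more than 16 mature nt paired (counted anywhere in the fold);
* (c) terminal loop smaller than 20 nt;
* (d) every internal loop smaller than 10 nt — sizes are the *total*
  unpaired count over both sides, standard nomenclature; the published
  bound does not say per-side, and total is the stricter reading;
* (e) every bulge smaller than 5 nt.

All five bounds are parameters; weakening a bound can never turn a pass
into a fail (property-tested).

Conservation: all paired positions of the component are mapped to genomic
coordinates, grouped into maximal runs of consecutive positions, and every
contiguous 15-nt sub-window inside a run is averaged against the per-base
conservation track; the locus is conserved when the best mean is ≥ 0.8.
Runs shorter than 15 nt yield the explicit flag `stem-too-short`.

## Discovery cascade

Genome-class reads are merged into candidate loci by single-linkage overlap
(≥ 1 nt, strand-aware); a group's representative sequence is its highest
total clone count, ties to the lexicographically smallest. Groups below the
support threshold (default 2 clones, to suppress singleton sequencing
errors) are rejected as `low-support`. The cascade is exclusive and
ordered:

1. overlap with a known precursor on the same strand: `opposite` if the
   candidate lies on the far side of the precursor's terminal-loop midpoint
   from the annotated mature (the precursor is folded to locate the loop),
   otherwise rejected as `overlaps-known`; opposite products are not
   re-folded — their precursor is already accepted;
2. overlap with a known mature locus on the other strand: `antisense` if
   the candidate's own-strand context passes (a)–(e); conservation is not
   required, since the locus is the same chromosomal region;
3. no overlap with any known locus: `novel` if (a)–(e) pass and the stem is
   conserved; structure failures are reported as the first failing
   criterion, conservation failures as `not-conserved`. Candidates that
   pass structure but lack a conservation track are rejected with
   `no-conservation-track` (novel calls require the track).

## Modification (editing) profiling

Reads annotated to a mature miRNA are re-aligned to it 5′-anchored with
offsets −2..+2 (offset 0 preferred, then smaller magnitude); reads below
90% identity at every offset, or with more than 2 substitutions in the
profiled range, are excluded as probable artifacts. Positions are numbered
+1 from the reference 5′ end; only +1..+18 within the shared 3′ extent are
profiled, because 1–3 nt of 3′-end variation is a normal biogenesis product
and must not be called as modification. A→G is reported as A→I (inosine
base-pairs like guanosine in sequencing), and T is rendered as U in class
labels (U→C, U→A, C→U, ...). Calls in the seed region (+2..+8) carry a
seed flag; they never affect annotation class, which is already tolerant
above 90% identity.

Per group, the modified fraction at a site is edited clones over clones
covering that position; groups with fewer than 10 clones (configurable) get
undefined (NaN) fractions, and a site is reported when some group reaches
the 5% reporting threshold. An optional SNP mask (positions to exclude)
replaces database lookups of known polymorphisms; no fraction-based SNP
heuristic is applied, because genuinely ~100% edited sites exist and would
be silently discarded.

## Expression statistics

* Prevalence filter: drop miRNAs expressed (nonzero) in fewer than 25% of
  samples; exactly 25% is retained ("fewer than" is strict).
* Clustering: samples are clustered by average linkage on
  1 − Pearson correlation of log2(normalized + 1) profiles (clone counts
  are heavy-tailed; the transform keeps single abundant miRNAs from
  dominating). Undefined correlations (constant profiles) become distance
  1 with a warning. A flat cluster (cut at k, default 3) is flagged high
  risk when all members are tumors and their mean raw normalized marker
  expression exceeds the threshold (default 250 per 1 000); the marker is
  configurable.
* SAM: d_i = (mean paired difference)/(s_i + s0) on log2(x+1), with s0 the
  5th percentile of the per-gene standard errors (simpler than the original
  coefficient-of-variation grid; the percentile choice is exposed). The
  null comes from sign flips of pair differences (balanced label
  permutations in unpaired mode), fully enumerated when there are ≤ 2¹²
  flips. Observed order statistics are compared with the mean permuted
  order statistics; delta is the smallest band width at which the estimated
  number of false positives is zero, and genes beyond the resulting cut
  values are significant. The false-positive estimate is the 0.99 quantile
  of per-permutation counts beyond the cuts rather than the median: the
  observed extreme is exchangeable with permutation extremes, so a median
  rule would still call the top gene in about half of all global-null
  data sets, which is not what a zero-false-positive threshold should do.
  Validated behaviour (also recomputed by the acceptance script): zero
  significant genes in ≥ 95% of 200 global-null simulations, and ≥ 0.9
  sensitivity for 4-fold planted genes at 18 vs 18 paired samples
  (200 genes, 100–200 permutations).
* Paired t: scipy's paired t on log2(x+1); all-zero difference rows are
  reported as t=0, p=1 and flagged; constant nonzero differences give an
  undefined p, flagged.
* Enrichment: two-sided Fisher exact per term on the 2×2 membership table,
  ranked ascending by p; verified against exhaustive hypergeometric
  enumeration for all margins ≤ 30 in the tests.

## Clinical analyses

* ROC: thresholds at every distinct value, classification by oriented
  value ≥ threshold — markers carry an orientation flag because a
  down-regulated marker predicts disease by *low* values. The per-cut-off
  table reports sensitivity, 1−specificity, PPV, NPV, LR+, LR− and
  accuracy; the trapezoid AUC equals the Mann-Whitney U statistic divided
  by n₁n₂ exactly, including ties.
* Kaplan-Meier: product-limit with right censoring; at tied times deaths
  are counted before censorings.
* Log-rank: the standard (O−E)²/V chi-square with 1 df; zero variance
  (no usable event times) is flagged rather than divided through.
* Cox: Newton-Raphson on the Breslow partial likelihood (Efron available),
  step-halving so the likelihood never decreases, at most 50 iterations.
  Convergence is declared when the gradient drops below 1e-8 or the
  parameter update stalls below the same tolerance — with ~2000 subjects
  the cumulative risk-set sums floor the attainable gradient near n·ε, so
  a gradient-only criterion would spuriously fail. Standard errors come
  from the inverse observed information and p-values are Wald. Monotone
  likelihoods (perfect separation) are detected by coefficient blow-up or
  a non-positive-definite information matrix and raised as errors naming
  the covariate.

## The synthetic study

The generator builds a single 100-kb chromosome (desk-scale, exhaustively
scannable) carrying, at ≥ 300-nt spacing: 30 known miRNA precursors, 10
un-annotated novel hairpins, and 50 decoy loci (tRNA/rRNA/snRNA/snoRNA
fragments at realistic lengths and 26–31-nt piRNAs). Precursors are built
as arm + loop + reverse-complement arm with a 2-nt mismatch block near the
arm base (one small internal loop, leaving a ≥ 15-nt contiguous paired run
on each arm for the conservation window). Arms are GC-biased (40% C, 40% G)
and loops are poly-A so the planted stem is the clearly dominant optimum of
the pairing surrogate; near-repetitive arms can still be shift-degenerate,
so every hairpin the pipeline must later fold — the novel loci, and the
antisense targets on the minus strand — is verified against the hairpin
module in its actual genomic context at planting time and redrawn if it
fails (at most 40 tries; typically none or one). The conservation track is
locus-constant with Gaussian jitter (σ=0.05, clipped to [0,1]): 0.9 over
known precursors, 0.95 over novel hairpins, 0.2 over decoys and background.

Libraries are 2 000 reads per sample over 22 tumor/normal pairs. The class
budget is 80% known-miRNA reads, 14% decoys (piRNA sources down-weighted
×0.1 — their 18–24-nt truncations are rare in the size-selected fraction),
3% novel, 2% opposite-arm and 1% antisense reads. Per-miRNA abundances are
log-normal, with the marker miRNA pinned at 8% and the down-regulated
liver miRNA at 12% of the library in normal tissue. Tumor samples apply
configured log2 fold changes (marker +1.0, down-regulated −2.0, one extra
+1.5); the 5 high-risk tumors additionally boost the marker ×2.5 (taking it
above the 250-per-1000 flag threshold) and carry an 8-miRNA ±2 log2
signature so that correlation clustering can isolate them. Every source
weight gets per-sample log-normal jitter (σ = 0.5 log2 units) for
biological variability; per-sample counts are multinomial. Reads take a 3′
trim of 0–3 nt (probabilities 0.55/0.25/0.15/0.05, keeping lengths in
18–24), then per-rule editing (three planted sites: A→G at +6 with rates
0.31/0.50 tumor/normal, C→A at +10 at 0.96/1.00, U→A at +17 at 0.74/0.78),
then uniform substitution errors at 0.002 per base. Identical
(sample, sequence) reads collapse into one FASTA record with a
`count=` attribute.

Clinical outcomes: recurrence times are exponential with baseline hazard
0.02 per month (mean 50 months), multiplied by 8 for high-risk-cluster
patients (mean 6.25 months — the order-of-magnitude contrast of an
aggressive subgroup); censoring is independent exponential calibrated to a
0.2 expected censored fraction, and five binary pathological covariates
plus age are drawn independently of the cluster. Everything derives from
the config seed through fixed per-stage offsets, so identical configs give
byte-identical files and clinical labels match whether or not reads are
simulated.

What the generator does **not** emulate: ligation/PCR bias, platform error
profiles (e.g. homopolymer miscalls), multi-chromosome genomes, isomiR 5′
heterogeneity beyond the ±2 alignment window, correlated pathological
covariates, or real sequence composition of miRNA families. Passing tests
therefore demonstrate that the decision rules are implemented correctly and
recover signals of the planted kind at desk scale — not that the pipeline
is robust to every artifact of real libraries.

## Validation sizes

The test suite and the acceptance script use: 500 random sequences ≤ 12 nt
against the exhaustive folding oracle; 1 000 random conservation tracks
against an all-windows scan; the full default study (44 samples × 2 000
reads) for annotation, discovery, editing, clustering and survival; 200
global-null and 10 planted-effect SAM simulations at 18 vs 18; 100 random
ROC data sets; 200 hazard-ratio-1 clinical simulations for log-rank
uniformity; and 5 × 2 000-subject cohorts for Cox parameter recovery.
These sizes make the whole validation run in a few minutes on one CPU
while keeping Monte-Carlo error well inside the asserted margins.

## Known limitations

* The folding surrogate maximizes pair weight, not free energy; its
  structures agree with a thermodynamic folder in decision-relevant
  topology for strongly paired hairpins but not in detail. A plug-in
  folder can replace it wherever a `FoldResult` is accepted.
* Opposite-arm classification trusts the known-precursor annotation and
  does not re-fold; a mis-annotated precursor propagates.
* The SAM s0 default (5th-percentile) is a documented simplification of
  the original tuning grid.
* Expression normalization is per 1 000 *miRNA-annotated* reads; if the
  non-miRNA fraction differs systematically between groups, per-total-read
  normalization (available from the composition table) may be preferable.
* Survival tooling covers right censoring only: no time-dependent
  covariates, competing risks or proportionality diagnostics.
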