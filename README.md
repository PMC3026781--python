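# mirclone

Clone-count small-RNA sequencing analysis for miRNA profiling studies.

In cloning/sequencing-based miRNA studies — for example comparing
hepatocellular carcinoma (HCC) tissue against adjacent normal liver (ANL) —
the complete sequence of every cloned small RNA is known, so a single
experiment supports several analyses at once: annotation of each read
against reference databases, discovery of novel miRNA precursors from
genome-matched but un-annotated reads, detection of RNA modifications such
as A-to-I editing from per-position base changes, expression profiling by
clone counts, and stratification of patients by their expression profiles.
`mirclone` implements this whole pipeline as a tested, reusable library
with a thin command-line front end, plus a synthetic-study generator so
every stage can be exercised end-to-end without any external database.

It is aimed at people building or evaluating small-RNA analysis pipelines:
each stage is an ordinary Python function over pandas/numpy containers with
explicit, documented decision rules.

## The methods at the core

* **Annotation.** Each read is compared to reference sets in a fixed class
  priority (miRNA, piRNA, rRNA, tRNA, snRNA, snoRNA, mRNA, then the
  genome); a hit is valid when a best ungapped alignment has identity
  strictly above 90%, allowing ≤ 3 nt of unpenalized 5′/3′ end variation.
  Reads matching only the genome (at 100%) are novel-miRNA candidates.
  Clone counts are normalized per 1 000 miRNA-annotated reads per library.
* **Hairpin screen.** Candidate loci get 88 nt of genomic context per side
  and are folded in sliding 110-nt windows with a maximum-weighted nested
  pairing model (G:C=3, A:U=2, G:U=1, minimum loop 3). The best window is
  screened with the classic precursor criteria: (a) a single stem-loop,
  (b) > 16 nt of the mature sequence paired, (c) terminal loop < 20 nt,
  (d) internal loops < 10 nt, (e) bulges < 5 nt, and a conservation test —
  some 15-nt stem window with mean per-base conservation ≥ 0.8.
* **Discovery cascade.** Overlapping same-strand candidate reads are merged
  (single linkage) and each locus is classified as *opposite* (other arm of
  a known precursor), *antisense* (opposite strand of a known miRNA locus,
  own-strand hairpin required, no conservation needed), *novel* (isolated,
  hairpin + conserved), or *rejected* with the first failing reason.
* **Editing.** Reads are re-aligned 5′-anchored to their mature reference;
  substitutions at positions +1..+18 are called per position (A→G reported
  as A→I), with per-group modified-read fractions, and the expression
  matrix is split into nonmodified / modified / total rows.
* **Statistics.** Prevalence filtering (drop miRNAs expressed in fewer than
  25% of samples), average-linkage clustering on 1 − Pearson correlation of
  log2 profiles with a high-risk-cluster flag (all-tumor cluster with mean
  marker expression > 250 per 1 000), the SAM permutation statistic
  d_i = (x̄₁ − x̄₂)/(s_i + s₀) with a zero-false-positive delta, paired
  t-tests, and Fisher 2×2 enrichment.
* **Clinical.** ROC cut-off tables (sensitivity, 1−specificity, PPV, NPV,
  likelihood ratios, accuracy; trapezoid AUC = Mann-Whitney U/(n₁n₂)),
  Kaplan-Meier curves, the log-rank test, and Cox proportional-hazards
  regression (Newton-Raphson partial likelihood, Breslow ties).

## Worked example

```python
from mirclone.synth import SimConfig, simulate_study
from mirclone.annotate import Annotator, ReadRecord, annotations_to_frame, count_and_normalize
from mirclone.editing import profile_all
from mirclone.discover import discover
from mirclone.stats import cluster, prevalence_filter, sam_test
from mirclone.clinical import logrank

cfg = SimConfig(seed=1)                      # 22 HCC/ANL pairs, 2000 reads each
truth, records, clinical = simulate_study(cfg)

dbs = {"miRNA": truth.mature_seqs}
for cls in ["piRNA", "rRNA", "snRNA", "snoRNA", "tRNA"]:
    dbs[cls] = {d: s for d, (c, s) in truth.decoy_entries.items() if c == cls}
annotator = Annotator(dbs, truth.genome)
reads = [ReadRecord(r, s, a["sample"], int(a["count"])) for r, s, a in records]
frame = annotations_to_frame(reads, annotator.classify_reads(reads))

groups = dict(zip(truth.sample_sheet.sample_id, truth.sample_sheet.group))
pairs = dict(zip(truth.sample_sheet.sample_id, truth.sample_sheet.pair_id))
sites, modified = profile_all(frame, truth.mature_seqs, groups)
norm, composition = count_and_normalize(frame, modified)
print("miRNA fraction of clones:", round(composition.loc["miRNA"].mean(), 3))

known = truth.loci[truth.loci.cls.isin(["known-precursor", "known-mature"])]
calls = discover(frame, known, truth.genome, truth.conservation)
print("candidate calls:", calls.call.value_counts().to_dict())

a2i = sites[(sites.mirna == "mir-03") & (sites.position == 6)]
print("A->I fraction at +6 of mir-03:",
      {g: round(f, 3) for g, f in zip(a2i.group, a2i.fraction)})

totals = norm.xs("total", level="form")
sam = sam_test(prevalence_filter(totals), groups, pairs, n_perm=1000, seed=1)
print("SAM significant miRNAs:", len(sam.significant), "delta:", round(sam.delta, 2))

res = cluster(prevalence_filter(norm.drop("total", level="form")), groups,
              marker="mir-01", marker_threshold=250)
hr = clinical.sample_id.isin(res.high_risk_samples).astype(int)
print("log-rank p (recurrence, high-risk vs rest):",
      round(logrank(clinical.time_months, clinical.event, hr).p, 5))
```

Output:

```
miRNA fraction of clones: 0.812
candidate calls: {'opposite': 15, 'novel': 10, 'antisense': 3}
A->I fraction at +6 of mir-03: {'ANL': 0.525, 'HCC': 0.273}
SAM significant miRNAs: 3 delta: 3.57
log-rank p (recurrence, high-risk vs rest): 0.0002
```

Reading it: roughly 80% of simulated clones annotate as known miRNAs, as in
real liver libraries. All 10 planted novel hairpins, all 15 opposite-arm
products and all 3 antisense loci are recovered, and none of the 50 decoy
loci (t/r/sn/sno/piRNA fragments) is called novel. The planted A→I editing
site (true rates 0.31 in tumor, 0.50 in normal) is estimated from clone
counts at 0.27 / 0.53. SAM at its zero-false-positive delta flags the three
strongest planted fold changes, clustering isolates the planted high-risk
tumor subgroup, and those patients recur significantly earlier.

The same pipeline runs from the shell on a run directory:

```sh
mirclone simulate --outdir run --seed 1
mirclone all      --outdir run --seed 1     # annotate .. clinical
```

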