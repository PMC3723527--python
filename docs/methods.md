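# Methods

This note documents the models, rules and numerical choices behind
`exonsplice`, the assumptions they rest on, and what the synthetic-data
tests do and do not establish.

## Gene-level normalization and the splicing index

Exon-array splicing analysis asks whether one exon's signal changes
*relative to its gene*. All intensities are kept on the log2 scale. For
each gene and sample we estimate gene-level expression as the 10%-trimmed
mean of the gene's constitutive probe-sets — those whose target region
lies inside every annotated isoform. The trim guards against a single
aberrant constitutive probe-set; for fewer than ten probe-sets the trim
count rounds to zero and the estimate is the plain mean. Genes without
any constitutive probe-set cannot be normalized and are dropped with a
warning.

The normalized intensity of probe-set *p* in sample *s* is
`NI(p, s) = log2 intensity(p, s) − gene estimate(g(p), s)`, and the
splicing index between conditions A and B is the difference of group-mean
NIs, i.e. the log2 ratio of gene-normalized exon signal. Two exact
properties follow and are enforced by tests: adding a constant to all of a
gene's probe-sets in one sample leaves NI unchanged (whole-gene expression
shifts, including subject-level intercepts, cancel), and in the noise-free
limit the SI of a planted inclusion shift of *e* log2 units equals *e*.

## Detection filtering

Probe-sets must be detected above background (DABG p < `alpha`, default
0.05) in at least `min_fraction` of samples (default 1.0, i.e. all
samples) before analysis. The filter is idempotent. Because published
descriptions of this filter are sometimes ambiguous about its direction,
the literal inverted reading (keep *undetected* probe-sets) is reachable
via `keep_undetected=True` / `--dabg-keep-undetected`, but the default is
the standard one. An optional annotation-tier filter (`tier_filter`)
restricts to "core" probe-sets when the map file carries a tier column;
synthetic maps mark everything core.

## Exon-level tests and the event cascade

Differential inclusion is tested per probe-set on NI with

* a two-sided Welch t-test (unpaired) or a paired t-test matched by
  subject id (paired designs must pair completely; unpaired subjects are
  an error), and
* a one-way ANOVA on the group factor (for two groups this is the pooled
  t-test squared, which the suite asserts to 1e-12).

An event is called when all hold (defaults in `Thresholds`):

| gate | default | meaning |
|---|---|---|
| `si_min` | 1.0 | at least two-fold change in gene-normalized signal |
| `p_max` | 0.05 | raw p, t-test *or* ANOVA may pass |
| `fdr_max` | 0.05 | Benjamini–Hochberg q over the comparison's t-test p-values |
| `max_gene_fold` | 3.0 | gene-level linear fold change gate, applied two-sidedly |

The BH family is all probe-sets tested within one pairwise comparison.
The gene-fold gate excludes genes whose overall expression moves more than
three-fold between the conditions, since such transcription-level changes
make exon-level ratios uninterpretable.

Degenerate rows are resolved explicitly: when within-group variance is
numerically zero (below 1e-8) the p-value is 0 if the group means differ
by more than 1e-8 and 1 otherwise. This makes the noise-free limit behave
correctly in both directions — planted events are always significant,
while floating-point dust (e.g. the 1e-16 residue left after gene-level
cancellation of a confounder) can never pass the filters.

## FIRMA

FIRMA fits the RMA-style additive model
`y[probe, sample] = μ + probe + chip + ε` to all probes of a gene by Tukey
median polish and scores each probe-set per sample as the median of its
probes' residuals divided by a robust scale.

Numerical choices: median polish runs at most 20 sweeps to tolerance 1e-6
(each sweep removes row medians, re-centres row effects by their median
into the overall term, then does the same for columns); it is
deterministic, which an IRLS robust fit would not guarantee. The scale is
1.4826 × MAD over all the gene's residuals, floored at 1e-8; median
residual magnitudes below 1e-10 are treated as exact zeros so that data
generated exactly by the additive model score exactly zero. When no
probe-level matrix exists, FIRMA degrades to one "probe" per probe-set —
the fit then pools the gene's probe-sets, which loses the within-probe-set
median but preserves the deviation logic; this is a documented limitation,
not an error.

FIRMA effects (difference of group-mean scores) are filtered through the
same cascade as SI. The score is in robust-SD units rather than log2
units, so the shared `si_min` default of 1.0 means "one robust SD", a
deliberately loose analogue. SI and FIRMA event sets overlap but need not
coincide; the suite asserts only that both recover strong planted signal.

## Consequence prediction

Events are mapped onto annotated isoforms structurally, from CDS
annotations alone. Isoforms are partitioned into those containing the
event region (≥ 50% of the region exonic; regions straddling a boundary
are assigned by majority overlap) and those lacking it, and every
(with, without) pair contributes evidence. The isoform favored in the
test condition is the "with" isoform for inclusion events and the
"without" isoform for exclusion events.

* **NMD**: the favored isoform's stop lies strictly more than `nmd_nt`
  (default 50) nucleotides upstream of its final exon–exon junction in
  spliced coordinates, and the other isoform's does not. Single-exon
  transcripts are never NMD-eligible; isoforms whose CDS length is not a
  codon multiple are flagged invalid and excluded from NMD evidence.
  Raising `nmd_nt` can only remove NMD calls (tested monotonicity).
* **truncation**: favored protein length ≤ `truncation_ratio` (default
  0.5, inclusive) times the other protein's length. Protein length is
  `CDS/3 − 1` residues (stop codon excluded).
* **altN / altC**: the CDS 5′ (3′) genomic anchors differ while the other
  end is shared. When both ends differ the call is {altN, altC}, never
  alt_coding.
* **intron retention**: the event region lies inside an intron of the
  non-favored isoform and that entire intron is exonic in the favored one.
* **alt_coding**: both termini shared, internal CDS structure different.

The call on an event is the union over isoform pairs, with per-pair
evidence (PTC distance, protein ratio) retained — events with multiple
functional predictions are expected and summarized (`frac_multi`).

A sequence-level mode (deriving a missing minor-isoform ORF by splicing
and translating) was considered and omitted: within this package's scope
every isoform carries an annotated CDS (the generator guarantees it), so
structural comparison is complete and a translation path would be dead
code.

## Classification

Samples are clustered agglomeratively on a feature × sample matrix —
gene-normalized intensities (or FIRMA scores) of the NMD-predicted
probe-sets. Features are mean-centered across samples first (the standard
relative-level heatmap convention); clustering then sees each group's
signature mirrored in the other, which matters because correlation
distance is blind to signatures that are pure per-sample offsets.
Distance is `1 − Pearson` between sample vectors (Euclidean available;
with a single feature correlation is undefined and the code falls back to
Euclidean with a warning), linkage is average, and the tree is cut at the
root into two groups. Misclassification is the minimum mismatch count
over the two cluster-to-label assignments, hence at most ⌊n/2⌋. Constant
sample vectors under correlation distance raise an error suggesting
Euclidean. Dendrograms are exported as newick.

## The synthetic world

The generator emulates the statistical structure the analysis assumes —
not raw array physics. Per probe-set log2 intensity is

```
baseline(gene) + affinity(probe-set) + intercept(sample)
  + effect(probe-set, group) + confounder(gene, group) + N(0, noise_sd)
```

with defaults: baseline N(8, 1.5²) (typical RMA post-summarization
scale), probe-set affinity N(0, 0.4²) fixed across samples, per-sample
intercept N(0, 0.5²) shared between a subject's case and post-treatment
samples (a subject random intercept), planted effect ±2.0 log2 units in
the case group, whole-gene confounder shifts of ±1.0 on 10% of event-free
genes, and noise SD 0.25. Cohorts default to 8 control + 8 case samples
(the scale of the source cohorts: 7 patients/6 controls in-house, 17/11 in
the public whole-blood set), with an optional paired post-treatment group
in which planted effects revert to baseline — treatment modeled as
reversal of the disease state. A consequence of reversal is that the
treatment contrast carries NMD calls when oriented with the disease state
as the test condition (case vs post); the orientation changes signs only.
10% of probe-sets are unexpressed decoys (DABG p ≥ 0.5) exercising the
detection filter. Probe-level matrices (4 probes/probe-set, probe offsets
N(0, 0.4²)) are generated on request for FIRMA.

Planted events are engineered per consequence class so the true label set
follows from construction arithmetic, independent of the classifier:
cassette exons whose annotated stop lands > 50 nt upstream of the final
junction (NMD; inclusion- and exclusion-triggered variants alternate
deterministically so both directions appear, as real cohorts show),
isoform pairs with ≤ half-length coding regions (truncation), alternative
first/last exons (altN/altC), in-frame retained introns, and in-frame
cassettes (alt_coding). Several constructions intrinsically carry a
second label (an NMD stop change also changes the C-terminus; a retained
in-frame intron also recodes), and the truth table records the full set.
Everything is deterministic given the seed, to the byte.

What the generator does **not** emulate: scanner artifacts, batch
effects, probe cross-hybridization, GC/affinity sequence effects,
correlated biological variation between genes, or partial (mixed-tissue)
inclusion levels. A green recovery test therefore establishes that the
statistics and rules are implemented correctly, not that the pipeline is
robust to real-array noise structure.

## Known limitations

* MiDAS is implemented as its published gloss — one-way ANOVA on
  gene-normalized intensities; the proprietary variance model is out of
  scope.
* FIRMA on probe-set-level data (no probe matrix) is a degraded mode.
* NMD prediction covers splicing-generated PTCs only; uORF- and
  long-3′UTR-triggered NMD are out of scope.
* Real-cohort event counts from the source studies are not reproducible
  at desk scale (they depend on specific array annotations and genome
  builds); validation is property-based on the synthetic world.
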