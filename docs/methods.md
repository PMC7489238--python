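# Methods

`promin` statistically compares a *foreground* set of protein sequences
(the proteins of interest, POI set — e.g. a biomineral matrix proteome)
against a *background* proteome. Every statistic is a two-set comparison:
the question is never "is this protein unusual?" but "is this feature of
the POI set unusual *given this proteome*?". This note documents the
models, the defaults and why, the synthetic-data conditions used for
validation, and the numerical choices that make runs reproducible.

## Sequence model and alphabet

Sequences are uppercase strings over the 20 standard amino acids.
Gene-model proteomes contain ambiguity and non-standard codes, so
`X B Z U O *` are tolerated on input but excluded from every count:
they contribute to no frequency, match no motif position (not even the
wildcard), and carry no entropy or disorder propensity. Frequencies are
pooled over residues (concatenation semantics), not averaged per protein,
so a long protein contributes proportionally to its length.

## Motif discovery

The discovery engine is an iterative binomial position/residue fixing
procedure in the style of motif-x. For each of the 20 amino acids in
turn, windows of odd width *w* (default 7) are extracted around every
occurrence of that residue in both sequence sets; flanks that run off a
sequence end are padded with a character that matches nothing, so edge
windows cannot support fixing beyond the sequence. Starting from the bare
centre, the procedure repeatedly evaluates every open (position, residue)
pair: with k = foreground windows carrying residue r at position j,
n = current foreground window count and p = the proportion of the
*current* background windows with r at j, the score is the binomial tail
P(X ≥ k), X ~ Bin(n, p). The minimum-p pair is fixed when its tail
probability clears the threshold (default 1e-6, deliberately
conservative) and its foreground support is at least the minimum
occurrence count (default 5); both window sets are then restricted to the
matching windows and the scan repeats. Background base rates are
recomputed from the restricted background at every step. Ties break by
lowest p, then highest fold enrichment, then lexicographic (position,
residue), so discovery is fully deterministic. When no pair qualifies,
the fixed positions spell a motif; its matched foreground windows leave
the pool and the search restarts, letting one centre yield several
motifs.

Motifs from all centres are pooled and *collapsed*: flanking wildcards
are trimmed and exact duplicates removed (shifted variants such as
`..S.S..` and `.S.S...` both reduce to `S.S`). Collapsed motifs are then
enumerated in both sets, counting every match start (overlaps included —
repeats like `GG` in polyglycine are the signal here, not an artefact;
non-overlapping counting is available behind a flag).

Two enrichment definitions are computed and written side by side,
because a single "fold enrichment" number is genuinely ambiguous for
motif counts:

* **density enrichment** — (fg occurrences / fg residues) ÷
  (bg occurrences / bg residues); robust to length differences and the
  definition used for ranking;
* **protein-fraction enrichment** — (fg proteins / |fg|) ÷
  (bg proteins / |bg|).

A motif present in the foreground but absent from the background is
flagged infinitely enriched rather than given an arbitrary large number.
The **PS-value** combines support and unusualness: foreground protein
count and density enrichment are min–max scaled to [0, 1] across the
finite-enrichment motifs and multiplied. When a measure is degenerate
(all motifs equal, including the single-motif case) it scales to 1.0 so
the product still reflects the other measure; infinitely enriched motifs
get no PS-value.

A practical note on strong spikes against small backgrounds: because the
restricted background can be exhausted after a few fixing steps (base
rates become 0/0), a literal k-mer wholly absent from the background is
typically reported as two or three overlapping sub-motifs (e.g. `CWCW`
and `WCWH` for a spiked `CWCWH`) rather than one full-width pattern.
Each sub-motif still matches every spiked sequence, so recovery is
assessed by pattern-in-literal matching, not string equality.

## Compositional bias

Per-residue enrichment is log2(fg frequency / bg frequency).

**Biased regions** are found by an exhaustive minimal-p
contiguous-subsequence scan: for each residue type, every window of
length ≥ 5 (capped at 1,000 residues to bound cost on giant proteins) is
scored by the binomial tail of its residue count at the background
frequency, and the minimum-p window per residue type is reported when it
clears the reporting threshold (default 1e-3; the clustering filter uses
1e-20). For a fixed window length the minimum p is attained at the
maximum count, which reduces the scan to one sliding maximum per length
— exhaustive and exact, unlike seed-and-extend heuristics. Ties resolve
to the earliest, then shortest window. Tail probabilities that underflow
double precision are floored at the smallest positive double so the
p ∈ (0, 1] contract holds; threshold comparisons are unaffected.

The **bias index** BI = Σ_aa |fg freq − bg freq| quantifies overall
compositional bias; it is symmetric, bounded by [0, 2] and zero iff the
vectors are equal. Its significance is estimated against an empirical
null: BI values of 1,000 without-replacement samples of the background,
each with the foreground's cardinality, smoothed by a Gaussian KDE
(Silverman bandwidth) and integrated (trapezoid, 2,048-point grid) above
the observed BI over [min null − 3h, max null + 3h]. This tests bias
*per se*: a foreground mixing several different bias types is still
detected, with no assumption that all foreground proteins share one
residue-frequency distribution. Note the null degenerates when
|fg| = |bg| (every sample is the whole background); the test is meant
for proper subsets.

## Low complexity, disorder, and their comparison

**Low-complexity segmentation** slides a 12-residue window and computes
Shannon entropy of its residue composition; windows at or below the
trigger entropy (2.2 bits) seed segments, which extend across contiguous
windows at or below the extension entropy (2.5 bits); overlapping or
adjacent segments merge. These are the canonical defaults of
entropy-based segmentation. The classic final refinement stage (minimal
probability subsegment trimming) is omitted: the downstream statistic is
percent coverage per protein, which is insensitive to exact segment
boundaries, and omitting the stage keeps the implementation exactly
checkable against a brute-force window-scan oracle.

**Disorder** uses a pluggable per-residue scoring contract. Trained
disorder predictors are not reimplemented here; the default is
transparent and fast: the TOP-IDP disorder-propensity scale (Campen et
al. 2008) mapped linearly to [0, 1] and smoothed with an edge-truncated
21-residue sliding mean. Scores from a genuine trained predictor can be
injected via a TSV (`protein_id, position, score`) and pass through
unchanged. A residue is called disordered at score ≥ 0.5 (the
conventional midpoint), and each protein is summarised as percent
disordered. Default scores are a propensity summary, not a prediction of
equal quality to a trained model — comparisons between two sets remain
meaningful because both sets are scored identically, but absolute
percentages should not be compared against published predictor output.

Foreground and background distributions of percent low complexity and
percent disorder are compared with a two-sided **Wilcoxon rank-sum
test** using the normal approximation with midranks, tie-corrected
variance and a sign-aware 0.5 continuity correction (the convention of
R's `wilcox.test`, reproduced to ~1e-10). Exhaustive enumeration shows
this approximation deviates from the exact permutation p by at most
0.0375 over all configurations with both samples ≤ 7, and by less than
0.03 wherever the exact p ≤ 0.3; at realistic sample sizes the
approximation is essentially exact. Fully tied data yields p = 1 with a
warning.

## Charged clusters

Positive clusters count K and R; negative clusters count D and E;
histidine is treated as uncharged. A 30-residue window seeds a cluster
when the binomial tail of its charged count, at the background
proteome's frequency of that charge class, falls below alpha (default
1e-3); overlapping seed windows of one sign merge into maximal clusters.
Because any window overlapping a dense charge run can be individually
significant, merged cluster spans extend up to a window length beyond
the run itself; the per-set summary statistic — the proportion of
sequences containing at least one cluster of each sign — is unaffected
by this span convention.

## Clustering by motif content

Foreground proteins are described by two protein × motif matrices:
occurrence counts, and per-protein density enrichment
((count / protein length) ÷ (bg occurrences / bg residues) — the cell
value is a design choice; counts are the unambiguous layer). Pairwise
similarity is the Székely distance correlation of matrix rows, computed
by double-centring the pairwise-distance matrices; 1 − dcor is the
clustering distance. A constant row (motif-free protein) is defined to
have dcor 0 — maximally uninformative. One inherent caveat: dcor is
invariant to affine maps, so two *perfectly complementary* binary
signatures ([1,1,0] vs [0,0,1]) are maximally dependent and land at
distance 0; real data with more than two motif patterns per protein
breaks this degeneracy (the validation fixture therefore includes a
shared anchor motif).

Five filters select what is clustered, in order: (1) keep proteins
containing a biased region at p < 1e-20; (2) remove infinitely enriched
motifs; (3) remove motifs present in fewer than 3 foreground proteins —
active only for the first heatmap and only when the foreground holds
more than 10 proteins; (4) keep the 70 most enriched motifs (ties: more
foreground proteins, then pattern order); (5) keep proteins whose best
dcor to another protein, computed on the post-filter-4 enrichment rows,
exceeds 0.65. Heatmap 2 skips filter 3; heatmap 3 shares heatmap 2's
selection but displays counts. Every dropped protein and motif is
recorded with the filter that dropped it. An everything-filtered outcome
is a valid empty result, not an error.

Agglomeration uses **Ward.D**: the Lance–Williams update applied to the
unsquared dissimilarities, the classic `hclust` convention (Ward.D2,
which squares first, is available behind a flag). Merges break ties
lexicographically, so trees are deterministic. The number of clusters is
explored — not chosen — via the **C-index**
(S − S_min)/(S_max − S_min) over k = 2..50, where S sums within-cluster
pairwise distances and S_min/S_max sum the equally many smallest/largest
distances overall; lower is better, the profile is written out, and the
cut (default k = 8) remains a judgement for the analyst.

## Synthetic data: what it emulates and what it does not

The generator draws i.i.d. sequences with lengths from a geometric-like
law (floor 50 residues, truncated at five times the mean — a heavy right
tail resembling real proteome length distributions) and residues i.i.d.
from a stated frequency vector. Spiking inserts exactly one copy of a
literal motif into a chosen fraction of sequences at a random internal
offset (insertion, not overwrite, so non-spiked positions keep the
background composition), and returns a truth table of ids and positions.
Negative controls are without-replacement samples of the background.
Replicate seeds derive from a master seed by a fixed documented rule
(`(master · 100003 + 7919 · (i+1)) mod (2³¹ − 1)`).

What the fixtures do **not** emulate: homology and domain structure,
repeat expansions, position-dependent composition, or correlated motif
occurrences. Passing tests on this synthetic material therefore
demonstrates statistical correctness and calibration of the machinery —
a spiked motif is found, a null foreground yields nothing, the bias
p-value is uniform-ish under the null — not biological performance on
real proteomes.

## Validation conditions and problem sizes

The package's own acceptance checks run at desk scale: spike recovery on
100 sequences of mean length 300 with a rare 5-mer spiked into half;
negative controls as five 100-protein foregrounds from a 2,000-sequence
background; bias-test calibration over 50 null replicates of 1,000
bootstrap samples each. These sizes give stable outcomes (binomial
s.d. arguments put all checked quantities many s.d. away from their
failure thresholds) while keeping a full validation run in minutes.
Reproduction of the published limpet shell-matrix numbers additionally
needs the original 381-protein foreground and the JGI filtered
gene-model background, which are distributed by their original sources
and not with this package; the corresponding test states where to place
the files.

## Known limitations

* Motifs are fixed-width with single-residue wildcards: no gaps, no
  residue classes, no position-weight matrices.
* Per-step binomial p-values are conservative and uncorrected across
  motifs; downstream analyses rely on enrichment, not on the p-values.
* The default disorder scores are a propensity summary (see above).
* Charge clusters use a single window length and ignore mixed-charge
  configurations.
* fLPS-style multi-residue bias signatures are out of scope; biased
  regions are single-residue.
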