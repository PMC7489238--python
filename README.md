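# promin

Statistical comparison of two protein sequence sets: a *foreground* set
of proteins of interest (POI set) against a *background* proteome.

Proteomic studies of biominerals — mollusc shells, diatom frustules,
tooth enamel — routinely turn up proteins of unknown function with low
sequence complexity, biased amino-acid composition and predicted
intrinsic disorder. Such proteins are hard to analyse with
homology-based tools and are often described only by eyeballing their
sequences. `promin` puts those observations on a statistical footing by
always asking the comparative question: *is this feature common in the
background proteome, or specific to the proteins of interest?*

It provides, as a library and a CLI:

* **Motif discovery** — iterative binomial position/residue fixing
  (motif-x style) centred on each amino acid, at a conservative per-step
  threshold (default p < 10⁻⁶, width 7, ≥ 5 occurrences); redundant
  shifted motifs are collapsed (`..S.S..`, `.S.S...` → `S.S`), then
  enumerated in both sets and scored by fold enrichment, protein count,
  and their scaled product (PS-value).
* **Compositional bias** — per-residue log2 enrichment; exhaustive
  minimal-p biased-region detection; and the bias index
  BI = Σ_aa |f_POI(aa) − f_bg(aa)| ∈ [0, 2], tested against a bootstrap
  null (1,000 background subsamples, Gaussian-KDE tail p-value).
* **Low complexity & disorder** — entropy-window segmentation
  (window 12, trigger 2.2 bits, extension 2.5 bits), per-residue
  disorder scores (propensity scale by default, external predictor
  scores injectable), and two-sided Wilcoxon rank-sum comparisons with
  continuity correction.
* **Charged clusters** — binomial sliding-window detection of K/R and
  D/E clusters and the per-set proportions of sequences carrying them.
* **Clustering by motif content** — protein × motif count and
  enrichment matrices, 1 − distance-correlation distances, Ward.D
  linkage, a five-filter selection pipeline, and a C-index profile over
  k = 2..50.
* **Synthetic fixtures** — seeded random proteomes, motif spiking with a
  truth table, and negative-control subsets, for validating any part of
  the pipeline.

## Worked example

Generate a synthetic proteome of 100 sequences, spike the 5-mer `CWCWH`
into half of them, and ask for motifs enriched in the spiked set
relative to the un-spiked one:

```sh
promin simulate --n 100 --mean-length 300 --spike-motif CWCWH \
    --spike-fraction 0.5 --seed 1 --out sim
promin motif-finder --foreground sim/foreground.fasta \
    --background sim/background.fasta --seed 1 --out motifs
head -7 motifs/motif_stats.tsv
```

```
motif   fg_occurrences  bg_occurrences  fg_proteins  bg_proteins  enrichment_density  enrichment_protein_fraction  ps_value  infinite_flag
RC.CW   5               0               5            0            inf                 inf                                    1
VC.CW   5               0               5            0            inf                 inf                                    1
CWCW    50              0               50           0            inf                 inf                                    1
Y..CWC  5               0               5            0            inf                 inf                                    1
C.H..I  5               0               5            0            inf                 inf                                    1
WCWH    50              0               50           0            inf                 inf                                    1
```

The spike is recovered in all 50 spiked proteins as the overlapping
patterns `CWCW` and `WCWH` (a literal absent from the background
exhausts the restricted background windows before every position can be
fixed, so it surfaces as sub-motifs; each matches only the spiked
sequences). All motifs are flagged infinitely enriched because the
background contains no copy. The junction motifs with 5 occurrences
arise where insertions meet random flanks.

Sequence properties of a 60-protein foreground sampled from a
500-protein background (80 % of it spiked):

```sh
promin seq-props --foreground fg.fasta --background bg.fasta \
    --samples 1000 --seed 1 --out props
cat props/summary.txt
```

```
bias_index          0.038519
bias_p              0.0114791
lcr_ranksum_p       0.813091
disorder_ranksum_p  0.257136
charge_positive_foreground  0.0167
charge_positive_background  0.0120
charge_negative_foreground  0.0167
charge_negative_background  0.0160
```

Reading: the spiked foreground's residue composition deviates from the
background (BI = 0.039) more than random 60-protein subsets do
(bootstrap p ≈ 0.011) — the inserted C/W/H-rich motif shifts
composition. Low-complexity and disorder distributions are
indistinguishable from the background (p = 0.81, p = 0.26), and the
proportions of sequences with charged clusters are similar in both
sets, as expected for a composition-preserving insertion.

Each run directory also holds the full per-protein tables
(`complexity.tsv`, `disorder.tsv`, `charge_clusters.tsv`,
`biased_regions.tsv`, heatmap matrices, `clusters.tsv`, `cindex.tsv`)
and a `run_metadata.json` with every parameter, the seed and input
digests; a rerun with the same configuration is byte-identical.

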