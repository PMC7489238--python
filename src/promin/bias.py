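"""Compositional bias: per-residue enrichment, biased regions, and the
bias index with its bootstrap/KDE significance test.

The bias index BI between a foreground and background frequency vector is
the sum over the 20 amino acids of the absolute frequency difference,
bounded in [0, 2].  Its significance is assessed against an empirical null:
BI values of repeated without-replacement samples of the background with
the foreground's cardinality, smoothed by a Gaussian kernel density
estimate whose upper tail area beyond the observed BI is the p-value.

Biased regions are found by an exhaustive minimal-p contiguous-subsequence
scan per residue type (binomial tail of the residue count in the window at
the background frequency), an exact re-specification of heuristic
low-probability-subsequence searches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom, gaussian_kde

from .seqio import (
    AA_CODES,
    AA_ORDER,
    FrequencyVector,
    ProteinSequence,
    SequenceSet,
    residue_counts_matrix,
    residue_frequencies,
)

_TINY = np.nextafter(0.0, 1.0)

#: Windows longer than this are not scanned; bounds cost on huge proteins.
MAX_REGION_LEN = 1000


def residue_log_enrichment(
    fg_freq: FrequencyVector, bg_freq: FrequencyVector
) -> np.ndarray:
    """log2(fg/bg) per residue; positive = enriched, negative = depleted.

    Residues absent from both sets map to 0; a residue present in the
    foreground but absent from the background is flagged ``+inf``.
    """
    f = fg_freq.values
    g = bg_freq.values
    out = np.zeros(20)
    both = (f > 0) & (g > 0)
    out[both] = np.log2(f[both] / g[both])
    out[(f > 0) & (g == 0)] = np.inf
    out[(f == 0) & (g > 0)] = -np.inf
    return out


@dataclass(frozen=True)
class BiasedRegion:
    """Minimal-p compositionally biased stretch of one residue type."""

    protein_id: str
    residue: str
    start: int  # 1-based inclusive
    end: int
    count: int
    p: float


def find_biased_regions(
    seq: ProteinSequence,
    bg_freq: FrequencyVector,
    min_len: int = 5,
    p_report: float = 1e-3,
    max_len: int = MAX_REGION_LEN,
) -> list[BiasedRegion]:
    """Exhaustive scan for the most biased contiguous region per residue.

    For every residue type present in the sequence, all windows of length
    ``min_len .. max_len`` are scored by the binomial tail of the residue
    count at the background frequency; the minimum-p window is reported
    when its p is below ``p_report``.  For a fixed window length the
    minimum p is attained at the maximum count, so the scan reduces to one
    sliding-max per length.  Ties resolve to the earliest, then shortest,
    window.
    """
    if min_len < 5:
        raise ValueError("min_len must be >= 5")
    codes = seq.codes()
    L = seq.length
    if L < min_len:
        return []
    top = min(L, max_len)
    lengths = np.arange(min_len, top + 1)
    regions: list[BiasedRegion] = []
    for r, aa in enumerate(AA_ORDER):
        indicator = (codes == AA_CODES[r]).astype(np.int64)
        total = int(indicator.sum())
        if total == 0:
            continue
        cs = np.concatenate(([0], np.cumsum(indicator)))
        kmax = np.empty(len(lengths), dtype=np.int64)
        argmax = np.empty(len(lengths), dtype=np.int64)
        for li, n in enumerate(lengths):
            wc = cs[n:] - cs[:-n]
            argmax[li] = int(np.argmax(wc))  # earliest maximal window
            kmax[li] = wc[argmax[li]]
        f = bg_freq.values[r]
        p = binom.sf(kmax - 1, lengths, f) if f > 0 else np.zeros(len(lengths))
        p = np.where(p > 0.0, p, _TINY)
        best = int(np.lexsort((lengths, argmax, p))[0])  # min p, earliest, shortest
        if p[best] < p_report:
            start = int(argmax[best])
            n = int(lengths[best])
            regions.append(
                BiasedRegion(
                    protein_id=seq.id,
                    residue=aa,
                    start=start + 1,
                    end=start + n,
                    count=int(kmax[best]),
                    p=float(p[best]),
                )
            )
    return regions


def count_biased_proteins(
    sset: SequenceSet,
    bg_freq: FrequencyVector,
    p_thresh: float = 1e-3,
    min_len: int = 5,
) -> dict[str, int]:
    """Per residue, the number of proteins with a biased region at p < thresh."""
    counts = dict.fromkeys(AA_ORDER, 0)
    if p_thresh <= 0:
        return counts
    for seq in sset:
        for region in find_biased_regions(
            seq, bg_freq, min_len=min_len, p_report=p_thresh
        ):
            counts[region.residue] += 1
    return counts


def bias_index(fg_freq: FrequencyVector, bg_freq: FrequencyVector) -> float:
    """BI = sum over amino acids of |fg frequency - bg frequency|, in [0, 2]."""
    return float(np.abs(fg_freq.values - bg_freq.values).sum())


def kde_tail_probability(null_values: np.ndarray, observed: float) -> float:
    """Upper tail area of a Gaussian KDE over ``null_values`` beyond ``observed``.

    Silverman bandwidth; trapezoid integration over
    [min - 3 bandwidths, max + 3 bandwidths]; clipped to [0, 1].
    """
    null_values = np.asarray(null_values, dtype=float)
    if null_values.std() == 0:
        # degenerate null: all mass at one point
        return 1.0 if observed <= null_values[0] else 0.0
    kde = gaussian_kde(null_values, bw_method="silverman")
    h = float(np.sqrt(kde.covariance[0, 0]))
    lo = float(null_values.min()) - 3 * h
    hi = float(null_values.max()) + 3 * h
    if observed >= hi:
        return 0.0
    start = max(observed, lo)
    grid = np.linspace(start, hi, 2048)
    p = float(np.trapezoid(kde(grid), grid))
    return float(np.clip(p, 0.0, 1.0))


@dataclass
class BiasTestResult:
    """Observed BI, its bootstrap null sample, and the KDE tail p-value."""

    observed_bi: float
    null_bis: np.ndarray
    p: float
    n_samples: int
    seed: int


def bias_significance(
    fg: SequenceSet,
    bg: SequenceSet,
    n_samples: int = 1000,
    seed: int = 0,
) -> BiasTestResult:
    """Probability of the observed compositional bias under random sampling.

    Null BI values come from ``n_samples`` without-replacement samples of
    the background, each with the foreground's cardinality; the p-value is
    the KDE tail area above the observed BI.
    """
    if len(fg) > len(bg):
        raise ValueError("foreground may not be larger than the background")
    fg_freq = residue_frequencies(fg)
    bg_counts = residue_counts_matrix(bg)
    bg_total = bg_counts.sum(axis=0)
    bg_freq = FrequencyVector.from_counts(bg_total)
    observed = bias_index(fg_freq, bg_freq)
    rng = np.random.default_rng(seed)
    n_bg = len(bg)
    k = len(fg)
    null = np.empty(n_samples)
    for i in range(n_samples):
        idx = rng.choice(n_bg, size=k, replace=False)
        sample = bg_counts[idx].sum(axis=0)
        total = sample.sum()
        null[i] = np.abs(sample / total - bg_freq.values).sum()
    p = kde_tail_probability(null, observed)
    return BiasTestResult(
        observed_bi=observed, null_bis=null, p=p, n_samples=n_samples, seed=seed
    )
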