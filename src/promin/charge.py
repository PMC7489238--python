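"""Charged-residue cluster detection and per-set cluster proportions.

A sliding window of fixed length (default 30) scans each sequence twice:
once for positively charged residues (K, R) and once for negatively
charged residues (D, E).  Histidine is treated as uncharged.  A window
seeds a cluster when the binomial tail of its charged count — at the
background proteome's frequency of that charge class — falls below alpha;
overlapping seed windows of one sign merge into maximal clusters.  The
headline statistic is the proportion of sequences in each set carrying at
least one cluster of each sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

from .seqio import FrequencyVector, ProteinSequence, SequenceSet, residue_frequencies

_TINY = np.nextafter(0.0, 1.0)

POSITIVE_RESIDUES = "KR"
NEGATIVE_RESIDUES = "DE"


@dataclass(frozen=True)
class ChargeCluster:
    protein_id: str
    sign: str  # "positive" | "negative"
    start: int  # 1-based inclusive
    end: int
    charged_count: int  # charged residues of the sign within the cluster span
    p: float  # smallest seed-window binomial tail


def _class_frequency(bg_freq: FrequencyVector, residues: str) -> float:
    return sum(bg_freq[a] for a in residues)


def find_charge_clusters(
    seq: ProteinSequence,
    bg_freq: FrequencyVector,
    window: int = 30,
    alpha: float = 1e-3,
) -> list[ChargeCluster]:
    """Significant like-charge clusters in one sequence.

    Sequences shorter than the window yield no clusters.  Merged clusters
    of one sign never overlap; spans respect sequence bounds.
    """
    L = seq.length
    if L < window:
        return []
    codes = seq.codes()
    clusters: list[ChargeCluster] = []
    for sign, residues in (("positive", POSITIVE_RESIDUES), ("negative", NEGATIVE_RESIDUES)):
        member = np.isin(codes, np.frombuffer(residues.encode(), dtype=np.uint8))
        if not member.any():
            continue
        cs = np.concatenate(([0], np.cumsum(member.astype(np.int64))))
        counts = cs[window:] - cs[:-window]  # count per window start
        f = _class_frequency(bg_freq, residues)
        if f > 0:
            p = binom.sf(counts - 1, window, f)
            p = np.where(counts > 0, np.where(p > 0, p, _TINY), 1.0)
        else:
            p = np.where(counts > 0, _TINY, 1.0)
        seeds = np.flatnonzero(p < alpha)
        if len(seeds) == 0:
            continue
        # merge overlapping seed windows (window spans [s, s+window-1])
        group_start = seeds[0]
        group_end = seeds[0] + window - 1
        group_p = p[seeds[0]]
        for s in seeds[1:]:
            if s <= group_end:  # overlap with current cluster
                group_end = s + window - 1
                group_p = min(group_p, p[s])
            else:
                count = int(cs[group_end + 1] - cs[group_start])
                clusters.append(
                    ChargeCluster(seq.id, sign, int(group_start) + 1,
                                  int(group_end) + 1, count, float(group_p))
                )
                group_start, group_end, group_p = s, s + window - 1, p[s]
        count = int(cs[group_end + 1] - cs[group_start])
        clusters.append(
            ChargeCluster(seq.id, sign, int(group_start) + 1,
                          int(group_end) + 1, count, float(group_p))
        )
    return clusters


def cluster_proportions(
    fg: SequenceSet,
    bg: SequenceSet,
    window: int = 30,
    alpha: float = 1e-3,
    bg_freq: FrequencyVector | None = None,
) -> dict[tuple[str, str], float]:
    """Fraction of sequences with >= 1 charge cluster, per set and sign.

    Keys are ("foreground"|"background", "positive"|"negative").  Charge
    class base rates come from the background proteome.
    """
    if bg_freq is None:
        bg_freq = residue_frequencies(bg)
    out: dict[tuple[str, str], float] = {}
    for label, sset in (("foreground", fg), ("background", bg)):
        with_pos = 0
        with_neg = 0
        for seq in sset:
            signs = {c.sign for c in find_charge_clusters(seq, bg_freq, window, alpha)}
            with_pos += "positive" in signs
            with_neg += "negative" in signs
        out[(label, "positive")] = with_pos / len(sset)
        out[(label, "negative")] = with_neg / len(sset)
    return out
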