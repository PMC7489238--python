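"""Low-complexity segmentation, disorder scoring and rank-sum comparisons.

Low-complexity regions (LCRs) are found with an entropy-window scheme in
the style of SEG: sliding windows below a *trigger* entropy seed segments,
which extend across contiguous windows below a laxer *extension* entropy;
overlapping or adjacent segments merge.  Defaults are the canonical
window 12 / trigger 2.2 bits / extension 2.5 bits.  The final
minimal-probability subsegment refinement of the original SEG algorithm is
deliberately omitted: the downstream statistic is percent coverage, which
is insensitive to exact segment trimming.

Intrinsic disorder uses a pluggable per-residue scoring contract.  The
default predictor is transparent: the TOP-IDP disorder-propensity scale
(Campen et al. 2008) linearly mapped to [0, 1] and smoothed by an
edge-truncated sliding-window mean (width 21).  Genuine output from a
trained predictor can be injected via a per-residue score file.

Foreground/background distributions of percent-LCR and percent-disorder
are compared with a two-sided Wilcoxon rank-sum test using the normal
approximation with tie correction and a sign-aware 0.5 continuity
correction (the convention of R's ``wilcox.test``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .seqio import AA_CODES, AA_ORDER, ProteinSequence

#: TOP-IDP per-residue disorder propensities (Campen et al. 2008).
#: Positive values favour disorder (P most), negative favour order (W most).
TOP_IDP = {
    "A": 0.06, "R": 0.180, "N": 0.007, "D": 0.192, "C": 0.02,
    "Q": 0.318, "E": 0.736, "G": 0.166, "H": 0.303, "I": -0.486,
    "L": -0.326, "K": 0.586, "M": -0.397, "F": -0.697, "P": 0.987,
    "S": 0.341, "T": 0.059, "W": -0.884, "Y": -0.510, "V": -0.121,
}

_SCALE_MIN = min(TOP_IDP.values())
_SCALE_MAX = max(TOP_IDP.values())
# per-byte lookup of the [0,1]-mapped propensity; NaN for unknown codes
_MAPPED = np.full(256, np.nan)
for _aa, _v in TOP_IDP.items():
    _MAPPED[ord(_aa)] = (_v - _SCALE_MIN) / (_SCALE_MAX - _SCALE_MIN)


def window_entropy(window: str) -> float:
    """Shannon entropy (bits) of the residue composition of ``window``.

    Unknown codes are excluded; a window of only unknowns has entropy 0.
    """
    if not window:
        raise ValueError("empty window")
    codes = np.frombuffer(window.upper().encode("ascii"), dtype=np.uint8)
    counts = np.bincount(codes, minlength=256)[AA_CODES]
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(max(0.0, -(p * np.log2(p)).sum()))


def _window_entropies(seq: ProteinSequence, window: int) -> np.ndarray:
    """Entropy of every length-``window`` window, vectorised via prefix sums."""
    codes = seq.codes()
    onehot = (codes[:, None] == AA_CODES[None, :]).astype(np.int64)
    cs = np.vstack([np.zeros((1, 20), dtype=np.int64), np.cumsum(onehot, axis=0)])
    wc = cs[window:] - cs[:-window]
    total = wc.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = wc / total
        terms = np.where(wc > 0, -p * np.log2(p), 0.0)
    ent = np.maximum(terms.sum(axis=1), 0.0)
    ent[total[:, 0] == 0] = 0.0
    return ent


@dataclass(frozen=True)
class LowComplexitySegment:
    protein_id: str
    start: int  # 1-based inclusive
    end: int
    trigger_entropy: float  # lowest trigger-window entropy inside the segment


def seg_segments(
    seq: ProteinSequence,
    window: int = 12,
    trigger: float = 2.2,
    extension: float = 2.5,
) -> list[LowComplexitySegment]:
    """Entropy-window low-complexity segmentation.

    A maximal run of contiguous windows with entropy <= ``extension`` that
    contains at least one window with entropy <= ``trigger`` becomes a
    segment covering the union of its window spans; overlapping or
    adjacent segments are merged.  Sequences shorter than the window yield
    no segments.
    """
    if seq.length < window:
        return []
    H = _window_entropies(seq, window)
    ext = H <= extension
    trig = H <= trigger
    intervals: list[tuple[int, int, float]] = []
    i = 0
    n = len(H)
    while i < n:
        if not ext[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and ext[j + 1]:
            j += 1
        run_trig = trig[i : j + 1]
        if run_trig.any():
            tmin = float(H[i : j + 1][run_trig].min())
            intervals.append((i + 1, j + window, tmin))  # 1-based residues
        i = j + 1
    merged: list[list[float]] = []
    for start, end, tmin in intervals:
        if merged and start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], end)
            merged[-1][2] = min(merged[-1][2], tmin)
        else:
            merged.append([start, end, tmin])
    return [
        LowComplexitySegment(seq.id, int(s), int(e), float(t)) for s, e, t in merged
    ]


def percent_low_complexity(
    seq: ProteinSequence, segments: Sequence[LowComplexitySegment]
) -> float:
    """Percentage of the sequence covered by the union of its segments."""
    covered = np.zeros(seq.length, dtype=bool)
    for seg in segments:
        covered[seg.start - 1 : seg.end] = True
    return 100.0 * covered.sum() / seq.length


DisorderPredictor = Callable[[ProteinSequence], np.ndarray]


def propensity_disorder_scores(
    seq: ProteinSequence, window: int = 21
) -> np.ndarray:
    """Default predictor: windowed mean of the [0,1]-mapped TOP-IDP scale.

    Edge windows are truncated to existing residues; unknown codes carry no
    propensity and are omitted from window means.  A window containing only
    unknowns scores the neutral 0.5.
    """
    vals = _MAPPED[seq.codes()]
    known = ~np.isnan(vals)
    filled = np.where(known, vals, 0.0)
    kernel = np.ones(window)
    sums = np.convolve(filled, kernel, mode="same")
    counts = np.convolve(known.astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = sums / counts
    scores[counts == 0] = 0.5
    return np.clip(scores, 0.0, 1.0)


def disorder_scores(
    seq: ProteinSequence, predictor: DisorderPredictor | None = None
) -> np.ndarray:
    """Per-residue disorder scores in [0, 1] from the given predictor.

    External predictors (e.g. genuine VSL2 output read from a score file)
    are passed through unchanged after a length check.
    """
    scores = (predictor or propensity_disorder_scores)(seq)
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (seq.length,):
        raise ValueError(
            f"predictor returned {scores.shape} scores for {seq.id!r} "
            f"of length {seq.length}"
        )
    if np.nanmin(scores) < 0 or np.nanmax(scores) > 1:
        raise ValueError("disorder scores must lie in [0, 1]")
    return scores


def read_external_scores(path: str | Path) -> dict[str, np.ndarray]:
    """Read a per-residue disorder score TSV: ``protein_id, position, score``.

    Positions must form 1..L per protein; scores must lie in [0, 1].
    """
    df = pd.read_csv(path, sep="\t")
    required = {"protein_id", "position", "score"}
    if not required <= set(df.columns):
        raise ValueError(f"score file must have columns {sorted(required)}")
    out: dict[str, np.ndarray] = {}
    for pid, grp in df.groupby("protein_id", sort=False):
        grp = grp.sort_values("position")
        pos = grp["position"].to_numpy()
        if not np.array_equal(pos, np.arange(1, len(pos) + 1)):
            raise ValueError(f"positions for {pid!r} are not contiguous from 1")
        out[str(pid)] = grp["score"].to_numpy(dtype=float)
    return out


def external_predictor(scores: dict[str, np.ndarray]) -> DisorderPredictor:
    """Wrap an id -> scores mapping as a predictor (identity contract)."""

    def _predict(seq: ProteinSequence) -> np.ndarray:
        if seq.id not in scores:
            raise KeyError(f"no external disorder scores for {seq.id!r}")
        return scores[seq.id]

    return _predict


def percent_disordered(scores: np.ndarray, threshold: float = 0.5) -> float:
    """Percentage of residues called disordered (score >= threshold)."""
    scores = np.asarray(scores, dtype=float)
    return 100.0 * float((scores >= threshold).sum()) / len(scores)


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # Mann-Whitney U of the foreground sample
    p: float  # two-sided
    n_fg: int
    n_bg: int


def ranksum_test(
    fg_values: Sequence[float], bg_values: Sequence[float]
) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test, normal approximation.

    Uses midranks with the standard tie correction of the variance and a
    continuity correction of 0.5 applied toward zero (so identical samples
    give p = 1 exactly, matching R's ``wilcox.test`` with ``correct=TRUE``).
    """
    x = np.asarray(fg_values, dtype=float)
    y = np.asarray(bg_values, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    U = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    mu = n1 * n2 / 2
    _, tie_counts = np.unique(combined, return_counts=True)
    n = n1 + n2
    tie_term = float((tie_counts**3 - tie_counts).sum())
    sigma2 = (n1 * n2 / 12) * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        warnings.warn("all values tied across both groups; p set to 1")
        return RankSumResult(statistic=U, p=1.0, n_fg=n1, n_bg=n2)
    z = U - mu
    z = z - np.sign(z) * 0.5
    z /= np.sqrt(sigma2)
    p = float(min(1.0, 2 * norm.sf(abs(z))))
    return RankSumResult(statistic=U, p=p, n_fg=n1, n_bg=n2)
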