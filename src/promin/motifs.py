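"""Motif discovery by iterative binomial position/residue fixing.

The engine follows the motif-x strategy: for every one of the 20 amino
acids, fixed-width windows centred on each occurrence of that residue are
extracted from the foreground and the background.  Starting from the bare
centre, the procedure repeatedly finds the (position, residue) pair whose
foreground count is most surprising under a binomial null with the
*current* background window proportions as success probability, fixes it
when its tail probability clears the significance threshold, restricts both
window sets to the matching windows, and recurses.  When no pair passes,
the fixed positions spell out a motif; its matched foreground windows are
removed and the search restarts, so one centre can yield several motifs.

Motifs from all centres are pooled, trimmed of flanking wildcards,
deduplicated, enumerated in both sequence sets (overlaps counted) and
scored by occurrence-density enrichment, protein counts and the PS-value
(product of min–max scaled protein count and enrichment).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import binom

from .seqio import AA_CODES, AA_ORDER, PAD, SequenceSet

WILDCARD = "."
_PAD_CODE = ord(PAD)
_TINY = np.nextafter(0.0, 1.0)  # smallest positive double; p in (0,1] floor


class MotifError(ValueError):
    pass


@dataclass(frozen=True)
class MotifPattern:
    """A fixed-width motif over amino acids and the ``.`` wildcard.

    The wildcard matches any of the 20 standard residues but never an
    unknown code (X, B, Z, U, O, *) — unknowns carry no evidence.  After
    collapsing, patterns start and end with a literal residue.
    """

    pattern: str
    center: str | None = None

    def __post_init__(self) -> None:
        if not self.pattern:
            raise MotifError("empty motif pattern")
        bad = set(self.pattern) - set(AA_ORDER) - {WILDCARD}
        if bad:
            raise MotifError(f"invalid characters in motif: {sorted(bad)}")
        if set(self.pattern) == {WILDCARD}:
            raise MotifError("motif must contain at least one literal residue")

    def __str__(self) -> str:
        return self.pattern

    @property
    def width(self) -> int:
        return len(self.pattern)


@lru_cache(maxsize=4096)
def _compiled(pattern: str) -> re.Pattern:
    # overlapping matches via a lookahead group; '.' -> explicit 20-residue
    # class so unknown codes are never matched
    body = "".join(f"[{AA_ORDER}]" if c == WILDCARD else c for c in pattern)
    return re.compile(f"(?=({body}))")


@dataclass(frozen=True)
class Window:
    """One extracted window: text, source protein and centre coordinate."""

    text: str
    source_id: str
    center_pos: int  # 1-based position of the central residue in its protein


class WindowSet:
    """Array-backed collection of equal-width windows sharing one centre.

    ``codes`` is an (n, width) uint8 matrix of ASCII codes, with the pad
    byte at out-of-sequence flank positions.  The array layout is what the
    fixing loop operates on; :meth:`windows` materialises individual
    :class:`Window` records on demand.
    """

    def __init__(
        self,
        codes: np.ndarray,
        source_ids: list[str],
        source_index: np.ndarray,
        center_pos: np.ndarray,
        center: str,
        width: int,
    ) -> None:
        self.codes = codes
        self.source_ids = source_ids
        self.source_index = source_index
        self.center_pos = center_pos
        self.center = center
        self.width = width

    def __len__(self) -> int:
        return self.codes.shape[0]

    def windows(self) -> list[Window]:
        return [
            Window(
                text=self.codes[i].tobytes().decode("ascii"),
                source_id=self.source_ids[self.source_index[i]],
                center_pos=int(self.center_pos[i]),
            )
            for i in range(len(self))
        ]


class _WindowTable:
    """All windows of one width for a sequence set, grouped by centre.

    Sequences are concatenated with ``width - 1`` pad bytes between them so
    a single sliding-window view yields every window without cross-talk.
    """

    def __init__(self, sset: SequenceSet, width: int) -> None:
        if width % 2 == 0 or not 3 <= width <= 35:
            raise MotifError("window width must be odd and within [3, 35]")
        half = width // 2
        gap = np.full(width - 1, _PAD_CODE, dtype=np.uint8)
        chunks = [gap]
        centers = []
        src = []
        pos = []
        offset = width - 1
        for si, seq in enumerate(sset):
            codes = seq.codes()
            chunks.append(codes)
            chunks.append(gap)
            centers.append(codes)
            src.append(np.full(seq.length, si, dtype=np.int64))
            pos.append(np.arange(1, seq.length + 1, dtype=np.int64))
            offset += seq.length + (width - 1)
        big = np.concatenate(chunks)
        # absolute index of residue r of sequence si in `big`
        starts = np.cumsum(
            [width - 1] + [s.length + (width - 1) for s in sset.sequences]
        )[:-1]
        abs_idx = np.concatenate(
            [starts[i] + np.arange(s.length) for i, s in enumerate(sset.sequences)]
        ) if len(sset) else np.empty(0, dtype=np.int64)
        self.width = width
        self.source_ids = sset.ids
        self._view = np.lib.stride_tricks.sliding_window_view(big, width)
        self._win_start = abs_idx - half
        self._center_codes = np.concatenate(centers) if centers else np.empty(0, np.uint8)
        self._src = np.concatenate(src) if src else np.empty(0, np.int64)
        self._pos = np.concatenate(pos) if pos else np.empty(0, np.int64)

    def for_center(self, center: str) -> WindowSet:
        mask = self._center_codes == ord(center)
        codes = self._view[self._win_start[mask]]
        return WindowSet(
            codes=np.ascontiguousarray(codes),
            source_ids=self.source_ids,
            source_index=self._src[mask],
            center_pos=self._pos[mask],
            center=center,
            width=self.width,
        )


def extract_windows(sset: SequenceSet, center: str, width: int) -> WindowSet:
    """Windows of odd ``width`` centred on every occurrence of ``center``.

    Flanks running off a sequence end are filled with the pad character,
    which matches no residue, so edge windows can never support fixing
    beyond the sequence.
    """
    if center not in AA_ORDER:
        raise MotifError(f"centre must be a standard residue, got {center!r}")
    return _WindowTable(sset, width).for_center(center)


def binomial_tail(k: int, n: int, p: float) -> float:
    """Upper binomial tail P(X >= k) for X ~ Binomial(n, p).

    Survival-function based, numerically stable to ~1e-300; results that
    underflow are floored at the smallest positive double so downstream
    threshold comparisons still behave.
    """
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    if not 0.0 <= p <= 1.0:
        raise ValueError("require 0 <= p <= 1")
    if k == 0:
        return 1.0
    val = float(binom.sf(k - 1, n, p))
    return val if val > 0.0 else (_TINY if p > 0.0 else 0.0)


@dataclass(frozen=True)
class FixStep:
    """One accepted fixing decision: window position, residue and its p."""

    position: int  # 0-based index within the window
    residue: str
    p: float


def _best_fix(
    fg_codes: np.ndarray,
    bg_codes: np.ndarray,
    open_positions: Sequence[int],
    p_thresh: float,
    min_occ: int,
) -> tuple[float, float, int, int] | None:
    """Scan all open (position, residue) pairs; return the winning fix.

    Returns ``(p, -fold, j, r_index)`` for the minimum-p candidate with
    foreground count >= min_occ and p < p_thresh, ties broken by highest
    fold enrichment then lexicographic (position, residue); None when no
    pair qualifies.
    """
    nf = fg_codes.shape[0]
    nb = bg_codes.shape[0]
    best: tuple[float, float, int, int] | None = None
    for j in open_positions:
        fk = (fg_codes[:, j][:, None] == AA_CODES[None, :]).sum(axis=0)
        bk = (bg_codes[:, j][:, None] == AA_CODES[None, :]).sum(axis=0)
        for r in range(20):
            k = int(fk[r])
            if k < min_occ:
                continue
            p_bg = bk[r] / nb
            pv = binomial_tail(k, nf, p_bg)
            if pv < p_thresh:
                fold = (k / nf) / p_bg if p_bg > 0 else np.inf
                cand = (pv, -fold, j, r)
                if best is None or cand < best:
                    best = cand
    return best


def discover_at_center(
    fg: WindowSet,
    bg: WindowSet,
    p_thresh: float = 1e-6,
    min_occ: int = 5,
) -> list[tuple[MotifPattern, list[FixStep]]]:
    """Iterative binomial fixing on windows sharing one centre residue.

    Background base rates are recomputed from the restricted background
    window set at every step, and every accepted step's tail probability is
    recorded in the trace, so conservativeness (each step p < ``p_thresh``)
    is checkable after the fact.  Once a motif is emitted its matching
    foreground windows leave the pool and the search restarts against the
    full background.
    """
    if fg.width != bg.width or fg.center != bg.center:
        raise MotifError("foreground and background windows must share width and centre")
    if len(bg) == 0:
        raise MotifError("empty background windows: no base rates available")
    width = fg.width
    c_idx = width // 2
    pool = np.ones(len(fg), dtype=bool)
    results: list[tuple[MotifPattern, list[FixStep]]] = []
    while True:
        fg_mask = pool.copy()
        bg_mask = np.ones(len(bg), dtype=bool)
        fixed: dict[int, str] = {}
        trace: list[FixStep] = []
        while True:
            if not fg_mask.any() or not bg_mask.any():
                break
            open_pos = [j for j in range(width) if j != c_idx and j not in fixed]
            if not open_pos:
                break
            best = _best_fix(
                fg.codes[fg_mask], bg.codes[bg_mask], open_pos, p_thresh, min_occ
            )
            if best is None:
                break
            pv, _negfold, j, r = best
            residue = AA_ORDER[r]
            fixed[j] = residue
            trace.append(FixStep(position=j, residue=residue, p=pv))
            code = AA_CODES[r]
            fg_mask &= fg.codes[:, j] == code
            bg_mask &= bg.codes[:, j] == code
        if not fixed:
            break
        if int(fg_mask.sum()) >= min_occ:
            chars = [
                fixed.get(j, fg.center if j == c_idx else WILDCARD)
                for j in range(width)
            ]
            results.append((MotifPattern("".join(chars), center=fg.center), trace))
        pool &= ~fg_mask
    return results


def collapse_motifs(motifs: Iterable[MotifPattern]) -> list[MotifPattern]:
    """Trim flanking wildcards and deduplicate, keeping first-seen order.

    Centre-by-centre discovery produces redundant shifted variants (e.g.
    ``..S.S..`` and ``.S.S...`` both reduce to ``S.S``); this is where they
    merge.  Patterns that trim to nothing are dropped with a warning.
    """
    seen: dict[str, MotifPattern] = {}
    for m in motifs:
        trimmed = m.pattern.strip(WILDCARD)
        if not trimmed:
            warnings.warn(f"motif {m.pattern!r} is all wildcards; dropped")
            continue
        if trimmed not in seen:
            seen[trimmed] = MotifPattern(trimmed)
    return list(seen.values())


def count_matches_per_sequence(
    motif: MotifPattern, sset: SequenceSet
) -> np.ndarray:
    """Occurrences of ``motif`` in each sequence (overlaps counted)."""
    rx = _compiled(motif.pattern)
    return np.array(
        [sum(1 for _ in rx.finditer(s.residues)) for s in sset], dtype=np.int64
    )


def count_matches(motif: MotifPattern, sset: SequenceSet) -> tuple[int, int]:
    """Total occurrences and number of sequences with >= 1 occurrence."""
    per = count_matches_per_sequence(motif, sset)
    return int(per.sum()), int((per > 0).sum())


def enrichment(motif: MotifPattern, fg: SequenceSet, bg: SequenceSet) -> float:
    """Occurrence-density enrichment of a motif: fg rate over bg rate.

    Rates are occurrences per residue.  Returns ``inf`` when the motif is
    absent from the background but present in the foreground, and ``nan``
    when absent from both.
    """
    if len(fg) == 0 or len(bg) == 0:
        raise ValueError("sets must be non-empty")
    fo, _ = count_matches(motif, fg)
    bo, _ = count_matches(motif, bg)
    return _density_ratio(fo, fg.total_residues, bo, bg.total_residues)


def _density_ratio(fo: int, fn: int, bo: int, bn: int) -> float:
    if bo == 0:
        return np.inf if fo > 0 else np.nan
    return (fo / fn) / (bo / bn)


@dataclass
class MotifStats:
    """Counts and scores of one discovered motif in both sequence sets."""

    motif: MotifPattern
    fg_occurrences: int
    bg_occurrences: int
    fg_proteins: int
    bg_proteins: int
    enrichment: float  # occurrence-density ratio
    enrichment_protein_fraction: float  # protein-fraction ratio (alt definition)
    ps_value: float | None = None

    @property
    def infinite(self) -> bool:
        return bool(np.isinf(self.enrichment))


def ps_values(stats: list[MotifStats]) -> list[MotifStats]:
    """Attach PS-values: product of min–max scaled protein count and enrichment.

    Scaling runs across the finite-enrichment motifs only; infinitely
    enriched motifs get no PS-value.  A degenerate measure (all motifs
    equal, including the single-motif case) scales to 1.0 so the product
    stays informative about the other measure.
    """
    finite = [s for s in stats if np.isfinite(s.enrichment)]
    if not finite:
        if stats:
            warnings.warn("all motif enrichments are infinite; PS-values undefined")
        for s in stats:
            s.ps_value = None
        return stats

    def _scale(values: np.ndarray) -> np.ndarray:
        lo, hi = values.min(), values.max()
        if hi == lo:
            return np.ones_like(values, dtype=float)
        return (values - lo) / (hi - lo)

    counts = _scale(np.array([s.fg_proteins for s in finite], dtype=float))
    enr = _scale(np.array([s.enrichment for s in finite], dtype=float))
    for s, c, e in zip(finite, counts, enr):
        s.ps_value = float(c * e)
    for s in stats:
        if not np.isfinite(s.enrichment):
            s.ps_value = None
    return stats


def run_motif_finder(
    fg: SequenceSet,
    bg: SequenceSet,
    width: int = 7,
    p_thresh: float = 1e-6,
    min_occ: int = 5,
) -> list[MotifStats]:
    """Full motif discovery: all 20 centres, collapse, enumerate, score.

    Defaults: width 7, per-step binomial threshold 1e-6, minimum 5
    foreground window matches.  Centres absent from the background carry no
    base rates and are skipped with a warning.  Deterministic given inputs.
    """
    if len(fg) == 0 or len(bg) == 0:
        raise ValueError("foreground and background must be non-empty")
    fg_table = _WindowTable(fg, width)
    bg_table = _WindowTable(bg, width)
    raw: list[MotifPattern] = []
    for aa in AA_ORDER:
        fgw = fg_table.for_center(aa)
        if len(fgw) == 0:
            continue
        bgw = bg_table.for_center(aa)
        if len(bgw) == 0:
            warnings.warn(
                f"centre {aa!r} occurs in foreground but not background; skipped"
            )
            continue
        raw.extend(p for p, _trace in discover_at_center(fgw, bgw, p_thresh, min_occ))
    collapsed = collapse_motifs(raw)
    stats: list[MotifStats] = []
    for pat in collapsed:
        fo, fp = count_matches(pat, fg)
        bo, bp = count_matches(pat, bg)
        dens = _density_ratio(fo, fg.total_residues, bo, bg.total_residues)
        if bp == 0:
            prot = np.inf if fp > 0 else np.nan
        else:
            prot = (fp / len(fg)) / (bp / len(bg))
        stats.append(
            MotifStats(
                motif=pat,
                fg_occurrences=fo,
                bg_occurrences=bo,
                fg_proteins=fp,
                bg_proteins=bp,
                enrichment=dens,
                enrichment_protein_fraction=prot,
            )
        )
    return ps_values(stats)
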