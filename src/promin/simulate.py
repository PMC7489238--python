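"""Synthetic foreground/background generators with known ground truth.

These generators define the validation conditions for the whole pipeline:
random proteomes drawn i.i.d. from a stated residue-frequency vector with a
heavy-right-tailed length distribution, deterministic spiking of a literal
motif into a known fraction of sequences (with a truth table recording every
insertion), and negative-control foreground sets subsampled from the
background.  Everything is seeded and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .seqio import (
    AA_ORDER,
    AA_SET,
    FrequencyVector,
    ProteinSequence,
    SequenceSet,
    sample_without_replacement,
)

#: Lower truncation of simulated sequence lengths (residues).
MIN_LENGTH = 50


def derive_seed(master: int, index: int) -> int:
    """Fixed arithmetic rule mapping a master seed to per-replicate seeds.

    ``(master * 100003 + 7919 * (index + 1)) mod (2^31 - 1)`` — documented so
    any replicate can be reproduced independently of the others.
    """
    return (int(master) * 100003 + 7919 * (int(index) + 1)) % (2**31 - 1)


@dataclass(frozen=True)
class SpikeRecord:
    """Ground truth of a motif-spiking operation.

    ``positions`` maps each spiked sequence id to the 1-based start of the
    inserted motif copy in the spiked sequence.
    """

    motif: str
    spiked_ids: tuple[str, ...]
    positions: dict[str, int]
    fraction: float


def generate_proteome(
    n: int,
    mean_length: int,
    freq: FrequencyVector | None = None,
    seed: int = 0,
    name: str = "synthetic-proteome",
) -> SequenceSet:
    """Simulate ``n`` i.i.d. protein sequences.

    Lengths are ``MIN_LENGTH - 1 + Geometric(p)`` with ``p`` chosen so the
    mean is ``mean_length``, truncated above at ``5 * mean_length`` — a
    geometric-like discrete law whose heavy right tail resembles real
    proteome length distributions.  Residues are drawn i.i.d. from ``freq``
    (uniform over the 20 standard residues by default).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if mean_length < 10:
        raise ValueError("mean_length must be >= 10")
    if freq is None:
        freq = FrequencyVector.uniform()
    rng = np.random.default_rng(seed)
    floor = min(MIN_LENGTH, mean_length)
    p = 1.0 / max(1.0, mean_length - floor + 1)
    lengths = np.minimum(floor - 1 + rng.geometric(p, size=n), 5 * mean_length)
    total = int(lengths.sum())
    letters = rng.choice(np.array(list(AA_ORDER)), size=total, p=freq.values)
    seqs = []
    offset = 0
    width = len(str(n))
    for i, L in enumerate(lengths):
        residues = "".join(letters[offset : offset + int(L)])
        offset += int(L)
        seqs.append(ProteinSequence(id=f"syn{str(i + 1).zfill(width)}", residues=residues))
    return SequenceSet(name=name, sequences=seqs)


def spike_motif(
    sset: SequenceSet,
    motif: str,
    fraction: float,
    seed: int = 0,
    overwrite: bool = False,
) -> tuple[SequenceSet, SpikeRecord]:
    """Insert a literal motif into a known fraction of the sequences.

    ``round(fraction * |set|)`` sequences are chosen at random; each
    receives exactly one copy of ``motif`` at a random internal offset.
    By default the copy is *inserted* (sequence lengthens), preserving the
    composition of all pre-existing positions; ``overwrite=True`` replaces
    residues in place instead.  The returned :class:`SpikeRecord` is a
    faithful truth table of ids and 1-based motif start positions.
    """
    motif = motif.upper()
    if not motif or not set(motif) <= AA_SET:
        raise ValueError(
            "spike motif must be a non-empty literal over the 20 standard residues"
        )
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    min_len = min(s.length for s in sset)
    if len(motif) >= min_len:
        raise ValueError("motif length must be shorter than the shortest sequence")
    rng = np.random.default_rng(seed)
    k = int(round(fraction * len(sset)))
    chosen = set(rng.choice(len(sset), size=k, replace=False).tolist())
    out = []
    positions: dict[str, int] = {}
    ids: list[str] = []
    m = len(motif)
    for i, seq in enumerate(sset):
        if i not in chosen:
            out.append(seq)
            continue
        if overwrite:
            start = int(rng.integers(0, seq.length - m + 1))
            residues = seq.residues[:start] + motif + seq.residues[start + m :]
            pos = start + 1
        else:
            cut = int(rng.integers(1, seq.length))  # internal insertion point
            residues = seq.residues[:cut] + motif + seq.residues[cut:]
            pos = cut + 1
        out.append(ProteinSequence(id=seq.id, residues=residues))
        positions[seq.id] = pos
        ids.append(seq.id)
    record = SpikeRecord(
        motif=motif, spiked_ids=tuple(ids), positions=positions, fraction=fraction
    )
    return SequenceSet(name=f"{sset.name}|spiked[{motif}]", sequences=out), record


def negative_control_sets(
    background: SequenceSet, n_sets: int, set_size: int, seed: int = 0
) -> list[SequenceSet]:
    """Independent without-replacement foreground samples of the background.

    Used for negative-control runs: a foreground that is just a random
    slice of the background should yield no enriched motifs and no
    significant property differences.  Per-set seeds come from
    :func:`derive_seed` so each replicate is independently reproducible.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    return [
        sample_without_replacement(
            background,
            set_size,
            derive_seed(seed, i),
            name=f"negative-control-{i + 1}",
        )
        for i in range(n_sets)
    ]


def write_truth_tsv(record: SpikeRecord, path: str | Path) -> None:
    """Write the spike truth table as TSV: ``seq_id, motif, position``."""
    df = pd.DataFrame(
        {
            "seq_id": list(record.spiked_ids),
            "motif": record.motif,
            "position": [record.positions[i] for i in record.spiked_ids],
        }
    )
    df.to_csv(path, sep="\t", index=False)
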