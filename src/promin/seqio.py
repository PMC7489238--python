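"""FASTA input/output, residue frequencies and background subsampling.

The package compares a *foreground* set of proteins of interest (POI set)
against a *background* proteome.  Both arrive as plain FASTA files of
amino-acid sequences.  This module owns the in-memory containers
(:class:`ProteinSequence`, :class:`SequenceSet`, :class:`FrequencyVector`),
validation of the amino-acid alphabet, pooled residue-frequency computation
and the without-replacement subsampling used to build bootstrap nulls.

Real gene-model proteomes contain ambiguity codes, so the characters
``X B Z U O *`` are tolerated on input but excluded from every statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO

#: Canonical ordering of the 20 standard amino acids used by every
#: frequency vector and count matrix in the package.
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}
AA_SET = frozenset(AA_ORDER)

#: Ambiguity / non-standard codes tolerated on input, never counted.
UNKNOWN_RESIDUES = frozenset("XBZUO*")

#: Padding character used for sequence-edge motif windows; matches nothing.
PAD = "-"

_ALLOWED = AA_SET | UNKNOWN_RESIDUES

# byte codes of the 20 standard residues, aligned with AA_ORDER
AA_CODES = np.frombuffer(AA_ORDER.encode("ascii"), dtype=np.uint8)


class FastaFormatError(ValueError):
    """Raised for unparsable, empty or alphabet-violating FASTA input."""


class DuplicateIdError(FastaFormatError):
    """Raised when a sequence set would contain a repeated identifier."""


@dataclass(frozen=True)
class ProteinSequence:
    """A single amino-acid sequence with a unique identifier.

    Residues are normalised to uppercase at construction; characters
    outside the 20-letter alphabet plus the tolerated unknowns are a hard
    error naming the offenders.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FastaFormatError(f"invalid sequence id {self.id!r}")
        object.__setattr__(self, "residues", self.residues.upper())
        if len(self.residues) == 0:
            raise FastaFormatError(f"sequence {self.id!r} has zero length")
        bad = sorted(set(self.residues) - _ALLOWED)
        if bad:
            raise FastaFormatError(
                f"sequence {self.id!r} contains non-amino-acid characters: "
                + ", ".join(repr(c) for c in bad)
            )

    @property
    def length(self) -> int:
        return len(self.residues)

    def codes(self) -> np.ndarray:
        """Residues as a uint8 byte array (view onto an ASCII encoding)."""
        return np.frombuffer(self.residues.encode("ascii"), dtype=np.uint8)


@dataclass
class SequenceSet:
    """Ordered, duplicate-free collection of protein sequences.

    ``name`` records the role of the set ("foreground", "background",
    or any free-text label such as a null-sample marker).
    """

    name: str
    sequences: list[ProteinSequence] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for seq in self.sequences:
            if seq.id in seen:
                raise DuplicateIdError(f"duplicate sequence id {seq.id!r}")
            seen.add(seq.id)

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[ProteinSequence]:
        return iter(self.sequences)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.sequences]

    @property
    def total_residues(self) -> int:
        return sum(s.length for s in self.sequences)

    def get(self, seq_id: str) -> ProteinSequence:
        for s in self.sequences:
            if s.id == seq_id:
                return s
        raise KeyError(seq_id)


@dataclass(frozen=True)
class FrequencyVector:
    """Proportions of the 20 standard amino acids, in :data:`AA_ORDER`.

    Entries lie in [0, 1] and sum to 1 within 1e-9 over counted residues.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (20,):
            raise ValueError("frequency vector must have 20 entries")
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError("frequencies must lie in [0, 1]")
        if abs(float(v.sum()) - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1")
        object.__setattr__(self, "values", v)

    def __getitem__(self, aa: str) -> float:
        return float(self.values[AA_INDEX[aa]])

    def as_dict(self) -> dict[str, float]:
        return {a: float(self.values[i]) for i, a in enumerate(AA_ORDER)}

    @classmethod
    def uniform(cls) -> "FrequencyVector":
        return cls(np.full(20, 1.0 / 20.0))

    @classmethod
    def from_counts(cls, counts: np.ndarray) -> "FrequencyVector":
        counts = np.asarray(counts, dtype=float)
        total = counts.sum()
        if total <= 0:
            raise ValueError("no countable residues")
        return cls(counts / total)


def read_fasta(path: str | Path, name: str | None = None) -> SequenceSet:
    """Read a protein FASTA file into a :class:`SequenceSet`.

    Ids are the first whitespace-delimited token of each header, kept
    byte-identical to the input.  Wrapped and unwrapped records are both
    accepted; lowercase residues are uppercased; empty records, duplicate
    ids and out-of-alphabet characters are hard errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinSequence(id=rec.id, residues=str(rec.seq)))
    if not records:
        raise FastaFormatError(f"no FASTA records found in {path}")
    return SequenceSet(name=name if name is not None else path.stem, sequences=records)


def write_fasta(sset: SequenceSet, path: str | Path, line_width: int = 60) -> None:
    """Write a sequence set as FASTA, reproducing ids byte-identically."""
    path = Path(path)
    with path.open("w") as fh:
        for seq in sset:
            fh.write(f">{seq.id}\n")
            for i in range(0, seq.length, line_width):
                fh.write(seq.residues[i : i + line_width] + "\n")


def residue_counts_matrix(sset: SequenceSet) -> np.ndarray:
    """Per-sequence counts of the 20 standard residues, shape (n, 20).

    Unknown residues contribute to no column.  This is the workhorse
    behind pooled frequencies and the bootstrap null, which only ever
    needs sums of rows.
    """
    out = np.zeros((len(sset), 20), dtype=np.int64)
    for i, seq in enumerate(sset):
        codes = seq.codes()
        counts = np.bincount(codes, minlength=256)
        out[i] = counts[AA_CODES]
    return out


def residue_frequencies(sset: SequenceSet) -> FrequencyVector:
    """Pooled amino-acid frequencies over all residues of all sequences.

    Pooling uses concatenation semantics (every residue weighted equally),
    not per-protein averaging.  Unknown residues are excluded from both
    numerator and denominator.
    """
    if len(sset) == 0:
        raise ValueError("cannot compute frequencies of an empty set")
    counts = residue_counts_matrix(sset).sum(axis=0)
    return FrequencyVector.from_counts(counts)


def sample_without_replacement(
    sset: SequenceSet, n: int, seed: int, name: str | None = None
) -> SequenceSet:
    """Draw ``n`` distinct sequences from ``sset``, deterministically per seed.

    Used to build the bootstrap null: repeated random subsets of the
    background with the same cardinality as the foreground.
    """
    if not 1 <= n <= len(sset):
        raise ValueError(f"sample size {n} out of range for set of {len(sset)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(sset), size=n, replace=False)
    label = name if name is not None else f"{sset.name}|null-sample[seed={seed}]"
    return SequenceSet(name=label, sequences=[sset.sequences[i] for i in idx])


def sample_with_replacement(
    sset: SequenceSet, n: int, seed: int, name: str | None = None
) -> SequenceSet:
    """Bootstrap variant of :func:`sample_without_replacement`.

    Resampled sequences receive suffixed ids so the result remains a valid
    (duplicate-free) set.
    """
    if n < 1 or len(sset) == 0:
        raise ValueError("invalid sample size or empty set")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(sset), size=n, replace=True)
    seqs = []
    seen: dict[str, int] = {}
    for i in idx:
        base = sset.sequences[i]
        k = seen.get(base.id, 0)
        seen[base.id] = k + 1
        new_id = base.id if k == 0 else f"{base.id}#{k}"
        seqs.append(ProteinSequence(id=new_id, residues=base.residues))
    label = name if name is not None else f"{sset.name}|bootstrap[seed={seed}]"
    return SequenceSet(name=label, sequences=seqs)
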