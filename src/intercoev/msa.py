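"""Paired multiple sequence alignments: reading, pairing, filtering, subsampling.

Two row-matched alignments (one per interacting protein family) are the
basic input of every inter-protein coevolution analysis.  Row *i* of both
members must come from the same organism/strain pair; all downstream column
pair statistics rely on that correspondence.

FASTA and PHYLIP parsing is delegated to :mod:`Bio.AlignIO`; the "raw"
format (one aligned sequence per line, no identifiers) is read directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import GAP, encode, normalize_symbol
from .errors import AlignmentError, PairingError, SamplingError

logger = logging.getLogger(__name__)

FORMATS = ("fasta", "phylip", "raw")
_BIO_FORMAT = {"fasta": "fasta", "phylip": "phylip-sequential"}
_PHYLIP_ID_LIMIT = 10


@dataclass
class Msa:
    """A multiple sequence alignment over the amino-acid + gap alphabet.

    Attributes
    ----------
    ids : list of str
        Unique sequence identifiers, one per row.
    matrix : ndarray of shape (N, L), dtype U1
        Uppercased symbols; non-standard residues are mapped to ``X``.
    label : str
        Protein-family name.
    """

    ids: list[str]
    matrix: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="U1")
        if self.matrix.ndim != 2 or self.matrix.shape[0] < 1 or self.matrix.shape[1] < 1:
            raise AlignmentError("alignment must have at least one row and one column")
        if len(self.ids) != self.matrix.shape[0]:
            raise AlignmentError("number of ids does not match number of rows")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("duplicate sequence identifiers")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def codes(self) -> np.ndarray:
        """Integer-encoded matrix (see :mod:`intercoev.alphabet`)."""
        return encode(self.matrix)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Msa):
            return NotImplemented
        return (
            self.ids == other.ids
            and self.matrix.shape == other.matrix.shape
            and bool(np.all(self.matrix == other.matrix))
        )


@dataclass
class PairedAlignment:
    """Two row-matched alignments; row i of both members share an organism."""

    msaA: Msa
    msaB: Msa

    def __post_init__(self) -> None:
        if self.msaA.n != self.msaB.n:
            raise AlignmentError(
                f"paired alignments must have equal row counts "
                f"({self.msaA.n} != {self.msaB.n})"
            )

    @property
    def n(self) -> int:
        return self.msaA.n

    @property
    def length(self) -> int:
        """Total number of columns in both alignments (L)."""
        return self.msaA.length + self.msaB.length

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PairedAlignment):
            return NotImplemented
        return self.msaA == other.msaA and self.msaB == other.msaB


def _normalize_matrix(rows: list[str]) -> np.ndarray:
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise AlignmentError(f"rows have unequal lengths: {sorted(lengths)}")
    mat = np.array([list(r) for r in rows], dtype="U1")
    out = np.empty_like(mat)
    for ch in np.unique(mat):
        out[mat == ch] = normalize_symbol(ch)
    return out


def read_alignment(path, format: str = "fasta", label: str = "") -> Msa:
    """Read an alignment file into an :class:`Msa`.

    ``format`` is one of ``fasta``, ``phylip`` (sequential) or ``raw``
    (one sequence per line; identifiers ``seq1..seqN`` are synthesized).
    """
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    if format == "raw":
        with open(path) as fh:
            rows = [line.strip() for line in fh if line.strip()]
        if not rows:
            raise AlignmentError(f"no sequences in {path}")
        ids = [f"seq{i + 1}" for i in range(len(rows))]
        return Msa(ids, _normalize_matrix(rows), label=label)
    try:
        aln = AlignIO.read(path, _BIO_FORMAT[format])
    except ValueError as exc:
        raise AlignmentError(f"cannot parse {path} as {format}: {exc}") from exc
    ids = [rec.id for rec in aln]
    return Msa(ids, _normalize_matrix([str(rec.seq) for rec in aln]), label=label)


def _truncate_ids(ids: Sequence[str], limit: int) -> list[str]:
    """Truncate identifiers to ``limit`` chars, disambiguating with suffixes."""
    out: list[str] = []
    seen: dict[str, int] = {}
    for name in ids:
        short = name[:limit]
        if short in seen:
            k = seen[short] + 1
            while True:
                suffix = str(k)
                cand = short[: limit - len(suffix)] + suffix
                if len(suffix) >= limit:
                    raise AlignmentError(f"cannot disambiguate identifier {name!r}")
                if cand not in seen and cand not in out:
                    break
                k += 1
            seen[short] = k
            short = cand
        seen.setdefault(short, 0)
        out.append(short)
    return out


def write_alignment(msa: Msa, path, format: str = "fasta") -> None:
    """Write an alignment; PHYLIP identifiers are truncated to 10 characters."""
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}")
    rows = ["".join(r) for r in msa.matrix]
    if format == "raw":
        with open(path, "w") as fh:
            for r in rows:
                fh.write(r + "\n")
        return
    ids = msa.ids
    if format == "phylip":
        ids = _truncate_ids(ids, _PHYLIP_ID_LIMIT)
    records = [SeqRecord(Seq(r), id=i, description="") for i, r in zip(ids, rows)]
    AlignIO.write(MultipleSeqAlignment(records), path, _BIO_FORMAT[format])


def pair_alignments(
    msaA: Msa,
    msaB: Msa,
    key_fn: Callable[[str], str] | None = None,
) -> PairedAlignment:
    """Match rows of two alignments by a pairing key on their identifiers.

    The default key is the identifier itself.  Rows whose key is missing
    from the partner alignment are dropped (counts are logged).  A key that
    occurs more than once in either alignment is ambiguous and raises.
    """
    key_fn = key_fn or (lambda s: s)
    keysA = [key_fn(i) for i in msaA.ids]
    keysB = [key_fn(i) for i in msaB.ids]
    for name, keys in (("first", keysA), ("second", keysB)):
        if len(set(keys)) != len(keys):
            raise PairingError(f"pairing keys are not unique in the {name} alignment")
    lookupB = {k: r for r, k in enumerate(keysB)}
    rowsA, rowsB = [], []
    for r, k in enumerate(keysA):
        if k in lookupB:
            rowsA.append(r)
            rowsB.append(lookupB[k])
    if not rowsA:
        raise PairingError("no shared pairing keys between the two alignments")
    droppedA = msaA.n - len(rowsA)
    droppedB = msaB.n - len(rowsB)
    if droppedA or droppedB:
        logger.info("pairing dropped %d rows from A and %d rows from B", droppedA, droppedB)
    subA = Msa([msaA.ids[r] for r in rowsA], msaA.matrix[rowsA], label=msaA.label)
    subB = Msa([msaB.ids[r] for r in rowsB], msaB.matrix[rowsB], label=msaB.label)
    return PairedAlignment(subA, subB)


_ID_SEP = "|"


def concatenate(paired: PairedAlignment) -> Msa:
    """Horizontally concatenate the two members into one alignment.

    If the member identifiers differ row-wise they are joined with ``|`` so
    that :func:`split` can restore them exactly.
    """
    if paired.msaA.ids == paired.msaB.ids:
        ids = list(paired.msaA.ids)
    else:
        ids = [a + _ID_SEP + b for a, b in zip(paired.msaA.ids, paired.msaB.ids)]
    matrix = np.concatenate([paired.msaA.matrix, paired.msaB.matrix], axis=1)
    label = "+".join(x for x in (paired.msaA.label, paired.msaB.label) if x)
    return Msa(ids, matrix, label=label)


def split(concat: Msa, L_A: int, labelA: str = "", labelB: str = "") -> PairedAlignment:
    """Inverse of :func:`concatenate`: cut a concatenated alignment at L_A."""
    if not 1 <= L_A < concat.length:
        raise IndexError(f"split point {L_A} outside 1..{concat.length - 1}")
    if all(_ID_SEP in i for i in concat.ids):
        idsA = [i.split(_ID_SEP, 1)[0] for i in concat.ids]
        idsB = [i.split(_ID_SEP, 1)[1] for i in concat.ids]
        if len(set(idsA)) != len(idsA) or len(set(idsB)) != len(idsB):
            idsA = list(concat.ids)
            idsB = list(concat.ids)
    else:
        idsA = list(concat.ids)
        idsB = list(concat.ids)
    labels = concat.label.split("+", 1) if "+" in concat.label else [concat.label] * 2
    return PairedAlignment(
        Msa(idsA, concat.matrix[:, :L_A], label=labelA or labels[0]),
        Msa(idsB, concat.matrix[:, L_A:], label=labelB or labels[-1]),
    )


def filter_gap_columns(
    msa: Msa, max_gap_fraction: float = 0.75
) -> tuple[Msa, list[int]]:
    """Remove columns whose gap fraction strictly exceeds ``max_gap_fraction``.

    A column with gap fraction exactly equal to the threshold is kept.
    Returns the filtered alignment and the kept columns as 1-based indices
    into the original alignment.
    """
    if not 0.0 <= max_gap_fraction <= 1.0:
        raise ValueError("max_gap_fraction must be in [0, 1]")
    gap_frac = (msa.matrix == GAP).mean(axis=0)
    keep = gap_frac <= max_gap_fraction
    if not keep.any():
        raise AlignmentError("all columns removed by the gap filter")
    kept = [int(i) + 1 for i in np.nonzero(keep)[0]]
    return Msa(list(msa.ids), msa.matrix[:, keep], label=msa.label), kept


def filter_gap_columns_paired(
    paired: PairedAlignment, max_gap_fraction: float = 0.75
) -> tuple[PairedAlignment, list[int], list[int]]:
    """Apply the gap-column filter to both members of a paired alignment."""
    fA, keptA = filter_gap_columns(paired.msaA, max_gap_fraction)
    fB, keptB = filter_gap_columns(paired.msaB, max_gap_fraction)
    return PairedAlignment(fA, fB), keptA, keptB


def subsample(
    paired: PairedAlignment,
    sizes: Sequence[int],
    replicates: int = 1,
    seed: int = 0,
) -> list[PairedAlignment]:
    """Uniformly subsample row pairs without replacement.

    Every sequence pair has equal probability of being sampled.  For each
    size ``s`` and replicate ``r`` an independent stream seeded by
    ``(seed, s, r)`` is used, so individual sub-alignments are reproducible
    regardless of the order in which they are drawn.  Results are ordered
    size-major.
    """
    if replicates < 1:
        raise SamplingError("replicates must be >= 1")
    for s in sizes:
        if not 1 <= s <= paired.n:
            raise SamplingError(f"sample size {s} exceeds alignment depth {paired.n}")
    out: list[PairedAlignment] = []
    for s in sizes:
        for r in range(replicates):
            rng = np.random.default_rng([seed, s, r])
            rows = np.sort(rng.choice(paired.n, size=s, replace=False))
            subA = Msa(
                [paired.msaA.ids[i] for i in rows],
                paired.msaA.matrix[rows],
                label=paired.msaA.label,
            )
            subB = Msa(
                [paired.msaB.ids[i] for i in rows],
                paired.msaB.matrix[rows],
                label=paired.msaB.label,
            )
            out.append(PairedAlignment(subA, subB))
    return out
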