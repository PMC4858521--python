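"""Alignment-site filtering ahead of phylogenetic reconstruction.

Columns of a protein multiple alignment are scored by gap fraction (counting
``-`` and ``.``) and by homogeneity, and gappy or heterogeneous sites are
removed before tree building.  Homogeneity here is the mean pairwise
identity among the column's non-gap residues (1.0 when a single distinct
residue remains, 0.0 for an all-gap column), a bounded [0, 1] conservation
statistic; alternative definitions can be registered via ``homogeneity_fn``.

Removal defaults to the union reading -- a site is dropped when it is gappy
(gap fraction > 0.5) OR heterogeneous (homogeneity < 0.1) -- with a
conjunctive mode available for the literal "and" reading.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

GAP_CHARS = frozenset("-.")


class AlignmentFormatError(ValueError):
    """Empty or ragged alignment."""


@dataclass(frozen=True)
class ColumnStats:
    index: int
    gap_fraction: float
    homogeneity: float


def _column(alignment: Sequence[str], index: int) -> str:
    return "".join(seq[index] for seq in alignment)


def _check(alignment: Sequence[str]) -> int:
    if not alignment:
        raise AlignmentFormatError("empty alignment")
    length = len(alignment[0])
    if any(len(seq) != length for seq in alignment):
        raise AlignmentFormatError("ragged alignment: sequences differ in length")
    return length


def mean_pairwise_identity(residues: str) -> float:
    """Mean identity over unordered pairs of residues; 1.0 when fewer than
    two residues are present (a single character is trivially homogeneous)."""
    n = len(residues)
    if n < 2:
        return 1.0
    counts = Counter(residues)
    same = sum(c * (c - 1) // 2 for c in counts.values())
    return same / (n * (n - 1) // 2)


def column_stats(
    alignment: Sequence[str],
    index: int,
    homogeneity_fn: Callable[[str], float] = mean_pairwise_identity,
) -> ColumnStats:
    """Gap fraction and homogeneity of one column.

    Homogeneity is computed on non-gap characters only; an all-gap column
    has homogeneity 0.0 by convention.
    """
    length = _check(alignment)
    if not 0 <= index < length:
        raise IndexError(f"column {index} outside alignment of length {length}")
    if len(alignment) < 2:
        raise AlignmentFormatError("need at least two sequences")
    col = _column(alignment, index)
    gaps = sum(1 for c in col if c in GAP_CHARS)
    residues = "".join(c for c in col if c not in GAP_CHARS)
    homogeneity = 0.0 if not residues else homogeneity_fn(residues)
    return ColumnStats(
        index=index,
        gap_fraction=gaps / len(col),
        homogeneity=homogeneity,
    )


def filter_alignment(
    alignment: Sequence[str],
    gap_thresh: float = 0.5,
    hom_thresh: float = 0.1,
    mode: str = "union",
    homogeneity_fn: Callable[[str], float] = mean_pairwise_identity,
) -> tuple[list[str], list[int]]:
    """Remove gappy and/or heterogeneous columns.

    ``mode="union"`` (default) removes a column when gap_fraction >
    ``gap_thresh`` OR homogeneity < ``hom_thresh``; ``mode="intersection"``
    requires both.  Returns (filtered sequences in input order, removed
    0-based column indices).
    """
    length = _check(alignment)
    if mode not in ("union", "intersection"):
        raise ValueError(f"mode must be 'union' or 'intersection', got {mode!r}")
    removed: list[int] = []
    for i in range(length):
        stats = column_stats(alignment, i, homogeneity_fn=homogeneity_fn)
        gappy = stats.gap_fraction > gap_thresh
        hetero = stats.homogeneity < hom_thresh
        drop = (gappy or hetero) if mode == "union" else (gappy and hetero)
        if drop:
            removed.append(i)
    removed_set = set(removed)
    filtered = [
        "".join(c for i, c in enumerate(seq) if i not in removed_set)
        for seq in alignment
    ]
    return filtered, removed


def read_aligned_fasta(path: str | Path) -> tuple[list[str], list[str]]:
    """Read an aligned FASTA; returns (ids, sequences)."""
    from Bio import SeqIO

    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq))
    _check(seqs)
    return ids, seqs


def write_aligned_fasta(ids: Sequence[str], seqs: Sequence[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in zip(ids, seqs):
            fh.write(f">{name}\n{seq}\n")
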