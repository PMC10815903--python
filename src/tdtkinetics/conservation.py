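"""Alignment-column conservation profiling of the dNTP-binding pocket.

Works on a pre-computed multiple sequence alignment of TdT-family enzymes
(the alignment itself is produced upstream, e.g. by MAFFT).  Positions are
addressed in the ungapped 1-based numbering of a designated reference row
(human TdT), so that "position 395" means the 395th residue of the human
sequence regardless of alignment gaps.

The default pocket positions profile the residues lining the
nucleotide-binding site: Asp395, Leu397, Phe404, Trp449, Arg453, Glu456 and
Arg457.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "GAP",
    "AMBIGUOUS",
    "POCKET_POSITIONS",
    "AlignedSet",
    "ColumnProfile",
    "filter_redundancy",
    "map_reference_position",
    "column_frequencies",
    "pocket_profile",
]

GAP = "-"
AMBIGUOUS = frozenset("XBZ")

#: human-TdT numbering of the dNTP-binding-pocket residues
POCKET_POSITIONS = (395, 397, 404, 449, 453, 456, 457)


@dataclass
class AlignedSet:
    """A gapped protein alignment keyed by record id, with a reference row."""

    records: dict[str, str]
    reference_id: str

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment contains no records")
        if self.reference_id not in self.records:
            raise ValueError(f"reference id {self.reference_id!r} not in alignment")
        lengths = {len(s) for s in self.records.values()}
        if len(lengths) != 1:
            raise ValueError("all gapped sequences must have equal length")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.records.values())))

    @property
    def reference(self) -> str:
        return self.records[self.reference_id]


@dataclass
class ColumnProfile:
    """Residue percentages at one reference-numbered alignment column."""

    ref_position: int  # human TdT numbering, 1-based
    percents: dict[str, float]  # residue -> percent of non-gap characters
    counts: dict[str, int]
    n_sequences: int
    n_gap: int


def _ungapped(seq: str) -> str:
    return seq.replace(GAP, "")


def filter_redundancy(a: AlignedSet, min_coverage: float = 0.8) -> AlignedSet:
    """Drop exact duplicates and fragments; always keep the reference.

    A record is a duplicate when its ungapped sequence equals one already
    retained, and a fragment when its ungapped length is below
    ``min_coverage`` times the reference's ungapped length.  Idempotent.
    """
    ref_len = len(_ungapped(a.reference))
    kept: dict[str, str] = {a.reference_id: a.reference}
    seen = {_ungapped(a.reference)}
    for rid, seq in a.records.items():
        if rid == a.reference_id:
            continue
        bare = _ungapped(seq)
        if bare in seen:
            continue
        if len(bare) < min_coverage * ref_len:
            continue
        kept[rid] = seq
        seen.add(bare)
    if not kept:
        raise ValueError("redundancy filtering removed every record")
    # preserve original record order
    ordered = {rid: seq for rid, seq in a.records.items() if rid in kept}
    return AlignedSet(records=ordered, reference_id=a.reference_id)


def map_reference_position(a: AlignedSet, ref_position: int) -> int:
    """Alignment column (1-based) holding the ref_position-th reference residue."""
    if ref_position < 1:
        raise ValueError("ref_position is 1-based and must be >= 1")
    count = 0
    for col, ch in enumerate(a.reference, start=1):
        if ch != GAP:
            count += 1
            if count == ref_position:
                return col
    raise ValueError(
        f"ref_position {ref_position} exceeds the reference's ungapped length ({count})"
    )


def column_frequencies(
    a: AlignedSet, ref_position: int, *, exclude_ambiguous: bool = False
) -> ColumnProfile:
    """Percent of each residue among non-gap characters at a reference position.

    Gaps are counted separately and never enter the percentage denominator.
    Ambiguity codes (X, B, Z) count as their own symbols; with
    ``exclude_ambiguous`` they are dropped from the denominator as well.
    """
    col = map_reference_position(a, ref_position)
    chars = [seq[col - 1].upper() for seq in a.records.values()]
    n_gap = sum(1 for c in chars if c == GAP)
    residues = [c for c in chars if c != GAP]
    if not residues:
        raise ValueError(f"column for position {ref_position} contains only gaps")
    if exclude_ambiguous:
        residues = [c for c in residues if c not in AMBIGUOUS]
        if not residues:
            raise ValueError(
                f"column for position {ref_position} has no unambiguous residues"
            )
    counts: dict[str, int] = {}
    for c in residues:
        counts[c] = counts.get(c, 0) + 1
    denom = len(residues)
    percents = {c: 100.0 * n / denom for c, n in counts.items()}
    return ColumnProfile(
        ref_position=ref_position,
        percents=percents,
        counts=counts,
        n_sequences=len(a.records),
        n_gap=n_gap,
    )


def pocket_profile(
    a: AlignedSet,
    positions: Sequence[int] = POCKET_POSITIONS,
    *,
    exclude_ambiguous: bool = False,
) -> list[ColumnProfile]:
    """One :class:`ColumnProfile` per requested position, in input order."""
    return [
        column_frequencies(a, pos, exclude_ambiguous=exclude_ambiguous)
        for pos in positions
    ]
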