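"""Maximal gap intervals of aligned sequences.

A gap interval is a maximal run of consecutive ``'-'`` characters in one
aligned sequence, identified by its 1-based inclusive ``[start, end]``
column range.  Interval lists, ordered by start position, are the currency
of the optimized SP scorers: a sequence of length L holds at most ⌈L/2⌉
of them.
"""

from __future__ import annotations

from dataclasses import dataclass

from .msa import GAP, Alignment


@dataclass(frozen=True)
class GapInterval:
    """One maximal gap run, 1-based inclusive columns.

    ``terminal`` marks intervals touching the first or last column of the
    *full* alignment; the flag survives pairwise restriction so terminal
    gaps can be penalized differently.
    """

    start: int
    end: int
    terminal: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end}]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def same_span(self, other: "GapInterval") -> bool:
        return self.start == other.start and self.end == other.end


def compute_gap_intervals(seq: str, full_length: int | None = None) -> list[GapInterval]:
    """Extract the ordered maximal gap runs of one aligned sequence, O(L).

    ``full_length`` is the column count used for the terminal test
    (start == 1 or end == full_length); it defaults to ``len(seq)``.
    A gap-free sequence yields an empty list; an all-gap sequence yields
    the single interval ``(1, L)``.
    """
    L = len(seq)
    if full_length is None:
        full_length = L
    out: list[GapInterval] = []
    start: int | None = None
    for k, ch in enumerate(seq, start=1):
        if ch == GAP and start is None:
            start = k
        elif ch != GAP and start is not None:
            out.append(
                GapInterval(start, k - 1, terminal=(start == 1 or k - 1 == full_length))
            )
            start = None
    if start is not None:  # gap running to the last column
        out.append(GapInterval(start, L, terminal=(start == 1 or L == full_length)))
    return out


def alignment_gap_intervals(aln: Alignment) -> list[list[GapInterval]]:
    """Per-sequence gap interval lists with alignment-level terminal flags."""
    return [compute_gap_intervals(seq, full_length=aln.L) for seq in aln.seqs]


def max_gap_interval_count(aln: Alignment) -> int:
    """G_max: the largest number of gap intervals in any single sequence."""
    return max(len(lst) for lst in alignment_gap_intervals(aln))
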