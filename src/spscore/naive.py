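"""Reference O(n²L) SP-score by explicit pairwise restriction.

The sum-of-pairs score of an alignment is the sum, over all unordered
sequence pairs, of the score of the induced pairwise alignment: the
restriction obtained by deleting every column where both sequences carry a
gap.  This module materializes those restricted strings and scores them
directly.  It is deliberately slow and structurally independent of the
optimized interval-merge scorers, so agreement with them is meaningful
evidence of correctness.

Terminal status of a restricted gap interval is inherited from the
full-alignment interval that generated it, so that all scorers share one
convention (the residue column bounding an internal gap run is never
deleted by a restriction, so the inherited flag is also what restricted
coordinates would give).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

from .errors import UsageError
from .gap_costs import AffineGapCost, GapCostModel
from .gap_intervals import GapInterval, compute_gap_intervals
from .msa import GAP, Alignment, SubstitutionMatrix


@dataclass(frozen=True)
class ScoreBreakdown:
    """SP-score decomposition: total = substitutions + gaps.

    For affine models the gap term splits further into opening and
    extension contributions (``sp_g = sp_go + sp_ge``); for general gap
    cost functions ``sp_go``/``sp_ge`` are ``None``.
    """

    sp_s: float
    sp_g: float
    sp_go: float | None = None
    sp_ge: float | None = None
    stats: dict[str, Any] | None = field(default=None, compare=False)

    @property
    def sp_total(self) -> float:
        return self.sp_s + self.sp_g

    def __str__(self) -> str:  # pragma: no cover - display helper
        parts = [f"sp_s={self.sp_s}", f"sp_g={self.sp_g}"]
        if self.sp_go is not None:
            parts += [f"sp_go={self.sp_go}", f"sp_ge={self.sp_ge}"]
        parts.append(f"sp_total={self.sp_total}")
        return " ".join(parts)


def restrict_pair(aln: Alignment, i: int, j: int) -> tuple[str, str]:
    """The induced pairwise alignment of rows ``i`` and ``j`` (0-based).

    Deletes every column where both sequences have a gap; the returned
    strings have equal length <= L and no doubly-gapped column.
    """
    si_p, sj_p, _ = restrict_pair_with_columns(aln, i, j)
    return si_p, sj_p


def restrict_pair_with_columns(
    aln: Alignment, i: int, j: int
) -> tuple[str, str, list[int]]:
    """As :func:`restrict_pair`, also returning the kept 1-based columns."""
    if i == j:
        raise UsageError(f"cannot restrict a sequence against itself (index {i})")
    si, sj = aln.seqs[i], aln.seqs[j]
    kept = [k for k in range(1, aln.L + 1) if not (si[k - 1] == GAP and sj[k - 1] == GAP)]
    si_p = "".join(si[k - 1] for k in kept)
    sj_p = "".join(sj[k - 1] for k in kept)
    return si_p, sj_p, kept


def restricted_gap_intervals_reference(
    aln: Alignment, i: int, j: int
) -> tuple[list[GapInterval], list[GapInterval]]:
    """Gap intervals of the explicitly restricted pair, per sequence.

    Coordinates are in the restricted pairwise alignment; each interval
    carries the terminal flag of the originating full-alignment interval.
    This is the oracle against which the interval-merge restriction is
    validated.
    """
    si_p, sj_p, kept = restrict_pair_with_columns(aln, i, j)
    out = []
    for row, restricted in ((i, si_p), (j, sj_p)):
        full = compute_gap_intervals(aln.seqs[row], full_length=aln.L)
        # map: full column -> terminal flag of its containing gap interval
        col_flag = {}
        for iv in full:
            for c in range(iv.start, iv.end + 1):
                col_flag[c] = iv.terminal
        restricted_ivs = []
        for iv in compute_gap_intervals(restricted):
            origin_col = kept[iv.start - 1]
            restricted_ivs.append(
                GapInterval(iv.start, iv.end, terminal=col_flag[origin_col])
            )
        out.append(restricted_ivs)
    return out[0], out[1]


def naive_sp_score(
    aln: Alignment, matrix: SubstitutionMatrix, gcost: GapCostModel
) -> ScoreBreakdown:
    """Sum-of-pairs score by explicit enumeration of all restricted pairs.

    O(n²L) time.  When ``gcost`` is affine the gap term is also decomposed
    into opening and extension parts.
    """
    affine = isinstance(gcost, AffineGapCost)
    sp_s = 0.0
    sp_g = 0.0
    sp_go = 0.0
    sp_ge = 0.0
    n = aln.n
    for i in range(n):
        for j in range(i + 1, n):
            si, sj = aln.seqs[i], aln.seqs[j]
            for k in range(aln.L):
                x, y = si[k], sj[k]
                if x != GAP and y != GAP:
                    sp_s += matrix.score(x, y)
            lg_i, lg_j = restricted_gap_intervals_reference(aln, i, j)
            for iv in lg_i + lg_j:
                sp_g += gcost.evaluate(iv)
                if affine:
                    sp_go += gcost.opening_cost(iv)
                    sp_ge += gcost.extension_cost(iv)
    if affine:
        return ScoreBreakdown(sp_s=sp_s, sp_g=sp_g, sp_go=sp_go, sp_ge=sp_ge)
    return ScoreBreakdown(sp_s=sp_s, sp_g=sp_g)
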