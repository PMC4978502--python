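"""O(nL + n²·G_max) SP-score for arbitrary gap cost functions.

The substitution term is computed once from per-column symbol counts.  The
gap term needs, for every unordered sequence pair, the gap intervals of the
induced pairwise restriction — obtained here *without* building the
restricted strings, by merging the two per-sequence interval lists in order
of gap start while tracking the coordinate shift caused by doubly-gapped
columns.  Each pair therefore costs O(G_i + G_j) instead of O(L).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from .gap_costs import GapCostModel
from .gap_intervals import GapInterval, alignment_gap_intervals
from .msa import Alignment, SiteSymbolCounts, SubstitutionMatrix, site_symbol_counts
from .naive import ScoreBreakdown


@dataclass
class MergeCounters:
    """Instrumentation of one (or many accumulated) list-merge runs.

    ``steps`` counts main-loop iterations; each iteration consumes at least
    one interval, so per pair ``steps <= |LG_i| + |LG_j|``.  ``branches``
    tallies which interval relations were exercised.  ``shift`` is the final
    coordinate shift — the number of doubly-gapped columns of the pair.
    """

    steps: int = 0
    shift: int = 0
    branches: dict[str, int] = field(default_factory=dict)

    def hit(self, branch: str) -> None:
        self.branches[branch] = self.branches.get(branch, 0) + 1


def restrict_gap_intervals(
    lg_i: list[GapInterval],
    lg_j: list[GapInterval],
    counters: MergeCounters | None = None,
) -> tuple[list[GapInterval], list[GapInterval]]:
    """Gap intervals of the pairwise restriction, from full-sequence lists.

    Both inputs are ordered, maximal interval lists of two sequences of the
    same alignment (full-alignment coordinates).  The outputs are the
    interval lists that explicit restriction would produce, in restricted
    coordinates, each interval inheriting the terminal flag of its
    originating full-alignment interval.  Runs in O(|lg_i| + |lg_j|).

    Relations between current intervals (equal spans, containment either
    way, partial overlap, disjoint) are handled by explicit branches;
    because intervals of one sequence are maximal and sorted, equal starts
    always imply containment or equality.
    """
    out_i: list[GapInterval] = []
    out_j: list[GapInterval] = []
    ii = jj = 0
    shift = 0  # doubly-gapped columns consumed so far
    start_i: int | None = None  # pending restricted start of lg_i[ii]
    start_j: int | None = None

    def emit(out: list[GapInterval], iv: GapInterval, pending: int | None, sh: int) -> None:
        s = pending if pending is not None else iv.start - sh
        e = iv.end - sh
        if e >= s:  # interval may vanish entirely into doubly-gapped columns
            out.append(GapInterval(s, e, terminal=iv.terminal))

    while ii < len(lg_i) and jj < len(lg_j):
        if counters is not None:
            counters.steps += 1
        A, B = lg_i[ii], lg_j[jj]
        if A.start == B.start:
            if A.end == B.end:
                # identical spans: both vanish in the restriction
                if counters is not None:
                    counters.hit("equal")
                shift += A.length
                ii += 1
                jj += 1
                start_i = start_j = None
            elif B.end < A.end:  # B ⊂ A: B vanishes, A shrinks
                if counters is not None:
                    counters.hit("nested_j_in_i")
                if start_i is None:
                    start_i = A.start - shift
                shift += B.length
                jj += 1
                start_j = None
            else:  # A ⊂ B
                if counters is not None:
                    counters.hit("nested_i_in_j")
                if start_j is None:
                    start_j = B.start - shift
                shift += A.length
                ii += 1
                start_i = None
        elif A.start < B.start:
            if B.end <= A.end:  # B ⊂ A (strictly inside or sharing A's end)
                if counters is not None:
                    counters.hit("nested_j_in_i")
                if start_i is None:
                    start_i = A.start - shift
                shift += B.length
                jj += 1
                start_j = None
            else:
                # A closes before B does: A can be finalized now
                if start_i is None:
                    start_i = A.start - shift
                overlap = A.end - B.start + 1
                if overlap > 0:
                    if counters is not None:
                        counters.hit("overlap_i_first")
                    if start_j is None:
                        start_j = B.start - shift
                    shift += overlap
                elif counters is not None:
                    counters.hit("disjoint_i_first")
                emit(out_i, A, start_i, shift)
                ii += 1
                start_i = None
        else:  # B.start < A.start: mirror of the previous case
            if A.end <= B.end:  # A ⊂ B
                if counters is not None:
                    counters.hit("nested_i_in_j")
                if start_j is None:
                    start_j = B.start - shift
                shift += A.length
                ii += 1
                start_i = None
            else:
                if start_j is None:
                    start_j = B.start - shift
                overlap = B.end - A.start + 1
                if overlap > 0:
                    if counters is not None:
                        counters.hit("overlap_j_first")
                    if start_i is None:
                        start_i = A.start - shift
                    shift += overlap
                elif counters is not None:
                    counters.hit("disjoint_j_first")
                emit(out_j, B, start_j, shift)
                jj += 1
                start_j = None

    # flush the unexhausted list: no further shift changes are possible
    while ii < len(lg_i):
        emit(out_i, lg_i[ii], start_i, shift)
        start_i = None
        ii += 1
    while jj < len(lg_j):
        emit(out_j, lg_j[jj], start_j, shift)
        start_j = None
        jj += 1

    if counters is not None:
        counters.shift += shift
    return out_i, out_j


def sp_substitution_score(counts: SiteSymbolCounts, matrix: SubstitutionMatrix) -> float:
    """Substitution/match term from per-column symbol counts, O(L|Σ|²).

    Within one column, symbols x and y pair up c_x·c_y times (x ≠ y) and a
    symbol pairs with itself C(c_x, 2) times; gaps contribute nothing here.
    """
    total = 0.0
    for col in counts.counts:
        symbols = sorted(col)
        for a, x in enumerate(symbols):
            cx = col[x]
            total += cx * (cx - 1) // 2 * matrix.score(x, x)
            for y in symbols[a + 1 :]:
                total += cx * col[y] * matrix.score(x, y)
    return total


def general_sp_score(
    aln: Alignment,
    matrix: SubstitutionMatrix,
    gcost: GapCostModel,
    collect_stats: bool = False,
) -> ScoreBreakdown:
    """SP-score via per-pair interval-list merging, O(nL + n²·G_max).

    Matches :func:`spscore.naive.naive_sp_score` exactly for integer-valued
    models and to floating-point accuracy otherwise.  With
    ``collect_stats`` the returned breakdown carries merge instrumentation
    (per-pair step counts and branch coverage).
    """
    counts = site_symbol_counts(aln)
    sp_s = sp_substitution_score(counts, matrix)
    per_seq = alignment_gap_intervals(aln)
    sp_g = 0.0
    stats: dict | None = None
    if collect_stats:
        stats = {"pairs": [], "branches": {}}
    for i, j in combinations(range(aln.n), 2):
        counters = MergeCounters() if collect_stats else None
        lg_i_p, lg_j_p = restrict_gap_intervals(per_seq[i], per_seq[j], counters)
        for iv in lg_i_p:
            sp_g += gcost.evaluate(iv)
        for iv in lg_j_p:
            sp_g += gcost.evaluate(iv)
        if counters is not None:
            stats["pairs"].append(
                {
                    "i": i,
                    "j": j,
                    "steps": counters.steps,
                    "list_sizes": (len(per_seq[i]), len(per_seq[j])),
                    "shift": counters.shift,
                }
            )
            for b, c in counters.branches.items():
                stats["branches"][b] = stats["branches"].get(b, 0) + c
    return ScoreBreakdown(sp_s=sp_s, sp_g=sp_g, stats=stats)
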