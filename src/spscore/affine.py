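"""Exact O(nL) SP-score under affine gap penalties.

The three terms of the decomposition SP = SP_s + SP_go + SP_ge are each
computed in linear time:

* SP_s from the L×|Σ| per-column symbol counts;
* SP_ge per column: each gap character facing a residue in a pair's
  restriction contributes one extension cost, so a column with g gaps and
  n−g residues contributes g·(n−g)·gap_extend (terminal-interval gaps are
  counted separately when the terminal extension cost differs — a gap
  facing a gap occupies a column that the pair's restriction removes, so
  it contributes nothing);
* SP_go by a left-to-right sweep: a gap interval IG of one sequence
  survives the restriction against sequence j unless j has a gap interval
  containing IG, so it is charged n − c opening costs where c is the
  number of sequences whose gap interval contains IG (its own included).
  ``nbOpenGap[k]`` maintains the number of gap intervals covering column k
  that have not yet closed; reading it at IG.start when IG closes gives c.

Within one closing column all closing intervals are scored before any
counter is decremented — nested intervals sharing an end column otherwise
lose their container's contribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigError
from .gap_costs import AffineGapCost
from .gap_intervals import alignment_gap_intervals
from .msa import Alignment, SiteSymbolCounts, SubstitutionMatrix, site_symbol_counts
from .naive import ScoreBreakdown
from .general import sp_substitution_score


@dataclass
class SweepStats:
    """Instrumentation of one gap-opening sweep.

    ``decrements`` equals the total number of gap characters in the
    alignment (each interval decrements each covered column exactly once);
    ``nb_open_gap_final`` must be all zero after the sweep;
    ``surviving_openings`` is Σ (n − c) over intervals — the number of gap
    intervals that survive into some pairwise restriction, matching what
    the interval-merge scorer counts across all pairs.
    """

    decrements: int = 0
    nb_open_gap_final: list[int] = field(default_factory=list)
    surviving_openings: int = 0


def sp_gap_extension_score(
    counts: SiteSymbolCounts,
    gap_extend: float,
    gap_extend_terminal: float | None = None,
) -> float:
    """Gap-extension term from per-column gap counts, O(L).

    When terminal and internal extension costs differ, ``counts`` must have
    been built with ``split_terminal_gaps=True``.
    """
    if gap_extend_terminal is None:
        gap_extend_terminal = gap_extend
    split_needed = gap_extend_terminal != gap_extend
    if split_needed and counts.terminal_gap_counts is None:
        raise ConfigError(
            "terminal gap extension differs from internal: build counts with "
            "split_terminal_gaps=True"
        )
    total = 0.0
    n = counts.n
    for k, g in enumerate(counts.gap_counts):
        residues = n - g
        if residues == 0 or g == 0:
            continue
        g_term = counts.terminal_gap_counts[k] if split_needed else 0
        total += (g - g_term) * residues * gap_extend + g_term * residues * gap_extend_terminal
    return total


def sp_gap_opening_score(
    aln: Alignment,
    gap_open: float,
    gap_open_terminal: float | None = None,
    stats: SweepStats | None = None,
) -> float:
    """Gap-opening term by the nbOpenGap sweep, O(nL) total work."""
    if gap_open_terminal is None:
        gap_open_terminal = gap_open
    L = aln.L
    n = aln.n
    nb_open_gap = [0] * (L + 1)  # 1-based columns
    gap_closing: list[list] = [[] for _ in range(L + 1)]
    for seq_idx, lg in enumerate(alignment_gap_intervals(aln)):
        for iv in lg:
            for k in range(iv.start, iv.end + 1):
                nb_open_gap[k] += 1
            gap_closing[iv.end].append((seq_idx, iv))

    sp_go = 0.0
    for i in range(1, L + 1):
        # score every interval closing here before touching the counters
        for _, iv in gap_closing[i]:
            c = nb_open_gap[iv.start]
            cost = gap_open_terminal if iv.terminal else gap_open
            sp_go += (n - c) * cost
            if stats is not None:
                stats.surviving_openings += n - c
        for _, iv in gap_closing[i]:
            for k in range(iv.start, iv.end + 1):
                nb_open_gap[k] -= 1
                if stats is not None:
                    stats.decrements += 1
    if stats is not None:
        stats.nb_open_gap_final = nb_open_gap[1:]
    return sp_go


def affine_sp_score(
    aln: Alignment,
    matrix: SubstitutionMatrix,
    gap_open: float,
    gap_extend: float,
    gap_open_terminal: float | None = None,
    gap_extend_terminal: float | None = None,
    collect_stats: bool = False,
) -> ScoreBreakdown:
    """Full SP-score under affine gap penalties in O(nL).

    Equals :func:`spscore.naive.naive_sp_score` with the matching
    :class:`~spscore.gap_costs.AffineGapCost`, exactly for integer
    parameters.  Penalties are signed contributions (negative numbers).
    """
    split = gap_extend_terminal is not None and gap_extend_terminal != gap_extend
    counts = site_symbol_counts(aln, split_terminal_gaps=split)
    sp_s = sp_substitution_score(counts, matrix)
    sp_ge = sp_gap_extension_score(counts, gap_extend, gap_extend_terminal)
    stats = SweepStats() if collect_stats else None
    sp_go = sp_gap_opening_score(aln, gap_open, gap_open_terminal, stats=stats)
    stats_dict = None
    if stats is not None:
        stats_dict = {
            "decrements": stats.decrements,
            "nb_open_gap_final": stats.nb_open_gap_final,
            "surviving_openings": stats.surviving_openings,
        }
    return ScoreBreakdown(sp_s=sp_s, sp_g=sp_go + sp_ge, sp_go=sp_go, sp_ge=sp_ge, stats=stats_dict)


def affine_score_from_model(
    aln: Alignment,
    matrix: SubstitutionMatrix,
    model: AffineGapCost,
    collect_stats: bool = False,
) -> ScoreBreakdown:
    """Convenience wrapper taking an :class:`AffineGapCost` instance."""
    return affine_sp_score(
        aln,
        matrix,
        gap_open=model.gap_open,
        gap_extend=model.gap_extend,
        gap_open_terminal=model.gap_open_terminal,
        gap_extend_terminal=model.gap_extend_terminal,
        collect_stats=collect_stats,
    )
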