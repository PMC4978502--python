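"""Hardware-independent operation counting for the three scorers.

Wall-clock comparisons of asymptotically different algorithms are noisy
and machine-bound; instead each scorer reports the number of elementary
operations it performs (column visits, interval-merge steps, sweep counter
updates).  These counts make the complexity claims directly observable:
the affine scorer grows ~n·L, the general scorer ~n·L + n²·G_max, the
naive scorer ~n²·L.
"""

from __future__ import annotations

from itertools import product
from typing import Iterable

from .affine import affine_sp_score
from .general import general_sp_score
from .msa import Alignment, identity_matrix
from .gap_costs import AffineGapCost
from .synthetic import GeneratorConfig, generate_alignment

_MATRIX = identity_matrix(1, 0)
_MODEL = AffineGapCost(-3.0, -1.0)


def count_operations(aln: Alignment, algorithm: str) -> int:
    """Elementary operations one scorer spends on ``aln``.

    naive: one column visit per pair and column, n(n−1)/2 · L.
    general: the O(nL) counting/extraction pass plus measured merge steps
    and emitted restricted intervals.
    affine: the O(nL) counting pass plus measured sweep increments,
    decrements and column visits.
    """
    n, L = aln.n, aln.L
    if algorithm == "naive":
        return n * (n - 1) // 2 * L
    if algorithm == "general":
        bd = general_sp_score(aln, _MATRIX, _MODEL, collect_stats=True)
        merge_steps = sum(p["steps"] for p in bd.stats["pairs"])
        return n * L + merge_steps
    if algorithm == "affine":
        bd = affine_sp_score(aln, _MATRIX, _MODEL.gap_open, _MODEL.gap_extend, collect_stats=True)
        # increments mirror decrements; one sweep visit per column
        return n * L + 2 * bd.stats["decrements"] + L
    raise ValueError(f"unknown algorithm {algorithm!r}")


def run_benchmark(
    n_grid: Iterable[int],
    L_grid: Iterable[int],
    density_grid: Iterable[float],
    structures: Iterable[str],
    seed: int = 0,
    algorithms: Iterable[str] = ("naive", "general", "affine"),
) -> list[dict]:
    """Operation-count table over a configuration grid."""
    rows = []
    for idx, (n, L, dens, struct) in enumerate(product(n_grid, L_grid, density_grid, structures)):
        cfg = GeneratorConfig(n=n, L=L, gap_density=dens, structure=struct, seed=seed + idx)
        aln = generate_alignment(cfg)
        for algo in algorithms:
            rows.append(
                {
                    "n": n,
                    "L": L,
                    "gap_density": dens,
                    "structure": struct,
                    "algorithm": algo,
                    "operations": count_operations(aln, algo),
                }
            )
    return rows
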