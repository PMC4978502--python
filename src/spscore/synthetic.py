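"""Seeded generation of alignments with controllable gap structure.

Correctness of the scorers is established by cross-checking against the
explicit-restriction reference on large batches of random alignments, so
the generator aims at structural coverage of gap-interval interactions —
nesting, identical spans, dense alternation, overlap — not at biological
realism.  Generation is a pure function of the configuration: the same
seed yields a byte-identical alignment.

Gap placement (``independent`` structure): per sequence, the interval
count is drawn Poisson with mean L·gap_density/mean_gap_length, interval
lengths are geometric with the requested mean, and intervals are placed
uniformly, rejection-sampling overlaps and adjacencies so that intervals
stay maximal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .msa import DNA_ALPHABET, GAP, PROTEIN_ALPHABET, Alignment

STRUCTURES = ("independent", "nested", "identical-blocks", "alternating-worst-case")


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of one synthetic alignment.

    gap_density is the expected fraction of gap characters (in [0, 0.9]);
    mean_gap_length the expected gap-interval length (>= 1).
    """

    n: int
    L: int
    alphabet: str = "dna"
    gap_density: float = 0.2
    mean_gap_length: float = 3.0
    structure: str = "independent"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ConfigError("need n >= 2 sequences")
        if self.L < 1:
            raise ConfigError("need L >= 1 columns")
        if not 0.0 <= self.gap_density <= 0.9:
            raise ConfigError("gap_density must lie in [0, 0.9]")
        if self.mean_gap_length < 1.0:
            raise ConfigError("mean_gap_length must be >= 1")
        if self.alphabet not in ("dna", "protein"):
            raise ConfigError(f"unknown alphabet {self.alphabet!r}")
        if self.structure not in STRUCTURES:
            raise ConfigError(f"unknown structure {self.structure!r}")


def _residues(rng: np.random.Generator, k: int, sigma: str) -> list[str]:
    return [sigma[i] for i in rng.integers(0, len(sigma), size=k)]


def _place_intervals(
    rng: np.random.Generator, L: int, density: float, mean_len: float
) -> list[tuple[int, int]]:
    """Uniformly placed, non-adjacent gap runs (1-based inclusive)."""
    if density == 0.0 or L < 2:
        return []
    n_iv = rng.poisson(L * density / mean_len)
    placed: list[tuple[int, int]] = []
    for _ in range(n_iv):
        length = min(int(rng.geometric(1.0 / mean_len)), L - 1)
        for _attempt in range(30):
            start = int(rng.integers(1, L - length + 2))
            end = start + length - 1
            # keep a residue column between runs so each stays maximal
            if all(end < s - 1 or start > e + 1 for s, e in placed):
                placed.append((start, end))
                break
    return sorted(placed)


def _gap_mask_to_seq(rng: np.random.Generator, L: int, runs: list[tuple[int, int]], sigma: str) -> str:
    seq = _residues(rng, L, sigma)
    for s, e in runs:
        for k in range(s - 1, e):
            seq[k] = GAP
    return "".join(seq)


def generate_alignment(cfg: GeneratorConfig) -> Alignment:
    """Generate one alignment according to ``cfg`` (deterministic in seed)."""
    rng = np.random.default_rng(cfg.seed)
    sigma = DNA_ALPHABET if cfg.alphabet == "dna" else PROTEIN_ALPHABET
    n, L = cfg.n, cfg.L
    seqs: list[str] = []

    if cfg.structure == "independent":
        for _ in range(n):
            runs = _place_intervals(rng, L, cfg.gap_density, cfg.mean_gap_length)
            seqs.append(_gap_mask_to_seq(rng, L, runs, sigma))
    elif cfg.structure == "identical-blocks":
        shared = _place_intervals(rng, L, max(cfg.gap_density, 0.1), cfg.mean_gap_length)
        if not shared and L >= 3:
            shared = [(2, min(L - 1, 3))]
        for idx in range(n):
            if idx < 2:  # first two rows share the exact same gap pattern
                seqs.append(_gap_mask_to_seq(rng, L, shared, sigma))
            else:
                runs = _place_intervals(rng, L, cfg.gap_density, cfg.mean_gap_length)
                seqs.append(_gap_mask_to_seq(rng, L, runs, sigma))
    elif cfg.structure == "nested":
        # even rows carry long containers, odd rows strictly inside sub-runs
        containers = _place_intervals(rng, L, max(cfg.gap_density, 0.2), max(cfg.mean_gap_length, 4.0))
        if not containers and L >= 5:
            containers = [(2, min(L - 1, 6))]
        for idx in range(n):
            if idx % 2 == 0:
                seqs.append(_gap_mask_to_seq(rng, L, containers, sigma))
            else:
                inner = [
                    (s + 1, e - 1)
                    for s, e in containers
                    if e - s + 1 >= 3  # room for strict containment
                ]
                seqs.append(_gap_mask_to_seq(rng, L, inner, sigma))
    else:  # alternating-worst-case: gap interval count approaches ceil(L/2)
        for idx in range(n):
            offset = int(rng.integers(0, 2))
            chars = _residues(rng, L, sigma)
            for k in range(L):
                if (k + offset) % 2 == 0 and not (L == 1):
                    chars[k] = GAP
            # avoid all-gap rows when L == 1 handled above; keep at least the pattern
            seqs.append("".join(chars))

    ids = tuple(f"seq{i + 1}" for i in range(n))
    return Alignment(ids=ids, seqs=tuple(seqs), alphabet=sigma)


def edge_case_fixtures() -> dict[str, Alignment]:
    """Named alignments hitting every delicate case of the scorers.

    Includes the worked three-sequence example, degenerate columns and
    rows, terminal-only gaps, nested intervals sharing an end column, and
    one two-sequence fixture per interval relation the list-merge
    restriction must handle.
    """
    dna = DNA_ALPHABET

    def mk(*seqs: str) -> Alignment:
        return Alignment(
            ids=tuple(f"s{i + 1}" for i in range(len(seqs))),
            seqs=tuple(seqs),
            alphabet=dna,
        )

    return {
        "worked-3seq": mk("AC-GT", "A--GT", "ACCGT"),
        "all-gap-column": mk("AC-GT", "AG-TT", "CC-GA"),
        "all-gap-sequence": mk("ACGTA", "-----", "AGGTA"),
        "terminal-only": mk("--CGT", "ACG--", "ACGTA"),
        "shared-end-nested": mk("A----G", "ACC--G", "ACCTAG"),
        "equal-intervals": mk("A--GT", "C--GA"),
        "containment-i-in-j": mk("AC--GT", "A----T"),
        "containment-j-in-i": mk("A----T", "AC--GT"),
        "partial-overlap-ij": mk("A--CGT", "AC--GT"),
        "partial-overlap-ji": mk("AC--GT", "A--CGT"),
        "disjoint": mk("A--CGT", "ACCG-T"),
        "disjoint-reversed": mk("ACCG-T", "A--CGT"),
    }
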