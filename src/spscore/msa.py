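"""Alignment data model, FASTA I/O and substitution matrices.

An :class:`Alignment` is an ordered set of ``n`` equal-length gapped
sequences over an alphabet Σ plus the gap symbol ``'-'``.  Scoring treats
every unordered pair of rows as an induced pairwise alignment; the model
here only represents and validates alignments, it never modifies them.

Column coordinates are 1-based inclusive throughout the public API.
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass
from typing import IO, Mapping

from Bio import SeqIO
from Bio.Align import substitution_matrices

from .errors import AlignmentFormatError, AlphabetError, MatrixError

GAP = "-"

DNA_ALPHABET = "ACGT"
PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
DNA_AMBIGUITY = "RYSWKMBDHVN"
PROTEIN_AMBIGUITY = "BZJX"


@dataclass(frozen=True)
class Alignment:
    """A validated multiple sequence alignment.

    Parameters
    ----------
    ids
        Record identifiers, in input order.
    seqs
        Aligned sequences over ``Σ ∪ {'-'}``; all of identical length.
    alphabet
        The residue alphabet Σ (gap excluded).
    """

    ids: tuple[str, ...]
    seqs: tuple[str, ...]
    alphabet: str = PROTEIN_ALPHABET

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise AlignmentFormatError("ids and seqs differ in length")
        if len(self.seqs) < 2:
            raise AlignmentFormatError(
                f"an alignment needs at least 2 sequences, got {len(self.seqs)}"
            )
        L = len(self.seqs[0])
        if L < 1:
            raise AlignmentFormatError("alignment length must be >= 1")
        allowed = set(self.alphabet) | {GAP}
        for ident, seq in zip(self.ids, self.seqs):
            if len(seq) != L:
                raise AlignmentFormatError(
                    f"record '{ident}' has length {len(seq)}, expected {L}"
                )
            for col, ch in enumerate(seq, start=1):
                if ch not in allowed:
                    raise AlphabetError(
                        f"record '{ident}': character {ch!r} at column {col} "
                        f"is outside the alphabet"
                    )

    @property
    def n(self) -> int:
        """Number of sequences."""
        return len(self.seqs)

    @property
    def L(self) -> int:
        """Number of alignment columns (sites)."""
        return len(self.seqs[0])

    def column(self, k: int) -> str:
        """Column ``k`` (1-based) as a string of n characters."""
        return "".join(seq[k - 1] for seq in self.seqs)


def _normalize(seq: str, policy: str) -> str:
    seq = seq.upper().replace(".", GAP)
    if policy == "dna":
        seq = seq.replace("U", "T")
    return seq


def _looks_like_dna(residues: set[str], allow_ambiguity: bool) -> bool:
    dna = set(DNA_ALPHABET) | {"U"}
    if allow_ambiguity:
        dna |= set(DNA_AMBIGUITY)
    return residues <= dna


def read_alignment(
    source: str | os.PathLike | IO[str],
    alphabet_policy: str = "auto",
    allow_ambiguity: bool = False,
) -> Alignment:
    """Read an aligned multi-FASTA file or stream.

    Lowercase is folded to uppercase and ``'.'`` is normalized to ``'-'``.
    Under the ``dna`` policy ``U`` is mapped to ``T``.  Ambiguity codes are
    rejected unless ``allow_ambiguity`` is set, in which case they are part
    of the alphabet and are expected to score as mismatches.

    ``alphabet_policy`` is one of ``dna``, ``protein`` or ``auto`` (guess
    ``dna`` when all residues are nucleotide-like).
    """
    if alphabet_policy not in ("dna", "protein", "auto"):
        raise ValueError(f"unknown alphabet policy {alphabet_policy!r}")
    if isinstance(source, (str, os.PathLike)):
        with open(source) as fh:
            records = [(r.id, str(r.seq)) for r in SeqIO.parse(fh, "fasta")]
    else:
        records = [(r.id, str(r.seq)) for r in SeqIO.parse(source, "fasta")]
    if len(records) < 2:
        raise AlignmentFormatError(
            f"need at least 2 aligned records, found {len(records)}"
        )

    raw = [(ident, seq.upper().replace(".", GAP)) for ident, seq in records]
    if alphabet_policy == "auto":
        residues = {c for _, s in raw for c in s if c != GAP}
        alphabet_policy = "dna" if _looks_like_dna(residues, allow_ambiguity) else "protein"

    ids = tuple(ident for ident, _ in records)
    seqs = tuple(_normalize(seq, alphabet_policy) for _, seq in records)
    alphabet = DNA_ALPHABET if alphabet_policy == "dna" else PROTEIN_ALPHABET
    if allow_ambiguity:
        alphabet += DNA_AMBIGUITY if alphabet_policy == "dna" else PROTEIN_AMBIGUITY
    return Alignment(ids=ids, seqs=seqs, alphabet=alphabet)


def write_alignment(aln: Alignment, dest: str | os.PathLike | IO[str]) -> None:
    """Write the alignment as multi-FASTA, wrapped at 80 columns."""

    def _emit(fh: IO[str]) -> None:
        for ident, seq in zip(aln.ids, aln.seqs):
            fh.write(f">{ident}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")

    if isinstance(dest, (str, os.PathLike)):
        with open(dest, "w") as fh:
            _emit(fh)
    else:
        _emit(dest)


@dataclass
class SubstitutionMatrix:
    """Symmetric residue substitution scores with O(1) lookup."""

    alphabet: str
    scores: Mapping[tuple[str, str], float]
    name: str = "custom"

    def __post_init__(self) -> None:
        for x in self.alphabet:
            for y in self.alphabet:
                if (x, y) not in self.scores:
                    raise MatrixError(f"matrix {self.name!r} lacks pair ({x},{y})")
                if self.scores[(x, y)] != self.scores[(y, x)]:
                    raise MatrixError(
                        f"matrix {self.name!r} is asymmetric at ({x},{y}): "
                        f"{self.scores[(x, y)]} != {self.scores[(y, x)]}"
                    )

    def score(self, x: str, y: str) -> float:
        try:
            return self.scores[(x, y)]
        except KeyError:
            raise MatrixError(f"matrix {self.name!r} has no score for ({x},{y})")


def identity_matrix(
    match: float = 1.0,
    mismatch: float = 0.0,
    alphabet: str = PROTEIN_ALPHABET,
    ambiguity: str = "",
) -> SubstitutionMatrix:
    """Identity matrix: ``match`` on the diagonal, ``mismatch`` elsewhere.

    Symbols listed in ``ambiguity`` are appended to the alphabet and score
    ``mismatch`` against everything, themselves included.  The default
    protein alphabet is a superset of the nucleotide one, so the default
    matrix works for both sequence types.
    """
    scores: dict[tuple[str, str], float] = {}
    full = alphabet + "".join(c for c in ambiguity if c not in alphabet)
    for x in full:
        for y in full:
            if x == y and x in alphabet:
                scores[(x, y)] = match
            else:
                scores[(x, y)] = mismatch
    return SubstitutionMatrix(alphabet=full, scores=scores, name=f"identity({match},{mismatch})")


def _from_biopython(arr, name: str) -> SubstitutionMatrix:
    alphabet = "".join(c for c in arr.alphabet)
    scores = {
        (x, y): float(arr[x, y]) for x in alphabet for y in alphabet
    }
    return SubstitutionMatrix(alphabet=alphabet, scores=scores, name=name)


def load_substitution_matrix(spec: str | IO[str]) -> SubstitutionMatrix:
    """Load a substitution matrix.

    ``spec`` may be a built-in name (``BLOSUM62``, or ``identity:M,X`` with
    match/mismatch scores), a path to an NCBI-style square matrix file, or a
    text stream in that layout (header row of symbols, one labelled row per
    symbol).  Asymmetric or incomplete matrices raise :class:`MatrixError`.
    """
    if not isinstance(spec, str):
        return _read_ncbi_stream(spec, name="<stream>")
    if spec.upper() == "BLOSUM62":
        return _from_biopython(substitution_matrices.load("BLOSUM62"), "BLOSUM62")
    if spec.lower().startswith("identity"):
        params = spec.split(":", 1)[1] if ":" in spec else "1,0"
        try:
            match_s, mismatch_s = params.split(",")
            return identity_matrix(float(match_s), float(mismatch_s))
        except ValueError:
            raise MatrixError(f"cannot parse identity spec {spec!r}; expected identity:M,X")
    if os.path.exists(spec):
        with open(spec) as fh:
            return _read_ncbi_stream(fh, name=os.path.basename(spec))
    raise MatrixError(f"unknown matrix {spec!r}: not a builtin and not a readable file")


def _read_ncbi_stream(stream: IO[str], name: str) -> SubstitutionMatrix:
    try:
        arr = substitution_matrices.read(stream)
    except Exception as exc:
        raise MatrixError(f"cannot parse matrix {name!r}: {exc}") from exc
    return _from_biopython(arr, name)


@dataclass
class SiteSymbolCounts:
    """Per-column residue counts — the L×|Σ| table driving O(nL) scoring.

    ``counts[k]`` maps each residue appearing at 1-based column ``k+0`` (the
    list is 0-indexed) to its multiplicity; ``gap_counts[k]`` counts gap
    characters.  When built with ``split_terminal_gaps``, ``terminal_gap_counts``
    holds the subset of gaps belonging to terminal gap intervals (those
    touching column 1 or column L of the alignment).
    """

    n: int
    counts: list[dict[str, int]]
    gap_counts: list[int]
    terminal_gap_counts: list[int] | None = None

    def __post_init__(self) -> None:
        for k, (col, g) in enumerate(zip(self.counts, self.gap_counts)):
            if sum(col.values()) + g != self.n:
                raise ValueError(f"column {k + 1}: counts do not sum to n={self.n}")


def site_symbol_counts(aln: Alignment, split_terminal_gaps: bool = False) -> SiteSymbolCounts:
    """Count residues and gaps per column in a single O(nL) pass.

    With ``split_terminal_gaps``, gap characters belonging to terminal gap
    intervals (touching column 1 or L) are counted separately — the internal
    relabelling that lets gap-extension costs differ at sequence extremities.
    """
    L = aln.L
    counts: list[Counter] = [Counter() for _ in range(L)]
    gap_counts = [0] * L
    term_counts = [0] * L if split_terminal_gaps else None
    for seq in aln.seqs:
        if split_terminal_gaps:
            lead = len(seq) - len(seq.lstrip(GAP))
            trail_start = len(seq.rstrip(GAP))  # 0-based index of first trailing gap
        for k, ch in enumerate(seq):
            if ch == GAP:
                gap_counts[k] += 1
                if split_terminal_gaps and (k < lead or k >= trail_start):
                    term_counts[k] += 1
            else:
                counts[k][ch] += 1
    return SiteSymbolCounts(
        n=aln.n,
        counts=[dict(c) for c in counts],
        gap_counts=gap_counts,
        terminal_gap_counts=term_counts,
    )
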