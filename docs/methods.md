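# Methods

## Objective and decomposition

The sum-of-pairs score of an alignment A of n sequences and L columns is
the sum over all unordered sequence pairs of the score of the induced
pairwise alignment A|{Sᵢ,Sⱼ} (the restriction deleting every
doubly-gapped column). Each pairwise score is a substitution term over
gap-free columns plus a gap term over the maximal gap intervals of the
two restricted sequences, so SP = SP_s + SP_g; for affine gap costs
SP_g = SP_go + SP_ge. All three scorers in this package compute exactly
this quantity; they differ only in how.

Conventions shared by all scorers:

* Columns are 1-based inclusive in every reported interval; any 0-based
  indexing is internal.
* `'-'` is the canonical gap; `'.'` is normalized to `'-'` on input,
  case is folded to uppercase, and `U` maps to `T` under the DNA policy.
  Ambiguity codes are rejected unless explicitly allowed, in which case
  they score as mismatch-with-everything under the identity matrix.
* An alignment needs n ≥ 2; scoring a smaller input is an error rather
  than a zero score, to surface caller bugs.
* A gap interval is *terminal* when it touches column 1 or column L of
  the **full** alignment, and the flag is inherited through pairwise
  restriction. This convention is in fact the only consistent one: the
  residue column bounding an internal gap interval can never be deleted
  by a pairwise restriction (deletion requires a gap in the *same*
  sequence), so an internal interval can never drift to the edge of a
  restricted pair — full-alignment and restricted-coordinate
  classification coincide. Classifying once, up front, keeps the three
  scorers trivially consistent.
* Scores are accumulated as floats; with integer-valued matrices and gap
  parameters every intermediate value is an exactly representable
  integer, so cross-scorer equality tests are exact. Real-valued models
  (log, log-affine) are compared at 1e-9 relative tolerance.

## The three scorers

**Naive reference, O(n²L).** Materializes each restricted pair as
strings, scores columns directly and extracts gap runs from the
restricted strings. It is deliberately slow and shares no interval
arithmetic with the optimized paths, so agreement between the scorers is
meaningful evidence rather than a tautology.

**General gap costs, O(nL + n²·G_max).** SP_s comes from the L×|Σ|
per-column symbol counts: a column with counts c_x contributes
C(c_x, 2)·subst(x,x) + Σ_{x<y} c_x·c_y·subst(x,y). The gap term merges,
for each pair, the two per-sequence interval lists in order of start
position while maintaining `shift`, the number of doubly-gapped columns
consumed so far; emitted intervals are translated into restricted
coordinates by subtracting the shift current at the time their start
(resp. end) is fixed. The merge distinguishes equal spans, containment
in either direction, partial overlap in either order, and disjoint
intervals. Because intervals of one sequence are maximal and sorted,
equal starts always imply containment or equality. Two details the
pseudocode-level description leaves open are resolved here:

* an interval entirely consumed by two or more intervals of the partner
  sequence would be emitted with end < start; such empty intervals are
  suppressed (they correspond to gaps that vanish in the restriction);
* once one list is exhausted, the remaining intervals of the other are
  flushed with the final shift — no further doubly-gapped columns can
  occur.

Every iteration of the merge loop consumes at least one interval, so a
pair costs at most |LGᵢ| + |LGⱼ| steps (instrumented and asserted in the
tests). On alignments whose sequences alternate gap/residue the interval
counts approach ⌈L/2⌉ and the method degenerates to the naive cost — the
known worst case.

**Affine costs, O(nL).** SP_s as above. SP_ge per column: g gaps facing
n−g residues contribute g·(n−g)·gap_ext, because a gap facing a gap
occupies a column the restriction removes; when terminal extension costs
differ, gap characters of terminal intervals are counted separately (an
internal relabelling of the gap symbol) and no interaction term is
needed — a terminal gap facing an internal gap is still a gap facing a
gap. SP_go uses the counting identity: interval IGᵢ is charged n − c
openings, c being the number of sequences owning a gap interval
containing IGᵢ (itself included). A left-to-right sweep maintains
`nbOpenGap[k]`, the number of intervals covering column k that have not
yet closed; when IGᵢ closes at column e, `nbOpenGap[IGᵢ.start]` equals
c. Within one closing column **all** closing intervals are scored before
any counter is decremented; decrementing eagerly would corrupt c for a
container interval sharing its end column with a nested one (a dedicated
fixture covers this). Each interval increments and decrements each
covered column exactly once, so total counter updates equal twice the
number of gap characters ≤ 2nL, and the counters must return to zero
after the sweep — both asserted.

## Substitution matrices and formats

Aligned FASTA is read and written through Biopython; output wraps at 80
columns. Matrices are the built-in BLOSUM62 (Biopython's table), an
identity matrix with configurable match/mismatch scores, or an
NCBI-layout text file parsed by Biopython; symmetry and completeness
over the alphabet are validated at construction, naming the first
offending pair.

## Synthetic alignments

The generator exists for structural coverage of gap-interval
interactions, not biological realism: residues are i.i.d. uniform and
gaps are placed by an explicit spatial model, so conclusions about real
data rest on the exactness of the algorithms (they compute the same
objective on any input), not on the generator's fidelity. Defaults:
gap density 0.2, mean gap length 3, DNA alphabet. Per sequence, the
interval count is Poisson with mean L·density/mean_length, lengths are
geometric with the requested mean (capped at L−1), and placements are
uniform with rejection of overlaps/adjacencies so runs stay maximal;
rejection is capped at 30 attempts per interval, so realized density can
fall slightly below the request at high densities — irrelevant to
correctness testing, which only needs varied structure. Four structure
modes: `independent`; `nested` (even rows carry long containers, odd
rows strictly contained sub-runs); `identical-blocks` (two rows share an
exact gap pattern, exercising interval cancellation); and
`alternating-worst-case` (every other column gapped, driving interval
counts to ~L/2, the merge scorer's worst case). Generation is a pure
function of the configuration, seed included.

Test and acceptance batches use 1000 alignments with n ∈ [2,12],
L ∈ [1,60] and gap densities in [0, 0.8] across all four modes — small
enough that the whole suite runs in well under a minute, large enough
that every merge branch and degenerate case (all-gap columns, all-gap
sequences, shared end columns, terminal-only gaps) is exercised both by
construction (named fixtures) and by chance.

## Design choices and limitations

* Gap cost models depend only on an interval's length and terminal
  status; costs depending on the partner sequence or on column content
  are out of contract. Position-specific (profile-style) penalties are
  not supported.
* The log and log-affine parameterizations are the conventional
  a + b·ln(len) and a + b·len + c·ln(len); any O(1) function of a
  flagged interval can be plugged in via the `GapCostModel` protocol.
* An all-gap sequence is permitted (it restricts to an empty pair
  against another all-gap sequence, contributing zero) and handled by
  all scorers.
* Benchmarks report abstract operation counts (column visits, merge
  steps, sweep updates) rather than wall-clock, so scaling claims are
  hardware-independent.
* There is no incremental score update under alignment edits; each call
  scores from scratch. Alignment construction/refinement itself is out
  of scope.
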