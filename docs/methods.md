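# Methods

## Scope and model

`epigraft` computes a scaffold-based mimic of a donor antigen in five
stages: interface footprinting, epitope-stretch selection, grafting,
proteome-9-mer elimination, and liability-variant application. The
package treats the reference proteome, the complex structures, the donor
and scaffold sequences and the species-variant alignment purely as
inputs; it performs no structure prediction, energy calculation or
binding-affinity estimation, and no prediction of MHC binding — the
humanness criterion is exact 9-mer identity only.

## Solvent-accessible and buried surface area

SASA uses Shrake–Rupley quadrature: each atom is expanded by the probe
radius (default 1.4 Å, water-sized) and covered with a golden-spiral
point set (default n = 960); the accessible fraction is the fraction of
points outside every neighbouring expanded sphere. Van der Waals radii
come from a fixed Bondi-style element table (C 1.70, N 1.55, O 1.52,
S 1.80 … Å); unknown elements fall back to 1.8 Å with a warning.

Two numerical choices matter:

* **Equivariant quadrature orientation.** Each atom's point set is
  oriented by a frame built from the directions to its nearest and
  second-nearest neighbours (ties broken by atom index; collinear or
  single-atom neighbourhoods fall back to a fixed global azimuth, which
  is exact there by axial symmetry). Because the frame is a function of
  the coordinates, a rigid motion of the model moves the points with it:
  SASA is translation- and rotation-invariant to floating-point
  precision, not merely to quadrature accuracy. A second consequence is
  used by the footprint stage: an atom whose local neighbourhood is the
  same in two models receives bit-identical points and occluders in
  both, so the buried area of residues far from any partner is exactly
  zero, with no noise floor. A pleasant side effect of aligning the
  polar axis to the nearest neighbour is that the golden spiral's
  equal-area z-bands integrate a single axial occluder exactly, so
  two-sphere configurations reproduce the closed-form spherical-cap area
  to machine precision; the tested guarantee is nevertheless the
  quadrature bound of 2 %.

* **Per-residue BSA** is the sum over a residue's atoms of
  SASA(target chains isolated) − SASA(full partitioned complex), clamped
  at zero per residue. Only the chains named in the partition enter the
  complex computation, so extra copies or tags in a file cannot
  contaminate the footprint. Donor positions missing from a structure
  get BSA 0 and are flagged as unmodelled.

Structure numbering is mapped to 1-based donor positions by globally
aligning each target chain's extracted sequence to the donor FASTA; a
structure residue that falls under a donor gap is a hard error rather
than a silent shift. Alternate conformations keep the highest-occupancy
conformer (ties by altloc identifier); waters, ions, glycans and other
non-polymer hetero groups are dropped on load.

## Stretch selection

A donor position is *critical* when its BSA reaches the contact
threshold (default 1.0 Å² — deliberately permissive, catching any
genuinely buried residue while quadrature noise is exactly zero by the
construction above) against at least `min_partners` partners (default 2:
an epitope supported by independent binders). Runs of critical positions
at most `gap_merge + 1` apart (default bridges 2 residues, keeping short
interruptions of a structurally contiguous patch in one transplantable
unit) are merged; each stretch records the union of supporting partners.
Selection is independent of partner iteration order, and raising either
threshold can only shrink the critical set. The threshold, gap rule and
partner minimum are all configurable and echoed into every report, since
reasonable alternatives exist for all three.

## Grafting

Donor→scaffold correspondence comes from one global pairwise alignment
(BLOSUM62, gap open −11 / gap extend −1, where "open" is the score of a
gap's first column; Biopython's canonical first alignment provides the
deterministic tie-break). Stretch columns take the donor residue:
matches and mismatches become substitutions in place, scaffold gaps
under stretch residues become insertions, and scaffold residues under
donor gaps bracketed by a single stretch are deleted — so the grafted
region is exactly the donor's stretch sequence, and everything outside
is exactly the scaffold. The graft plan records the full
position mapping, which downstream stages use both to lock the epitope
and to map substitution-pool columns.

## Proteome screen and dehumanization

The humanness screen indexes every length-k window (default k = 9, the
canonical T-cell epitope core length) of every reference protein in an
exact hash map; scanning reports each query window present in the index
with all its sources. Identity is strict: no I/L equivalence, no
near-matches. The unknown residue X poisons any window containing it on
both sides; the ambiguity codes B/Z/J/U/O are rejected outright rather
than remapped, since silently remapping them would distort an
exact-identity screen. Every report carries a content checksum of the
proteome, because the screen's meaning is relative to a specific
proteome release.

Dehumanization is greedy set cover over the matched windows. Each round
rescans the sequence and evaluates every (mutable position, allowed
replacement): a replacement is legal only if none of the ≤ k windows it
rewrites becomes an index key — checked exactly — so every applied
mutation strictly reduces the match count and the loop terminates. The
applied mutation maximizes windows destroyed, with ties broken by higher
pool weight, lower position, then alphabetical replacement (fully
deterministic). Replacements are restricted to residues observed at that
column of the species-variant alignment at least `min_count` times
(default 1), the idea being that a residue tolerated by evolution at
that position is least likely to disrupt fold or expression; grafted
insertions, which have no own column, inherit the nearest
scaffold-derived neighbour's pool and are flagged. Transplanted epitope
positions and user-locked sites are immutable, ever. Termination is an
explicit status — `clean` (zero matches, re-verified by a full rescan),
`infeasible` (some remaining window admits no legal destroying mutation,
e.g. it lies wholly inside the epitope), or `budget_exhausted` (default
budget 50 mutations) — never an exception. Greedy set cover is not
guaranteed minimal in general, but on single-window fixtures it uses
exactly one mutation and on double-window fixtures it matches the
exhaustive minimum (one if the windows overlap at a legally mutable
position, else two), which the test suite verifies by enumeration.

Liability variants (e.g. protease-site removals identified
experimentally) are applied last as named substitutions; each variant's
from-residue must match the sequence at its stated position, guarding
against numbering-convention mistakes. Numbering is 1-based over the
construct sequence as supplied.

## Synthetic data

The generators emulate each real input with exact, recorded ground
truth; one seeded NumPy generator stream per fixture, consumed in fixed
order, makes regeneration byte-identical.

* **Decoy proteomes** draw uniform sequences over a configurable
  alphabet; *planting* copies chosen query windows into chosen proteins,
  rejecting contradictory overlaps, so the expected match set is known
  exactly (and choosing disjoint alphabets makes chance matches
  impossible).
* **Toy complexes** use single-sphere residues of radius 1.9 Å at 3.8 Å
  spacing (carbon-like spheres at Cα spacing), so every geometric
  expectation reduces to the closed-form cap formula. The target chain
  is a straight line; the partner places one sphere at the requested
  distance from each contact-span residue. At close distances a sphere
  in register over a span boundary would also graze the neighbouring
  non-span residue (3.8 Å along the chain and ~3.3 Å across is within
  the 6.6 Å contact range), so the boundary spheres are leaned inward
  just enough that every non-span residue stays ≥ 2(r + probe) + 0.05 Å
  from every partner sphere; remaining partner residues are parked on a
  distant rail. The achieved contact set is verified against the request
  after construction — interior length-1 spans at close distance, which
  cannot satisfy both constraints, raise a geometric-impossibility
  error. The default inter-chain distance 3.3 Å buries ~16–34 Å² per
  span residue, far above the 1.0 Å² contact threshold.
* **Species MSAs** substitute each column of each non-base row
  independently with probability `sub_rate` (bundled study: 0.1, giving
  most columns at least one observed alternative among 7 variant rows)
  and return exact per-column counts.
* The **bundled study** (seed 7) ties these together: a 40-residue donor;
  two partners each burying donor spans 5–8 and 12–14; a scaffold made
  by mutating ~35 % of donor positions; two grafted-sequence windows
  planted into a 20-protein decoy proteome away from the epitope; an
  8-row species MSA. Problem sizes are deliberately small — the design
  computation is exact, not statistical, so a fixture that exercises
  every code path (multiple partners, multiple stretches, overlapping
  planted windows, restricted pools) demonstrates correctness as well as
  a large one would.

What the synthetic fixtures do **not** emulate: realistic folds or
interface shapes (single-sphere residues have no side chains or
packing), realistic proteome composition (uniform sequences have far
fewer repeated 9-mers than real proteomes), phylogenetic correlation
among species variants, or missing residues/altlocs of real crystal
structures. Passing tests therefore demonstrate algorithmic correctness
of footprinting, selection, grafting and screening — not that a
particular BSA threshold or gap rule is biologically optimal for a given
real antigen; those remain configurable calibration choices, echoed into
every report.

## Pipeline and provenance

The orchestrated run executes the five stages from one YAML
configuration, writes every intermediate (footprint TSV, stretch
TSV/JSON, graft plan JSON, mutation TSV, humanness TSV/JSON, construct
FASTA) plus a report that echoes the full parameter set and the SHA-256
digest of every input file. Reports contain no timestamps (those live in
the run log), so re-running the same configuration on the same inputs
reproduces the report byte-identically. Stage failures write a `FAILED`
marker naming the stage and re-raise with the stage name; an empty
stretch selection halts the pipeline before grafting rather than
producing an unconstrained design.

## Known limitations

* The Shrake–Rupley implementation is a per-atom Python loop over a KD
  tree — ample for the fixtures and for single antigen-sized complexes,
  but not tuned for high-throughput scanning of large structures.
* Greedy mutation selection can exceed the true minimum on three or more
  densely overlapping windows; the bound mutation count ≤ initial match
  count always holds.
* The optional per-position penalty hook for structure-guided mutation
  preferences is exposed in the pool weights (any positive weights may
  be supplied) but no structural scoring is computed in-package.
* Pairwise-alignment tie-breaking delegates to the alignment library's
  canonical order; equal-scoring alignments are resolved
  deterministically but not configurably.
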