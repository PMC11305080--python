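"""Epitope grafting and proteome-9-mer elimination.

This is the design core of the package: donor epitope stretches are mapped
onto a homolog scaffold through a global alignment and transplanted; the
grafted sequence is then *dehumanized* — every length-k window shared with
the reference proteome is destroyed by greedy point mutation, with the
transplanted epitope positions locked and replacements restricted to
residues actually observed at that position among species variants of the
antigen.  A mutation is legal only if none of the (at most k) windows it
rewrites becomes a new proteome hit, so the loop strictly shrinks the
match set and terminates with an explicit status rather than an exception.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

from .alignment import GAP, PairwiseAlignment, global_align
from .footprint import EpitopeStretch
from .humanness import (
    AMINO_ACIDS,
    HumannessReport,
    KmerIndex,
    scan_sequence,
    validate_protein_sequence,
)

__all__ = [
    "GraftPlan",
    "SubstitutionPool",
    "Mutation",
    "DesignCandidate",
    "align_donor_scaffold",
    "transplant_stretches",
    "build_substitution_pool",
    "dehumanize",
    "apply_variants",
    "evaluate_design",
]


def align_donor_scaffold(
    donor: str,
    scaffold: str,
    matrix: str = "BLOSUM62",
    gap_open: float = -11.0,
    gap_extend: float = -1.0,
) -> PairwiseAlignment:
    """Global alignment giving the donor -> scaffold positional correspondence."""
    return global_align(donor, scaffold, matrix, gap_open, gap_extend)


@dataclass
class GraftPlan:
    """Record of a transplant: which grafted positions carry donor residues.

    ``transplanted`` maps 1-based positions of the *grafted* sequence to the
    donor residue placed there; ``graft_to_scaffold`` maps every grafted
    position to its scaffold position (None for residues inserted because
    the scaffold had a gap inside a stretch).
    """

    stretches: list[EpitopeStretch]
    transplanted: dict[int, str] = field(default_factory=dict)
    graft_to_scaffold: dict[int, int | None] = field(default_factory=dict)
    substitutions: list[tuple[int, str, str]] = field(default_factory=list)
    insertions: list[tuple[int, str]] = field(default_factory=list)
    deletions: list[tuple[int, str]] = field(default_factory=list)

    @property
    def transplanted_positions(self) -> set[int]:
        return set(self.transplanted)


def transplant_stretches(
    scaffold: str,
    donor: str,
    stretches: list[EpitopeStretch],
    alignment: PairwiseAlignment,
) -> tuple[str, GraftPlan]:
    """Copy the donor residues of each stretch onto the scaffold.

    Outside the stretch columns the grafted sequence is the scaffold;
    inside, it is exactly ``donor[start..end]``: scaffold mismatches become
    substitutions, scaffold gaps under stretch residues become insertions,
    and scaffold residues under donor gaps bracketed by one stretch are
    deleted.
    """
    if alignment.donor != donor or alignment.scaffold != scaffold:
        raise ValueError("alignment does not correspond to the given sequences")
    for st in stretches:
        if st.start < 1 or st.end > len(donor):
            raise ValueError(f"stretch [{st.start},{st.end}] outside donor range")

    def stretch_of(donor_pos: int | None) -> int | None:
        if donor_pos is None:
            return None
        for i, st in enumerate(stretches):
            if st.start <= donor_pos <= st.end:
                return i
        return None

    # donor-gap columns are inside a stretch when the nearest donor
    # positions on both sides belong to the same stretch
    cols = alignment.column_map
    n = len(cols)
    in_stretch = [stretch_of(d) for d, _ in cols]
    prev_idx: list[int | None] = [None] * n
    last = None
    for i, (d, _) in enumerate(cols):
        prev_idx[i] = last
        if d is not None:
            last = i
    next_idx: list[int | None] = [None] * n
    nxt = None
    for i in range(n - 1, -1, -1):
        next_idx[i] = nxt
        if cols[i][0] is not None:
            nxt = i
    for i, (d, _) in enumerate(cols):
        if d is None:
            p, q = prev_idx[i], next_idx[i]
            if (
                p is not None
                and q is not None
                and in_stretch[p] is not None
                and in_stretch[p] == in_stretch[q]
            ):
                in_stretch[i] = in_stretch[p]

    plan = GraftPlan(stretches=list(stretches))
    out: list[str] = []
    for i, (dpos, spos) in enumerate(cols):
        dch = alignment.aligned_donor[i]
        sch = alignment.aligned_scaffold[i]
        if in_stretch[i] is not None:
            if dch == GAP:
                plan.deletions.append((spos, sch))
                continue
            out.append(dch)
            gpos = len(out)
            plan.transplanted[gpos] = dch
            plan.graft_to_scaffold[gpos] = spos
            if sch == GAP:
                plan.insertions.append((gpos, dch))
            elif sch != dch:
                plan.substitutions.append((spos, sch, dch))
        else:
            if sch == GAP:
                continue
            out.append(sch)
            plan.graft_to_scaffold[len(out)] = spos
    return "".join(out), plan


@dataclass
class SubstitutionPool:
    """Allowed replacements per position, weighted by observed frequency.

    ``pools[pos]`` maps replacement amino acids to positive weights; the
    current residue of the working sequence is never in its own pool.
    ``inherited`` flags positions (grafting insertions) whose pool was
    borrowed from the nearest scaffold-derived neighbour.
    """

    pools: dict[int, dict[str, float]] = field(default_factory=dict)
    inherited: set[int] = field(default_factory=set)

    def replacements(self, pos: int) -> dict[str, float]:
        return self.pools.get(pos, {})

    @classmethod
    def unrestricted(cls, sequence: str, positions=None) -> "SubstitutionPool":
        """All 19 alternatives at each position, unit weight (testing aid)."""
        positions = range(1, len(sequence) + 1) if positions is None else positions
        pools = {
            p: {aa: 1.0 for aa in AMINO_ACIDS if aa != sequence[p - 1]}
            for p in positions
        }
        return cls(pools=pools)


def build_substitution_pool(
    msa: dict[str, str],
    scaffold_id: str,
    sequence: str,
    positions,
    min_count: int = 1,
    graft_to_scaffold: dict[int, int | None] | None = None,
) -> SubstitutionPool:
    """Per-position replacement sets from a species-variant alignment.

    The alignment's scaffold row anchors the column mapping: scaffold
    position p corresponds to the column where the (degapped) scaffold row
    reaches its p-th residue.  The pool at a sequence position is every
    amino acid observed at least ``min_count`` times in that column (gaps
    and X excluded), minus the residue currently in the sequence.  Grafted
    insertions (scaffold position None) inherit the nearest mapped
    neighbour's column and are flagged.
    """
    if scaffold_id not in msa:
        raise ValueError(f"scaffold row {scaffold_id!r} not in alignment")
    scaffold_row = msa[scaffold_id]
    width = len(scaffold_row)
    if any(len(row) != width for row in msa.values()):
        raise ValueError("alignment rows differ in length")
    pos_to_col: dict[int, int] = {}
    p = 0
    for col, ch in enumerate(scaffold_row):
        if ch != GAP:
            p += 1
            pos_to_col[p] = col

    g2s = graft_to_scaffold or {}
    pool = SubstitutionPool()
    for pos in sorted(positions):
        spos = g2s.get(pos, pos) if not g2s else g2s.get(pos)
        if g2s and pos not in g2s:
            raise ValueError(f"position {pos} absent from graft mapping")
        if spos is None:
            spos = _nearest_scaffold_pos(pos, g2s)
            pool.inherited.add(pos)
        col = pos_to_col.get(spos)
        if col is None:
            raise ValueError(f"no alignment column for scaffold position {spos}")
        counts: dict[str, int] = {}
        for row in msa.values():
            aa = row[col].upper()
            if aa == GAP or aa == "X":
                continue
            counts[aa] = counts.get(aa, 0) + 1
        current = sequence[pos - 1]
        pool.pools[pos] = {
            aa: float(c) for aa, c in counts.items() if c >= min_count and aa != current
        }
    return pool


def _nearest_scaffold_pos(pos: int, g2s: dict[int, int | None]) -> int:
    mapped = [(abs(p - pos), p, s) for p, s in g2s.items() if s is not None]
    if not mapped:
        raise ValueError("graft mapping contains no scaffold-derived position")
    mapped.sort()
    return mapped[0][2]


@dataclass(frozen=True)
class Mutation:
    """A point substitution, 1-based, with the windows it destroyed."""

    position: int
    from_aa: str
    to_aa: str
    windows_destroyed: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.from_aa == self.to_aa:
            raise ValueError("mutation must change the residue")

    @property
    def label(self) -> str:
        return f"{self.from_aa}{self.position}{self.to_aa}"

    def inverse(self) -> "Mutation":
        return dc_replace(self, from_aa=self.to_aa, to_aa=self.from_aa)


@dataclass
class DesignCandidate:
    """A (possibly partially) dehumanized sequence with full provenance."""

    sequence: str
    mutations: list[Mutation]
    humanness: HumannessReport
    epitope_intact: bool
    status: str  # clean | infeasible | budget_exhausted
    offending_windows: list[int] = field(default_factory=list)


def _new_windows_ok(seq: str, pos: int, k: int, index: KmerIndex) -> bool:
    """True when no window covering ``pos`` of ``seq`` is an index key."""
    lo = max(1, pos - k + 1)
    hi = min(len(seq) - k + 1, pos)
    for s in range(lo, hi + 1):
        w = seq[s - 1 : s - 1 + k]
        if "X" in w:
            continue
        if w in index:
            return False
    return True


def dehumanize(
    seq: str,
    index: KmerIndex,
    immutable: set[int],
    pool: SubstitutionPool,
    max_mutations: int = 50,
    expected_residues: dict[int, str] | None = None,
) -> DesignCandidate:
    """Greedily remove every proteome k-mer match by constrained point mutation.

    Each round rescans the sequence, scores every (mutable position,
    allowed replacement) by the number of currently matched windows the
    substitution destroys, discards replacements that would create any new
    indexed window, and applies the best: most windows destroyed, then
    highest pool weight, then lowest position, then alphabetical
    replacement.  Terminates with status ``clean`` (no matches left),
    ``infeasible`` (remaining matches admit no legal destroying mutation)
    or ``budget_exhausted``; the final sequence is re-verified by a full
    rescan.
    """
    seq = validate_protein_sequence(seq)
    if any(p < 1 or p > len(seq) for p in immutable):
        raise ValueError("immutable positions outside sequence")
    expected = expected_residues or {p: seq[p - 1] for p in immutable}
    k = index.k
    mutations: list[Mutation] = []
    status = "clean"
    offending: list[int] = []

    while True:
        report = scan_sequence(seq, index)
        if report.is_clean:
            status = "clean"
            break
        if len(mutations) >= max_mutations:
            status = "budget_exhausted"
            offending = [m.query_start for m in report.matches]
            break
        matched_starts = [m.query_start for m in report.matches]
        best = None  # (destroyed, weight, -pos ordering handled via tuple)
        for pos in range(1, len(seq) + 1):
            if pos in immutable:
                continue
            covering = [s for s in matched_starts if s <= pos <= s + k - 1]
            if not covering:
                continue
            for aa in sorted(pool.replacements(pos)):
                weight = pool.replacements(pos)[aa]
                if aa == seq[pos - 1]:
                    continue
                trial = seq[: pos - 1] + aa + seq[pos:]
                if not _new_windows_ok(trial, pos, k, index):
                    continue
                key = (len(covering), weight, -pos, _alpha_rank(aa))
                if best is None or key > best[0]:
                    best = (key, pos, aa, covering)
        if best is None:
            status = "infeasible"
            offending = matched_starts
            break
        _, pos, aa, covering = best
        mutations.append(
            Mutation(
                position=pos,
                from_aa=seq[pos - 1],
                to_aa=aa,
                windows_destroyed=tuple(sorted(covering)),
            )
        )
        seq = seq[: pos - 1] + aa + seq[pos:]

    final_report = scan_sequence(seq, index)
    intact = all(seq[p - 1] == aa for p, aa in expected.items())
    return DesignCandidate(
        sequence=seq,
        mutations=mutations,
        humanness=final_report,
        epitope_intact=intact,
        status=status,
        offending_windows=offending,
    )


def _alpha_rank(aa: str) -> int:
    # earlier letters preferred; encoded so that bigger tuple wins
    return -ord(aa)


def apply_variants(seq: str, variants) -> str:
    """Apply named point substitutions (e.g. liability-removing K21Q, R218E).

    Each variant's from-residue must match the sequence at its position;
    a mismatch is an error, guarding against numbering-convention slips.
    """
    out = list(seq)
    for var in variants:
        if var.position < 1 or var.position > len(seq):
            raise ValueError(f"variant {var.label}: position outside sequence")
        if out[var.position - 1] != var.from_aa:
            raise ValueError(
                f"variant {var.label}: from-residue mismatch "
                f"(sequence has {out[var.position - 1]} at {var.position})"
            )
        out[var.position - 1] = var.to_aa
    return "".join(out)


def evaluate_design(
    candidate: DesignCandidate,
    index: KmerIndex,
    plan: GraftPlan,
    donor: str | None = None,
) -> dict:
    """Independent post-hoc check of a design candidate.

    Rescans the sequence and re-derives the epitope-integrity flag from
    the graft plan (and, when given, from the donor sequence itself),
    with per-mutation provenance of destroyed windows.
    """
    report = scan_sequence(candidate.sequence, index, query_id="candidate")
    intact = all(
        p <= len(candidate.sequence) and candidate.sequence[p - 1] == aa
        for p, aa in plan.transplanted.items()
    )
    if donor is not None:
        # guard against a stale plan: recorded stretch residues must still
        # be the donor's
        for st in plan.stretches:
            if st.donor_residues and st.donor_residues != donor[st.start - 1 : st.end]:
                raise ValueError(
                    f"plan stretch [{st.start},{st.end}] disagrees with donor sequence"
                )
    return {
        "n_matches": report.n_matched_windows,
        "is_clean": report.is_clean,
        "epitope_intact": intact,
        "n_mutations": len(candidate.mutations),
        "status": candidate.status,
        "mutations": [
            {
                "label": m.label,
                "windows_destroyed": list(m.windows_destroyed),
            }
            for m in candidate.mutations
        ],
    }
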