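"""Global pairwise alignment with an explicit column map.

Thin wrapper over Biopython's ``PairwiseAligner`` that renders the optimal
global alignment (BLOSUM62, affine gaps by default) into two equal-length
gapped strings plus a per-column map between 1-based positions of the two
inputs.  The aligner's canonical enumeration order provides the
deterministic tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Align import PairwiseAligner, substitution_matrices

__all__ = ["PairwiseAlignment", "global_align"]

GAP = "-"


@dataclass(frozen=True)
class PairwiseAlignment:
    """A rendered global alignment of (donor, scaffold)."""

    aligned_donor: str
    aligned_scaffold: str
    column_map: tuple[tuple[int | None, int | None], ...]
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_donor) != len(self.aligned_scaffold):
            raise ValueError("aligned strings differ in length")

    @property
    def donor(self) -> str:
        return self.aligned_donor.replace(GAP, "")

    @property
    def scaffold(self) -> str:
        return self.aligned_scaffold.replace(GAP, "")

    def donor_to_scaffold(self) -> dict[int, int | None]:
        """1-based donor position -> scaffold position (None under a gap)."""
        return {d: s for d, s in self.column_map if d is not None}


def _column_map(a: str, b: str) -> tuple[tuple[int | None, int | None], ...]:
    out = []
    pa = pb = 0
    for ca, cb in zip(a, b):
        da = sb = None
        if ca != GAP:
            pa += 1
            da = pa
        if cb != GAP:
            pb += 1
            sb = pb
        out.append((da, sb))
    return tuple(out)


def global_align(
    donor: str,
    scaffold: str,
    matrix: str = "BLOSUM62",
    gap_open: float = -11.0,
    gap_extend: float = -1.0,
) -> PairwiseAlignment:
    """Optimal global alignment of two protein sequences.

    ``gap_open`` is the score of the first gapped column of a gap run and
    ``gap_extend`` of each further column.
    """
    if not donor or not scaffold:
        raise ValueError("sequences must be non-empty")
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aligner.mode = "global"
    aln = aligner.align(donor, scaffold)[0]
    a, b = str(aln[0]), str(aln[1])
    return PairwiseAlignment(
        aligned_donor=a,
        aligned_scaffold=b,
        column_map=_column_map(a, b),
        score=float(aln.score),
    )
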