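"""Exact k-mer screening of a designed sequence against a reference proteome.

The screen behind "no consecutive 9-residue stretch in common with any
human protein": every length-k window of every reference protein is put in
an exact-match index, and a query sequence is reported window by window.
Identity is strict — no I/L equivalence, no near matches — and any window
containing the unknown residue X is excluded on both sides of the
comparison.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

__all__ = [
    "AMINO_ACIDS",
    "ProteomeRecord",
    "KmerIndex",
    "KmerMatch",
    "HumannessReport",
    "build_kmer_index",
    "scan_sequence",
    "validate_protein_sequence",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_ALLOWED = set(AMINO_ACIDS) | {"X"}
# ambiguity/rare codes that would silently distort an exact-identity screen
_REJECTED = set("UBZJO")


def validate_protein_sequence(seq: str, label: str = "sequence") -> str:
    """Uppercase ``seq`` and reject anything outside the 20 amino acids + X."""
    seq = seq.upper()
    bad = sorted(set(seq) - _ALLOWED)
    if bad:
        hint = " (ambiguity codes are rejected, not remapped)" if set(bad) & _REJECTED else ""
        raise ValueError(f"{label} contains invalid residue(s) {bad}{hint}")
    return seq


@dataclass(frozen=True)
class ProteomeRecord:
    """One reference protein."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id}: empty sequence")
        object.__setattr__(
            self, "sequence", validate_protein_sequence(self.sequence, f"protein {self.id}")
        )


@dataclass
class KmerIndex:
    """Exact index of every X-free length-k window of a proteome."""

    k: int = 9
    window_map: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    proteome_checksum: str = ""
    n_proteins: int = 0

    def __contains__(self, window: str) -> bool:
        return window in self.window_map

    def sources(self, window: str) -> list[tuple[str, int]]:
        return self.window_map.get(window, [])


@dataclass(frozen=True)
class KmerMatch:
    query_start: int  # 1-based
    window: str
    sources: tuple[tuple[str, int], ...]


@dataclass
class HumannessReport:
    """Result of scanning one query against the proteome index."""

    query_id: str
    n_windows: int
    matches: list[KmerMatch]
    k: int = 9
    proteome_checksum: str = ""

    @property
    def n_matched_windows(self) -> int:
        return len(self.matches)

    @property
    def distinct_proteins_hit(self) -> int:
        return len({pid for m in self.matches for pid, _ in m.sources})

    @property
    def is_clean(self) -> bool:
        return not self.matches


def proteome_checksum(proteome) -> str:
    """Stable content digest of a proteome (order-independent)."""
    h = hashlib.sha256()
    for rec in sorted(proteome, key=lambda r: (r.id, r.sequence)):
        h.update(rec.id.encode())
        h.update(b"\x00")
        h.update(rec.sequence.encode())
        h.update(b"\x01")
    return h.hexdigest()


def build_kmer_index(proteome, k: int = 9) -> KmerIndex:
    """Index every X-free length-k window of every record.

    Duplicate windows accumulate all their (protein id, 1-based start)
    sources.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    proteome = list(proteome)
    if not proteome:
        raise ValueError("empty proteome")
    index = KmerIndex(k=k, proteome_checksum=proteome_checksum(proteome),
                      n_proteins=len(proteome))
    for rec in proteome:
        seq = rec.sequence
        for start in range(len(seq) - k + 1):
            window = seq[start : start + k]
            if "X" in window:
                continue
            index.window_map.setdefault(window, []).append((rec.id, start + 1))
    return index


def scan_sequence(query: str, index: KmerIndex, query_id: str = "query") -> HumannessReport:
    """Report every query window found verbatim in the proteome index.

    Windows containing X never match.  A query shorter than k has zero
    windows and trivially zero matches.
    """
    query = validate_protein_sequence(query, f"query {query_id}")
    k = index.k
    n_windows = max(0, len(query) - k + 1)
    matches = []
    for start in range(n_windows):
        window = query[start : start + k]
        if "X" in window:
            continue
        sources = index.sources(window)
        if sources:
            matches.append(
                KmerMatch(query_start=start + 1, window=window, sources=tuple(sources))
            )
    return HumannessReport(
        query_id=query_id,
        n_windows=n_windows,
        matches=matches,
        k=k,
        proteome_checksum=index.proteome_checksum,
    )
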