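"""File I/O: FASTA via Biopython, tabular/JSON reports, content digests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import DesignCandidate, GraftPlan, Mutation
from .footprint import EpitopeStretch, FootprintProfile
from .humanness import HumannessReport, ProteomeRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_proteome",
    "read_msa",
    "file_checksum",
    "profile_to_tsv",
    "stretches_to_tsv",
    "stretches_to_json",
    "report_to_tsv",
    "report_to_json",
    "mutations_to_tsv",
    "candidate_to_json",
    "parse_mutation",
]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """All (id, sequence) records of a FASTA file, uppercased."""
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(path: str | Path, records: list[tuple[str, str]]) -> None:
    seqs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_proteome(path: str | Path) -> list[ProteomeRecord]:
    return [ProteomeRecord(id=rid, sequence=seq) for rid, seq in read_fasta(path)]


def read_msa(path: str | Path) -> dict[str, str]:
    """Aligned FASTA as an id -> row mapping (equal-length rows enforced)."""
    rows = dict(read_fasta(path))
    widths = {len(v) for v in rows.values()}
    if len(widths) > 1:
        raise ValueError(f"alignment rows in {path} differ in length")
    return rows


def file_checksum(path: str | Path) -> str:
    p = Path(path)
    if not p.is_file():
        raise FileNotFoundError(f"cannot checksum missing file: {p}")
    return hashlib.sha256(p.read_bytes()).hexdigest()


def profile_to_tsv(profile: FootprintProfile) -> str:
    lines = ["donor_pos\tresidue\tpartner_id\tbsa_A2"]
    for pos in sorted(profile.bsa):
        res = profile.residue.get(pos, "X")
        for pid in sorted(profile.bsa[pos]):
            lines.append(f"{pos}\t{res}\t{pid}\t{profile.bsa[pos][pid]:.3f}")
    return "\n".join(lines) + "\n"


def stretches_to_tsv(stretches: list[EpitopeStretch]) -> str:
    lines = ["start\tend\tresidues\tsupporting_partners"]
    for st in stretches:
        lines.append(
            f"{st.start}\t{st.end}\t{st.donor_residues}\t"
            f"{','.join(sorted(st.supporting_partners))}"
        )
    return "\n".join(lines) + "\n"


def stretches_to_json(stretches: list[EpitopeStretch]) -> str:
    return json.dumps(
        [
            {
                "start": st.start,
                "end": st.end,
                "residues": st.donor_residues,
                "supporting_partners": sorted(st.supporting_partners),
            }
            for st in stretches
        ],
        indent=2,
    )


def report_to_tsv(report: HumannessReport) -> str:
    lines = ["query_start\twindow\tprotein_id\tprotein_start"]
    for m in report.matches:
        for pid, start in m.sources:
            lines.append(f"{m.query_start}\t{m.window}\t{pid}\t{start}")
    return "\n".join(lines) + "\n"


def report_to_json(report: HumannessReport) -> str:
    return json.dumps(
        {
            "query_id": report.query_id,
            "k": report.k,
            "n_windows": report.n_windows,
            "n_matched_windows": report.n_matched_windows,
            "distinct_proteins_hit": report.distinct_proteins_hit,
            "proteome_checksum": report.proteome_checksum,
            "matches": [
                {
                    "query_start": m.query_start,
                    "window": m.window,
                    "sources": [list(s) for s in m.sources],
                }
                for m in report.matches
            ],
        },
        indent=2,
    )


def mutations_to_tsv(mutations: list[Mutation]) -> str:
    lines = ["position\tfrom\tto\twindows_destroyed"]
    for m in mutations:
        lines.append(
            f"{m.position}\t{m.from_aa}\t{m.to_aa}\t"
            f"{','.join(str(w) for w in m.windows_destroyed)}"
        )
    return "\n".join(lines) + "\n"


def plan_to_json(plan: GraftPlan) -> str:
    return json.dumps(
        {
            "stretches": [
                {"start": st.start, "end": st.end, "residues": st.donor_residues}
                for st in plan.stretches
            ],
            "transplanted": {str(p): aa for p, aa in sorted(plan.transplanted.items())},
            "substitutions": [list(s) for s in plan.substitutions],
            "insertions": [list(i) for i in plan.insertions],
            "deletions": [list(d) for d in plan.deletions],
        },
        indent=2,
    )


def candidate_to_json(candidate: DesignCandidate) -> str:
    return json.dumps(
        {
            "status": candidate.status,
            "sequence": candidate.sequence,
            "epitope_intact": candidate.epitope_intact,
            "n_mutations": len(candidate.mutations),
            "mutations": [
                {
                    "position": m.position,
                    "from": m.from_aa,
                    "to": m.to_aa,
                    "windows_destroyed": list(m.windows_destroyed),
                }
                for m in candidate.mutations
            ],
            "n_residual_matches": candidate.humanness.n_matched_windows,
            "offending_windows": candidate.offending_windows,
        },
        indent=2,
    )


def profile_from_tsv(text: str, donor_length: int | None = None) -> FootprintProfile:
    """Inverse of :func:`profile_to_tsv` (unmodeled flags are not round-tripped)."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or lines[0].split("\t")[0] != "donor_pos":
        raise ValueError("not a footprint TSV")
    bsa: dict[int, dict[str, float]] = {}
    residue: dict[int, str] = {}
    for ln in lines[1:]:
        pos_s, res, pid, val = ln.split("\t")
        pos = int(pos_s)
        bsa.setdefault(pos, {})[pid] = float(val)
        residue[pos] = res
    length = donor_length or (max(bsa) if bsa else 0)
    return FootprintProfile(donor_length=length, bsa=bsa, residue=residue)


def stretches_from_json(text: str) -> list[EpitopeStretch]:
    return [
        EpitopeStretch(
            start=d["start"],
            end=d["end"],
            donor_residues=d.get("residues", ""),
            supporting_partners=frozenset(d.get("supporting_partners", [])),
        )
        for d in json.loads(text)
    ]


def parse_mutation(text: str) -> Mutation:
    """Parse compact mutation notation like ``K21Q``."""
    text = text.strip()
    if len(text) < 3 or not text[0].isalpha() or not text[-1].isalpha():
        raise ValueError(f"cannot parse mutation {text!r}")
    try:
        pos = int(text[1:-1])
    except ValueError as exc:
        raise ValueError(f"cannot parse mutation {text!r}") from exc
    return Mutation(position=pos, from_aa=text[0].upper(), to_aa=text[-1].upper())
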