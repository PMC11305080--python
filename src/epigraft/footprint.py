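"""Per-residue buried surface area and epitope-stretch selection.

The interface footprint of the antigen against one binding partner is the
per-residue buried surface area (BSA): the solvent-accessible area each
antigen residue loses on complex formation,

    BSA(residue) = sum over atoms [ SASA(target chains isolated)
                                    - SASA(full complex) ].

Residues buried by at least ``min_partners`` independent partners (the LDL
receptor and/or therapeutic antibodies, each from its own complex
structure) are merged into contiguous epitope stretches, the units later
transplanted onto the scaffold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .alignment import global_align
from .sasa import DEFAULT_N_POINTS, DEFAULT_PROBE, compute_sasa, per_residue_sasa
from .structure import ChainPartition, StructureModel

__all__ = [
    "FootprintProfile",
    "EpitopeStretch",
    "map_residues_to_donor",
    "per_residue_bsa",
    "contact_residues",
    "select_epitope_stretches",
]


@dataclass
class FootprintProfile:
    """Donor-position-indexed BSA per binding partner.

    ``bsa[pos][partner_id]`` is the buried area in Å² of donor position
    ``pos`` (1-based) against that partner's complex.  Donor positions not
    modelled in a partner's crystal structure carry BSA 0 and are listed in
    ``unmodeled[partner_id]``.
    """

    donor_length: int
    bsa: dict[int, dict[str, float]] = field(default_factory=dict)
    residue: dict[int, str] = field(default_factory=dict)
    unmodeled: dict[str, set[int]] = field(default_factory=dict)

    @property
    def partners(self) -> set[str]:
        ids = set(self.unmodeled)
        for entry in self.bsa.values():
            ids.update(entry)
        return ids

    def merge(self, other: "FootprintProfile") -> "FootprintProfile":
        if other.donor_length != self.donor_length:
            raise ValueError("profiles cover donors of different length")
        for pos, entry in other.bsa.items():
            self.bsa.setdefault(pos, {}).update(entry)
        self.residue.update(other.residue)
        for pid, positions in other.unmodeled.items():
            self.unmodeled.setdefault(pid, set()).update(positions)
        return self


@dataclass(frozen=True)
class EpitopeStretch:
    """A contiguous run of donor positions buried by >= min_partners partners."""

    start: int
    end: int
    supporting_partners: frozenset[str]
    donor_residues: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("stretch start must be <= end")
        if self.donor_residues and len(self.donor_residues) != self.end - self.start + 1:
            raise ValueError("donor_residues length does not match span")

    @property
    def positions(self) -> range:
        return range(self.start, self.end + 1)


def map_residues_to_donor(
    model: StructureModel, chain_ids, donor_seq: str
) -> dict[tuple, int]:
    """Map structure residue keys of the given chains to 1-based donor positions.

    Each chain's extracted one-letter sequence is globally aligned to the
    donor sequence; a structure residue falling under a donor gap is a hard
    error (it would silently shift downstream numbering).
    """
    mapping: dict[tuple, int] = {}
    for cid in chain_ids:
        residues = model.chains[cid]
        chain_seq = model.chain_sequence(cid)
        aln = global_align(donor_seq, chain_seq)
        chain_to_donor = {s: d for d, s in aln.column_map if s is not None}
        for idx, res in enumerate(residues, start=1):
            donor_pos = chain_to_donor.get(idx)
            if donor_pos is None:
                raise ValueError(
                    f"structure residue {res.key} of chain {cid} does not map "
                    f"to any donor position"
                )
            mapping[res.key] = donor_pos
    return mapping


def per_residue_bsa(
    model: StructureModel,
    partition: ChainPartition,
    partner_id: str | None = None,
    donor_seq: str | None = None,
    probe_radius: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> FootprintProfile:
    """Footprint of one partner: per-donor-position buried surface area.

    The complex SASA uses only the partitioned chains, so extra chains in
    the file (second copies, tags) cannot contaminate the footprint.
    Negative per-residue differences (quadrature noise) are clamped to 0.
    """
    partition.check_against(model)
    pid = partner_id or "+".join(sorted(partition.partner_chains))
    target = sorted(partition.target_chains)
    both = target + sorted(partition.partner_chains)

    iso_sasa, iso_owner = compute_sasa(model, probe_radius, n_points, chain_ids=target)
    cx_sasa, cx_owner = compute_sasa(model, probe_radius, n_points, chain_ids=both)
    iso = per_residue_sasa(iso_sasa, iso_owner)
    cx = per_residue_sasa(cx_sasa, cx_owner)

    if donor_seq is not None:
        key_to_pos = map_residues_to_donor(model, target, donor_seq)
        donor_length = len(donor_seq)
    else:
        # no donor reference: positions are 1-based over the target residues
        keys = [r.key for cid in target for r in model.chains[cid]]
        key_to_pos = {k: i for i, k in enumerate(keys, start=1)}
        donor_length = len(keys)

    profile = FootprintProfile(donor_length=donor_length)
    for cid in target:
        for res in model.chains[cid]:
            pos = key_to_pos[res.key]
            buried = max(0.0, iso[res.key] - cx.get(res.key, 0.0))
            profile.bsa.setdefault(pos, {})[pid] = buried
            profile.residue[pos] = res.one_letter
    modeled = set(key_to_pos.values())
    missing = set(range(1, donor_length + 1)) - modeled
    for pos in missing:
        profile.bsa.setdefault(pos, {})[pid] = 0.0
        if donor_seq is not None:
            profile.residue.setdefault(pos, donor_seq[pos - 1])
    profile.unmodeled[pid] = missing
    return profile


def contact_residues(
    profile: FootprintProfile, partner_id: str, bsa_threshold: float = 1.0
) -> set[int]:
    """Donor positions buried by >= ``bsa_threshold`` Å² against one partner."""
    if bsa_threshold < 0:
        raise ValueError("bsa_threshold must be >= 0")
    if partner_id not in profile.partners:
        raise KeyError(f"unknown partner id {partner_id!r}")
    return {
        pos
        for pos, entry in profile.bsa.items()
        if entry.get(partner_id, 0.0) >= bsa_threshold
    }


def select_epitope_stretches(
    contact_sets: dict[str, set[int]],
    min_partners: int = 2,
    gap_merge: int = 2,
    donor_seq: str | None = None,
) -> list[EpitopeStretch]:
    """Merge multiply-contacted positions into ordered epitope stretches.

    A donor position is *critical* when it appears in at least
    ``min_partners`` of the contact sets.  Consecutive critical positions
    at most ``gap_merge + 1`` apart are merged into one stretch (bridging
    up to ``gap_merge`` non-critical residues).  The result is independent
    of the iteration order of ``contact_sets``.
    """
    if min_partners < 1:
        raise ValueError("min_partners must be >= 1")
    if gap_merge < 0:
        raise ValueError("gap_merge must be >= 0")
    support: dict[int, set[str]] = {}
    for pid, positions in contact_sets.items():
        for pos in positions:
            support.setdefault(pos, set()).add(pid)
    critical = sorted(p for p, pids in support.items() if len(pids) >= min_partners)
    stretches: list[EpitopeStretch] = []
    run: list[int] = []
    for pos in critical:
        if run and pos - run[-1] > gap_merge + 1:
            stretches.append(_close_run(run, support, donor_seq))
            run = []
        run.append(pos)
    if run:
        stretches.append(_close_run(run, support, donor_seq))
    return stretches


def _close_run(run: list[int], support: dict[int, set[str]], donor_seq: str | None):
    start, end = run[0], run[-1]
    partners: set[str] = set()
    for pos in run:
        partners |= support.get(pos, set())
    residues = donor_seq[start - 1 : end] if donor_seq else ""
    return EpitopeStretch(
        start=start,
        end=end,
        supporting_partners=frozenset(partners),
        donor_residues=residues,
    )
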