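"""Seeded synthetic fixtures with exact ground truth.

Every pipeline stage gets a miniature, fully controlled stand-in for its
real input: decoy proteomes with deliberately planted shared 9-mers (for
the humanness screen and dehumanization), toy two-chain complexes whose
contact geometry reduces to the closed-form spherical-cap area (for the
footprint stage), and species-variant alignments generated by independent
per-column substitution (for the mutation pools).  One seeded generator
stream per fixture; regenerating with the same seed and parameters
reproduces the fixture exactly.

Toy complexes use single-sphere "residues" of radius 1.9 Å spaced 3.8 Å
apart (carbon-like spheres at C-alpha spacing).  The target chain is a
straight line; the partner chain places one sphere at the requested
distance from each residue of the contact span, with the two boundary
spheres leaned inward just enough that every non-span target residue stays
beyond contact range (minimum separation 2*(radius+probe) + 0.05 Å), and
any remaining partner residues parked on a distant rail.  Spans of length
one at close distance cannot satisfy both constraints and are rejected as
geometrically impossible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structure import Atom, ChainPartition, Residue, StructureModel
from .humanness import AMINO_ACIDS, ProteomeRecord

__all__ = [
    "generate_proteome",
    "plant_shared_windows",
    "generate_toy_complex",
    "generate_species_msa",
    "SyntheticFixture",
    "full_fixture",
    "model_to_pdb",
]

RESIDUE_SPACING = 3.8  # Å, C-alpha like
TOY_RADIUS = 1.9  # Å, carbon-like single-sphere residue
_MARGIN = 0.05  # Å beyond contact range for guaranteed-zero-BSA residues

ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def random_sequence(length: int, rng: np.random.Generator, alphabet: str = AMINO_ACIDS) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def generate_proteome(
    n_proteins: int,
    length_range: tuple[int, int],
    alphabet: str = AMINO_ACIDS,
    seed: int = 0,
) -> list[ProteomeRecord]:
    """Uniform-random decoy proteome, deterministic in (seed, params)."""
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid length range")
    if not alphabet:
        raise ValueError("empty alphabet")
    rng = _rng(seed)
    records = []
    for i in range(n_proteins):
        length = int(rng.integers(lo, hi + 1))
        records.append(
            ProteomeRecord(
                id=f"decoy{i:04d}",
                sequence=random_sequence(length, rng, alphabet),
                description="synthetic decoy protein",
            )
        )
    return records


def plant_shared_windows(
    query: str,
    proteome: list[ProteomeRecord],
    plant_spec: list[tuple[int, str, int]],
    k: int = 9,
) -> tuple[list[ProteomeRecord], list[tuple[int, str]]]:
    """Copy query windows into decoy proteins at stated positions.

    ``plant_spec`` entries are (query 1-based start, target protein id,
    target 1-based start).  Overlapping plants that would write different
    residues to the same proteome position are rejected.  Returns the
    modified proteome and the ground-truth list of (query start, window).
    """
    by_id = {rec.id: list(rec.sequence) for rec in proteome}
    written: dict[tuple[str, int], str] = {}
    truth: list[tuple[int, str]] = []
    for qstart, pid, tstart in plant_spec:
        if qstart < 1 or qstart + k - 1 > len(query):
            raise ValueError(f"query window at {qstart} does not fit")
        if pid not in by_id:
            raise ValueError(f"unknown target protein {pid!r}")
        target = by_id[pid]
        if tstart < 1 or tstart + k - 1 > len(target):
            raise ValueError(f"target window at {tstart} does not fit in {pid}")
        window = query[qstart - 1 : qstart - 1 + k]
        for off, aa in enumerate(window):
            key = (pid, tstart + off)
            if key in written and written[key] != aa:
                raise ValueError(f"contradictory plants at {pid} position {key[1]}")
            written[key] = aa
            target[tstart - 1 + off] = aa
        truth.append((qstart, window))
    out = [
        ProteomeRecord(id=rec.id, sequence="".join(by_id[rec.id]),
                       description=rec.description)
        for rec in proteome
    ]
    return out, truth


def _contact_sphere_positions(
    spans: list[tuple[int, int]],
    distance: float,
    n_target: int,
    radius: float,
    probe: float,
) -> list[tuple[float, float, float]]:
    """Partner sphere centres realizing exactly the requested contact spans."""
    two_r = 2.0 * (radius + probe)
    sp = RESIDUE_SPACING
    # inward lean of boundary spheres so the adjacent non-span residue is
    # at least two_r + margin away
    lean = max(0.0, ((two_r + _MARGIN) ** 2 - distance**2 - sp**2) / (2.0 * sp))
    if lean > 0 and lean >= distance:
        raise ValueError("geometrically impossible parameters (distance too small)")
    b = float(np.sqrt(max(distance**2 - lean**2, 0.0)))
    centres = []
    for s, e in spans:
        for i in range(s, e + 1):
            x = (i - 1) * sp
            if lean > 0 and i == s and s > 1:
                if s == e and e < n_target:
                    raise ValueError(
                        "geometrically impossible parameters "
                        "(length-1 span at close distance)"
                    )
                centres.append((x + lean, b, 0.0))
            elif lean > 0 and i == e and e < n_target:
                centres.append((x - lean, b, 0.0))
            else:
                centres.append((x, distance, 0.0))
    return centres


def generate_toy_complex(
    n_target: int,
    n_partner: int,
    inter_chain_distance: float,
    contact_span: tuple[int, int] | list[tuple[int, int]],
    seed: int = 0,
    radius: float = TOY_RADIUS,
    probe: float = 1.4,
    jitter: float = 0.0,
    target_seq: str | None = None,
    source_id: str = "toy",
) -> tuple[StructureModel, ChainPartition, set[int]]:
    """Two-chain toy complex with an exactly known contact set.

    The expected contacts are the residues of ``contact_span`` when
    ``inter_chain_distance`` < 2*(radius+probe), otherwise empty.  All
    other target residues are guaranteed beyond contact range of every
    partner sphere (verified, not just constructed).  ``seed`` only feeds
    the optional coordinate ``jitter`` (default 0: fully deterministic
    geometry).
    """
    spans = [contact_span] if isinstance(contact_span, tuple) else list(contact_span)
    for s, e in spans:
        if not (1 <= s <= e <= n_target):
            raise ValueError(f"span ({s},{e}) outside target chain")
    if target_seq is not None and len(target_seq) != n_target:
        raise ValueError("target_seq length must equal n_target")
    two_r = 2.0 * (radius + probe)
    in_contact = inter_chain_distance < two_r
    n_contact = sum(e - s + 1 for s, e in spans) if in_contact else 0
    if n_contact > n_partner:
        raise ValueError("partner chain too short for the requested spans")

    sp = RESIDUE_SPACING
    target_xyz = [((i - 1) * sp, 0.0, 0.0) for i in range(1, n_target + 1)]
    if in_contact:
        partner_xyz = _contact_sphere_positions(
            spans, inter_chain_distance, n_target, radius, probe
        )
    else:
        partner_xyz = [((i - 1) * sp, inter_chain_distance, 0.0)
                       for i in range(1, min(n_partner, n_target) + 1)]
    # park any remaining partner residues on a distant rail
    rail_y = inter_chain_distance + two_r + 4.0
    j = 0
    while len(partner_xyz) < n_partner:
        partner_xyz.append((j * sp, rail_y, 0.0))
        j += 1

    if jitter > 0:
        rng = _rng(seed)
        target_xyz = [tuple(np.asarray(p) + rng.normal(0, jitter, 3)) for p in target_xyz]
        partner_xyz = [tuple(np.asarray(p) + rng.normal(0, jitter, 3)) for p in partner_xyz]

    expected = {i for s, e in spans for i in range(s, e + 1)} if in_contact else set()
    _verify_contacts(target_xyz, partner_xyz, expected, two_r)

    model = StructureModel(source_id=source_id)
    serial = 0
    for cid, coords in (("T", target_xyz), ("P", partner_xyz)):
        residues = []
        for i, xyz in enumerate(coords, start=1):
            serial += 1
            if cid == "T" and target_seq is not None:
                resname = ONE_TO_THREE[target_seq[i - 1]]
            else:
                resname = "ALA"
            residues.append(
                Residue(
                    chain_id=cid,
                    number=i,
                    name=resname,
                    atoms=(
                        Atom(serial=serial, element="C",
                             coords=tuple(float(v) for v in xyz),
                             radius=radius, name="CA"),
                    ),
                )
            )
        model.chains[cid] = residues
    partition = ChainPartition(target_chains={"T"}, partner_chains={"P"})
    return model, partition, expected


def _verify_contacts(target_xyz, partner_xyz, expected: set[int], two_r: float) -> None:
    t = np.asarray(target_xyz)
    p = np.asarray(partner_xyz)
    d = np.linalg.norm(t[:, None, :] - p[None, :, :], axis=-1)
    mind = d.min(axis=1)
    actual = {i + 1 for i in range(len(t)) if mind[i] < two_r}
    if actual != expected:
        raise ValueError(
            "geometrically impossible parameters: achievable contact set "
            f"{sorted(actual)} != requested {sorted(expected)}"
        )


def generate_species_msa(
    base: str,
    n_sequences: int,
    sub_rate: float,
    seed: int = 0,
    alphabet: str = AMINO_ACIDS,
    base_id: str = "base",
) -> tuple[dict[str, str], list[dict[str, int]]]:
    """Gap-free species-variant alignment by per-column substitution.

    Every non-base row independently substitutes each column with
    probability ``sub_rate`` to a uniformly chosen *different* residue.
    Returns the alignment (base row first) and the exact per-column
    residue counts over all rows as ground truth.
    """
    if not 0 <= sub_rate <= 1:
        raise ValueError("sub_rate must be in [0, 1]")
    rng = _rng(seed)
    rows = {base_id: base}
    letters = list(alphabet)
    for v in range(1, n_sequences):
        chars = []
        for ch in base:
            if rng.random() < sub_rate:
                options = [aa for aa in letters if aa != ch]
                chars.append(str(rng.choice(options)))
            else:
                chars.append(ch)
        rows[f"variant{v:02d}"] = "".join(chars)
    truth = []
    for col in range(len(base)):
        counts: dict[str, int] = {}
        for row in rows.values():
            aa = row[col]
            counts[aa] = counts.get(aa, 0) + 1
        truth.append(counts)
    return rows, truth


@dataclass
class SyntheticFixture:
    """A complete seeded study: complexes, sequences, proteome, MSA, truth."""

    seed: int
    donor: str
    scaffold: str
    grafted: str
    proteome: list[ProteomeRecord]
    planted_windows: list[tuple[int, str]]
    complexes: dict[str, tuple[StructureModel, ChainPartition, set[int]]]
    msa: dict[str, str]
    msa_truth: list[dict[str, int]]
    expected_spans: list[tuple[int, int]]
    k: int = 9
    scaffold_id: str = "scaffold"
    params: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit the fixture as standard FASTA/PDB files plus a truth JSON."""
        from . import io as egio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        paths["donor"] = outdir / "donor.fasta"
        egio.write_fasta(paths["donor"], [("donor", self.donor)])
        paths["scaffold"] = outdir / "scaffold.fasta"
        egio.write_fasta(paths["scaffold"], [(self.scaffold_id, self.scaffold)])
        paths["proteome"] = outdir / "proteome.fasta"
        egio.write_fasta(paths["proteome"], [(r.id, r.sequence) for r in self.proteome])
        paths["msa"] = outdir / "species_msa.fasta"
        egio.write_fasta(paths["msa"], list(self.msa.items()))
        for pid, (model, _, _) in self.complexes.items():
            p = outdir / f"complex_{pid}.pdb"
            p.write_text(model_to_pdb(model))
            paths[f"complex_{pid}"] = p
        truth = {
            "seed": self.seed,
            "planted_windows": [[q, w] for q, w in self.planted_windows],
            "expected_spans": [list(s) for s in self.expected_spans],
            "expected_contacts": {
                pid: sorted(exp) for pid, (_, _, exp) in self.complexes.items()
            },
            "grafted": self.grafted,
        }
        paths["truth"] = outdir / "truth.json"
        paths["truth"].write_text(json.dumps(truth, indent=2))
        return paths


def full_fixture(seed: int = 7) -> SyntheticFixture:
    """The bundled end-to-end study (two partners, two epitope spans).

    Two toy complexes (partners P1 and P2) bury donor spans (5,8) and
    (12,14); the scaffold is the donor mutated at ~35% of positions; two
    9-mer windows of the grafted sequence are planted into the decoy
    proteome away from the epitope; the species MSA substitutes columns at
    rate 0.1.
    """
    from .design import align_donor_scaffold, transplant_stretches
    from .footprint import EpitopeStretch

    rng = _rng(seed)
    spans = [(5, 8), (12, 14)]
    n_res = 40
    donor = random_sequence(n_res, rng)

    # scaffold homolog: point-mutate ~35% of donor positions
    scaffold_chars = list(donor)
    for i in range(n_res):
        if rng.random() < 0.35:
            options = [aa for aa in AMINO_ACIDS if aa != scaffold_chars[i]]
            scaffold_chars[i] = str(rng.choice(options))
    scaffold = "".join(scaffold_chars)

    complexes = {}
    for pid, cseed in (("P1", seed * 1000 + 1), ("P2", seed * 1000 + 2)):
        model, partition, expected = generate_toy_complex(
            n_target=n_res,
            n_partner=12,
            inter_chain_distance=3.3,
            contact_span=spans,
            seed=cseed,
            target_seq=donor,
            source_id=f"toy-{pid}",
        )
        complexes[pid] = (model, partition, expected)

    stretches = [
        EpitopeStretch(start=s, end=e, supporting_partners=frozenset(complexes),
                       donor_residues=donor[s - 1 : e])
        for s, e in spans
    ]
    aln = align_donor_scaffold(donor, scaffold)
    grafted, plan = transplant_stretches(scaffold, donor, stretches, aln)

    proteome = generate_proteome(20, (60, 60), seed=seed * 1000 + 3)
    # plant two grafted-sequence windows well clear of both epitope spans
    plant_spec = [
        (22, proteome[3].id, 10),
        (30, proteome[7].id, 25),
    ]
    proteome, planted = plant_shared_windows(grafted, proteome, plant_spec, k=9)

    msa, msa_truth = generate_species_msa(
        scaffold, n_sequences=8, sub_rate=0.1, seed=seed * 1000 + 4,
        base_id="scaffold",
    )

    return SyntheticFixture(
        seed=seed,
        donor=donor,
        scaffold=scaffold,
        grafted=grafted,
        proteome=proteome,
        planted_windows=planted,
        complexes=complexes,
        msa=msa,
        msa_truth=msa_truth,
        expected_spans=spans,
        params={"n_res": n_res, "sub_rate": 0.1, "n_msa": 8,
                "inter_chain_distance": 3.3},
    )


def model_to_pdb(model: StructureModel) -> str:
    """Render a StructureModel as minimal standard PDB text."""
    lines = []
    serial = 0
    for cid, residues in model.chains.items():
        for res in residues:
            for atom in res.atoms:
                serial += 1
                x, y, z = atom.coords
                name = atom.name or atom.element
                lines.append(
                    f"ATOM  {serial:5d} {name:^4s}{res.name:>4s} {cid:1s}"
                    f"{res.number:4d}{res.insertion_code or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}"
                )
        lines.append(f"TER   {serial + 1:5d}      {residues[-1].name:>3s} {cid:1s}"
                     f"{residues[-1].number:4d}")
    lines.append("END")
    return "\n".join(lines) + "\n"
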