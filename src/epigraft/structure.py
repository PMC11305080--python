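"""Structure models and readers for antigen-partner complexes.

Parses PDB/mmCIF files into a light-weight chain/residue/atom model that
carries exactly what the buried-surface computation needs: coordinates and
van der Waals radii.  Waters, ions, glycans and other non-polymer hetero
groups are dropped on load; alternate conformations are collapsed to the
highest-occupancy conformer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "ChainPartition",
    "VDW_RADII",
    "DEFAULT_RADIUS",
    "load_structure",
]

# Bondi-style van der Waals radii (Å) keyed by element symbol.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}
DEFAULT_RADIUS = 1.8  # fallback for elements outside the table


@dataclass(frozen=True)
class Atom:
    """A single atom: element, position (Å) and van der Waals radius (Å)."""

    serial: int
    element: str
    coords: tuple[float, float, float]
    radius: float
    name: str = ""

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError(f"atom {self.serial}: radius must be > 0")
        if not all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial}: non-finite coordinates")


@dataclass(frozen=True)
class Residue:
    """One amino-acid residue identified by author numbering within a chain."""

    chain_id: str
    number: int
    name: str
    atoms: tuple[Atom, ...]
    insertion_code: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"residue {self.key}: no atoms")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.insertion_code)

    @property
    def one_letter(self) -> str:
        info = gemmi.find_tabulated_residue(self.name)
        if info is not None and info.is_amino_acid():
            code = info.one_letter_code.upper()
            if code.isalpha():
                return code
        return "X"


@dataclass
class StructureModel:
    """Protein chains of a complex, hetero/solvent content already removed."""

    source_id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)

    def chain_sequence(self, chain_id: str) -> str:
        return "".join(r.one_letter for r in self.chains[chain_id])

    def chain_coords(self, chain_ids) -> tuple[np.ndarray, np.ndarray, list[tuple]]:
        """Stack coordinates/radii for the given chains.

        Returns (coords (n,3), radii (n,), owner) where owner[i] is the
        residue key of atom i.
        """
        coords, radii, owner = [], [], []
        for cid in chain_ids:
            for res in self.chains[cid]:
                for atom in res.atoms:
                    coords.append(atom.coords)
                    radii.append(atom.radius)
                    owner.append(res.key)
        return np.asarray(coords, float), np.asarray(radii, float), owner

    def validate(self) -> None:
        seen = set()
        for cid, residues in self.chains.items():
            for res in residues:
                if res.chain_id != cid:
                    raise ValueError(f"residue {res.key} filed under chain {cid}")
                if res.key in seen:
                    raise ValueError(f"duplicate residue {res.key}")
                seen.add(res.key)


@dataclass(frozen=True)
class ChainPartition:
    """Split of a complex into the antigen (target) and a binding partner."""

    target_chains: frozenset[str]
    partner_chains: frozenset[str]

    def __init__(self, target_chains, partner_chains):
        object.__setattr__(self, "target_chains", frozenset(target_chains))
        object.__setattr__(self, "partner_chains", frozenset(partner_chains))
        if not self.target_chains or not self.partner_chains:
            raise ValueError("both partition sides must be non-empty")
        if self.target_chains & self.partner_chains:
            raise ValueError("target and partner chains overlap")

    def check_against(self, model: StructureModel) -> None:
        missing = (self.target_chains | self.partner_chains) - set(model.chains)
        if missing:
            raise ValueError(
                f"partition chains absent from model {model.source_id}: "
                f"{sorted(missing)}"
            )


def _radius_for(element: str) -> float:
    el = element.strip().upper()
    r = VDW_RADII.get(el)
    if r is None:
        warnings.warn(
            f"no van der Waals radius tabulated for element {element!r}; "
            f"using {DEFAULT_RADIUS} Å",
            stacklevel=3,
        )
        return DEFAULT_RADIUS
    return r


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties broken by altloc identifier order
    return sorted(atoms, key=lambda a: (-a.occ, a.altloc))[0]


def load_structure(source: str, format: str = "pdb", source_id: str = "") -> StructureModel:
    """Parse PDB or mmCIF text into a :class:`StructureModel`.

    Only standard amino-acid residues of polymer chains are retained;
    waters, ions, glycans and other hetero groups are discarded.  Each atom
    is assigned a van der Waals radius from the element table.

    Parameters
    ----------
    source:
        File content (text).
    format:
        ``"pdb"`` or ``"mmcif"``.
    source_id:
        Identifier recorded on the model (defaults to the structure's own
        name if present).
    """
    if format == "pdb":
        st = gemmi.read_pdb_string(source)
    elif format == "mmcif":
        doc = gemmi.cif.read_string(source)
        st = gemmi.make_structure_from_block(doc.sole_block())
    else:
        raise ValueError(f"unknown structure format {format!r}")

    st.setup_entities()
    model = StructureModel(source_id=source_id or st.name or "structure")
    gmodel = st[0]  # first model only
    serial = 0
    for chain in gmodel:
        residues: list[Residue] = []
        for gres in chain:
            info = gemmi.find_tabulated_residue(gres.name)
            if info is None or not info.is_amino_acid() or gres.is_water():
                continue
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in gres:
                by_name.setdefault(atom.name, []).append(atom)
            atoms = []
            for name in by_name:
                ga = _pick_altloc(by_name[name])
                serial += 1
                atoms.append(
                    Atom(
                        serial=serial,
                        element=ga.element.name,
                        coords=(ga.pos.x, ga.pos.y, ga.pos.z),
                        radius=_radius_for(ga.element.name),
                        name=name,
                    )
                )
            if atoms:
                residues.append(
                    Residue(
                        chain_id=chain.name,
                        number=gres.seqid.num,
                        insertion_code=(gres.seqid.icode or "").strip(),
                        name=gres.name,
                        atoms=tuple(atoms),
                    )
                )
        if residues:
            model.chains[chain.name] = residues
    if not model.chains:
        raise ValueError("no polymer residues in structure")
    model.validate()
    return model
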