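"""PDB parsing, chain classification, bound/unbound views and interface detection.

The parser handles the fixed-column ATOM/HETATM/TER/MODEL/ENDMDL subset of
the PDB format.  Only the first model of multi-model files is kept, waters
are dropped, and alternate locations are resolved to the highest-occupancy
conformer (ties broken alphabetically by altloc code).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._tables import DNA_RESIDUES, PROTEIN_RESIDUES, WATER_RESIDUES

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "InterfaceSet",
    "PdbFormatError",
    "InputError",
    "read_pdb",
    "write_pdb",
    "classify_chain",
    "find_interface_residues",
]


class PdbFormatError(ValueError):
    """Unparseable record in a PDB file."""


class InputError(ValueError):
    """Structurally valid input that cannot be used (e.g. no protein chain)."""


#: (chain id, residue sequence number, insertion code)
ResidueId = tuple[str, int, str]


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    residue_id: ResidueId
    coordinates: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError(f"non-finite coordinates for atom {self.serial}")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    chain_id: str
    seqnum: int
    icode: str
    name: str
    atoms: list[Atom] = field(default_factory=list)
    kind: str = "other"  # protein | DNA | other

    @property
    def residue_id(self) -> ResidueId:
        return (self.chain_id, self.seqnum, self.icode)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    @property
    def ca(self) -> Atom | None:
        return self.atom("CA")


class StructureModel:
    """Residues grouped by chain with bound (all chains) and unbound
    (protein-only) coordinate views."""

    def __init__(self, residues: list[Residue]):
        self.residues = residues
        self.chains: dict[str, list[Residue]] = {}
        for res in residues:
            self.chains.setdefault(res.chain_id, []).append(res)
        self.chain_kinds: dict[str, str] = {
            cid: classify_chain([r.name for r in resl]) for cid, resl in self.chains.items()
        }
        for res in residues:
            kind = self.chain_kinds[res.chain_id]
            if kind == "protein" and res.name in PROTEIN_RESIDUES:
                res.kind = "protein"
            elif kind == "DNA" and res.name in DNA_RESIDUES:
                res.kind = "DNA"
            else:
                res.kind = (
                    "protein" if res.name in PROTEIN_RESIDUES
                    else "DNA" if res.name in DNA_RESIDUES
                    else "other"
                )
        self._index = {r.residue_id: r for r in residues}

    def set_chain_kinds(self, protein_chains=(), dna_chains=()) -> None:
        """Override auto-classification with explicit chain role assignment."""
        for cid in protein_chains:
            self.chain_kinds[cid] = "protein"
        for cid in dna_chains:
            self.chain_kinds[cid] = "DNA"
        for res in self.residues:
            if res.chain_id in protein_chains:
                res.kind = "protein"
            elif res.chain_id in dna_chains:
                res.kind = "DNA"

    def residue(self, residue_id: ResidueId) -> Residue:
        return self._index[residue_id]

    @property
    def protein_chains(self) -> list[str]:
        return [c for c, k in self.chain_kinds.items() if k == "protein"]

    @property
    def dna_chains(self) -> list[str]:
        return [c for c, k in self.chain_kinds.items() if k == "DNA"]

    def protein_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.kind == "protein"]

    def dna_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.kind == "DNA"]

    def bound_atoms(self) -> list[Atom]:
        """All atoms of the complex (bound state)."""
        return [a for r in self.residues for a in r.atoms]

    def unbound_atoms(self) -> list[Atom]:
        """Protein-chain atoms only, coordinates unchanged (unbound state)."""
        return [a for r in self.residues if r.kind == "protein" for a in r.atoms]

    def next_residue_in_chain(self, res: Residue) -> Residue | None:
        chain = self.chains[res.chain_id]
        idx = chain.index(res)
        if idx + 1 < len(chain):
            return chain[idx + 1]
        return None


@dataclass
class InterfaceSet:
    """Ordered interface residue ids with per-residue neighbor lists.

    Neighbors are themselves interface residues and the relation is
    symmetric and irreflexive.
    """

    residue_ids: list[ResidueId]
    neighbors: dict[ResidueId, list[ResidueId]]
    casa: dict[ResidueId, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.residue_ids)

    def __iter__(self):
        return iter(self.residue_ids)


def classify_chain(residue_names: list[str]) -> str:
    """Majority vote over residue-name tables; ties -> ``other``."""
    if not residue_names:
        raise ValueError("empty residue name list")
    n_prot = sum(1 for n in residue_names if n in PROTEIN_RESIDUES)
    n_dna = sum(1 for n in residue_names if n in DNA_RESIDUES)
    n_other = len(residue_names) - n_prot - n_dna
    best = max(n_prot, n_dna, n_other)
    if [n_prot, n_dna, n_other].count(best) > 1:
        return "other"
    if best == n_prot:
        return "protein"
    if best == n_dna:
        return "DNA"
    return "other"


def _guess_element(atom_name: str) -> str:
    name = atom_name.strip()
    name = name.lstrip("0123456789")
    if not name:
        return ""
    if name[0] in ("H", "D") or name[:2] in ("1H", "2H", "3H"):
        return "H"
    two = name[:2].upper()
    if two in ("SE", "CL", "BR", "FE", "ZN", "MG", "MN"):
        return two
    return name[0].upper()


def _parse_atom_line(line: str, lineno: int) -> Atom:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        element = line[76:78].strip() if len(line) >= 78 else ""
        chain_id = line[21].strip() or " "
        seqnum = int(line[22:26])
        icode = line[26].strip()
    except (ValueError, IndexError) as exc:
        raise PdbFormatError(f"unparseable ATOM/HETATM record at line {lineno}: {exc}") from exc
    if not element:
        element = _guess_element(name)
    return Atom(
        serial=serial,
        name=name,
        element=element,
        residue_id=(chain_id, seqnum, icode),
        coordinates=np.array([x, y, z]),
        occupancy=occupancy,
        altloc=altloc,
    )


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    # group by (residue, atom name); keep highest occupancy, ties -> first
    # alphabetical altloc
    groups: dict[tuple, list[Atom]] = {}
    order: list[tuple] = []
    for a in atoms:
        key = (a.residue_id, a.name)
        if key not in groups:
            order.append(key)
        groups.setdefault(key, []).append(a)
    kept = []
    for key in order:
        grp = groups[key]
        if len(grp) == 1:
            kept.append(grp[0])
        else:
            kept.append(min(grp, key=lambda a: (-a.occupancy, a.altloc)))
    return kept


def read_pdb(text: str) -> StructureModel:
    """Parse PDB-format content into a :class:`StructureModel`.

    First model only; waters excluded; altlocs resolved to the
    highest-occupancy conformer.
    """
    atoms: list[Atom] = []
    resnames: dict[ResidueId, str] = {}
    in_model = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            in_model += 1
            if in_model > 1:
                break
        elif rec == "ENDMDL":
            break
        elif rec in ("ATOM", "HETATM"):
            resname = line[17:20].strip()
            if resname in WATER_RESIDUES:
                continue
            atom = _parse_atom_line(line, lineno)
            atoms.append(atom)
            resnames[atom.residue_id] = resname
    if not atoms:
        raise InputError("no ATOM records found")
    atoms = _resolve_altlocs(atoms)

    residues: list[Residue] = []
    index: dict[ResidueId, Residue] = {}
    for atom in atoms:
        rid = atom.residue_id
        if rid not in index:
            res = Residue(
                chain_id=rid[0], seqnum=rid[1], icode=rid[2], name=resnames[rid]
            )
            index[rid] = res
            residues.append(res)
        index[rid].atoms.append(atom)

    model = StructureModel(residues)
    if not model.protein_chains:
        raise InputError("structure contains no protein chain")
    return model


def write_pdb(model: StructureModel) -> str:
    """Serialize a model back to PDB text (ATOM records only)."""
    lines = []
    for res in model.residues:
        record = "ATOM" if res.kind in ("protein", "DNA") else "HETATM"
        for a in res.atoms:
            name = a.name if len(a.name) == 4 else f" {a.name}"
            lines.append(
                f"{record:<6s}{a.serial:>5d} {name:<4s}{a.altloc or ' ':1s}"
                f"{res.name:>3s} {res.chain_id:1s}{res.seqnum:>4d}{res.icode or ' ':1s}   "
                f"{a.coordinates[0]:8.3f}{a.coordinates[1]:8.3f}{a.coordinates[2]:8.3f}"
                f"{a.occupancy:6.2f}{0.0:6.2f}          {a.element:>2s}"
            )
    lines.append("END")
    return "\n".join(lines) + "\n"


def _distance_interface(model: StructureModel, cutoff: float = 5.0) -> list[ResidueId]:
    """Alternative interface criterion: any heavy atom within ``cutoff`` of a
    DNA heavy atom."""
    dna_xyz = np.array(
        [a.coordinates for r in model.dna_residues() for a in r.heavy_atoms]
    )
    ids = []
    if dna_xyz.size == 0:
        return ids
    from scipy.spatial import cKDTree

    tree = cKDTree(dna_xyz)
    for res in model.protein_residues():
        xyz = np.array([a.coordinates for a in res.heavy_atoms])
        if xyz.size == 0:
            continue
        d, _ = tree.query(xyz, k=1)
        if np.min(d) <= cutoff:
            ids.append(res.residue_id)
    return ids


def find_interface_residues(
    model: StructureModel,
    sasa_fn=None,
    threshold: float = 0.0,
    neighbor_cutoff: float = 6.5,
    mode: str = "casa",
    distance_cutoff: float = 5.0,
) -> InterfaceSet:
    """Identify interface residues and build their neighbor lists.

    A protein residue is interfacial iff its total absolute ASA drops by more
    than ``threshold`` (strict) from the unbound protein to the bound
    complex; ``mode='distance'`` switches to a heavy-atom distance criterion.
    Neighbors are other interface residues whose Calpha lies within
    ``neighbor_cutoff`` of the target's Calpha.

    ``sasa_fn(model, view) -> {residue_id: total_asa}`` may be injected; by
    default the package's own SASA engine is used.
    """
    if not model.protein_chains:
        raise InputError("no protein chains")
    if not model.dna_chains:
        raise InputError("no DNA chains")

    casa: dict[ResidueId, float] = {}
    if mode == "distance":
        ids = _distance_interface(model, distance_cutoff)
        casa = {rid: float("nan") for rid in ids}
    elif mode == "casa":
        if sasa_fn is None:
            from .sasa import residue_total_asa

            sasa_fn = residue_total_asa
        mono = sasa_fn(model, "unbound")
        comp = sasa_fn(model, "bound")
        ids = []
        for res in model.protein_residues():
            rid = res.residue_id
            delta = mono.get(rid, 0.0) - comp.get(rid, 0.0)
            if delta > threshold:
                ids.append(rid)
                casa[rid] = delta
    else:
        raise ValueError(f"unknown interface mode {mode!r}")

    # neighbor lists: Calpha-Calpha <= cutoff among interface residues
    coords = {}
    for rid in ids:
        ca = model.residue(rid).ca
        if ca is None:
            warnings.warn(
                f"interface residue {rid} lacks a CA atom; excluded from neighbor sets"
            )
            continue
        coords[rid] = ca.coordinates
    neighbors: dict[ResidueId, list[ResidueId]] = {rid: [] for rid in ids}
    withca = list(coords)
    for i, ri in enumerate(withca):
        for rj in withca[i + 1:]:
            if np.linalg.norm(coords[ri] - coords[rj]) <= neighbor_cutoff:
                neighbors[ri].append(rj)
                neighbors[rj].append(ri)
    return InterfaceSet(residue_ids=ids, neighbors=neighbors, casa=casa)
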