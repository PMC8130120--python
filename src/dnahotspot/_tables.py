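"""Static chemistry tables: residue name sets, radii, reference ASA, H-bond atom roles.

All tables are plain module-level dicts so callers can copy and override them
through configuration objects.
"""

from __future__ import annotations

PROTEIN_RESIDUES = frozenset(
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    }
)

DNA_RESIDUES = frozenset({"DA", "DC", "DG", "DT", "DI"})

WATER_RESIDUES = frozenset({"HOH", "WAT", "DOD"})

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

#: Heavy-atom van der Waals radii (Angstrom), NACCESS-style values.
VDW_RADII = {
    "C": 1.87,
    "N": 1.65,
    "O": 1.40,
    "S": 1.85,
    "P": 1.90,
    "H": 1.00,
    "D": 1.00,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}

#: Reference maximum ASA (Angstrom^2) per residue type, tripeptide-derived
#: published values; total and side-chain variants.  Used to turn absolute
#: ASA into relative ASA percentages.
MAX_ASA_TOTAL = {
    "ALA": 113.0, "ARG": 241.0, "ASN": 158.0, "ASP": 151.0, "CYS": 140.0,
    "GLN": 189.0, "GLU": 183.0, "GLY": 85.0, "HIS": 194.0, "ILE": 182.0,
    "LEU": 180.0, "LYS": 211.0, "MET": 204.0, "PHE": 218.0, "PRO": 143.0,
    "SER": 122.0, "THR": 146.0, "TRP": 259.0, "TYR": 229.0, "VAL": 160.0,
}

MAX_ASA_SIDECHAIN = {
    "ALA": 67.0, "ARG": 196.0, "ASN": 113.0, "ASP": 106.0, "CYS": 104.0,
    "GLN": 144.0, "GLU": 138.0, "GLY": 0.0, "HIS": 151.0, "ILE": 140.0,
    "LEU": 137.0, "LYS": 167.0, "MET": 160.0, "PHE": 175.0, "PRO": 105.0,
    "SER": 80.0, "THR": 102.0, "TRP": 217.0, "TYR": 187.0, "VAL": 117.0,
}

# Hydrogen-bond donor heavy atoms per residue type.  Backbone amide N is a
# donor for every protein residue except proline; it is added in code, not
# listed here.
HBOND_DONORS = {
    "ARG": {"NE", "NH1", "NH2"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"},
    "LYS": {"NZ"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TRP": {"NE1"},
    "TYR": {"OH"},
    "CYS": {"SG"},
    # DNA base exocyclic amines / imino nitrogens
    "DA": {"N6"},
    "DC": {"N4"},
    "DG": {"N1", "N2"},
    "DT": {"N3"},
    "DI": {"N1"},
}

# Hydrogen-bond acceptor heavy atoms per residue type.  Backbone carbonyl O
# (and OXT) accept for every protein residue and are added in code.
_DNA_BACKBONE_ACCEPTORS = {
    "OP1", "OP2", "O1P", "O2P", "O5'", "O3'", "O4'",
    "O5*", "O3*", "O4*",
}

HBOND_ACCEPTORS = {
    "ASN": {"OD1"},
    "ASP": {"OD1", "OD2"},
    "GLN": {"OE1"},
    "GLU": {"OE1", "OE2"},
    "HIS": {"ND1", "NE2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "MET": {"SD"},
    "DA": {"N1", "N3", "N7"} | _DNA_BACKBONE_ACCEPTORS,
    "DC": {"O2", "N3"} | _DNA_BACKBONE_ACCEPTORS,
    "DG": {"O6", "N3", "N7"} | _DNA_BACKBONE_ACCEPTORS,
    "DT": {"O2", "O4"} | _DNA_BACKBONE_ACCEPTORS,
    "DI": {"O6", "N3", "N7"} | _DNA_BACKBONE_ACCEPTORS,
}


def element_radius(element: str, table: dict | None = None, default: float | None = None) -> float:
    """Resolve an element symbol to a vdW radius.

    Raises ``KeyError`` for unknown elements unless ``default`` is given.
    """
    tab = VDW_RADII if table is None else table
    key = element.strip().upper()
    if key in tab:
        return tab[key]
    if default is not None:
        return default
    raise KeyError(f"no van der Waals radius for element {element!r}")
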