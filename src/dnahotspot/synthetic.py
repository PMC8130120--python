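"""Synthetic test fixtures: toy protein-DNA complexes and labeled feature tables.

The toy complex is an ideal-geometry extended peptide placed at a
controlled gap from a simplified B-DNA duplex (helical rise 3.4 A, twist
36 deg; backbone P/O5'/C5'/C4'/C3'/O3' plus OP1/OP2 and a base anchor
nitrogen).  It is geometrically plausible for ASA, contact and H-bond
computations, not chemically exact.

Feature tables draw informative columns from class-shifted Gaussians and
plant correlated pairs with an exact in-sample Pearson r, so selection
behavior can be asserted against known ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import KEY_COLUMNS, LABEL_COLUMN, FeatureTable
from .structure import Atom, Residue, StructureModel, write_pdb

__all__ = ["ToyComplexSpec", "SyntheticTableSpec", "make_toy_complex", "make_feature_table"]


@dataclass
class ToyComplexSpec:
    peptide_length: int = 6
    dna_length: int = 8
    gap: float = 3.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.peptide_length < 3 or self.dna_length < 3:
            raise ValueError("chain lengths must be >= 3")
        if self.gap < 0:
            raise ValueError("gap must be >= 0")


@dataclass
class SyntheticTableSpec:
    n_positive: int = 62
    n_negative: int = 88
    n_informative: int = 3
    effect_size: float = 1.5
    n_noise: int = 7
    n_corr_pairs: int = 0
    corr_target: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        for v in (self.n_positive, self.n_negative, self.n_informative, self.n_noise, self.n_corr_pairs):
            if v < 0:
                raise ValueError("counts must be >= 0")
        if not -1.0 < self.corr_target < 1.0:
            raise ValueError("target correlation must lie in (-1, 1)")


# ---------------------------------------------------------------------------
# geometry helpers


def _unit(v):
    return v / np.linalg.norm(v)


def _place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF placement: new atom bonded to c with given b-c-new angle and
    a-b-c-new torsion (degrees)."""
    ang = math.radians(angle)
    tor = math.radians(torsion)
    d2 = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            -bond * math.sin(ang) * math.sin(tor),
        ]
    )
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.column_stack([bc, np.cross(n, bc), n])
    return c + m @ d2


_PEPTIDE_POOL = ["SER", "ALA", "LYS", "THR", "ARG", "ASN", "GLY", "LEU", "TYR", "GLN"]

# ideal backbone internal coordinates
_B = {"n_ca": 1.458, "ca_c": 1.525, "c_n": 1.329, "c_o": 1.231, "ca_cb": 1.522}
_A = {"n_ca_c": 111.0, "ca_c_n": 116.2, "c_n_ca": 121.7, "ca_c_o": 120.8}
_PHI, _PSI, _OMEGA = -135.0, 135.0, 180.0


def _build_peptide(length: int, rng: np.random.Generator):
    seq = [ _PEPTIDE_POOL[int(rng.integers(len(_PEPTIDE_POOL)))] for _ in range(length) ]
    backbone = []  # (N, CA, C) triples
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B["n_ca"], 0.0, 0.0])
    ang = math.radians(_A["n_ca_c"])
    c0 = ca0 + _B["ca_c"] * np.array([-math.cos(ang), math.sin(ang), 0.0])
    backbone.append((n0, ca0, c0))
    for _ in range(1, length):
        n_prev, ca_prev, c_prev = backbone[-1]
        n = _place_atom(n_prev, ca_prev, c_prev, _B["c_n"], _A["ca_c_n"], _PSI)
        ca = _place_atom(ca_prev, c_prev, n, _B["n_ca"], _A["c_n_ca"], _OMEGA)
        c = _place_atom(c_prev, n, ca, _B["ca_c"], _A["n_ca_c"], _PHI)
        backbone.append((n, ca, c))

    residues = []
    for i, (name, (n, ca, c)) in enumerate(zip(seq, backbone)):
        atoms = {"N": n, "CA": ca, "C": c}
        if i + 1 < length:
            n_next = backbone[i + 1][0]
            atoms["O"] = _place_atom(n_next, ca, c, _B["c_o"], _A["ca_c_o"], 180.0 + _PSI)
        else:
            atoms["O"] = _place_atom(n, ca, c, _B["c_o"], _A["ca_c_o"], _PSI - 180.0)
        if name != "GLY":
            atoms["CB"] = _place_cb(n, ca, c)
        # one representative side-chain tip atom to give donors something real
        tip = _SIDECHAIN_TIP.get(name)
        if tip is not None and "CB" in atoms:
            direction = _unit(atoms["CB"] - ca)
            atoms[tip[0]] = atoms["CB"] + tip[1] * direction
        residues.append((name, atoms))
    return residues


#: minimal side-chain tip per residue type: (atom name, distance from CB
#: along the CA->CB direction).  Gives each residue its donor/acceptor atom.
_SIDECHAIN_TIP = {
    "SER": ("OG", 1.42),
    "THR": ("OG1", 1.43),
    "LYS": ("NZ", 3.1),
    "ARG": ("NH1", 4.1),
    "ASN": ("ND2", 2.5),
    "GLN": ("NE2", 3.2),
    "TYR": ("OH", 4.3),
    "LEU": ("CD1", 2.5),
}


def _place_cb(n, ca, c, length: float = 1.522) -> np.ndarray:
    v1 = _unit(n - ca)
    v2 = _unit(c - ca)
    bis = _unit(v1 + v2)
    perp = _unit(np.cross(v2, v1))
    cos_t = math.cos(math.radians(110.5))
    alpha = -cos_t / float(np.dot(bis, v1))
    alpha = min(1.0, max(-1.0, alpha))
    beta = math.sqrt(max(0.0, 1.0 - alpha * alpha))
    return ca + length * _unit(-alpha * bis + beta * perp)


_DNA_ATOMS = [  # (name, radius from helix axis, angular offset deg)
    ("P", 8.9, 95.0),
    ("OP1", 9.7, 103.0),
    ("OP2", 9.3, 112.0),
    ("O5'", 8.4, 82.0),
    ("C5'", 7.9, 70.0),
    ("C4'", 7.3, 60.0),
    ("C3'", 7.7, 46.0),
    ("O3'", 7.5, 32.0),
    ("O4'", 6.4, 52.0),
    ("C1'", 5.8, 40.0),
]

_COMPLEMENT = {"DA": "DT", "DT": "DA", "DG": "DC", "DC": "DG"}
_RISE, _TWIST = 3.4, 36.0


def _build_dna(length: int, rng: np.random.Generator):
    bases = [["DA", "DT", "DG", "DC"][int(rng.integers(4))] for _ in range(length)]
    strands = []
    for strand_idx, (phase, direction) in enumerate([(0.0, 1.0), (154.0, -1.0)]):
        residues = []
        for i in range(length):
            theta = math.radians(direction * _TWIST * i + phase)
            x = _RISE * i
            atoms = {}
            for name, r, off in _DNA_ATOMS:
                a = theta + math.radians(direction * off)
                atoms[name] = np.array([x, r * math.cos(a), r * math.sin(a)])
            base = bases[i] if strand_idx == 0 else _COMPLEMENT[bases[i]]
            anchor = "N9" if base in ("DA", "DG") else "N1"
            a = theta + math.radians(direction * 10.0)
            atoms[anchor] = np.array([x, 4.6 * math.cos(a), 4.6 * math.sin(a)])
            residues.append((base, atoms))
        strands.append(residues)
    return strands


def make_toy_complex(spec: ToyComplexSpec) -> str:
    """PDB text of a peptide (chain A) facing a DNA duplex (chains B, C).

    The duplex is translated so the smallest peptide-DNA heavy-atom
    distance equals ``spec.gap`` (within 0.2 A).
    """
    rng = np.random.default_rng(spec.seed)
    pep = _build_peptide(spec.peptide_length, rng)
    strands = _build_dna(spec.dna_length, rng)

    pep_xyz = np.array([p for _, atoms in pep for p in atoms.values()])
    dna_xyz = np.array(
        [p for strand in strands for _, atoms in strand for p in atoms.values()]
    )
    # translate the duplex along +y until the closest approach matches the gap
    offset = np.array([0.0, 25.0, 0.0])
    for _ in range(25):
        d = np.sqrt(
            ((pep_xyz[:, None, :] - (dna_xyz + offset)[None, :, :]) ** 2).sum(-1)
        ).min()
        if abs(d - spec.gap) < 0.2:
            break
        offset[1] += spec.gap - d

    residues = []
    serial = 1
    for i, (name, atoms) in enumerate(pep, start=1):
        res = Residue(chain_id="A", seqnum=i, icode="", name=name)
        for aname, xyz in atoms.items():
            res.atoms.append(
                Atom(serial=serial, name=aname, element=aname[0], residue_id=("A", i, ""), coordinates=xyz)
            )
            serial += 1
        residues.append(res)
    for chain_id, strand in zip("BC", strands):
        for i, (name, atoms) in enumerate(strand, start=1):
            res = Residue(chain_id=chain_id, seqnum=i, icode="", name=name)
            for aname, xyz in atoms.items():
                res.atoms.append(
                    Atom(
                        serial=serial,
                        name=aname,
                        element=aname[0],
                        residue_id=(chain_id, i, ""),
                        coordinates=xyz + offset,
                    )
                )
                serial += 1
            residues.append(res)
    return write_pdb(StructureModel(residues))


# ---------------------------------------------------------------------------
# labeled feature tables


def _exact_corr_partner(base: np.ndarray, r: float, rng: np.random.Generator) -> np.ndarray:
    """A column whose in-sample Pearson correlation with ``base`` is exactly r."""
    if not -1.0 < r < 1.0:
        raise ValueError("target correlation must lie in (-1, 1)")
    f = base - base.mean()
    fnorm = np.linalg.norm(f)
    if fnorm == 0:
        raise ValueError("cannot correlate against a constant column")
    f = f / fnorm
    eps = rng.standard_normal(len(base))
    eps = eps - eps.mean()
    eps = eps - (eps @ f) * f
    enorm = np.linalg.norm(eps)
    if enorm == 0:
        raise ValueError("degenerate noise draw; infeasible correlation request")
    eps = eps / enorm
    return r * f + math.sqrt(1.0 - r * r) * eps


def make_feature_table(spec: SyntheticTableSpec) -> tuple[FeatureTable, dict]:
    """Labeled table with known informative features and planted correlated pairs.

    Informative columns are Gaussian with a between-class mean shift of
    ``effect_size`` standard deviations; noise columns are class-free; each
    planted pair adds a partner column with exact in-sample correlation
    ``corr_target`` to one of the existing columns (informative first).
    Ground truth (informative names, partner pairs) is returned alongside.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_positive + spec.n_negative
    y = np.array([1] * spec.n_positive + [0] * spec.n_negative)

    columns: list[np.ndarray] = []
    names: list[str] = []
    for i in range(spec.n_informative):
        col = rng.standard_normal(n) + spec.effect_size * y
        columns.append(col)
        names.append(f"inf_{i + 1:02d}")
    for i in range(spec.n_noise):
        columns.append(rng.standard_normal(n))
        names.append(f"noise_{i + 1:02d}")

    pairs = []
    if spec.n_corr_pairs > len(columns):
        raise ValueError("more correlated pairs requested than base columns")
    for k in range(spec.n_corr_pairs):
        base_idx = k % len(names)
        partner = _exact_corr_partner(columns[base_idx], spec.corr_target, rng)
        pname = f"dup_{names[base_idx]}"
        pairs.append((names[base_idx], pname, spec.corr_target))
        columns.append(partner)
        names.append(pname)

    perm = rng.permutation(n)
    data = np.column_stack(columns)[perm]
    y = y[perm]

    frame = pd.DataFrame(data, columns=names)
    for col, val in zip(KEY_COLUMNS, ["SYN", "A", None, "", "ALA"]):
        frame[col] = np.arange(1, n + 1) if val is None else val
    frame[LABEL_COLUMN] = y
    frame = frame[KEY_COLUMNS + names + [LABEL_COLUMN]]

    truth = {
        "informative": names[: spec.n_informative],
        "noise": [f"noise_{i + 1:02d}" for i in range(spec.n_noise)],
        "pairs": pairs,
        "effect_size": spec.effect_size,
    }
    table = FeatureTable(frame, names, provenance={"generator": "synthetic", "seed": spec.seed})
    return table, truth
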