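"""Solvent-accessible surface area via Shrake-Rupley on a deterministic
Fibonacci lattice.

Per-atom ASA is the exposed fraction of lattice points on the expanded
sphere of radius ``r_vdw + probe`` times the full sphere area.  Hydrogens
are ignored (heavy-atom radii only).  Values differ from slice-based
engines (NACCESS) by roughly 1-2 percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ._tables import (
    BACKBONE_ATOMS,
    MAX_ASA_SIDECHAIN,
    MAX_ASA_TOTAL,
    VDW_RADII,
    element_radius,
)

__all__ = ["SasaParams", "ResidueAsa", "fibonacci_sphere", "shrake_rupley", "residue_asa", "residue_total_asa"]


@dataclass
class SasaParams:
    probe_radius: float = 1.4
    n_points: int = 960
    radii: dict = field(default_factory=lambda: dict(VDW_RADII))
    default_radius: float | None = None
    #: glycine convention: side-chain ASA is 0 (no CB).  With
    #: ``gly_ca_sidechain=True`` the CA is counted as side chain instead.
    gly_ca_sidechain: bool = False

    def __post_init__(self) -> None:
        if self.probe_radius < 0:
            raise ValueError("probe radius must be >= 0")
        if self.n_points < 24:
            raise ValueError("need at least 24 sphere points")


@dataclass
class ResidueAsa:
    total_asa: float
    sidechain_asa: float
    total_rsa: float | None  # percent, None when no reference value
    sidechain_rsa: float | None


def fibonacci_sphere(n: int, rotation: np.ndarray | None = None) -> np.ndarray:
    """Deterministic near-uniform unit-sphere point set (golden-angle spiral).

    ``rotation`` (3x3) re-generates the lattice in a rotated frame, which
    makes ASA exactly invariant under the matching rigid rotation of the
    atoms.
    """
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    if rotation is not None:
        pts = pts @ np.asarray(rotation, dtype=float).T
    return pts


def shrake_rupley(
    atoms,
    params: SasaParams | None = None,
    rotation: np.ndarray | None = None,
) -> np.ndarray:
    """Per-atom ASA (Angstrom^2) for a list of atoms.

    Hydrogen atoms receive ASA 0 and do not occlude.  Unknown elements raise
    ``KeyError`` unless ``params.default_radius`` is set.
    """
    params = params or SasaParams()
    heavy_idx = [i for i, a in enumerate(atoms) if not a.is_hydrogen]
    n_all = len(atoms)
    out = np.zeros(n_all)
    if not heavy_idx:
        return out

    xyz = np.array([atoms[i].coordinates for i in heavy_idx], dtype=float)
    radii = np.array(
        [
            element_radius(atoms[i].element, params.radii, params.default_radius)
            for i in heavy_idx
        ]
    )
    expanded = radii + params.probe_radius
    sphere = fibonacci_sphere(params.n_points, rotation)

    tree = cKDTree(xyz)
    max_r = expanded.max()
    for k in range(len(heavy_idx)):
        center = xyz[k]
        rk = expanded[k]
        pts = center + sphere * rk
        neigh = [j for j in tree.query_ball_point(center, rk + max_r) if j != k]
        exposed = np.ones(len(pts), dtype=bool)
        for j in neigh:
            d2 = np.sum((pts - xyz[j]) ** 2, axis=1)
            exposed &= d2 > expanded[j] ** 2
            if not exposed.any():
                break
        frac = exposed.sum() / params.n_points
        out[heavy_idx[k]] = frac * 4.0 * np.pi * rk * rk
    return out


def _is_sidechain(atom, resname: str, params: SasaParams) -> bool:
    if atom.name in BACKBONE_ATOMS:
        if resname == "GLY" and params.gly_ca_sidechain and atom.name == "CA":
            return True
        return False
    return True


def residue_asa(
    residue,
    atom_asa: dict[int, float],
    params: SasaParams | None = None,
) -> ResidueAsa:
    """Aggregate per-atom ASA into the four per-residue quantities.

    ``atom_asa`` maps atom serial -> ASA computed on the desired view
    (bound or unbound).  RSA is in percent; ``None`` when the residue type
    has no reference value (ASA is still reported).
    """
    params = params or SasaParams()
    total = 0.0
    side = 0.0
    for a in residue.heavy_atoms:
        v = atom_asa.get(a.serial, 0.0)
        total += v
        if _is_sidechain(a, residue.name, params):
            side += v
    ref_t = MAX_ASA_TOTAL.get(residue.name)
    ref_s = MAX_ASA_SIDECHAIN.get(residue.name)
    rsa_t = 100.0 * total / ref_t if ref_t else None
    rsa_s = (100.0 * side / ref_s) if ref_s else (0.0 if ref_s == 0.0 else None)
    return ResidueAsa(total, side, rsa_t, rsa_s)


def compute_view_asa(model, view: str, params: SasaParams | None = None):
    """Per-atom and per-residue ASA for a model view.

    ``view`` is ``'bound'`` (all chains) or ``'unbound'`` (protein chains
    only, identical coordinates).  Returns ``(atom_asa, residue_asa_map)``
    where keys are atom serials and residue ids.
    """
    params = params or SasaParams()
    atoms = model.bound_atoms() if view == "bound" else model.unbound_atoms()
    per_atom = shrake_rupley(atoms, params)
    atom_asa = {a.serial: v for a, v in zip(atoms, per_atom)}
    residues = model.residues if view == "bound" else [
        r for r in model.residues if r.kind == "protein"
    ]
    res_map = {r.residue_id: residue_asa(r, atom_asa, params) for r in residues}
    return atom_asa, res_map


def residue_total_asa(model, view: str, params: SasaParams | None = None) -> dict:
    """Total absolute ASA per residue id for a view (interface detection hook)."""
    _, res_map = compute_view_asa(model, view, params)
    return {rid: ra.total_asa for rid, ra in res_map.items()}


def rsa_table_to_tsv(res_map, model) -> str:
    """NACCESS-like per-residue dump: ABS/REL x ALL-ATOMS/SIDE-CHAIN."""
    lines = ["chain\tresnum\ticode\tresname\tabs_total\trel_total\tabs_side\trel_side"]
    for rid, ra in res_map.items():
        res = model.residue(rid)
        rel_t = f"{ra.total_rsa:.1f}" if ra.total_rsa is not None else "NA"
        rel_s = f"{ra.sidechain_rsa:.1f}" if ra.sidechain_rsa is not None else "NA"
        lines.append(
            f"{rid[0]}\t{rid[1]}\t{rid[2]}\t{res.name}\t"
            f"{ra.total_asa:.2f}\t{rel_t}\t{ra.sidechain_asa:.2f}\t{rel_s}"
        )
    return "\n".join(lines) + "\n"
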