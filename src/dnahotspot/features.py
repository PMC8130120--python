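"""The 24-feature structural encoding of interface residues.

Feature order (fixed, used everywhere):

  1-4   bound ASA            BsASA BsRSA BtASA BtRSA
  5-8   change on binding    CsASA CsRSA CtASA CtRSA   (monomer - complex)
  9-12  relative change      RsASA RsRSA RtASA RtRSA   (change / monomer)
  13    Eig   eigenvector centrality in the interface contact network
  14    Psi   backbone psi torsion (degrees)
  15    HbCN  half-sphere Calpha-Cbeta contact number (total)
  16    DN    hydrogen bonds donated by the residue in the bound complex
  17-20 INP1-{sASA,sRSA,tASA,tRSA}   neighbor-ratio difference, monomer vs complex
  21-24 INP2-{CsASA,CsRSA,CtASA,CtRSA}  neighbor-ratio of binding-induced change

INP features compare the target residue's ASA quantity to the mean over its
interfacial neighbors (Calpha within 6.5 A, interface residues only,
target excluded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._tables import BACKBONE_ATOMS, HBOND_ACCEPTORS, HBOND_DONORS
from .sasa import SasaParams, ResidueAsa, compute_view_asa
from .structure import InterfaceSet, StructureModel, find_interface_residues

__all__ = [
    "FEATURE_NAMES",
    "KEY_COLUMNS",
    "FeatureTable",
    "FeatureParams",
    "asa_block",
    "inp1",
    "inp2",
    "psi_angle",
    "dihedral",
    "eigenvector_centrality",
    "half_sphere_contact_numbers",
    "pseudo_cb",
    "hbond_donor_count",
    "featurize",
    "impute_median",
]

FEATURE_NAMES = [
    "BsASA", "BsRSA", "BtASA", "BtRSA",
    "CsASA", "CsRSA", "CtASA", "CtRSA",
    "RsASA", "RsRSA", "RtASA", "RtRSA",
    "Eig", "Psi", "HbCN", "DN",
    "INP1-sASA", "INP1-sRSA", "INP1-tASA", "INP1-tRSA",
    "INP2-CsASA", "INP2-CsRSA", "INP2-CtASA", "INP2-CtRSA",
]

KEY_COLUMNS = ["pdb_id", "chain", "resnum", "icode", "resname"]

LABEL_COLUMN = "label"


@dataclass
class FeatureParams:
    sasa: SasaParams = field(default_factory=SasaParams)
    interface_threshold: float = 0.0
    interface_mode: str = "casa"
    neighbor_cutoff: float = 6.5
    eig_cutoff: float = 7.0
    hse_radius: float = 13.0
    hbond_da_cutoff: float = 3.9
    hbond_ha_cutoff: float = 2.5
    hbond_angle_min: float = 90.0
    #: which half-sphere count feeds the HbCN column: up | down | total
    hbcn_variant: str = "total"


@dataclass
class FeatureTable:
    """Residues x features matrix with optional labels and provenance."""

    frame: pd.DataFrame
    feature_names: list[str] = field(default_factory=lambda: list(FEATURE_NAMES))
    provenance: dict = field(default_factory=dict)

    @property
    def X(self) -> np.ndarray:
        return self.frame[self.feature_names].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray | None:
        if LABEL_COLUMN in self.frame.columns:
            return self.frame[LABEL_COLUMN].to_numpy(dtype=int)
        return None

    def subset(self, names: list[str]) -> "FeatureTable":
        keep = [c for c in self.frame.columns if c not in self.feature_names or c in names]
        return FeatureTable(self.frame[keep].copy(), list(names), dict(self.provenance))

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "FeatureTable":
        frame = pd.read_csv(path, sep="\t")
        names = [c for c in frame.columns if c not in KEY_COLUMNS + [LABEL_COLUMN]]
        return cls(frame, names)


# ---------------------------------------------------------------------------
# ASA-derived scalar blocks


def asa_block(mono: ResidueAsa, comp: ResidueAsa) -> list[float]:
    """The 12 ASA features: bound values, change on binding, relative change.

    Relative change is defined as 0 when the monomer value is 0 (a residue
    buried even in the monomer carries no relative-change signal).  RSA
    entries are NaN when the residue type has no reference value.
    """

    def _pairs():
        yield mono.sidechain_asa, comp.sidechain_asa
        yield mono.sidechain_rsa, comp.sidechain_rsa
        yield mono.total_asa, comp.total_asa
        yield mono.total_rsa, comp.total_rsa

    bound, change, relchange = [], [], []
    for m, c in _pairs():
        if m is None or c is None:
            bound.append(math.nan)
            change.append(math.nan)
            relchange.append(math.nan)
            continue
        bound.append(c)
        delta = m - c
        change.append(delta)
        relchange.append(delta / m if m != 0 else 0.0)
    return bound + change + relchange


def inp1(
    target_mono: float,
    target_comp: float,
    neighbor_mono: list[float],
    neighbor_comp: list[float],
) -> float:
    """Ratio of target to neighbor-mean ASA, monomer minus complex.

    ``target_mono / mean(neighbor_mono) - target_comp / mean(neighbor_comp)``.
    Conventions: no neighbors -> 0; a zero neighbor mean with nonzero
    numerator -> that term contributes 0 (value stays bounded).
    """
    if len(neighbor_mono) != len(neighbor_comp):
        raise ValueError("neighbor lists must have equal length")
    n = len(neighbor_mono)
    if n == 0:
        return 0.0

    def term(target, vals):
        mean = float(np.mean(vals))
        if mean == 0.0:
            return 0.0
        return target / mean

    return term(target_mono, neighbor_mono) - term(target_comp, neighbor_comp)


def inp2(target_change: float, neighbor_changes: list[float]) -> float:
    """Ratio of the target's binding-induced ASA change to the neighbor mean.

    Same degenerate-case conventions as :func:`inp1`.
    """
    n = len(neighbor_changes)
    if n == 0:
        return 0.0
    mean = float(np.mean(neighbor_changes))
    if mean == 0.0:
        return 0.0
    return target_change / mean


# ---------------------------------------------------------------------------
# Geometry


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees, IUPAC convention, in (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang == -180.0 else ang


def psi_angle(residue, next_residue) -> float | None:
    """Backbone psi torsion N(i)-CA(i)-C(i)-N(i+1); None when undefined."""
    if residue is None or next_residue is None:
        return None
    n, ca, c = residue.atom("N"), residue.atom("CA"), residue.atom("C")
    n_next = next_residue.atom("N")
    if any(a is None for a in (n, ca, c, n_next)):
        return None
    return dihedral(n.coordinates, ca.coordinates, c.coordinates, n_next.coordinates)


def eigenvector_centrality(
    interface: InterfaceSet, model: StructureModel, cutoff: float = 7.0
) -> dict:
    """Principal-eigenvector centrality on the interface contact graph.

    Nodes are interface residues; an edge joins two residues whose Calpha
    atoms lie within ``cutoff``.  Per connected component the adjacency
    principal eigenvector is normalized to max 1; isolated nodes score 0.
    """
    ids = [rid for rid in interface.residue_ids if model.residue(rid).ca is not None]
    out = {rid: 0.0 for rid in interface.residue_ids}
    if not ids:
        return out
    xyz = np.array([model.residue(rid).ca.coordinates for rid in ids])
    n = len(ids)
    adj = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(xyz[i] - xyz[j]) <= cutoff:
                adj[i, j] = adj[j, i] = 1.0

    from scipy.sparse.csgraph import connected_components

    ncomp, labels = connected_components(adj > 0, directed=False)
    for comp in range(ncomp):
        members = np.where(labels == comp)[0]
        if len(members) == 1:
            continue  # isolated node -> 0
        sub = adj[np.ix_(members, members)]
        vec = _principal_eigenvector(sub)
        vec = vec / vec.max()
        for k, m in enumerate(members):
            out[ids[m]] = float(vec[k])
    return out


def _principal_eigenvector(adj: np.ndarray, max_iter: int = 1000, tol: float = 1e-12) -> np.ndarray:
    # power iteration; Perron-Frobenius guarantees a nonnegative vector on a
    # connected component.  Falls back to dense eigendecomposition.
    n = adj.shape[0]
    v = np.ones(n) / math.sqrt(n)
    for _ in range(max_iter):
        w = adj @ v
        norm = np.linalg.norm(w)
        if norm == 0:
            break
        w /= norm
        if np.linalg.norm(w - v) < tol:
            return np.abs(w)
        v = w
    vals, vecs = np.linalg.eigh(adj)
    return np.abs(vecs[:, np.argmax(vals)])


_TETRAHEDRAL_OFF_ANGLE = 110.5  # deg, ideal N-CA-CB / C-CA-CB


def pseudo_cb(residue, length: float = 1.522) -> np.ndarray | None:
    """Cbeta position; the real atom when present, else an ideal tetrahedral
    construction from N, CA, C (used for glycine)."""
    cb = residue.atom("CB")
    if cb is not None:
        return cb.coordinates
    n, ca, c = residue.atom("N"), residue.atom("CA"), residue.atom("C")
    if any(a is None for a in (n, ca, c)):
        return None
    v1 = n.coordinates - ca.coordinates
    v2 = c.coordinates - ca.coordinates
    v1 /= np.linalg.norm(v1)
    v2 /= np.linalg.norm(v2)
    bis = v1 + v2
    bis /= np.linalg.norm(bis)
    perp = np.cross(v2, v1)
    perp /= np.linalg.norm(perp)
    # choose in-plane/out-of-plane mix so the CB-CA-N angle is ideal
    cos_target = math.cos(math.radians(_TETRAHEDRAL_OFF_ANGLE))
    denom = float(np.dot(bis, v1))
    alpha = -cos_target / denom if denom != 0 else 0.0
    alpha = min(1.0, max(-1.0, alpha))
    beta = math.sqrt(max(0.0, 1.0 - alpha * alpha))
    direction = -alpha * bis + beta * perp
    direction /= np.linalg.norm(direction)
    return ca.coordinates + length * direction


def half_sphere_contact_numbers(
    residue, model: StructureModel, radius: float = 13.0
) -> tuple[int, int, int] | None:
    """Counts of other residues' Calpha atoms within ``radius``, split by the
    hemisphere defined by the Calpha->Cbeta vector; returns
    ``(up, down, total)`` or None when Cbeta cannot be placed."""
    ca = residue.ca
    if ca is None:
        return None
    cb = pseudo_cb(residue)
    if cb is None:
        return None
    axis = cb - ca.coordinates
    norm = np.linalg.norm(axis)
    if norm == 0:
        return None
    axis /= norm
    up = down = 0
    for other in model.protein_residues():
        if other is residue:
            continue
        oca = other.ca
        if oca is None:
            continue
        d = oca.coordinates - ca.coordinates
        if np.linalg.norm(d) <= radius:
            if np.dot(d, axis) >= 0:
                up += 1
            else:
                down += 1
    return up, down, up + down


# ---------------------------------------------------------------------------
# Hydrogen bonds


def _donor_atoms(residue):
    out = []
    if residue.kind == "protein" and residue.name != "PRO":
        n = residue.atom("N")
        if n is not None:
            out.append(n)
    for name in HBOND_DONORS.get(residue.name, ()):
        a = residue.atom(name)
        if a is not None:
            out.append(a)
    return out


def _acceptor_atoms(residue):
    out = []
    if residue.kind == "protein":
        for name in ("O", "OXT"):
            a = residue.atom(name)
            if a is not None:
                out.append(a)
    for name in HBOND_ACCEPTORS.get(residue.name, ()):
        a = residue.atom(name)
        if a is not None:
            out.append(a)
    return out


def _attached_hydrogens(residue, donor):
    out = []
    for a in residue.atoms:
        if a.is_hydrogen and np.linalg.norm(a.coordinates - donor.coordinates) <= 1.3:
            out.append(a)
    return out


def hbond_donor_count(
    residue,
    model: StructureModel,
    da_cutoff: float = 3.9,
    ha_cutoff: float = 2.5,
    angle_min: float = 90.0,
) -> int:
    """Hydrogen bonds donated by ``residue`` in the bound complex.

    A donor-acceptor pair counts when the heavy-atom distance is within
    ``da_cutoff``; when the donor hydrogen is present in the file the
    H..acceptor distance and D-H..A angle must also pass.
    """
    count = 0
    donors = _donor_atoms(residue)
    if not donors:
        return 0
    for other in model.residues:
        if other is residue:
            continue
        acceptors = _acceptor_atoms(other)
        for d in donors:
            hydrogens = _attached_hydrogens(residue, d)
            for a in acceptors:
                dist = np.linalg.norm(d.coordinates - a.coordinates)
                if dist > da_cutoff:
                    continue
                if hydrogens:
                    ok = False
                    for h in hydrogens:
                        ha = np.linalg.norm(h.coordinates - a.coordinates)
                        if ha > ha_cutoff:
                            continue
                        v1 = d.coordinates - h.coordinates
                        v2 = a.coordinates - h.coordinates
                        cosang = np.dot(v1, v2) / (
                            np.linalg.norm(v1) * np.linalg.norm(v2)
                        )
                        ang = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
                        if ang >= angle_min:
                            ok = True
                            break
                    if not ok:
                        continue
                count += 1
    return count


# ---------------------------------------------------------------------------
# Assembly


def _variant_values(ra: ResidueAsa) -> list[float]:
    # order: sASA, sRSA, tASA, tRSA
    return [
        ra.sidechain_asa,
        math.nan if ra.sidechain_rsa is None else ra.sidechain_rsa,
        ra.total_asa,
        math.nan if ra.total_rsa is None else ra.total_rsa,
    ]


def featurize(
    model: StructureModel,
    interface: InterfaceSet | None = None,
    params: FeatureParams | None = None,
    pdb_id: str = "",
) -> FeatureTable:
    """Compute one 24-feature row per interface residue.

    Undefined entries (chain-terminal psi, unplaceable Cbeta, missing RSA
    references) are NaN; impute before modeling with :func:`impute_median`.
    """
    params = params or FeatureParams()
    atom_mono, res_mono = compute_view_asa(model, "unbound", params.sasa)
    atom_comp, res_comp = compute_view_asa(model, "bound", params.sasa)

    if interface is None:
        mono_totals = {rid: ra.total_asa for rid, ra in res_mono.items()}
        comp_totals = {rid: ra.total_asa for rid, ra in res_comp.items()}

        def sasa_fn(_model, view):
            return mono_totals if view == "unbound" else comp_totals

        interface = find_interface_residues(
            model,
            sasa_fn=sasa_fn,
            threshold=params.interface_threshold,
            neighbor_cutoff=params.neighbor_cutoff,
            mode=params.interface_mode,
        )
    if len(interface) == 0:
        raise ValueError("empty interface set; nothing to featurize")

    eig = eigenvector_centrality(interface, model, params.eig_cutoff)

    rows = []
    for rid in interface.residue_ids:
        res = model.residue(rid)
        mono = res_mono[rid]
        comp = res_comp[rid]
        values = asa_block(mono, comp)

        values.append(eig[rid])

        psi = psi_angle(res, model.next_residue_in_chain(res))
        values.append(math.nan if psi is None else psi)

        hse = half_sphere_contact_numbers(res, model, params.hse_radius)
        if hse is None:
            values.append(math.nan)
        else:
            idx = {"up": 0, "down": 1, "total": 2}[params.hbcn_variant]
            values.append(float(hse[idx]))

        values.append(
            float(
                hbond_donor_count(
                    res,
                    model,
                    params.hbond_da_cutoff,
                    params.hbond_ha_cutoff,
                    params.hbond_angle_min,
                )
            )
        )

        neigh = interface.neighbors.get(rid, [])
        n_mono = [_variant_values(res_mono[j]) for j in neigh]
        n_comp = [_variant_values(res_comp[j]) for j in neigh]
        t_mono = _variant_values(mono)
        t_comp = _variant_values(comp)
        for v in range(4):
            values.append(
                inp1(
                    t_mono[v],
                    t_comp[v],
                    [nm[v] for nm in n_mono],
                    [nc[v] for nc in n_comp],
                )
            )
        for v in range(4):
            t_change = (
                t_mono[v] - t_comp[v]
                if not (math.isnan(t_mono[v]) or math.isnan(t_comp[v]))
                else math.nan
            )
            n_change = [
                nm[v] - nc[v] for nm, nc in zip(n_mono, n_comp)
            ]
            values.append(inp2(t_change, n_change))

        rows.append(
            dict(
                zip(
                    KEY_COLUMNS + FEATURE_NAMES,
                    [pdb_id, rid[0], rid[1], rid[2], res.name] + values,
                )
            )
        )

    frame = pd.DataFrame(rows, columns=KEY_COLUMNS + FEATURE_NAMES)
    return FeatureTable(
        frame,
        list(FEATURE_NAMES),
        provenance={
            "pdb_id": pdb_id,
            "interface_mode": params.interface_mode,
            "neighbor_cutoff": params.neighbor_cutoff,
            "n_interface": len(interface),
        },
    )


def impute_median(
    table: FeatureTable, medians: dict[str, float] | None = None
) -> tuple[FeatureTable, dict[str, float]]:
    """Median-impute NaN feature entries.

    When ``medians`` is None they are computed from the table (training
    path); pass a stored vector at prediction time.  A column that is
    entirely NaN imputes to 0.
    """
    frame = table.frame.copy()
    if medians is None:
        medians = {}
        for name in table.feature_names:
            med = frame[name].median()
            medians[name] = 0.0 if pd.isna(med) else float(med)
    for name in table.feature_names:
        frame[name] = frame[name].fillna(medians.get(name, 0.0))
    return FeatureTable(frame, list(table.feature_names), dict(table.provenance)), medians
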