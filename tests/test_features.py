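import math

import numpy as np
import pytest

from dnahotspot.features import (
    FEATURE_NAMES,
    FeatureParams,
    asa_block,
    dihedral,
    eigenvector_centrality,
    featurize,
    half_sphere_contact_numbers,
    hbond_donor_count,
    impute_median,
    inp1,
    inp2,
    pseudo_cb,
    psi_angle,
)
from dnahotspot.sasa import ResidueAsa
from dnahotspot.structure import Atom, InterfaceSet, Residue, StructureModel


# --------------------------------------------------------------------------- oracles

def oracle_inp1(tm, tc, nm, nc):
    return tm / (sum(nm) / len(nm)) - tc / (sum(nc) / len(nc))


def oracle_inp2(t, n):
    return t / (sum(n) / len(n))


def oracle_dihedral(p0, p1, p2, p3):
    """Independent formulation: arccos of plane normals, sign from triple product."""
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    cosang = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    ang = math.degrees(math.acos(np.clip(cosang, -1, 1)))
    if np.dot(np.cross(n1, n2), b2) > 0:
        ang = -ang
    return ang


# --------------------------------------------------------------------------- helpers

def _res(chain, num, name, atom_specs, kind="protein"):
    r = Residue(chain, num, "", name)
    base = abs(hash((chain, num))) % 1000 * 100
    for i, (aname, xyz) in enumerate(atom_specs):
        elem = "H" if aname.startswith("H") else aname[0]
        r.atoms.append(Atom(base + i + 1, aname, elem, (chain, num, ""), np.asarray(xyz, float)))
    r.kind = kind
    return r


def _model(residues, protein_chains=("A",), dna_chains=("B",)):
    m = StructureModel(residues)
    m.set_chain_kinds(list(protein_chains), list(dna_chains))
    return m


class TestAsaBlock:
    def _ra(self, s, t, rs=None, rt=None):
        return ResidueAsa(total_asa=t, sidechain_asa=s, total_rsa=rt, sidechain_rsa=rs)

    def test_direct_formula(self):
        mono = self._ra(s=50, t=100, rs=40, rt=80)
        comp = self._ra(s=20, t=40, rs=16, rt=32)
        vals = asa_block(mono, comp)
        named = dict(zip(FEATURE_NAMES[:12], vals))
        assert named["BtASA"] == 40
        assert named["CtASA"] == 60
        assert named["RtASA"] == pytest.approx(0.6)
        assert named["CsASA"] == 30
        assert named["RsRSA"] == pytest.approx(0.6)

    def test_identity_gives_zero_changes(self):
        ra = self._ra(s=30, t=70, rs=25, rt=55)
        vals = asa_block(ra, ra)
        assert all(v == 0 for v in vals[4:])

    def test_zero_mono_denominator_convention(self):
        mono = self._ra(s=0, t=0, rs=0, rt=0)
        comp = self._ra(s=0, t=0, rs=0, rt=0)
        vals = asa_block(mono, comp)
        assert all(v == 0 for v in vals[4:])

    def test_missing_rsa_propagates_nan(self):
        mono = self._ra(s=10, t=20)
        comp = self._ra(s=5, t=10)
        named = dict(zip(FEATURE_NAMES[:12], asa_block(mono, comp)))
        assert math.isnan(named["BtRSA"])
        assert named["CtASA"] == 10


class TestInp:
    def test_inp1_balanced_is_zero(self):
        assert inp1(40.0, 10.0, [40.0, 40.0], [10.0, 10.0]) == pytest.approx(0.0)

    def test_inp1_direct(self):
        assert inp1(80.0, 10.0, [40.0, 40.0], [10.0, 10.0]) == pytest.approx(1.0)

    def test_inp2_ratio_identity(self):
        assert inp2(30.0, [20.0, 30.0, 40.0]) == pytest.approx(1.0)

    def test_inp2_direct(self):
        assert inp2(60.0, [20.0, 30.0, 40.0]) == pytest.approx(2.0)

    def test_no_neighbors_convention(self):
        assert inp1(5.0, 3.0, [], []) == 0.0
        assert inp2(5.0, []) == 0.0

    def test_zero_mean_convention(self):
        assert inp1(5.0, 3.0, [0.0, 0.0], [1.0, 1.0]) == pytest.approx(-3.0)
        assert inp2(5.0, [0.0, 0.0]) == 0.0

    def test_inp1_matches_oracle_100_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 6))
            tm, tc = rng.uniform(1, 100, 2)
            nm = rng.uniform(1, 100, n)
            nc = rng.uniform(1, 100, n)
            assert inp1(tm, tc, list(nm), list(nc)) == pytest.approx(
                oracle_inp1(tm, tc, list(nm), list(nc)), rel=1e-12
            )

    def test_inp2_matches_oracle_100_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 6))
            t = float(rng.uniform(-50, 100))
            vals = rng.uniform(1, 100, n)
            assert inp2(t, list(vals)) == pytest.approx(oracle_inp2(t, list(vals)), rel=1e-12)

    def test_scale_invariance(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 6))
            tm, tc = rng.uniform(1, 100, 2)
            nm, nc = rng.uniform(1, 100, n), rng.uniform(1, 100, n)
            c = float(rng.uniform(0.1, 10))
            a = inp1(tm, tc, list(nm), list(nc))
            b = inp1(c * tm, c * tc, list(c * nm), list(c * nc))
            assert a == pytest.approx(b, rel=1e-9)
            assert inp2(tm, list(nm)) == pytest.approx(inp2(c * tm, list(c * nm)), rel=1e-9)


class TestPsi:
    def test_beta_strand_near_plus_135(self, toy_model):
        chain = toy_model.chains["A"]
        for res, nxt in zip(chain, chain[1:]):
            psi = psi_angle(res, nxt)
            assert psi == pytest.approx(135.0, abs=5.0)

    def test_planar_zero(self):
        p = [np.array([0.0, 1, 0]), np.array([0.0, 0, 0]), np.array([1.0, 0, 0]), np.array([1.0, 1, 0])]
        assert dihedral(*p) == pytest.approx(0.0, abs=1e-9)

    def test_mirror_flips_sign(self, rng):
        pts = rng.normal(size=(4, 3))
        a = dihedral(*pts)
        mirrored = pts * np.array([1, 1, -1])
        assert dihedral(*mirrored) == pytest.approx(-a, abs=1e-9)

    def test_matches_oracle_100_instances(self, rng):
        from test_features import oracle_dihedral

        for _ in range(100):
            pts = rng.normal(size=(4, 3)) * 3
            got = dihedral(*pts)
            want = oracle_dihedral(*pts)
            assert got == pytest.approx(want, abs=1e-6)

    def test_terminal_residue_masked(self, toy_model):
        last = toy_model.chains["A"][-1]
        assert psi_angle(last, None) is None


def _interface_from_cas(positions):
    residues = []
    ids = []
    for i, xyz in enumerate(positions, start=1):
        r = _res("A", i, "ALA", [("CA", xyz)])
        residues.append(r)
        ids.append(("A", i, ""))
    dna = _res("B", 1, "DA", [("P", [0, 50, 0])], kind="DNA")
    model = _model(residues + [dna])
    iface = InterfaceSet(residue_ids=ids, neighbors={})
    return model, iface


class TestEigenvectorCentrality:
    def test_path_graph(self):
        model, iface = _interface_from_cas([[0, 0, 0], [6, 0, 0], [12, 0, 0]])
        eig = eigenvector_centrality(iface, model, cutoff=7.0)
        vals = [eig[rid] for rid in iface.residue_ids]
        assert vals == pytest.approx([math.sqrt(0.5), 1.0, math.sqrt(0.5)], abs=1e-6)

    def test_complete_graph(self):
        model, iface = _interface_from_cas([[0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3]])
        eig = eigenvector_centrality(iface, model, cutoff=7.0)
        assert all(v == pytest.approx(1.0, abs=1e-9) for v in eig.values())

    def test_isolated_node_zero(self):
        model, iface = _interface_from_cas([[0, 0, 0], [3, 0, 0], [40, 0, 0]])
        eig = eigenvector_centrality(iface, model, cutoff=7.0)
        assert eig[("A", 3, "")] == 0.0

    def test_matches_dense_eigendecomposition_oracle(self, rng):
        positions = rng.uniform(0, 14, size=(8, 3))
        model, iface = _interface_from_cas(positions)
        eig = eigenvector_centrality(iface, model, cutoff=7.0)

        # oracle: dense adjacency + numpy eigh, per connected component
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(8))
        for i in range(8):
            for j in range(i + 1, 8):
                if np.linalg.norm(positions[i] - positions[j]) <= 7.0:
                    g.add_edge(i, j)
        expected = {i: 0.0 for i in range(8)}
        for comp in nx.connected_components(g):
            comp = sorted(comp)
            if len(comp) == 1:
                continue
            sub = np.zeros((len(comp), len(comp)))
            for a in range(len(comp)):
                for b in range(len(comp)):
                    if g.has_edge(comp[a], comp[b]):
                        sub[a, b] = 1
            w, v = np.linalg.eigh(sub)
            vec = np.abs(v[:, np.argmax(w)])
            vec /= vec.max()
            for k, node in enumerate(comp):
                expected[node] = vec[k]
        for i, rid in enumerate(iface.residue_ids):
            assert eig[rid] == pytest.approx(expected[i], abs=1e-6)

    def test_values_in_unit_interval_with_max_one(self, rng):
        positions = rng.uniform(0, 20, size=(10, 3))
        model, iface = _interface_from_cas(positions)
        eig = eigenvector_centrality(iface, model, cutoff=7.0)
        vals = np.array(list(eig.values()))
        assert np.all(vals >= 0) and np.all(vals <= 1 + 1e-12)
        if np.any(vals > 0):
            assert np.isclose(vals.max(), 1.0)


class TestHalfSphere:
    def _residue_with_cb(self, num, ca, cb, chain="A"):
        return _res(chain, num, "ALA", [("CA", ca), ("CB", cb)])

    def test_isolated_residue(self):
        r = self._residue_with_cb(1, [0, 0, 0], [1.5, 0, 0])
        dna = _res("B", 1, "DA", [("P", [0, 50, 0])], kind="DNA")
        model = _model([r, dna])
        assert half_sphere_contact_numbers(r, model) == (0, 0, 0)

    def test_contact_along_cb_axis(self):
        r = self._residue_with_cb(1, [0, 0, 0], [1.5, 0, 0])
        other = self._residue_with_cb(2, [5.0, 0, 0], [6.5, 0, 0])
        dna = _res("B", 1, "DA", [("P", [0, 50, 0])], kind="DNA")
        model = _model([r, other, dna])
        assert half_sphere_contact_numbers(r, model) == (1, 0, 1)

    def test_matches_brute_force_oracle(self, rng):
        residues = []
        for i in range(12):
            ca = rng.uniform(0, 18, 3)
            cb = ca + rng.normal(size=3) * 0.8
            residues.append(self._residue_with_cb(i + 1, ca, cb))
        dna = _res("B", 1, "DA", [("P", [0, 60, 0])], kind="DNA")
        model = _model(residues + [dna])
        radius = 13.0
        for r in residues:
            got = half_sphere_contact_numbers(r, model, radius)
            ca = r.atom("CA").coordinates
            axis = r.atom("CB").coordinates - ca
            axis = axis / np.linalg.norm(axis)
            up = down = 0
            for other in residues:
                if other is r:
                    continue
                d = other.atom("CA").coordinates - ca
                if np.linalg.norm(d) <= radius:
                    if np.dot(d, axis) >= 0:
                        up += 1
                    else:
                        down += 1
            assert got == (up, down, up + down)

    def test_gly_pseudo_cb_geometry(self):
        gly = _res(
            "A", 1, "GLY",
            [("N", [1.46, 0, 0]), ("CA", [0, 0, 0]), ("C", [-0.55, 1.42, 0])],
        )
        cb = pseudo_cb(gly)
        ca = gly.atom("CA").coordinates
        assert np.linalg.norm(cb - ca) == pytest.approx(1.522, abs=1e-6)
        for aname in ("N", "C"):
            v1 = gly.atom(aname).coordinates - ca
            v2 = cb - ca
            ang = math.degrees(
                math.acos(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
            )
            assert ang == pytest.approx(110.5, abs=2.0)

    def test_missing_backbone_masked(self):
        r = _res("A", 1, "GLY", [("CA", [0, 0, 0])])
        dna = _res("B", 1, "DA", [("P", [0, 50, 0])], kind="DNA")
        model = _model([r, dna])
        assert half_sphere_contact_numbers(r, model) is None


class TestHbond:
    def _ser(self, og_xyz):
        return _res(
            "A", 1, "SER",
            [("N", [-3, 0, 0]), ("CA", [-2, 0, 0]), ("C", [-1.0, 0.9, 0]),
             ("O", [-1.0, 2.1, 0]), ("CB", [-2, 1.5, 0]), ("OG", og_xyz)],
        )

    def _phosphate(self, o1p_xyz):
        return _res("B", 1, "DA", [("P", [6.0, 0, 0]), ("O1P", o1p_xyz)], kind="DNA")

    def test_ser_og_to_phosphate_at_3A(self):
        ser = self._ser([0.0, 0, 0])
        dna = self._phosphate([3.0, 0, 0])
        model = _model([ser, dna])
        assert hbond_donor_count(ser, model) == 1

    def test_beyond_cutoff_is_zero(self):
        ser = self._ser([0.0, 0, 0])
        dna = self._phosphate([4.5, 0, 0])
        model = _model([ser, dna])
        assert hbond_donor_count(ser, model) == 0

    def test_hydrogen_criteria_applied_when_present(self):
        ser = self._ser([0.0, 0, 0])
        # HG pointing at the acceptor: D-H...A near-linear, H..A = 2.0
        ser.atoms.append(Atom(9999, "HG", "H", ("A", 1, ""), np.array([1.0, 0.0, 0.0])))
        dna = self._phosphate([3.0, 0, 0])
        model = _model([ser, dna])
        assert hbond_donor_count(ser, model) == 1
        # HG pointing away: angle fails
        ser.atoms[-1].coordinates = np.array([-1.0, 0.0, 0.0])
        assert hbond_donor_count(ser, model) == 0

    def test_matches_exhaustive_enumeration(self, rng):
        from dnahotspot._tables import HBOND_ACCEPTORS, HBOND_DONORS

        for trial in range(20):
            ser = self._ser(rng.uniform(-1, 1, 3))
            acceptors = _res(
                "B", 1, "DT",
                [("P", rng.uniform(0, 6, 3)), ("O1P", rng.uniform(0, 6, 3)),
                 ("O2P", rng.uniform(0, 6, 3)), ("O4", rng.uniform(0, 6, 3))],
                kind="DNA",
            )
            model = _model([ser, acceptors])
            got = hbond_donor_count(ser, model)

            donor_atoms = [ser.atom("N"), ser.atom("OG")]
            acc_names = HBOND_ACCEPTORS["DT"]
            count = 0
            for d in donor_atoms:
                for a in acceptors.atoms:
                    if a.name in acc_names:
                        if np.linalg.norm(d.coordinates - a.coordinates) <= 3.9:
                            count += 1
            assert got == count

    def test_proline_backbone_not_donor(self):
        pro = _res("A", 1, "PRO", [("N", [0, 0, 0]), ("CA", [1.4, 0, 0])])
        dna = self._phosphate([0.0, 3.0, 0])
        model = _model([pro, dna])
        assert hbond_donor_count(pro, model) == 0


class TestFeaturize:
    def test_shape_and_imputation(self, toy_model):
        table = featurize(toy_model)
        assert table.feature_names == FEATURE_NAMES
        assert list(table.frame.columns[:5]) == ["pdb_id", "chain", "resnum", "icode", "resname"]
        imputed, medians = impute_median(table)
        assert not imputed.frame[FEATURE_NAMES].isna().any().any()
        assert set(medians) == set(FEATURE_NAMES)

    def test_no_neighbor_inp_convention(self, toy_model):
        # restrict the interface to a single residue -> n = 0 for every INP
        from dnahotspot.structure import find_interface_residues

        iface = find_interface_residues(toy_model)
        solo = InterfaceSet(residue_ids=iface.residue_ids[:1], neighbors={iface.residue_ids[0]: []})
        table = featurize(toy_model, interface=solo)
        row = table.frame.iloc[0]
        for col in FEATURE_NAMES[16:]:
            assert row[col] == 0.0

    def test_composition_against_per_feature_oracles(self, toy_model):
        from dnahotspot.sasa import compute_view_asa
        from dnahotspot.structure import find_interface_residues

        table = featurize(toy_model)
        _, res_mono = compute_view_asa(toy_model, "unbound")
        _, res_comp = compute_view_asa(toy_model, "bound")
        iface = find_interface_residues(toy_model)
        eig = eigenvector_centrality(iface, toy_model, 7.0)

        for _, row in table.frame.iterrows():
            rid = (row["chain"], int(row["resnum"]), "")
            res = toy_model.residue(rid)
            mono, comp = res_mono[rid], res_comp[rid]
            assert row["BtASA"] == pytest.approx(comp.total_asa)
            assert row["CtASA"] == pytest.approx(mono.total_asa - comp.total_asa)
            assert row["Eig"] == pytest.approx(eig[rid])
            assert row["DN"] == hbond_donor_count(res, toy_model)
            hse = half_sphere_contact_numbers(res, toy_model)
            assert row["HbCN"] == hse[2]
            neigh = iface.neighbors[rid]
            want = inp1(
                mono.total_asa,
                comp.total_asa,
                [res_mono[j].total_asa for j in neigh],
                [res_comp[j].total_asa for j in neigh],
            )
            assert row["INP1-tASA"] == pytest.approx(want)
            want2 = inp2(
                mono.total_asa - comp.total_asa,
                [res_mono[j].total_asa - res_comp[j].total_asa for j in neigh],
            )
            assert row["INP2-CtASA"] == pytest.approx(want2)

    def test_geometric_features_rigid_motion_invariant(self, toy_pdb_text):
        from scipy.spatial.transform import Rotation

        from dnahotspot.structure import read_pdb

        m1 = read_pdb(toy_pdb_text)
        m2 = read_pdb(toy_pdb_text)
        rot = Rotation.random(random_state=3).as_matrix()
        shift = np.array([5.0, -7.0, 11.0])
        for res in m2.residues:
            for a in res.atoms:
                a.coordinates = rot @ a.coordinates + shift
        t1 = featurize(m1)
        t2 = featurize(m2)
        assert list(t1.frame["resnum"]) == list(t2.frame["resnum"])
        for col in ("Psi", "HbCN", "DN", "Eig"):
            np.testing.assert_allclose(
                t1.frame[col].to_numpy(float), t2.frame[col].to_numpy(float), atol=1e-6
            )
        # lattice-based ASA features only approximately invariant
        for col in ("BtASA", "CtASA"):
            np.testing.assert_allclose(
                t1.frame[col].to_numpy(float), t2.frame[col].to_numpy(float), atol=3.0
            )

    def test_empty_interface_raises(self, far_model):
        with pytest.raises(ValueError, match="empty interface"):
            featurize(far_model)
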