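import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hintmaps as hm
from hintmaps.conformation import (
    chess_square, chi1_parse, assign_bin, compute_dihedrals,
    align_to_canonical_frame, frame_from_coords, DihedralSet, DihedralError,
)
from hintmaps._geometry import dihedral, DegenerateGeometryError


def oracle_dihedral(p0, p1, p2, p3):
    """Independent torsion oracle: plane-normal arccos with explicit sign."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1 /= np.linalg.norm(n1)
    n2 /= np.linalg.norm(n2)
    cosang = np.clip(n1 @ n2, -1.0, 1.0)
    ang = np.degrees(np.arccos(cosang))
    if np.cross(n1, n2) @ b2 < 0:
        ang = -ang
    return ang


class TestDihedral:
    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            pts = rng.normal(0, 5, (4, 3))
            try:
                expected = oracle_dihedral(*pts)
            except FloatingPointError:
                continue
            got = dihedral(*pts)
            diff = abs((got - expected + 180) % 360 - 180)
            assert diff < 1e-6

    def test_planar_cis_trans(self):
        a, b, c = [0, 1, 0], [0, 0, 0], [1, 0, 0]
        assert dihedral(a, b, c, [1, 1, 0]) == pytest.approx(0.0, abs=1e-9)
        assert abs(dihedral(a, b, c, [1, -1, 0])) == pytest.approx(180.0, abs=1e-9)

    def test_collinear_raises(self):
        with pytest.raises(DegenerateGeometryError):
            dihedral([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])

    def test_helix_fixture_angles(self, ala_helix):
        cands = hm.extract_candidates(ala_helix, {"ALA"})
        d = compute_dihedrals(cands[3], *ala_helix.flanking(cands[3]))
        assert d.phi == pytest.approx(-63.0, abs=0.01)
        assert d.psi == pytest.approx(-43.0, abs=0.01)

    def test_missing_atom_named(self, ala_helix):
        cands = hm.extract_candidates(ala_helix, {"ALA"})
        res = cands[0]
        mask = np.ones(len(ala_helix), dtype=bool)
        mask[res.atom_index("C")] = False
        pruned = ala_helix.subset(mask)
        pruned_res = pruned.residue_by_key(*res.key)
        prev_r, next_r = pruned.flanking(pruned_res)
        with pytest.raises(DihedralError, match="C"):
            compute_dihedrals(pruned_res, prev_r, next_r)


class TestChessboard:
    def test_alpha_helix_anchor(self):
        """(−63, −43) is the α-helix motif square c5."""
        assert chess_square("ALA", -63.0, -43.0) == "c5"

    def test_beta_strand_anchor(self):
        assert chess_square("ALA", -110.0, 130.0) == "b1"

    def test_parse_boundaries(self):
        assert chi1_parse("ILE", 240.0) == ".300"
        assert chi1_parse("ILE", 239.999) == ".180"
        assert chi1_parse("ILE", 0.0) == ".60"
        assert chi1_parse("ILE", 119.999) == ".60"
        assert chi1_parse("LEU", 120.0) == ".180"
        assert chi1_parse("PRO", 330.0) == ".30m"
        assert chi1_parse("PRO", 30.0) == ".30p"
        assert chi1_parse("PRO", 180.0) == ".30m"
        assert chi1_parse("PRO", 179.999) == ".30p"

    def test_parse_labels_by_type(self):
        assert chi1_parse("ALA", None) == "none"
        assert chi1_parse("VAL", 155.0) == "none"
        key = assign_bin("ALA", DihedralSet(-63, -43, 180, None))
        assert key.label == "c5"
        key = assign_bin("ILE", DihedralSet(-63, -43, 180, 250.0))
        assert key.label == "c5.300"

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(phi=st.floats(-180, 180), psi=st.floats(-180, 180))
    def test_every_angle_maps_to_one_square(self, phi, psi):
        sq = chess_square("ALA", phi, psi)
        assert sq[0] in "abcdefgh" and sq[1] in "12345678"

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(phi=st.floats(-500, 500), psi=st.floats(-500, 500),
           kx=st.integers(-2, 2), ky=st.integers(-2, 2))
    def test_periodicity(self, phi, psi, kx, ky):
        assert chess_square("ALA", phi, psi) == \
            chess_square("ALA", phi + 360 * kx, psi + 360 * ky)

    def test_squares_partition_the_torus(self):
        """Each square covers exactly 1/64 of a uniform angle lattice."""
        counts = {}
        for phi in np.arange(-177.5, 180, 5.0):
            for psi in np.arange(-177.5, 180, 5.0):
                counts[chess_square("VAL", phi, psi)] = \
                    counts.get(chess_square("VAL", phi, psi), 0) + 1
        assert len(counts) == 64
        # 72x72 lattice, 45°/5° = 9 points per cell edge
        assert set(counts.values()) == {81}

    def test_proline_shift_differs(self):
        assert chess_square("PRO", -63.0, -43.0) != \
            chess_square("ALA", -63.0, -43.0) or \
            hm.GRID_SHIFTS["PRO"] != hm.GRID_SHIFTS["ALA"]


class TestCanonicalFrame:
    def test_postconditions(self, ala_helix):
        res = hm.extract_candidates(ala_helix, {"ALA"})[0]
        frame = align_to_canonical_frame(res)
        assert np.linalg.norm(frame.apply(res.coord("CA"))) < 1e-9
        cb = frame.apply(res.coord("CB"))
        assert abs(cb[0]) < 1e-6 and abs(cb[1]) < 1e-6 and cb[2] > 0
        ha = frame.apply(res.coord("HA"))
        assert abs(ha[0]) < 1e-6 and ha[1] > 0
        assert np.linalg.det(frame.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_rigidity_preserves_distances(self, ala_helix):
        res = hm.extract_candidates(ala_helix, {"ALA"})[1]
        frame = align_to_canonical_frame(res)
        before = res.coords
        after = frame.apply(before)
        d0 = np.linalg.norm(before[:, None] - before[None], axis=-1)
        d1 = np.linalg.norm(after[:, None] - after[None], axis=-1)
        np.testing.assert_allclose(d0, d1, atol=1e-9)
        assert np.linalg.norm(after[list(res.atom_names).index("CB")]) == \
            pytest.approx(np.linalg.norm(res.coord("CB") - res.coord("CA")), abs=1e-9)

    def test_canonical_pose_is_identity(self):
        ca = np.zeros(3)
        cb = np.array([0.0, 0.0, 1.53])
        ha = np.array([0.0, 0.95, -0.35])
        frame = frame_from_coords(ca, cb, ha)
        np.testing.assert_allclose(frame.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(frame.translation, 0.0, atol=1e-9)

    def test_rigid_motion_round_trip(self):
        """Frame recovered after a random rigid motion composes to identity."""
        rng = np.random.default_rng(11)
        ca, cb, ha = rng.normal(0, 2, (3, 3))
        cb = ca + 1.5 * (cb - ca) / np.linalg.norm(cb - ca)
        ha = ca + 1.1 * (ha - ca) / np.linalg.norm(ha - ca)
        f0 = frame_from_coords(ca, cb, ha)
        # random rotation + translation
        q = rng.normal(0, 1, (3, 3))
        u, _, vt = np.linalg.svd(q)
        rot = u @ vt
        if np.linalg.det(rot) < 0:
            rot[:, 0] *= -1
        t = rng.normal(0, 10, 3)
        moved = [rot @ p + t for p in (ca, cb, ha)]
        f1 = frame_from_coords(*moved)
        # both frames map their pose to the same canonical coordinates
        for p, pm in zip((ca, cb, ha), moved):
            np.testing.assert_allclose(f0.apply(p), f1.apply(pm), atol=1e-6)

    def test_degenerate_ca_cb_raises(self):
        with pytest.raises(DegenerateGeometryError):
            frame_from_coords(np.zeros(3), np.array([0.1, 0, 0]),
                              np.array([0, 1, 0]))
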