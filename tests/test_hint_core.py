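import numpy as np
import pytest

import hintmaps as hm
from hintmaps.hint_core import (
    HintAtomParams, PolarClass, InteractionClass, ParameterTable,
    score_pair, classify_interaction, environment_scores, lipid_score_ratio,
    resolve_T,
)
from conftest import make_model, atom

HPHOB = HintAtomParams(0.8, 20.0, PolarClass.HYDROPHOBIC)
HPHOB2 = HintAtomParams(0.23, 15.0, PolarClass.HYDROPHOBIC)
ACID = HintAtomParams(-1.0, 18.0, PolarClass.ACID)
BASE = HintAtomParams(-1.2, 16.0, PolarClass.BASE)


class TestScorePair:
    def test_zero_T_beyond_contact_is_zero(self):
        s = score_pair(HPHOB, HPHOB, 5.0, T=0)
        assert s.b == 0.0

    def test_hydrophobic_pair_favorable(self):
        s = score_pair(HPHOB, HPHOB2, 4.0)
        assert s.b > 0
        assert s.interaction_class is InteractionClass.FAVORABLE_HYDROPHOBIC

    def test_hydrophobic_polar_unfavorable(self):
        s = score_pair(HPHOB, BASE, 4.0)
        assert s.b < 0
        assert s.interaction_class is InteractionClass.UNFAVORABLE_HYDROPHOBIC

    def test_acid_base_favorable_polar(self):
        s = score_pair(ACID, BASE, 4.0)
        assert s.b > 0
        assert s.interaction_class is InteractionClass.FAVORABLE_POLAR

    def test_like_polar_unfavorable(self):
        for p in (ACID, BASE):
            s = score_pair(p, p, 4.0)
            assert s.b < 0
            assert s.interaction_class is InteractionClass.UNFAVORABLE_POLAR

    def test_exponential_distance_ratio(self):
        """Beyond the LJ contact the score decays as e^(−r): unit Å ratio."""
        b3 = score_pair(HPHOB, HPHOB, 4.0).b
        b4 = score_pair(HPHOB, HPHOB, 5.0).b
        assert b4 / b3 == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            r = rng.uniform(1.0, 8.0)
            assert score_pair(HPHOB, ACID, r).b == \
                pytest.approx(score_pair(ACID, HPHOB, r).b, rel=1e-12)

    def test_monotone_decay_beyond_contact(self):
        rs = np.linspace(3.5, 10.0, 30)
        bs = [abs(score_pair(HPHOB, HPHOB, r).b) for r in rs]
        assert all(b1 > b2 for b1, b2 in zip(bs, bs[1:]))

    def test_lj_penalty_below_contact(self):
        with_lj = score_pair(HPHOB, HPHOB, 1.5, lj_enabled=True)
        without = score_pair(HPHOB, HPHOB, 1.5, lj_enabled=False)
        assert with_lj.b < without.b

    def test_nonpositive_distance_raises(self):
        with pytest.raises(ValueError):
            score_pair(HPHOB, HPHOB, 0.0)

    def test_sign_class_invariant(self):
        s = score_pair(HPHOB, HPHOB, 5.0)
        assert (s.b > 0) == s.interaction_class.value.startswith("favorable")


class TestClassify:
    def test_both_hydrophobic(self):
        assert classify_interaction(HPHOB, HPHOB2) is \
            InteractionClass.FAVORABLE_HYDROPHOBIC

    def test_hydrophobic_vs_backbone_o(self):
        table = ParameterTable()
        a_cb, cls_cb = table.resolve("ALA", "CB")
        a_o, cls_o = table.resolve("ALA", "O")
        assert cls_cb is PolarClass.HYDROPHOBIC and a_cb > 0
        assert a_o < 0
        assert classify_interaction(cls_cb, cls_o) is \
            InteractionClass.UNFAVORABLE_HYDROPHOBIC

    def test_carboxylate_pair_unfavorable_polar(self):
        table = ParameterTable()
        _, cls1 = table.resolve("ASP", "OD1")
        assert classify_interaction(cls1, cls1) is \
            InteractionClass.UNFAVORABLE_POLAR

    def test_T_resolution(self):
        assert resolve_T(PolarClass.ACID, PolarClass.BASE) == 1
        assert resolve_T(PolarClass.ACID, PolarClass.ACID) == -1
        assert resolve_T(PolarClass.BASE, PolarClass.BASE) == -1
        assert resolve_T(PolarClass.HYDROPHOBIC, PolarClass.BASE) == 1


class TestParameterTable:
    def test_sign_convention_across_residues(self):
        table = ParameterTable()
        for res, name, positive in [
            ("ALA", "CB", True), ("LEU", "CD1", True), ("ILE", "CD1", True),
            ("ALA", "HB1", True), ("ALA", "O", False), ("ALA", "N", False),
            ("ALA", "H", False), ("SER", "OG", False), ("LYS", "NZ", False),
        ]:
            a, cls = table.resolve(res, name)
            assert (a > 0) == positive, (res, name, a)
            assert (cls is PolarClass.HYDROPHOBIC) == positive

    def test_complete_for_standard_residues(self):
        from hintmaps.structures_io import STANDARD_AA, _reference
        table = ParameterTable()
        for res in STANDARD_AA:
            ref = _reference(res)
            for n in ref.atom_name:
                a, cls = table.resolve(res, str(n))
                assert np.isfinite(a)

    def test_tsv_round_trip(self, tmp_path):
        table = ParameterTable()
        table.resolve("ALA", "CB")
        path = tmp_path / "params.tsv"
        table.save_tsv(path, residues=["ALA"])
        override = ParameterTable().load_tsv(path)
        assert override.resolve("ALA", "CB") == table.resolve("ALA", "CB")

    def test_lipid_entries(self):
        table = ParameterTable()
        a_tail, cls_tail = table.resolve("DPPC", "C5", "C", is_lipid=True)
        a_head, cls_head = table.resolve("DPPC", "O1", "O", is_lipid=True)
        assert a_tail > 0 and cls_tail is PolarClass.HYDROPHOBIC
        assert a_head < 0


class TestEnvironmentScores:
    def _ala_with_water(self, water_offset=3.0):
        """Protonated single-ALA-in-triplet plus one water O near CB."""
        model = hm.protonate(hm.build_peptide(
            hm.FixtureSpec(kind="helix", n_residues=3, sequence="ALA")))
        res = model.protein_residues()[1]
        w = res.coord("CB") + np.array([water_offset, 0.0, 0.0])
        water = atom(w, "O", res_name="HOH", res_id=99, chain="W", hetero=True)
        import biotite.structure as struc
        merged = model.atoms + struc.array([water])
        return hm.StructureModel(merged), res.key

    def test_hand_enumerated_water_pairs(self):
        model, key = self._ala_with_water(3.0)
        res = model.residue_by_key(*key)
        scores = environment_scores(res, model, cutoff=4.0, s_mode="unit")
        water_pairs = [(str(model.atoms.atom_name[s.target_index]))
                       for s in scores
                       if model.atoms.res_name[s.env_index] == "HOH"]
        # exactly the sidechain atoms within 4 Å of the water O
        side = res.sidechain_indices
        expect = [str(model.atoms.atom_name[i]) for i in side
                  if np.linalg.norm(model.atoms.coord[i]
                                    - model.atoms.coord[-1]) <= 4.0]
        assert sorted(water_pairs) == sorted(expect)
        assert "CB" in water_pairs

    def test_excludes_own_residue(self, ala_helix):
        res = hm.extract_candidates(ala_helix, {"ALA"})[0]
        scores = environment_scores(res, ala_helix, s_mode="unit")
        own = set(res.indices)
        assert all(s.env_index not in own for s in scores)
        assert all(s.target_index in own for s in scores)

    def test_lipid_toggle_noop_without_lipids(self, ala_helix):
        res = hm.extract_candidates(ala_helix, {"ALA"})[0]
        with_l = environment_scores(res, ala_helix, include_lipids=True,
                                    s_mode="unit")
        without = environment_scores(res, ala_helix, include_lipids=False,
                                     s_mode="unit")
        assert len(with_l) == len(without)
        np.testing.assert_allclose([s.b for s in with_l],
                                   [s.b for s in without])

    def test_class_partition_sums_to_total(self, ala_helix):
        res = hm.extract_candidates(ala_helix, {"ALA"})[2]
        scores = environment_scores(res, ala_helix, s_mode="unit")
        total = sum(s.b for s in scores)
        by_class = {}
        for s in scores:
            by_class[s.interaction_class] = by_class.get(s.interaction_class, 0) + s.b
        assert sum(by_class.values()) == pytest.approx(total, rel=1e-12)

    def test_lipid_ratio_bounds(self, membrane_prepared):
        model, _, _ = membrane_prepared
        res = hm.extract_candidates(model, {"LEU"})[0]
        scores = environment_scores(res, model, s_mode="unit")
        ratio = lipid_score_ratio(scores)
        assert 0.0 <= ratio <= 1.0

    def test_all_zero_constants_null_maps(self, ala_helix, identity_frame):
        """Zeroing every atom constant nulls scores and downstream maps."""
        class ZeroTable(ParameterTable):
            def resolve(self, *args, **kwargs):
                return 0.0, PolarClass.NEUTRAL

        res = hm.extract_candidates(ala_helix, {"ALA"})[0]
        scores = environment_scores(res, ala_helix, table=ZeroTable(),
                                    s_mode="unit", lj_enabled=False)
        assert all(s.b == 0.0 for s in scores)
        frame = hm.align_to_canonical_frame(res)
        maps = hm.compute_maps(scores, frame, hm.make_box("ALA"), ala_helix)
        assert all(np.all(g == 0) for g in maps.grids.values())
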