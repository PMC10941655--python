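import numpy as np
import pytest

import specswitch as sw
from specswitch.design import DesignError, N_CHI, RESIDUE_CLASS


class TestClassifyResidue:
    @pytest.mark.parametrize("aa,expected", [
        ("A", "hydrophobic"), ("L", "hydrophobic"), ("F", "hydrophobic"),
        ("W", "hydrophobic"), ("K", "positive"), ("R", "positive"),
        ("D", "negative"), ("E", "negative"), ("S", "polar_uncharged"),
        ("Q", "polar_uncharged"), ("G", "special"), ("P", "special"),
        ("C", "special"), ("H", "special"),
    ])
    def test_class_table(self, aa, expected):
        assert sw.classify_residue(aa).value == expected

    def test_every_standard_residue_has_exactly_one_class(self):
        assert set(RESIDUE_CLASS) == set("ACDEFGHIKLMNPQRSTVWY")

    def test_nonstandard_rejected(self):
        with pytest.raises(DesignError):
            sw.classify_residue("X")


class TestProposeMutation:
    def test_hydrophobic_goes_to_glutamine(self):
        p = sw.propose_mutation(775, "A")
        assert (p.mutant_aa, p.rule) == ("Q", "hydrophobic_to_gln")

    def test_lysine_enlarged_to_arginine(self):
        p = sw.propose_mutation(768, "K")
        assert (p.mutant_aa, p.rule) == ("R", "charge_size_up")

    def test_aspartate_enlarged_to_glutamate(self):
        p = sw.propose_mutation(5, "D")
        assert (p.mutant_aa, p.rule) == ("E", "charge_size_up")

    @pytest.mark.parametrize("aa", ["R", "E", "S", "T", "N", "Q", "G", "P", "C", "H"])
    def test_rule_less_residues_flagged_manual_with_wt_kept(self, aa):
        p = sw.propose_mutation(1, aa)
        assert p.rule == "flagged_manual"
        assert p.mutant_aa == aa

    def test_total_and_deterministic_over_all_standard_residues(self):
        for aa in "ACDEFGHIKLMNPQRSTVWY":
            first = sw.propose_mutation(10, aa)
            second = sw.propose_mutation(10, aa)
            assert (first.mutant_aa, first.rule) == (second.mutant_aa, second.rule)


class TestGrowSidechain:
    def test_glycine_yields_single_empty_set(self, helix10):
        assert sw.grow_sidechain(helix10.residues[3], "G") == [[]]

    def test_alanine_cb_matches_ideal_construction(self, helix10):
        res = helix10.residues[3]
        (atoms,) = sw.grow_sidechain(res, "A")
        assert [a.name for a in atoms] == ["CB"]
        ideal = sw.chem.build_cb(res.atom("N").coords, res.atom("CA").coords,
                                 res.atom("C").coords)
        assert np.allclose(atoms[0].coords, ideal)

    def test_glutamine_rotamer_count_and_bond_lengths(self, helix10):
        res = helix10.residues[3]
        rotamers = sw.grow_sidechain(res, "Q")
        assert len(rotamers) == len(sw.rotamer_chi_sets("Q")) == 27
        bonds = [("CA", "CB", 1.53), ("CB", "CG", 1.52), ("CG", "CD", 1.52),
                 ("CD", "OE1", 1.23), ("CD", "NE2", 1.33)]
        for atoms in rotamers:
            table = {a.name: a.coords for a in atoms}
            table["CA"] = res.atom("CA").coords
            for a, b, want in bonds:
                assert np.linalg.norm(table[a] - table[b]) == pytest.approx(want, abs=0.01)

    def test_rotamer_cap(self):
        # arginine has 4 chi angles; the library caps the varied ones at 3
        assert len(sw.rotamer_chi_sets("R")) == 27
        assert all(len(chis) == 4 for chis in sw.rotamer_chi_sets("R"))

    def test_all_buildable_residues_have_topology(self, helix10):
        res = helix10.residues[5]
        for aa in "ACDEFGHIKLMNPQRSTVWY":
            rotamers = sw.grow_sidechain(res, aa)
            assert len(rotamers) >= 1

    def test_missing_backbone_rejected(self):
        res = sw.Residue("A", 1, "ALA", [sw.Atom("CA", "C", [0, 0, 0])])
        with pytest.raises(DesignError, match="backbone"):
            sw.grow_sidechain(res, "Q")


class TestClashScore:
    def _model_with_partner_atom(self, offset):
        """Single focal residue + one partner atom at a chosen offset from CB."""
        chain = sw.make_helix(5, chain_id="A")
        cb = chain.residues[2].atom("CB").coords
        partner = sw.Chain("B", [sw.Residue("B", 1, "ALA",
                                            [sw.Atom("CB", "C", cb + offset)])])
        st = sw.Structure("toy", [chain, partner])
        return sw.ComplexModel("toy", st, {"A": "shared_subunit", "B": "partner_specific"})

    def test_distant_partner_scores_zero_for_every_rotamer(self, two_partner_models):
        m1, _, _ = two_partner_models
        # residue 45 is far outside partner B's footprint (10..24)
        p = sw.propose_mutation(45, "A")
        report = sw.clash_score(m1, p, "B")
        assert report.max_score == 0.0 and report.min_score == 0.0

    def test_closed_form_single_pair_overlap(self):
        model = self._model_with_partner_atom(np.array([0.0, 0.0, 0.0]))
        # mutate to alanine: single CB rotamer; move partner atom 1.0 Å from it
        res = model.shared_chain().residues[2]
        (atoms,) = sw.grow_sidechain(res, "A")
        cb = atoms[0].coords
        model.structure.chain("B").residues[0].atoms[0].coords = cb + np.array([1.0, 0.0, 0.0])
        p = sw.MutationProposal(3, "A", "A", "flagged_manual")
        report = sw.clash_score(model, p, "B")
        assert report.per_rotamer == [pytest.approx((1.70 + 1.70 - 1.0) ** 2)]

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_brute_force_all_pairs_oracle(self, seed, helix10):
        rng = np.random.default_rng(seed)
        partner_atoms = [sw.Atom("CB", "C", rng.uniform(-6, 6, 3) +
                                 helix10.residues[4].atom("CA").coords)
                         for _ in range(8)]
        partner = sw.Chain("B", [sw.Residue("B", 1, "ALA", partner_atoms)])
        st = sw.Structure("toy", [helix10, partner])
        model = sw.ComplexModel("toy", st, {"A": "shared_subunit", "B": "partner_specific"})
        p = sw.propose_mutation(5, "A")  # -> Q
        report = sw.clash_score(model, p, "B")
        for atoms, got in zip(sw.grow_sidechain(model.shared_chain().residue(5), "Q"),
                              report.per_rotamer):
            expect = 0.0
            for a in atoms:
                for b in partner_atoms:
                    pen = (sw.chem.VDW_RADII[a.element] + sw.chem.VDW_RADII[b.element]
                           - np.linalg.norm(a.coords - b.coords))
                    if pen > 0:
                        expect += pen ** 2
            assert got == pytest.approx(expect)

    def test_score_increases_as_partner_approaches(self):
        scores = []
        for d in (6.0, 4.0, 3.0, 2.0, 1.0):
            model = self._model_with_partner_atom(np.array([d, 0.0, 0.0]))
            p = sw.MutationProposal(3, "A", "A", "flagged_manual")
            scores.append(sw.clash_score(model, p, "B").per_rotamer[0])
        assert scores == sorted(scores)
        assert scores[0] == 0.0 and scores[-1] > 0.0

    def test_absent_partner_rejected(self, two_partner_models):
        m1, _, _ = two_partner_models
        with pytest.raises(KeyError):
            sw.clash_score(m1, sw.propose_mutation(12, "A"), "Z")


class TestExposureCheck:
    def test_isolated_helix_surface_residue_is_exposed(self, two_partner_models):
        m1, _, _ = two_partner_models
        assert sw.exposure_check(m1, 12, "Q", threshold=0.2) is True

    def test_buried_core_residue_is_not_exposed(self):
        # surround the focal residue with a cage of dummy chains' atoms
        chain = sw.make_helix(7, chain_id="A")
        core = chain.residues[3].atom("CB").coords
        rng = np.random.default_rng(0)
        cage_atoms = []
        golden = np.pi * (3 - np.sqrt(5))
        for i in range(80):
            z = 1 - 2 * (i + 0.5) / 80
            r = np.sqrt(1 - z * z)
            p = core + 4.0 * np.array([r * np.cos(golden * i), r * np.sin(golden * i), z])
            cage_atoms.append(sw.Atom("CA", "C", p))
        chain.residues.append(sw.Residue("A", 100, "ALA", cage_atoms))
        st = sw.Structure("toy", [chain, sw.Chain("B", [
            sw.Residue("B", 1, "ALA", [sw.Atom("CA", "C", core + 50.0)])])])
        model = sw.ComplexModel("toy", st, {"A": "shared_subunit", "B": "partner_specific"})
        assert sw.exposure_check(model, 4, "A", threshold=0.2) is False

    def test_zero_threshold_always_true(self, two_partner_models):
        m1, _, _ = two_partner_models
        assert sw.exposure_check(m1, 30, "Q", threshold=0.0) is True


class TestGrouping:
    def _proposals(self, positions):
        return [sw.propose_mutation(p, "A") for p in positions]

    def test_window_grouping_of_canonical_nine_positions(self):
        # the nine-target pattern: {740,742} {768,772,775,777,781} {817,818}
        positions = [740, 742, 768, 772, 775, 777, 781, 817, 818]
        groups = sw.group_targets(self._proposals(positions), window_len=10)
        assert {g: [p.position for p in m] for g, m in groups.items()} == {
            "G1": [740, 742],
            "G2": [768, 772, 775, 777, 781],
            "G3": [817, 818],
        }

    def test_single_proposal_single_group(self):
        groups = sw.group_targets(self._proposals([5]))
        assert list(groups) == ["G1"]

    def test_explicit_partition_must_cover_all(self):
        props = self._proposals([1, 5, 9])
        with pytest.raises(DesignError, match="cover"):
            sw.group_targets(props, "explicit", partition={"G1": [1, 5]})

    def test_explicit_partition_respected(self):
        props = self._proposals([1, 5, 9])
        groups = sw.group_targets(props, "explicit",
                                  partition={"Ga": [1, 9], "Gb": [5]})
        assert [p.position for p in groups["Ga"]] == [1, 9]


class TestEnumerateCombinations:
    def test_three_groups_give_seven_named_combinations(self):
        props = [sw.propose_mutation(p, "A") for p in (740, 768, 817)]
        groups = {"G1": props[:1], "G2": props[1:2], "G3": props[2:]}
        combos = sw.enumerate_combinations(groups)
        assert list(combos) == ["K1", "K2", "K3", "K12", "K13", "K23", "K123"]
        assert [p.position for p in combos["K13"]] == [740, 817]

    def test_single_group(self):
        combos = sw.enumerate_combinations({"G1": [sw.propose_mutation(1, "A")]})
        assert list(combos) == ["K1"]

    @pytest.mark.parametrize("g", range(1, 7))
    def test_counting_identity(self, g):
        groups = {f"G{i+1}": [sw.propose_mutation(10 * i + 1, "A")] for i in range(g)}
        assert len(sw.enumerate_combinations(groups)) == 2 ** g - 1


class TestRunDesign:
    def _config(self, tmp_path, spec, **over):
        c1, c2, truth = sw.make_two_partner_fixture(spec)
        p1, p2 = tmp_path / "c1.pdb", tmp_path / "c2.pdb"
        sw.write_structure(c1, p1)
        sw.write_structure(c2, p2)
        cfg = {
            "complex_1": {"id": "M1", "template": str(p1), "chains": {
                "A": {"role": "shared_subunit"}, "B": {"role": "partner_specific"}}},
            "complex_2": {"id": "M2", "template": str(p2), "chains": {
                "A": {"role": "shared_subunit"}, "C": {"role": "partner_specific"}}},
            "included_partner": "B",
            "excluded_partners": ["C"],
        }
        cfg.update(over)
        return cfg, truth

    def test_fixture_design_recovers_truth_with_glutamine_proposals(self, tmp_path):
        spec = sw.FixtureSpec(seed=7, n_res_focal=50, partner_specs=[
            sw.PartnerSpec("B", (10, 25)), sw.PartnerSpec("C", (20, 40))])
        cfg, truth = self._config(tmp_path, spec)
        design, report = sw.run_design(cfg)
        assert design.status == "ok"
        want = truth.differential("B", "C")
        assert {p.position for p in design.proposals} == want
        assert all(p.mutant_aa == "Q" and p.rule == "hydrophobic_to_gln"
                   for p in design.proposals)  # poly-A focal chain
        assert all(p.exposed for p in design.proposals)

    def test_identical_footprints_give_no_candidates(self, tmp_path):
        spec = sw.FixtureSpec(seed=8, n_res_focal=40, partner_specs=[
            sw.PartnerSpec("B", (10, 20)), sw.PartnerSpec("C", (10, 20))])
        cfg, _ = self._config(tmp_path, spec)
        design, report = sw.run_design(cfg)
        assert design.status == "no-candidates"
        assert design.proposals == []

    def test_two_runs_are_byte_identical(self, tmp_path):
        import json
        spec = sw.FixtureSpec(seed=9, n_res_focal=50, partner_specs=[
            sw.PartnerSpec("B", (8, 20)), sw.PartnerSpec("C", (25, 35))])
        cfg, _ = self._config(tmp_path, spec)
        _, r1 = sw.run_design(cfg)
        _, r2 = sw.run_design(cfg)
        assert json.dumps(r1, sort_keys=True) == json.dumps(r2, sort_keys=True)

    def test_mutant_sequence_applies_combination(self, tmp_path):
        spec = sw.FixtureSpec(seed=7, n_res_focal=50, partner_specs=[
            sw.PartnerSpec("B", (10, 14)), sw.PartnerSpec("C", (30, 40))])
        cfg, _ = self._config(tmp_path, spec)
        design, _ = sw.run_design(cfg)
        wt = "A" * 50
        mut = design.mutant_sequence(wt, "K1")
        assert mut.count("Q") == len(design.combinations["K1"])
        assert len(mut) == 50
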