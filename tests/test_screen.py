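import math

import numpy as np
import pytest

from hlapocket.association import AssociationResult
from hlapocket.cohort import CASE, CONTROL
from hlapocket.haplotypes import em_fit
from hlapocket.registry import Allele, parse_allele
from hlapocket.screen import (ComboError, ComboSpec, ComboTerm, DEFAULT_COMBOS,
                              DirectionalitySets, candidate_residues,
                              combo_association, combo_dosage, opposing_screen,
                              parse_combo)
from conftest import mk_subject, mk_table


def res(or_, p):
    return AssociationResult("x", or_, (or_ * 0.8, or_ * 1.25), p, 100)


class TestComboGrammar:
    def test_parse_alpha_beta_disjunction(self):
        spec = parse_combo("a31:M + b84:G|V")
        assert spec.terms == (ComboTerm("alpha", 31, frozenset("M")),
                              ComboTerm("beta", 84, frozenset({"G", "V"})))

    def test_case_insensitive_and_label_roundtrip(self):
        spec = parse_combo("A31:m + B84:g|v")
        assert parse_combo(spec.label) == spec

    @pytest.mark.parametrize("bad", ["31:M", "a31", "a31:", "x31:M", ""])
    def test_malformed_rejected(self, bad):
        with pytest.raises(ComboError):
            parse_combo(bad)

    def test_packaged_combos_cover_ten_hypotheses(self):
        assert len(DEFAULT_COMBOS) == 10
        assert {c.pocket for c in DEFAULT_COMBOS} == {"P1", "P4", "P6", "P7", "P9"}


class TestOpposingScreen:
    def test_partition_by_direction(self):
        alleles = {n: Allele("DPA1", n) for n in ("01:03", "02:01", "02:02",
                                                  "03:01")}
        results = [(alleles["01:03"], res(0.60, 5.9e-7)),
                   (alleles["02:01"], res(1.49, 0.0013)),
                   (alleles["02:02"], res(1.78, 0.0028)),
                   (alleles["03:01"], res(2.05, 0.024))]
        sets = opposing_screen(results)
        assert set(sets.protective) == {alleles["01:03"]}
        assert set(sets.susceptible) == {alleles["02:01"], alleles["02:02"],
                                         alleles["03:01"]}

    def test_nothing_significant_gives_empty_sets(self):
        results = [(Allele("DPB1", "04:01"), res(0.7, 0.06)),
                   (Allele("DPB1", "01:01"), res(1.4, 0.5))]
        sets = opposing_screen(results)
        assert not sets.protective and not sets.susceptible

    def test_alpha_screen_threshold_is_uncorrected(self):
        # p = 0.024 passes the 0.05 screen even though it would fail a
        # 4-test family correction (0.0125)
        allele = Allele("DPA1", "03:01")
        sets = opposing_screen([(allele, res(2.05, 0.024))])
        assert allele in sets.susceptible


class TestCandidateResidues:
    def _sets(self, gene, protective, susceptible):
        s = DirectionalitySets()
        for n in protective:
            s.protective[Allele(gene, n)] = res(0.6, 1e-4)
        for n in susceptible:
            s.susceptible[Allele(gene, n)] = res(1.6, 1e-3)
        return s

    def test_dpb1_candidates_annotate_pockets(self):
        from hlapocket.registry import BETA1_TRACKED, combined_residue_map
        sets = self._sets("DPB1", ["04:01"], ["06:01", "18:01", "104:01"])
        cands = candidate_residues(combined_residue_map(), sets, "beta",
                                   BETA1_TRACKED)
        by_pos = {c.position: c.pockets for c in cands}
        assert by_pos[84] == ("P1",)
        assert by_pos[76] == ("P2", "P4")
        assert by_pos[69] == ("P4", "P5", "P7")
        assert by_pos[65] == ("P7",)
        assert by_pos[11] == ("P6",)
        for pos in (9, 36, 55):
            assert by_pos[pos] == ("P9",)
        # positions outside every pocket (8, 56, 57, 85-87) are not candidates
        assert set(by_pos) == {9, 11, 36, 55, 65, 69, 76, 84}

    def test_dpa1_candidates(self):
        from hlapocket.registry import ALPHA1_TRACKED, combined_residue_map
        sets = self._sets("DPA1", ["01:03"], ["02:01", "02:02", "03:01"])
        cands = candidate_residues(combined_residue_map(), sets, "alpha",
                                   ALPHA1_TRACKED)
        by_pos = {c.position: c.pockets for c in cands}
        assert by_pos == {31: ("P1",), 11: ("P6",), 66: ("P6",)}
        c31 = next(c for c in cands if c.position == 31)
        assert c31.protective_residues == {"M"}
        assert c31.susceptible_residues == {"Q"}

    def test_groups_sharing_all_residues_give_no_candidates(self):
        from hlapocket.registry import BETA1_TRACKED, combined_residue_map
        sets = self._sets("DPB1", ["04:01"], ["04:01"])
        assert candidate_residues(combined_residue_map(), sets, "beta",
                                  BETA1_TRACKED) == []

    def test_empty_side_is_an_error(self):
        from hlapocket.registry import BETA1_TRACKED, combined_residue_map
        sets = self._sets("DPB1", ["04:01"], [])
        with pytest.raises(ComboError):
            candidate_residues(combined_residue_map(), sets, "beta",
                               BETA1_TRACKED)


P1_PROTECTIVE = DEFAULT_COMBOS[0]  # a31:M + (b84:G|V)


class TestComboDosage:
    def test_homozygous_unambiguous_carrier_scores_two(self):
        table = mk_table([(CASE, {"DPA1": ("01:03", "01:03"),
                                  "DPB1": ("04:01", "04:01")})])
        est = em_fit(table, "DPA1", "DPB1")
        assert combo_dosage(table.subjects[0], P1_PROTECTIVE, est) == 2.0

    def test_no_qualifying_beta_allele_scores_zero(self):
        table = mk_table([(CASE, {"DPA1": ("01:03", "01:03"),
                                  "DPB1": ("17:01", "01:01")})])
        est = em_fit(table, "DPA1", "DPB1")
        assert combo_dosage(table.subjects[0], P1_PROTECTIVE, est) == 0.0

    def test_balanced_phase_ambiguity_gives_expected_dosage_one(self):
        # lone double heterozygote: posterior 0.5/0.5 between one qualifying
        # and one non-qualifying configuration per phasing
        table = mk_table([(CASE, {"DPA1": ("01:03", "02:01"),
                                  "DPB1": ("04:01", "17:01")})])
        est = em_fit(table, "DPA1", "DPB1")
        # phasings: (01:03~04:01, 02:01~17:01) and (01:03~17:01, 02:01~04:01)
        # exactly one haplotype qualifies in the first, none in the second
        d = combo_dosage(table.subjects[0], P1_PROTECTIVE, est)
        assert d == pytest.approx(0.5)

    def test_independent_mode_pairs_loci_at_random(self):
        table = mk_table([(CASE, {"DPA1": ("01:03", "02:01"),
                                  "DPB1": ("04:01", "17:01")})])
        d = combo_dosage(table.subjects[0], P1_PROTECTIVE, mode="independent")
        assert d == pytest.approx(0.5)  # 1 alpha-sat x 1 beta-sat / 2

    def test_conjunction_dosage_bounded_by_single_terms(self):
        rng = np.random.default_rng(0)
        dpa = ["01:03", "02:01", "02:02"]
        dpb = ["04:01", "17:01", "01:01", "18:01"]
        specs = [(CASE if i % 2 else CONTROL,
                  {"DPA1": tuple(rng.choice(dpa, 2)),
                   "DPB1": tuple(rng.choice(dpb, 2))}) for i in range(60)]
        table = mk_table(specs)
        est = em_fit(table, "DPA1", "DPB1")
        single_alpha = ComboSpec((P1_PROTECTIVE.terms[0],))
        single_beta = ComboSpec((P1_PROTECTIVE.terms[1],))
        for s in table.subjects:
            both = combo_dosage(s, P1_PROTECTIVE, est)
            a = combo_dosage(s, single_alpha, est)
            b = combo_dosage(s, single_beta, est)
            assert both <= min(a, b) + 1e-9

    def test_dosage_mass_matches_em_frequency_mass(self):
        from hlapocket.registry import combined_residue_map
        rng = np.random.default_rng(1)
        dpa = ["01:03", "02:01"]
        dpb = ["04:01", "17:01", "01:01"]
        specs = [(CASE if i % 2 else CONTROL,
                  {"DPA1": tuple(rng.choice(dpa, 2)),
                   "DPB1": tuple(rng.choice(dpb, 2))}) for i in range(80)]
        table = mk_table(specs)
        est = em_fit(table, "DPA1", "DPB1")
        rmap = combined_residue_map()
        total = sum(combo_dosage(s, P1_PROTECTIVE, est) for s in table.subjects)
        mass = sum(f for h, f in zip(est.haplotypes, est.freqs)
                   if P1_PROTECTIVE.haplotype_qualifies(*h, rmap))
        assert total == pytest.approx(2 * est.n_subjects * mass, abs=1e-6)

    def test_missing_genotype_is_an_error(self):
        s = mk_subject(0, CASE, None, DPB1=("04:01", "04:01"))
        with pytest.raises(ComboError):
            combo_dosage(s, P1_PROTECTIVE, mode="independent")


class TestComboAssociation:
    def test_unsatisfiable_combo_is_constant_dosage_error(self):
        table = mk_table([(CASE, {"DPB1": ("04:01", "04:01")}),
                          (CONTROL, {"DPB1": ("04:01", "01:01")})])
        spec = parse_combo("b84:W")  # no packaged allele carries tryptophan
        with pytest.raises(ValueError, match="constant"):
            combo_association(table, spec)

    def test_beta_only_combo_needs_no_em(self):
        specs = []
        for i in range(120):
            b = ("04:01", "04:01") if (i % 3 == 0) == (i % 2 == 0) else \
                ("17:01", "01:01")
            specs.append((CASE if i % 2 else CONTROL, {"DPB1": b}))
        table = mk_table(specs)
        out = combo_association(table, parse_combo("b36:A + b55:A"))
        assert out.n_subjects == 120
        assert math.isfinite(out.p)
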