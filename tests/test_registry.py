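import pytest

from hlapocket.registry import (ALPHA1_TRACKED, BETA1_TRACKED, Allele,
                                AlleleParseError, AlleleResidueMap,
                                RegistryError, combined_residue_map,
                                default_expression_map, default_pockets,
                                default_residue_map, default_tce_map,
                                differing_pocket_residues,
                                infer_expression_snp, load_pockets,
                                parse_allele, pocket_positions, residue_at,
                                tce_assign)


def dpb1(name):
    return Allele("DPB1", name)


class TestParseAllele:
    @pytest.mark.parametrize("raw, gene, name", [
        ("DPA1*01:03", "DPA1", "01:03"),
        ("DPB1*04:01:01:24", "DPB1", "04:01"),   # higher fields truncated
        ("DRB1*13:01:01", "DRB1", "13:01"),
        ("DQB1*05:01:01:02N", "DQB1", "05:01"),  # expression suffix dropped
        ("DPB1*104:01", "DPB1", "104:01"),
    ])
    def test_two_field_truncation(self, raw, gene, name):
        assert parse_allele(raw) == Allele(gene, name)

    def test_bare_name_with_gene(self):
        assert parse_allele("04:01", gene="DPB1") == dpb1("04:01")

    @pytest.mark.parametrize("raw", ["DPZ9*01:01", "DPB1-04:01", "DPB1*4:1x",
                                     "A*01:01", ""])
    def test_malformed_rejected(self, raw):
        with pytest.raises(AlleleParseError):
            parse_allele(raw)

    def test_error_names_offending_token(self):
        with pytest.raises(AlleleParseError, match="DPZ9"):
            parse_allele("DPZ9*01:01")


class TestResidueLookup:
    @pytest.mark.parametrize("allele, position, residue", [
        ("04:01", 84, "G"), ("17:01", 84, "D"), ("04:01", 96, "R"),
        ("01:01", 96, "K"), ("04:01", 170, "T"), ("18:01", 84, "V"),
        ("04:01", 11, "G"), ("03:01", 11, "L"), ("04:01", 36, "A"),
        ("04:01", 55, "A"), ("04:01", 69, "K"), ("04:01", 76, "M"),
    ])
    def test_published_beta_assignments(self, allele, position, residue):
        m = default_residue_map("DPB1")
        assert residue_at(m, dpb1(allele), "beta", position) == residue

    @pytest.mark.parametrize("allele, position, residue", [
        ("01:03", 31, "M"), ("02:01", 31, "Q"),
        ("01:03", 11, "A"), ("02:02", 11, "M"),
    ])
    def test_published_alpha_assignments(self, allele, position, residue):
        m = default_residue_map("DPA1")
        assert residue_at(m, Allele("DPA1", allele), "alpha", position) == residue

    def test_missing_lookup_is_an_error_not_a_default(self):
        m = default_residue_map("DPB1")
        with pytest.raises(RegistryError):
            residue_at(m, dpb1("888:88"), "beta", 84)
        with pytest.raises(RegistryError):
            residue_at(m, dpb1("04:01"), "beta", 999)


class TestPockets:
    @pytest.mark.parametrize("pocket, chain, expected", [
        ("P1", "alpha", {24, 31, 32, 43, 52, 53, 54, 55}),
        ("P1", "beta", {80, 83, 84}),
        ("P2", "alpha", {9}), ("P2", "beta", {76, 79, 80}),
        ("P3", "alpha", {22, 54, 58}), ("P3", "beta", set()),
        ("P4", "alpha", {9, 62}), ("P4", "beta", {13, 24, 26, 68, 69, 72, 76}),
        ("P5", "alpha", set()), ("P5", "beta", {69}),
        ("P6", "alpha", {11, 62, 65, 66}), ("P6", "beta", {11, 13, 26, 28}),
        ("P7", "alpha", {65, 69}), ("P7", "beta", {26, 28, 45, 59, 65, 68, 69}),
        ("P8", "alpha", {65, 68, 69}), ("P8", "beta", set()),
        ("P9", "alpha", {69, 72, 73, 76}), ("P9", "beta", {9, 28, 35, 36, 55, 59}),
    ])
    def test_dp_pocket_membership(self, pocket, chain, expected):
        assert pocket_positions(pocket, chain) == frozenset(expected)

    def test_serialize_reload_roundtrip(self, tmp_path):
        pk = default_pockets()
        path = tmp_path / "pockets.tsv"
        pk.to_tsv(path)
        assert load_pockets(path).table == pk.table

    def test_beta_pocket_union_covers_screen_positions(self):
        pk = default_pockets()
        union = set().union(*(pk.positions(p, "beta") for p in
                              ("P1", "P2", "P3", "P4", "P5", "P6", "P7", "P8", "P9")))
        assert {9, 11, 36, 55, 65, 69, 76, 84} <= union


class TestDifferingResidues:
    def test_fourteen_beta1_positions_between_opposing_dpb1_groups(self):
        m = default_residue_map("DPB1")
        got = differing_pocket_residues(
            m, [dpb1("04:01")],
            [dpb1("06:01"), dpb1("18:01"), dpb1("104:01")],
            "beta", BETA1_TRACKED)
        assert got == {8, 9, 11, 36, 55, 56, 57, 65, 69, 76, 84, 85, 86, 87}

    def test_alpha_groups_differ_at_tracked_positions(self):
        m = default_residue_map("DPA1")
        got = differing_pocket_residues(
            m, [Allele("DPA1", "01:03")],
            [Allele("DPA1", n) for n in ("02:01", "02:02", "03:01")],
            "alpha", ALPHA1_TRACKED)
        assert got == {11, 31, 66}

    def test_identical_groups_differ_nowhere(self):
        m = default_residue_map("DPB1")
        group = [dpb1("04:01"), dpb1("17:01")]
        assert differing_pocket_residues(m, group, group, "beta",
                                         BETA1_TRACKED) == set()

    def test_synthetic_three_position_map(self):
        a, b = dpb1("04:01"), dpb1("17:01")
        m = AlleleResidueMap({(a, "beta", 1): "A", (a, "beta", 2): "G",
                              (a, "beta", 3): "K",
                              (b, "beta", 1): "A", (b, "beta", 2): "D",
                              (b, "beta", 3): "K"})
        assert differing_pocket_residues(m, [a], [b], "beta", {1, 2, 3}) == {2}

    def test_symmetry(self):
        m = default_residue_map("DPB1")
        ga = [dpb1("04:01"), dpb1("02:01")]
        gb = [dpb1("17:01"), dpb1("18:01")]
        fwd = differing_pocket_residues(m, ga, gb, "beta", BETA1_TRACKED)
        rev = differing_pocket_residues(m, gb, ga, "beta", BETA1_TRACKED)
        assert fwd == rev

    def test_coverage_gap_raises(self):
        m = default_residue_map("DPB1")
        with pytest.raises(RegistryError):
            differing_pocket_residues(m, [dpb1("04:01")], [dpb1("777:77")],
                                      "beta", BETA1_TRACKED)


class TestExpressionSNP:
    @pytest.mark.parametrize("allele, cls", [
        ("04:01", "A"), ("17:01", "A"), ("02:01", "A"), ("04:02", "A"),
        ("01:01", "G"), ("03:01", "G"), ("18:01", "G"), ("104:01", "G"),
    ])
    def test_published_classes(self, allele, cls):
        assert infer_expression_snp(default_expression_map(), dpb1(allele)) == cls

    def test_unmapped_allele_is_explicit_error(self):
        with pytest.raises(RegistryError, match="unknown expression class"):
            infer_expression_snp(default_expression_map(), dpb1("999:99"))

    def test_classes_partition_the_allele_universe(self):
        emap = default_expression_map()
        classes = [emap.infer(a) for a in emap.entries]
        assert set(classes) == {"A", "G"}
        # every packaged allele has exactly one class by construction;
        # the published universe splits 17 low / 27 high (plus 2 fillers)
        a_real = [a for a, c in emap.entries.items()
                  if c == "A" and a.name not in ("99:99", "105:01")]
        g_real = [a for a, c in emap.entries.items()
                  if c == "G" and a.name not in ("99:99", "105:01")]
        assert (len(a_real), len(g_real)) == (17, 27)


class TestTCE:
    def test_direct_lookup(self):
        tmap = default_tce_map()
        assert tce_assign(tmap, dpb1("17:01")) == 1
        assert tce_assign(tmap, dpb1("04:01")) == 3

    def test_novel_allele_via_exon2_fallback(self):
        tmap = default_tce_map()
        # a novel allele sharing exon 2 with a known allele gets its group
        known_seq = next(seq for seq, g in tmap.fallback.items() if g == 1)
        assert tce_assign(tmap, dpb1("999:99"), exon2_seq=known_seq) == 1

    def test_novel_allele_without_sequence_is_unassigned(self):
        with pytest.raises(RegistryError, match="unassigned"):
            tce_assign(default_tce_map(), dpb1("999:99"))


def test_combined_map_merges_both_chains():
    m = combined_residue_map()
    assert m.residue_at(Allele("DPA1", "01:03"), "alpha", 31) == "M"
    assert m.residue_at(dpb1("04:01"), "beta", 84) == "G"
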