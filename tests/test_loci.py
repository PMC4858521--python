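"""Operon prediction, locus assembly, template scoring, completeness."""

import pytest
from helpers import catalog_from_roles, make_genome

from t4pcensus import synthetic as syn
from t4pcensus.census import CensusConfig, default_seed_families, run_census
from t4pcensus.features import compute_features
from t4pcensus.genome_io import FamilyCatalog, FamilyInfo
from t4pcensus.loci import (
    ARCHAELLUM_COMPONENTS,
    GenomeContext,
    Locus,
    build_loci,
    check_archaellum_completeness,
    classify_locus,
    load_templates,
    predict_operons,
)


class TestPredictOperons:
    def test_small_gaps_same_strand_one_block(self):
        g = make_genome("g0", ["A", "B", "C"], gaps=[300, 20, 20])
        assert predict_operons(g) == [["g0_g0", "g0_g1", "g0_g2"]]

    def test_strand_flip_splits_block(self):
        g = make_genome("g0", ["A", "B", "C"], strands=["+", "+", "-"], gaps=[300, 20, 20])
        assert predict_operons(g) == [["g0_g0", "g0_g1"], ["g0_g2"]]

    def test_large_gap_splits_block(self):
        g = make_genome("g0", ["A", "B"], gaps=[300, 250])
        assert predict_operons(g) == [["g0_g0"], ["g0_g1"]]

    def test_coordinate_free_fallback_uses_strand_adjacency(self):
        g = make_genome("g0", ["A", "B", "C"], strands=["+", "+", "-"])
        for rec in g.genes():
            rec.start = rec.end = None
        assert predict_operons(g) == [["g0_g0", "g0_g1"], ["g0_g2"]]

    def test_every_gene_in_exactly_one_block(self, acc_collection):
        tables, _, _ = acc_collection
        for table in tables[:5]:
            blocks = predict_operons(table)
            flat = [g for b in blocks for g in b]
            assert sorted(flat) == sorted(r.gene_id for r in table.genes())

    def test_blocks_reproduce_generator_operon_plan(self, acc_collection):
        tables, truth, _ = acc_collection
        for table in tables:
            got = [tuple(b) for b in predict_operons(table)]
            assert got == truth.operons[table.genome_id]


class TestBuildLoci:
    CAT = catalog_from_roles({"A": "secretion_ATPase", "B": "tadC"})

    def test_two_intervening_genes_merge(self):
        g = make_genome("g0", ["A", None, None, "B"])
        loci = build_loci(g, {"A", "B"}, self.CAT, max_intervening=2)
        assert len(loci) == 1
        assert (loci[0].start_index, loci[0].end_index) == (0, 3)
        assert not loci[0].is_standalone

    def test_three_intervening_genes_split(self):
        g = make_genome("g0", ["A", None, None, None, "B"])
        loci = build_loci(g, {"A", "B"}, self.CAT, max_intervening=2)
        assert len(loci) == 2
        assert all(l.is_standalone for l in loci)  # single-family groups

    def test_planted_ranges_recovered(self, acc_collection, acc_census, acc_loci):
        _, truth, _ = acc_collection
        recovered = {
            (l.genome_id, l.contig_id, l.start_index, l.end_index)
            for ll in acc_loci.values()
            for l in ll
            if not l.is_standalone
        }
        planted = {
            (p.genome_id, p.contig_id, p.start_index, p.end_index)
            for p in truth.planted_loci
        }
        matched = len(planted & recovered)
        assert matched / len(planted) >= 0.95

    def test_every_census_gene_in_locus_or_standalone(self, acc_collection, acc_census, acc_loci):
        tables, _, _ = acc_collection
        for table in tables:
            member_count = {}
            for locus in acc_loci[table.genome_id]:
                for gid in locus.gene_ids:
                    member_count[gid] = member_count.get(gid, 0) + 1
            census_genes = [
                r.gene_id for r in table.genes()
                if r.family_id in acc_census.final_families
            ]
            assert sorted(member_count) == sorted(census_genes)
            assert all(v == 1 for v in member_count.values())


def _archaellum_locus(n_archaellins=3, n_cde=1, drop=None):
    cat = FamilyCatalog(
        {
            "fI": FamilyInfo("secretion_ATPase", component="flaI"),
            "fH": FamilyInfo("flaH", component="flaH"),
            "fJ": FamilyInfo("tadC", component="flaJ"),
            "fF": FamilyInfo("archaellin", component="flaF"),
            "fG": FamilyInfo("archaellin", component="flaG"),
            "fB": FamilyInfo("archaellin"),
            "fCDE": FamilyInfo("membrane_accessory", component="flaCDE"),
        }
    )
    fams = (
        ["fI", "fH", "fJ", "fF", "fG"] + ["fB"] * n_archaellins + ["fCDE"] * n_cde
    )
    if drop:
        fams = [f for f in fams if cat.match_key(f) != drop]
    g = make_genome("g0", fams, gaps=[300] + [20] * (len(fams) - 1))
    loci = build_loci(g, set(fams), cat)
    return g, loci, cat


class TestClassifyLocus:
    TEMPLATES = load_templates()

    def test_complete_archaellum_scores_one(self):
        g, loci, cat = _archaellum_locus()
        name, score = classify_locus(loci[0], self.TEMPLATES, catalog=cat)
        assert (name, score) == ("archaellum", 1.0)

    def test_archaellum_missing_flaH_scores_six_sevenths(self):
        g, loci, cat = _archaellum_locus(drop="flaH")
        name, score = classify_locus(loci[0], self.TEMPLATES, catalog=cat)
        assert name == "archaellum"
        assert score == pytest.approx(6 / 7)
        complete, missing, _ = check_archaellum_completeness(g, loci, cat)
        assert not complete and missing == {"flaH"}

    def test_two_component_locus_is_sub4D(self):
        cat = catalog_from_roles(
            {"ATP": "secretion_ATPase", "MEM": "membrane_accessory"}
        )
        g = make_genome("g0", ["ATP", "MEM"], gaps=[300, 20])
        loci = build_loci(g, {"ATP", "MEM"}, cat)
        name, score = classify_locus(loci[0], self.TEMPLATES, catalog=cat)
        assert (name, score) == ("sub4D", 1.0)

    def test_pilin_in_locus_blocks_sub4D(self):
        cat = catalog_from_roles(
            {"ATP": "secretion_ATPase", "MEM": "membrane_accessory",
             "PIL": "major_pilin"}
        )
        g = make_genome("g0", ["ATP", "MEM", "PIL"], gaps=[300, 20, 20])
        loci = build_loci(g, {"ATP", "MEM", "PIL"}, cat)
        name, _ = classify_locus(loci[0], self.TEMPLATES, catalog=cat)
        assert name != "sub4D"

    def test_majors_in_trans_satisfy_requirement(self):
        cat = catalog_from_roles(
            {"ATP": "secretion_ATPase", "TAD": "tadC"}
        )
        g = make_genome("g0", ["ATP", "TAD"], gaps=[300, 20])
        locus = build_loci(g, {"ATP", "TAD"}, cat)[0]
        with_ctx, s1 = classify_locus(
            locus, self.TEMPLATES, GenomeContext(has_standalone_majors=True), cat
        )
        without_ctx, s2 = classify_locus(
            locus, self.TEMPLATES, GenomeContext(has_standalone_majors=False), cat
        )
        assert with_ctx == "sulfolobales_simple" and s1 == 1.0
        assert s2 < s1

    def test_score_always_within_unit_interval(self, confusion_run):
        _, _, _, _, by_genome = confusion_run
        for loci in by_genome.values():
            for locus in loci:
                assert 0.0 <= locus.score <= 1.0


class TestArchaellumCompleteness:
    def test_complete_with_up_to_nine_archaellins(self):
        for n in (1, 5, 9):
            g, loci, cat = _archaellum_locus(n_archaellins=n)
            complete, missing, counts = check_archaellum_completeness(g, loci, cat)
            assert complete and counts["archaellin"] == n

    def test_ten_archaellins_is_out_of_range(self):
        g, loci, cat = _archaellum_locus(n_archaellins=10)
        complete, missing, _ = check_archaellum_completeness(g, loci, cat)
        assert not complete and missing == {"archaellin"}

    def test_zero_archaellins_reported_missing(self):
        g, loci, cat = _archaellum_locus(n_archaellins=3, drop="archaellin")
        complete, missing, _ = check_archaellum_completeness(g, loci, cat)
        assert not complete and missing == {"archaellin"}

    def test_standalone_archaellins_count(self):
        # archaellins encoded away from the main locus still complete it
        cat = _archaellum_locus()[2]
        fams = ["fI", "fH", "fJ", "fF", "fG", "fCDE", None, None, None, "fB"]
        g = make_genome("g0", fams)
        loci = build_loci(g, {f for f in fams if f}, cat)
        complete, _, counts = check_archaellum_completeness(g, loci, cat)
        assert complete and counts["archaellin"] == 1

    def test_cde_fusion_counts_once_per_gene(self):
        g, loci, cat = _archaellum_locus(n_cde=3)
        complete, _, counts = check_archaellum_completeness(g, loci, cat)
        assert complete and counts["flaCDE"] == 3
        g, loci, cat = _archaellum_locus(n_cde=4)
        assert not check_archaellum_completeness(g, loci, cat)[0]


class TestTemplateLibrary:
    def test_eleven_templates_shipped(self):
        templates = load_templates()
        assert len(templates) == 11
        names = {t.name for t in templates}
        assert {"clade1", "archaellum", "sub4D", "sulfolobales_simple"} <= names

    def test_archaellum_template_lists_exactly_seven_components(self):
        arc = {t.name: t for t in load_templates()}["archaellum"]
        assert set(arc.required) == set(ARCHAELLUM_COMPONENTS)
        assert arc.required == ARCHAELLUM_COMPONENTS

    def test_required_and_forbidden_disjoint(self):
        for t in load_templates():
            assert not set(t.required) & t.forbidden
            for lo, hi in t.required.values():
                assert 0 <= lo <= hi
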