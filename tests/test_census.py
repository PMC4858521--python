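"""Neighborhood expansion, curation, counting and phyletic patterns."""

import numpy as np
import pytest
from helpers import brute_force_census, catalog_from_roles, make_genome, random_collection

from t4pcensus.census import (
    CensusConfig,
    ConfigurationError,
    count_t4p_per_genome,
    curate_candidates,
    expand_once,
    phyletic_matrix,
    run_census,
)
from t4pcensus.features import compute_features
from t4pcensus.genome_io import FamilyCatalog
from t4pcensus import synthetic as syn


class TestExpandOnce:
    def test_family_in_five_genomes_is_added(self):
        genomes = [make_genome(f"g{i}", ["SEED", "X"]) for i in range(5)]
        assert expand_once(genomes, {"SEED"}, window=3, min_genomes=5) == {"SEED", "X"}

    def test_family_in_four_genomes_is_not_added(self):
        genomes = [make_genome(f"g{i}", ["SEED", "X"]) for i in range(4)]
        assert expand_once(genomes, {"SEED"}, window=3, min_genomes=5) == {"SEED"}

    def test_multiple_occurrences_count_once_per_genome(self):
        # one genome with many SEED-X adjacencies must still count as one
        genomes = [make_genome("g0", ["SEED", "X"] * 6)] + [
            make_genome(f"g{i}", ["SEED", "X"]) for i in range(1, 4)
        ]
        assert expand_once(genomes, {"SEED"}, window=3, min_genomes=5) == {"SEED"}

    def test_unlabeled_genes_ignored(self):
        genomes = [make_genome(f"g{i}", ["SEED", None]) for i in range(6)]
        assert expand_once(genomes, {"SEED"}, window=3, min_genomes=5) == {"SEED"}

    def test_empty_current_set_rejected(self):
        with pytest.raises(ConfigurationError):
            expand_once([make_genome("g0", ["A"])], set(), 3, 5)

    def test_matches_brute_force_on_random_toys(self):
        rng = np.random.default_rng(77)
        for _ in range(10):
            genomes = random_collection(rng, 8, 40, 12)
            got = expand_once(genomes, {"SEED"}, window=2, min_genomes=3)
            want = brute_force_census(genomes, {"SEED"}, 2, 3, 1)
            assert got == want


class TestRunCensus:
    @staticmethod
    def _chain_genomes(n=5):
        # SEED at 0, A at 3, B at 6, C at 9: each iteration reaches one link
        fams = ["SEED", None, None, "A", None, None, "B", None, None, "C"]
        return [make_genome(f"g{i}", fams) for i in range(n)]

    def test_chain_reachability_grows_with_iterations(self):
        genomes = self._chain_genomes()
        catalog = FamilyCatalog()
        one = run_census(
            genomes, CensusConfig(seed_families={"SEED"}, iterations=1), {}, catalog
        )
        three = run_census(
            genomes, CensusConfig(seed_families={"SEED"}, iterations=3), {}, catalog
        )
        assert "C" not in one.final_families
        assert {"SEED", "A", "B", "C"} <= three.final_families

    def test_accepted_sets_non_decreasing_and_fixed_point(self):
        genomes = self._chain_genomes()
        res = run_census(
            genomes, CensusConfig(seed_families={"SEED"}, iterations=6), {}, FamilyCatalog()
        )
        chain = res.accepted_families_by_iteration
        for earlier, later in zip(chain, chain[1:]):
            assert earlier <= later
        fixed = chain[-1]
        assert expand_once(genomes, fixed, 3, 5) == fixed

    def test_lowering_min_genomes_never_removes_families(self):
        rng = np.random.default_rng(5)
        genomes = random_collection(rng, 8, 40, 10)
        accepted = {}
        for m in (2, 3, 4, 6):
            accepted[m] = expand_once(genomes, {"SEED"}, window=3, min_genomes=m)
        assert accepted[6] <= accepted[4] <= accepted[3] <= accepted[2]

    def test_empty_seed_set_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            run_census([make_genome("g0", ["A"])], CensusConfig(), {}, FamilyCatalog())

    def test_no_exclusion_roles_keeps_everything(self, acc_collection, acc_features):
        tables, _, catalog = acc_collection
        from t4pcensus.census import default_seed_families

        cfg = CensusConfig(
            seed_families=default_seed_families(catalog), exclusion_roles=set()
        )
        res = run_census(tables, cfg, acc_features, catalog)
        assert res.excluded_families == {}
        assert any(catalog.role_of(f) == "s_layer" for f in res.final_families)

    def test_excluded_slayer_kept_as_potential_components(self, acc_census, acc_collection):
        _, _, catalog = acc_collection
        assert acc_census.excluded_families
        assert all(
            catalog.role_of(f) == "s_layer" for f in acc_census.excluded_families
        )
        assert not (set(acc_census.excluded_families) & acc_census.final_families)

    def test_assignments_only_reference_final_families(self, acc_census):
        fams = {a[2] for a in acc_census.protein_assignments}
        assert fams <= acc_census.final_families
        assert acc_census.summary["n_proteins"] == len(acc_census.protein_assignments)
        assert 0.0 <= acc_census.summary["fraction_hypothetical"] <= 1.0


class TestCuration:
    def _setup(self, stray_member: bool):
        roles = {"ATP": "secretion_ATPase", "CAND": "unknown"}
        catalog = catalog_from_roles(roles)
        seqs = {
            "ATP": syn.emit_cytoplasmic(200, np.random.default_rng(0)),
            "CAND": syn.emit_prepilin(200, np.random.default_rng(1)),
        }
        genomes = []
        for i in range(3):
            fams = ["ATP", "CAND"]
            strands = ["+", "+"]
            gaps = [300, 20]  # same operon
            seq_list = [seqs["ATP"], seqs["CAND"]]
            if stray_member and i == 0:
                fams += [None, None, None, None, "CAND"]
                strands += ["+"] * 5
                gaps += [300] * 5
                seq_list += [None] * 4 + [seqs["CAND"]]
            genomes.append(
                make_genome(f"g{i}", fams, strands=strands, gaps=gaps, seqs=seq_list)
            )
        features = compute_features(genomes)
        return genomes, features, catalog

    def test_secreted_operonic_exclusive_family_accepted(self):
        genomes, features, catalog = self._setup(stray_member=False)
        accepted, rejected = curate_candidates(
            {"CAND"}, genomes, features, {"ATP"}, catalog
        )
        assert "CAND" in accepted
        assert accepted["CAND"] == "loc=1.00,excl=1.00,operon=yes"

    def test_member_in_foreign_context_breaks_exclusivity(self):
        genomes, features, catalog = self._setup(stray_member=True)
        accepted, rejected = curate_candidates(
            {"CAND"}, genomes, features, {"ATP"}, catalog
        )
        assert "CAND" in rejected
        assert "excl=0.75" in rejected["CAND"]

    def test_cytoplasmic_family_rejected_by_localization(self):
        rng = np.random.default_rng(2)
        seq = syn.emit_cytoplasmic(150, rng)
        genomes = [
            make_genome(
                f"g{i}", ["ATP", "CAND"], gaps=[300, 20],
                seqs=[syn.emit_cytoplasmic(200, rng), seq],
            )
            for i in range(3)
        ]
        features = compute_features(genomes)
        catalog = catalog_from_roles({"ATP": "secretion_ATPase"})
        accepted, rejected = curate_candidates(
            {"CAND"}, genomes, features, {"ATP"}, catalog
        )
        assert "CAND" in rejected
        assert rejected["CAND"].startswith("loc=0.00")


class TestCounting:
    def test_gene_count_semantics(self):
        g = make_genome("g0", ["ATP", "X", "ATP"])
        counts = count_t4p_per_genome([g, make_genome("g1", ["X"])], {"ATP"})
        assert counts == {"g0": 2, "g1": 0}
        distinct = count_t4p_per_genome([g], {"ATP"}, distinct_families=True)
        assert distinct == {"g0": 1}

    def test_phyletic_matrix_paralogs_and_absent_family(self):
        g = make_genome("g0", ["F1", "F1", "F1"])
        m = phyletic_matrix([g], {"F1", "F2"})
        assert m.loc["F1", "g0"] == 3
        assert m.loc["F2", "g0"] == 0

    def test_phyletic_row_sums_equal_recount(self, acc_collection, acc_census):
        tables, _, _ = acc_collection
        m = phyletic_matrix(tables, acc_census.final_families)
        for fam in m.index:
            recount = sum(
                1 for t in tables for r in t.genes() if r.family_id == fam
            )
            assert m.loc[fam].sum() == recount
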