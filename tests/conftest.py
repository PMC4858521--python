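import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for helpers.py

from t4pcensus import loci as loci_mod
from t4pcensus import pilins as pilins_mod
from t4pcensus import synthetic as syn
from t4pcensus.census import CensusConfig, default_seed_families, run_census
from t4pcensus.features import compute_features


@pytest.fixture(scope="session")
def acc_collection():
    """The default 30-genome collection (all 11 architectures, seed 17)."""
    params = syn.acceptance_params(17)
    return syn.generate_collection(params)


@pytest.fixture(scope="session")
def acc_features(acc_collection):
    tables, _, _ = acc_collection
    return compute_features(tables)


@pytest.fixture(scope="session")
def acc_census(acc_collection, acc_features):
    tables, _, catalog = acc_collection
    cfg = CensusConfig(seed_families=default_seed_families(catalog))
    return run_census(tables, cfg, acc_features, catalog)


@pytest.fixture(scope="session")
def acc_loci(acc_collection, acc_features, acc_census):
    """Classified loci of the default collection, keyed by genome."""
    tables, _, catalog = acc_collection
    templates = loci_mod.load_templates()
    by_genome = {
        g.genome_id: loci_mod.build_loci(
            g, acc_census.final_families, catalog, max_intervening=2
        )
        for g in tables
    }
    loci_mod.classify_all_loci(tables, by_genome, templates, acc_features, catalog)
    return by_genome


@pytest.fixture(scope="session")
def acc_pilin_calls(acc_collection, acc_features, acc_census, acc_loci):
    tables, _, _ = acc_collection
    all_loci = [l for ll in acc_loci.values() for l in ll]
    return pilins_mod.classify_census_families(
        acc_census.final_families, tables, all_loci, acc_features
    )


@pytest.fixture(scope="session")
def confusion_run():
    """Large panel (>200 planted loci) with census + classified loci."""
    params = syn.confusion_params(17)
    tables, truth, catalog = syn.generate_collection(params)
    features = compute_features(tables)
    cfg = CensusConfig(seed_families=default_seed_families(catalog))
    result = run_census(tables, cfg, features, catalog)
    templates = loci_mod.load_templates()
    by_genome = {
        g.genome_id: loci_mod.build_loci(g, result.final_families, catalog, 2)
        for g in tables
    }
    loci_mod.classify_all_loci(tables, by_genome, templates, features, catalog)
    return tables, truth, catalog, result, by_genome
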