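"""Iterative guilt-by-association census of pili-linked gene families.

Starting from seed families (the secretion ATPases, the one component every
system shares), the census repeatedly scans the gene-order neighborhoods
(window genes up- and downstream) of every gene of an accepted family and
accepts any family that shows up in such neighborhoods in at least
``min_genomes`` distinct genomes.  Three iterations of this expansion are
the default, after which sub-threshold neighborhood families ("candidates")
go through an automated stand-in for manual curation: a candidate is
accepted when its members are predicted secreted/membrane proteins, occur
(essentially) nowhere outside candidate loci, and share a predicted operon
with an accepted family.  Families whose catalog role is on the exclusion
list (S-layer proteins by default) are pulled out of the final set but kept
as "potential components", mirroring how such families are usually reported.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .features import ProteinFeatures
from .genome_io import FamilyCatalog, GenomeTable
from .loci import build_loci, predict_operons


class ConfigurationError(ValueError):
    """Invalid census configuration."""


#: Roles whose families make up the default seed set: the components of
#: pili/archaellum systems that are recognizable a priori (the energizing
#: ATPase, the TadC/FlaJ membrane platform, FlaH, the FleN/MinD regulatory
#: ATPase and the prepilin peptidases).  Seeding from every known component
#: family, not the ATPases alone, is what lets three expansion iterations
#: reach the far ends of the longest (~15 gene) loci.
DEFAULT_SEED_ROLES = frozenset(
    {
        "secretion_ATPase",
        "tadC",
        "flaH",
        "fleN_minD",
        "peptidase_5TM",
        "peptidase_9TM",
    }
)


def default_seed_families(catalog: "FamilyCatalog") -> set[str]:
    """Every catalog family whose role is a recognized system component."""
    return {
        fam
        for fam, info in catalog.entries.items()
        if info.role in DEFAULT_SEED_ROLES
    }


@dataclass
class CensusConfig:
    """Parameters of the iterative neighborhood census."""

    seed_families: set[str] = field(default_factory=set)
    window: int = 3
    min_genomes: int = 5
    iterations: int = 3
    exclusion_roles: set[str] = field(default_factory=lambda: {"s_layer"})
    context_exclusivity_min: float = 1.0
    curation_localization_min: float = 0.8
    max_intervening: int = 2
    operon_max_gap_bp: int = 100

    def validate(self) -> None:
        if not self.seed_families:
            raise ConfigurationError("seed_families must not be empty")
        if self.window < 1 or self.min_genomes < 1 or self.iterations < 1:
            raise ConfigurationError("window, min_genomes and iterations must be >= 1")
        if not 0.0 <= self.context_exclusivity_min <= 1.0:
            raise ConfigurationError("context_exclusivity_min must be in [0, 1]")


@dataclass
class CensusResult:
    accepted_families_by_iteration: list[set[str]]
    final_families: set[str]
    curated_additions: dict[str, str]  # family -> reason code
    excluded_families: dict[str, str]  # family -> reason code ("potential components")
    rejected_candidates: dict[str, str]
    protein_assignments: list[tuple[str, str, str]]  # genome_id, gene_id, family_id
    summary: dict


def _neighborhood_genome_counts(
    genomes: list[GenomeTable], current: set[str], window: int
) -> dict[str, set[str]]:
    """For each family: the set of genomes where it occurs within ``window``
    genes of a gene of a current family (deduplicated per genome)."""
    counts: dict[str, set[str]] = defaultdict(set)
    for genome in genomes:
        found: set[str] = set()
        for records in genome.contigs.values():
            n = len(records)
            for i, rec in enumerate(records):
                if rec.family_id in current:
                    for j in range(max(0, i - window), min(n, i + window + 1)):
                        fam = records[j].family_id
                        if fam is not None:
                            found.add(fam)
        for fam in found:
            counts[fam].add(genome.genome_id)
    return counts


def expand_once(
    genomes: list[GenomeTable],
    current: set[str],
    window: int = 3,
    min_genomes: int = 5,
) -> set[str]:
    """One iteration of neighborhood expansion.

    Returns ``current`` plus every family found in the window-neighborhood
    of a current-family gene in at least ``min_genomes`` distinct genomes.
    Occurrences are deduplicated per genome (the threshold counts genomes,
    not genes); genes without a family label are ignored.
    """
    if not current:
        raise ConfigurationError("current family set must not be empty")
    counts = _neighborhood_genome_counts(genomes, current, window)
    return current | {f for f, gs in counts.items() if len(gs) >= min_genomes}


def curate_candidates(
    candidates: set[str],
    genomes: list[GenomeTable],
    features: dict[tuple[str, str], ProteinFeatures],
    accepted: set[str],
    catalog: FamilyCatalog,
    context_exclusivity_min: float = 1.0,
    localization_min: float = 0.8,
    max_intervening: int = 2,
    operon_max_gap_bp: int = 100,
) -> tuple[dict[str, str], dict[str, str]]:
    """Automated curation of sub-threshold candidate families.

    A candidate is accepted iff (a) at least ``localization_min`` of its
    members are predicted secreted or membrane proteins, (b) the fraction of
    its members lying inside candidate loci is >= ``context_exclusivity_min``
    (the "never in a different gene context" rule), and (c) at least one
    member shares a predicted operon with a gene of an accepted family.
    Returns (accepted: family -> reason, rejected: family -> reason); reason
    codes record which clauses held, e.g. ``"loc=1.00,excl=1.00,operon=yes"``.
    """
    accepted_out: dict[str, str] = {}
    rejected: dict[str, str] = {}
    if not candidates:
        return accepted_out, rejected

    pool = accepted | candidates
    in_locus: dict[str, list[bool]] = defaultdict(list)
    localized: dict[str, list[bool]] = defaultdict(list)
    operonic: set[str] = set()

    for genome in genomes:
        loci = build_loci(genome, pool, catalog, max_intervening=max_intervening)
        covered: dict[str, set[int]] = defaultdict(set)
        for locus in loci:
            if not locus.is_standalone:
                covered[locus.contig_id].update(
                    range(locus.start_index, locus.end_index + 1)
                )
        blocks = predict_operons(genome, max_gap_bp=operon_max_gap_bp)
        block_of: dict[str, int] = {}
        for bi, block in enumerate(blocks):
            for gid in block:
                block_of[gid] = bi
        accepted_blocks = {
            block_of[rec.gene_id]
            for rec in genome.genes()
            if rec.family_id in accepted
        }
        for contig_id, records in genome.contigs.items():
            for i, rec in enumerate(records):
                fam = rec.family_id
                if fam not in candidates:
                    continue
                in_locus[fam].append(i in covered[contig_id])
                feats = features.get((genome.genome_id, rec.gene_id))
                localized[fam].append(
                    feats is not None and feats.localization in ("secreted", "membrane")
                )
                if block_of[rec.gene_id] in accepted_blocks:
                    operonic.add(fam)

    for fam in sorted(candidates):
        if not in_locus[fam]:
            rejected[fam] = "no_members"
            continue
        loc_frac = sum(localized[fam]) / len(localized[fam])
        excl_frac = sum(in_locus[fam]) / len(in_locus[fam])
        has_operon = fam in operonic
        reason = f"loc={loc_frac:.2f},excl={excl_frac:.2f},operon={'yes' if has_operon else 'no'}"
        if loc_frac >= localization_min and excl_frac >= context_exclusivity_min and has_operon:
            accepted_out[fam] = reason
        else:
            rejected[fam] = reason
    return accepted_out, rejected


def run_census(
    genomes: list[GenomeTable],
    config: CensusConfig,
    features: dict[tuple[str, str], ProteinFeatures],
    catalog: FamilyCatalog,
) -> CensusResult:
    """Full census: seeded expansion, curation, role exclusion, assignment."""
    config.validate()
    accepted = set(config.seed_families)
    by_iteration: list[set[str]] = []
    for _ in range(config.iterations):
        accepted = expand_once(genomes, accepted, config.window, config.min_genomes)
        by_iteration.append(set(accepted))

    # sub-threshold candidates seen in neighborhoods of the accepted set
    counts = _neighborhood_genome_counts(genomes, accepted, config.window)
    candidates = {f for f in counts if f not in accepted}
    curated, rejected = curate_candidates(
        candidates,
        genomes,
        features,
        accepted,
        catalog,
        context_exclusivity_min=config.context_exclusivity_min,
        localization_min=config.curation_localization_min,
        max_intervening=config.max_intervening,
        operon_max_gap_bp=config.operon_max_gap_bp,
    )
    final = accepted | set(curated)

    excluded: dict[str, str] = {}
    for fam in sorted(final):
        role = catalog.role_of(fam)
        if role in config.exclusion_roles and fam not in config.seed_families:
            excluded[fam] = f"role={role}"
    final -= set(excluded)

    assignments = [
        (g.genome_id, rec.gene_id, rec.family_id)
        for g in genomes
        for rec in g.genes()
        if rec.family_id in final
    ]
    n_hyp = sum(
        1
        for g in genomes
        for rec in g.genes()
        if rec.family_id in final
        and any(s in rec.product.lower() for s in ("hypothetical", "uncharacterized"))
    )
    summary = {
        "n_families": len(final),
        "n_proteins": len(assignments),
        "fraction_hypothetical": (n_hyp / len(assignments)) if assignments else 0.0,
        "n_curated": len(curated),
        "n_excluded": len(excluded),
    }
    return CensusResult(
        accepted_families_by_iteration=by_iteration,
        final_families=final,
        curated_additions=curated,
        excluded_families=excluded,
        rejected_candidates=rejected,
        protein_assignments=assignments,
        summary=summary,
    )


def count_t4p_per_genome(
    genomes: list[GenomeTable],
    atpase_families: set[str],
    distinct_families: bool = False,
) -> dict[str, int]:
    """Number of pili systems per genome, using secretion-ATPase genes as the
    proxy.  By default genes are counted (duplicated ATPase genes mark
    duplicated systems); ``distinct_families=True`` counts families instead."""
    out: dict[str, int] = {}
    for genome in genomes:
        hits = [rec.family_id for rec in genome.genes() if rec.family_id in atpase_families]
        out[genome.genome_id] = len(set(hits)) if distinct_families else len(hits)
    return out


def phyletic_matrix(genomes: list[GenomeTable], families: set[str]) -> pd.DataFrame:
    """Families x genomes occurrence-count matrix (gene counts per cell)."""
    fams = sorted(families)
    data = {}
    for genome in genomes:
        counts = Counter(
            rec.family_id for rec in genome.genes() if rec.family_id in families
        )
        data[genome.genome_id] = [counts.get(f, 0) for f in fams]
    return pd.DataFrame(data, index=fams)
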