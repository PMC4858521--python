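"""Operon prediction, locus assembly and architecture classification.

A locus is a maximal run of census-family genes separated by at most
``max_intervening`` non-census genes.  Each locus is scored against a library
of declarative architecture templates (role -> multiplicity-range
requirements plus forbidden roles); the library shipped as package data
covers the ten most abundant pili variants plus the archaellum.

Role counting is component-aware: a family carrying a component tag (e.g.
``flaI``) counts only under that tag, so generic pili templates cannot claim
archaellum parts and vice versa.  Major pilins are special: many systems
keep their major pilin genes elsewhere in the genome ("encoded in trans"),
so a major_pilin requirement with zero in-locus copies is satisfied whenever
the genome carries stand-alone major pilin genes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .genome_io import FamilyCatalog, GeneRecord, GenomeTable


@dataclass
class Locus:
    """A contiguous run of census genes on one contig."""

    genome_id: str
    contig_id: str
    start_index: int
    end_index: int
    gene_ids: list[str]
    families: list[str]
    roles_present: Counter = field(default_factory=Counter)
    classification: str = "unclassified"
    score: float = 0.0

    @property
    def is_standalone(self) -> bool:
        """Single-family groups are stand-alone genes, not loci."""
        return len(set(self.families)) <= 1


@dataclass(frozen=True)
class ArchitectureTemplate:
    """Declarative model of one system architecture."""

    name: str
    required: dict[str, tuple[int, int]]
    forbidden: frozenset[str] = frozenset()
    optional: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        overlap = set(self.required) & self.forbidden
        if overlap:
            raise ValueError(f"template {self.name}: roles {overlap} both required and forbidden")


def load_templates(path: str | Path | None = None) -> list[ArchitectureTemplate]:
    """Load the template library (shipped YAML by default)."""
    if path is None:
        text = resources.files("t4pcensus").joinpath("data/templates.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    templates = []
    for name, spec in raw["templates"].items():
        required = {
            role: (int(rng[0]), int(rng[1])) for role, rng in spec["required"].items()
        }
        templates.append(
            ArchitectureTemplate(
                name=name,
                required=required,
                forbidden=frozenset(spec.get("forbidden", [])),
                optional=frozenset(spec.get("optional", [])),
            )
        )
    return templates


def predict_operons(genome: GenomeTable, max_gap_bp: int = 100) -> list[list[str]]:
    """Partition each contig into predicted operons.

    An operon is a maximal run of same-strand genes whose intergenic
    distances are <= ``max_gap_bp``.  When coordinates are absent the
    fallback is same-strand adjacency in gene order.  Every gene belongs to
    exactly one block.
    """
    blocks: list[list[str]] = []
    for records in genome.contigs.values():
        current: list[str] = []
        prev: GeneRecord | None = None
        for rec in records:
            if prev is None:
                current = [rec.gene_id]
            else:
                same_strand = rec.strand == prev.strand
                if rec.start is not None and prev.end is not None:
                    close = (rec.start - prev.end - 1) <= max_gap_bp
                else:
                    close = True
                if same_strand and close:
                    current.append(rec.gene_id)
                else:
                    blocks.append(current)
                    current = [rec.gene_id]
            prev = rec
        if current:
            blocks.append(current)
    return blocks


def build_loci(
    genome: GenomeTable,
    final_families: set[str],
    catalog: FamilyCatalog,
    max_intervening: int = 2,
) -> list[Locus]:
    """Greedy left-to-right merge of census genes into loci.

    Census-family genes are joined into one locus while separated by at most
    ``max_intervening`` non-census genes; range endpoints are always census
    genes.  Single-family groups are flagged stand-alone (see
    ``Locus.is_standalone``); callers classify only true loci.
    """
    loci: list[Locus] = []
    for contig_id, records in genome.contigs.items():
        hits = [i for i, r in enumerate(records) if r.family_id in final_families]
        if not hits:
            continue
        group = [hits[0]]
        for i in hits[1:]:
            if i - group[-1] - 1 <= max_intervening:
                group.append(i)
            else:
                loci.append(_make_locus(genome, contig_id, records, group, catalog))
                group = [i]
        loci.append(_make_locus(genome, contig_id, records, group, catalog))
    return loci


def _make_locus(
    genome: GenomeTable,
    contig_id: str,
    records: list[GeneRecord],
    member_indices: list[int],
    catalog: FamilyCatalog,
) -> Locus:
    members = [records[i] for i in member_indices]
    roles = Counter(
        catalog.match_key(r.family_id)
        for r in members
        if catalog.match_key(r.family_id) != "unknown"
    )
    return Locus(
        genome_id=genome.genome_id,
        contig_id=contig_id,
        start_index=member_indices[0],
        end_index=member_indices[-1],
        gene_ids=[r.gene_id for r in members],
        families=[r.family_id for r in members],
        roles_present=roles,
    )


@dataclass(frozen=True)
class GenomeContext:
    """Genome-level facts a locus alone cannot see."""

    has_standalone_majors: bool = False


def classify_locus(
    locus: Locus,
    templates: list[ArchitectureTemplate],
    genome_context: GenomeContext | None = None,
    catalog: FamilyCatalog | None = None,
    score_threshold: float = 0.6,
) -> tuple[str, float]:
    """Score a locus against every template and return the best match.

    score(t) = satisfied required-role ranges / total required roles, minus
    1.0 (floored at 0) when any forbidden role is present.  Ties at the best
    score go to the more specific template (more required roles), then to the
    lexicographically smaller name.  Returns ("unclassified", best_score)
    when the best score is below ``score_threshold``.
    """
    context = genome_context or GenomeContext()
    member_roles = set(locus.roles_present)
    if catalog is not None:
        member_roles |= {
            catalog.role_of(f) for f in locus.families if catalog.role_of(f) != "unknown"
        }
    best: tuple[float, int, str] | None = None
    best_score = 0.0
    for t in templates:
        satisfied = 0
        for key, (lo, hi) in t.required.items():
            n = locus.roles_present.get(key, 0)
            if lo <= n <= hi:
                satisfied += 1
            elif key == "major_pilin" and n == 0 and context.has_standalone_majors:
                satisfied += 1  # majors encoded in trans
        score = satisfied / len(t.required)
        if t.forbidden & member_roles:
            score = max(0.0, score - 1.0)
        cand = (score, len(t.required), t.name)
        if best is None or (cand[0], cand[1], _neg_name(cand[2])) > (
            best[0],
            best[1],
            _neg_name(best[2]),
        ):
            best = cand
            best_score = score
    assert best is not None
    if best_score < score_threshold:
        return "unclassified", best_score
    return best[2], best_score


def _neg_name(name: str) -> tuple[int, ...]:
    # lexicographically *smaller* names win ties; invert for max() comparison
    return tuple(-ord(c) for c in name)


def standalone_major_context(
    genome: GenomeTable,
    loci: list[Locus],
    features: dict[tuple[str, str], "ProteinFeatures"],  # noqa: F821
    max_major_length: int = 160,
) -> GenomeContext:
    """Detect stand-alone major-pilin candidates: class III positive genes of
    mature length <= ``max_major_length`` lying outside every locus range."""
    covered: set[int] = set()
    for locus in loci:
        if not locus.is_standalone:
            contig_records = genome.contigs[locus.contig_id]
            covered.update(range(locus.start_index, locus.end_index + 1))
    for records in genome.contigs.values():
        for i, rec in enumerate(records):
            if i in covered or not rec.protein_seq:
                continue
            feats = features.get((genome.genome_id, rec.gene_id))
            if feats is None or not feats.is_class3:
                continue
            mature = len(rec.protein_seq) - (feats.signal.cleavage_pos or 0)
            if mature <= max_major_length:
                return GenomeContext(has_standalone_majors=True)
    return GenomeContext(has_standalone_majors=False)


def classify_all_loci(
    genomes: list[GenomeTable],
    loci_by_genome: dict[str, list[Locus]],
    templates: list[ArchitectureTemplate],
    features: dict[tuple[str, str], "ProteinFeatures"],  # noqa: F821
    catalog: FamilyCatalog,
    score_threshold: float = 0.6,
) -> None:
    """Classify every non-stand-alone locus in place."""
    by_id = {g.genome_id: g for g in genomes}
    for genome_id, loci in loci_by_genome.items():
        genome = by_id[genome_id]
        context = standalone_major_context(genome, loci, features)
        for locus in loci:
            if locus.is_standalone:
                locus.classification = "stand_alone"
                continue
            name, score = classify_locus(
                locus, templates, context, catalog, score_threshold
            )
            locus.classification = name
            locus.score = score


# ---------------------------------------------------------------------------
# Archaellum completeness
# ---------------------------------------------------------------------------

#: The archaellum's seven core components and their gene-count ranges:
#: single-copy FlaI (ATPase), FlaH, FlaJ (membrane platform) and the minor
#: archaellins FlaF and FlaG; 1-9 major archaellins; 1-3 FlaC/D/E genes
#: (C/D/E fusions count once per gene).
ARCHAELLUM_COMPONENTS: dict[str, tuple[int, int]] = {
    "flaI": (1, 1),
    "flaH": (1, 1),
    "flaJ": (1, 1),
    "flaF": (1, 1),
    "flaG": (1, 1),
    "archaellin": (1, 9),
    "flaCDE": (1, 3),
}


def check_archaellum_completeness(
    genome: GenomeTable,
    loci: list[Locus],
    catalog: FamilyCatalog,
) -> tuple[bool, set[str], dict[str, int]]:
    """Does this genome encode a complete archaellum?

    Counts genes per component across the whole genome: archaellins are
    frequently encoded away from the main locus as stand-alone genes, so
    genome-wide counting is the correct reading for every component.
    Returns (complete, missing-or-out-of-range components, multiplicities).
    """
    counts: dict[str, int] = {k: 0 for k in ARCHAELLUM_COMPONENTS}
    for rec in genome.genes():
        key = catalog.match_key(rec.family_id)
        if key in counts:
            counts[key] += 1
    bad = {
        k
        for k, (lo, hi) in ARCHAELLUM_COMPONENTS.items()
        if not lo <= counts[k] <= hi
    }
    return (not bad, bad, counts)


def loci_to_bed(loci: list[Locus], genomes: list[GenomeTable]) -> list[str]:
    """BED lines (0-based half-open) for loci whose genes carry coordinates."""
    by_id = {g.genome_id: g for g in genomes}
    lines = []
    for locus in loci:
        genome = by_id[locus.genome_id]
        records = genome.contigs[locus.contig_id]
        span = records[locus.start_index : locus.end_index + 1]
        starts = [r.start for r in span if r.start is not None]
        ends = [r.end for r in span if r.end is not None]
        if not starts:
            continue
        name = f"{locus.genome_id}:{locus.classification}"
        lines.append(f"{locus.contig_id}\t{min(starts) - 1}\t{max(ends)}\t{name}")
    return lines
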