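"""Major/minor pilin calling over census families.

The survey's discriminating cues, reduced to per-family evidence numbers:

* ``class3_fraction``   -- fraction of sequence-bearing members with a class
  III (prepilin) signal peptide; pilins of every kind carry one.
* ``median_mature_length`` -- median length after the predicted cleavage
  site (full length when none); major pilins are small, roughly 70 aa,
  while the recurring minor-pilin families run to several hundred aa.
* ``standalone_fraction`` -- fraction of members encoded outside every
  census locus; majors typically are stand-alone singletons or tandem genes.
* ``max_paralogs_per_genome`` -- majors are duplication-prone.

A family is a major pilin when it is class III positive (>= 0.8), short
(median mature length <= 160 aa) and either mostly stand-alone (>= 0.5) or
paralogous (>= 2 per genome somewhere); class III positive families failing
the major test are minor pilins; everything else is non-pilin.  Every census
family receives exactly one call.
"""

from __future__ import annotations

import statistics
from collections import defaultdict
from dataclasses import dataclass

from .features import ProteinFeatures
from .genome_io import GenomeTable, UnknownGeneError
from .loci import Locus


@dataclass(frozen=True)
class PilinEvidence:
    class3_fraction: float
    median_mature_length: int
    standalone_fraction: float
    max_paralogs_per_genome: int


@dataclass(frozen=True)
class PilinCall:
    family_id: str
    call: str  # major_pilin | minor_pilin | non_pilin
    evidence: PilinEvidence


def standalone_fraction(
    family_id: str,
    genomes: list[GenomeTable],
    loci: list[Locus],
) -> float:
    """Fraction of a family's members lying outside all census loci.

    Single-family groups (including tandem runs) count as stand-alone, so
    only multi-family loci cover their members.
    """
    covered: dict[tuple[str, str], set[int]] = defaultdict(set)
    for locus in loci:
        if not locus.is_standalone:
            covered[(locus.genome_id, locus.contig_id)].update(
                range(locus.start_index, locus.end_index + 1)
            )
    total = 0
    outside = 0
    for genome in genomes:
        for contig_id, records in genome.contigs.items():
            spans = covered[(genome.genome_id, contig_id)]
            for i, rec in enumerate(records):
                if rec.family_id == family_id:
                    total += 1
                    if i not in spans:
                        outside += 1
    if total == 0:
        raise UnknownGeneError(f"family {family_id!r} has no members")
    return outside / total


def compute_pilin_evidence(
    family_id: str,
    genomes: list[GenomeTable],
    loci: list[Locus],
    features: dict[tuple[str, str], ProteinFeatures],
) -> PilinEvidence:
    """Collect the four evidence numbers for one family."""
    class3 = []
    mature_lengths = []
    per_genome: dict[str, int] = defaultdict(int)
    for genome in genomes:
        for rec in genome.genes():
            if rec.family_id != family_id:
                continue
            per_genome[genome.genome_id] += 1
            if not rec.protein_seq:
                continue
            feats = features.get((genome.genome_id, rec.gene_id))
            is3 = feats is not None and feats.is_class3
            class3.append(is3)
            if is3 and feats.signal.cleavage_pos is not None:
                mature_lengths.append(len(rec.protein_seq) - feats.signal.cleavage_pos)
            else:
                mature_lengths.append(len(rec.protein_seq))
    if not per_genome:
        raise UnknownGeneError(f"family {family_id!r} has no members")
    return PilinEvidence(
        class3_fraction=(sum(class3) / len(class3)) if class3 else 0.0,
        median_mature_length=int(statistics.median(mature_lengths)) if mature_lengths else 0,
        standalone_fraction=standalone_fraction(family_id, genomes, loci),
        max_paralogs_per_genome=max(per_genome.values()),
    )


def classify_pilin_family(
    family_id: str,
    evidence: PilinEvidence,
    class3_min: float = 0.8,
    major_max_length: int = 160,
    standalone_min: float = 0.5,
    paralog_min: int = 2,
) -> PilinCall:
    """Apply the major/minor/non-pilin decision rule to one family."""
    if evidence.class3_fraction >= class3_min:
        if evidence.median_mature_length <= major_max_length and (
            evidence.standalone_fraction >= standalone_min
            or evidence.max_paralogs_per_genome >= paralog_min
        ):
            call = "major_pilin"
        else:
            call = "minor_pilin"
    else:
        call = "non_pilin"
    return PilinCall(family_id=family_id, call=call, evidence=evidence)


def classify_census_families(
    families: set[str],
    genomes: list[GenomeTable],
    loci: list[Locus],
    features: dict[tuple[str, str], ProteinFeatures],
    **thresholds,
) -> dict[str, PilinCall]:
    """One PilinCall per census family (a partition of the family set)."""
    return {
        fam: classify_pilin_family(
            fam,
            compute_pilin_evidence(fam, genomes, loci, features),
            **thresholds,
        )
        for fam in sorted(families)
    }
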