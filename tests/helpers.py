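"""Small builders shared by the test modules."""

from __future__ import annotations

import numpy as np

from t4pcensus.genome_io import FamilyCatalog, FamilyInfo, GeneRecord, GenomeTable


def make_genome(
    genome_id: str,
    families: list[str | None],
    contig_id: str = "c1",
    strands: list[str] | None = None,
    gaps: list[int] | None = None,
    seqs: list[str | None] | None = None,
    products: list[str] | None = None,
    gene_len: int = 300,
) -> GenomeTable:
    """One-contig genome from a list of family labels.

    ``gaps[i]`` is the intergenic distance before gene i (default 300, i.e.
    every gene its own operon under the 100 bp rule).
    """
    n = len(families)
    strands = strands or ["+"] * n
    gaps = gaps or [300] * n
    seqs = seqs or [None] * n
    products = products or [""] * n
    records = []
    pos = 0
    for i in range(n):
        start = pos + gaps[i]
        end = start + gene_len - 1
        pos = end
        records.append(
            GeneRecord(
                genome_id=genome_id,
                contig_id=contig_id,
                order_index=i,
                gene_id=f"{genome_id}_g{i}",
                strand=strands[i],
                start=start,
                end=end,
                family_id=families[i],
                product=products[i],
                protein_seq=seqs[i],
            )
        )
    return GenomeTable(genome_id=genome_id, contigs={contig_id: records})


def catalog_from_roles(roles: dict[str, str]) -> FamilyCatalog:
    return FamilyCatalog({f: FamilyInfo(role=r) for f, r in roles.items()})


def random_collection(
    rng: np.random.Generator,
    n_genomes: int,
    genes_per_genome: int,
    n_families: int,
    seed_family: str = "SEED",
) -> list[GenomeTable]:
    """Random family layouts (no sequences) for census oracle checks.

    Every genome gets at least one seed gene; the rest draw uniformly from a
    small family pool so that neighborhood overlaps arise by chance.
    """
    genomes = []
    for g in range(n_genomes):
        fams: list[str | None] = [
            f"F{int(rng.integers(n_families))}" for _ in range(genes_per_genome)
        ]
        for _ in range(int(rng.integers(1, 3))):
            fams[int(rng.integers(genes_per_genome))] = seed_family
        if rng.random() < 0.2:  # some unlabeled genes
            fams[int(rng.integers(genes_per_genome))] = None
        genomes.append(make_genome(f"g{g}", fams))
    return genomes


def brute_force_census(
    genomes: list[GenomeTable],
    seeds: set[str],
    window: int,
    min_genomes: int,
    iterations: int,
) -> set[str]:
    """Independent re-statement of the iterated expansion as a set
    comprehension over all (gene, neighbor) index pairs."""
    current = set(seeds)
    for _ in range(iterations):
        genome_hits: dict[str, set[str]] = {}
        for genome in genomes:
            for records in genome.contigs.values():
                for i, x in enumerate(records):
                    for j, y in enumerate(records):
                        if (
                            abs(i - j) <= window
                            and x.family_id in current
                            and y.family_id is not None
                        ):
                            genome_hits.setdefault(y.family_id, set()).add(
                                genome.genome_id
                            )
        current = current | {
            f for f, gs in genome_hits.items() if len(gs) >= min_genomes
        }
    return current
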