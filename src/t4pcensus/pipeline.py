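"""End-to-end orchestration: input -> features -> census -> pilins -> loci.

``run_pipeline`` drives every stage in order, writes the result tables
(families, assignments, phyletic matrix, pilin calls, loci, classification)
plus a JSON summary, and records a MANIFEST with a content hash per
artifact so reruns can be verified byte for byte.  All randomness flows
from the single ``rng_seed`` in the configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import census as census_mod
from . import loci as loci_mod
from . import pilins as pilins_mod
from . import synthetic as synthetic_mod
from .features import compute_features
from .genome_io import FamilyCatalog, GenomeTable, read_gene_table, write_gene_table

log = logging.getLogger("t4pcensus")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Exactly one input source: a gene-table TSV, or synthetic parameters."""

    gene_table: str | None = None
    catalog_path: str | None = None
    synthetic: synthetic_mod.GeneratorParams | None = None
    census: census_mod.CensusConfig = field(default_factory=census_mod.CensusConfig)
    template_library: str | None = None
    outdir: str = "t4pcensus_out"
    rng_seed: int = 17

    def validate(self) -> None:
        sources = [s for s in (self.gene_table, self.synthetic) if s is not None]
        if len(sources) != 1:
            raise census_mod.ConfigurationError(
                "exactly one input source (gene_table or synthetic) is required"
            )
        if self.gene_table is not None and self.catalog_path is None:
            raise census_mod.ConfigurationError(
                "a family catalog is required with gene-table input"
            )


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the run report (also written as JSON)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    stage = "setup"
    try:
        # ---------------- input ----------------
        stage = "input"
        if config.synthetic is not None:
            params = config.synthetic
            params.rng_seed = config.rng_seed
            genomes, truth, catalog = synthetic_mod.generate_collection(params)
            write_gene_table(genomes, outdir / "genes.tsv")
            catalog.write_tsv(outdir / "catalog.tsv")
            artifacts += [outdir / "genes.tsv", outdir / "catalog.tsv"]
        else:
            genomes = read_gene_table(config.gene_table)
            catalog = FamilyCatalog.read_tsv(config.catalog_path)
        log.info("input: %d genomes, %d genes", len(genomes), sum(g.n_genes for g in genomes))

        # ---------------- features ----------------
        stage = "features"
        features = compute_features(genomes)
        log.info("features: %d proteins scored", len(features))

        # ---------------- census ----------------
        stage = "census"
        cfg = config.census
        if not cfg.seed_families:
            # the catalog may describe families absent from this collection
            present = {r.family_id for g in genomes for r in g.genes() if r.family_id}
            cfg.seed_families = census_mod.default_seed_families(catalog) & present
        result = census_mod.run_census(genomes, cfg, features, catalog)
        log.info(
            "census: %d families, %d assignments (per iteration: %s)",
            result.summary["n_families"],
            result.summary["n_proteins"],
            [len(s) for s in result.accepted_families_by_iteration],
        )
        _write_tsv(
            outdir / "families.tsv",
            ["family_id", "role", "clade_label", "status", "reason"],
            [
                [f, catalog.role_of(f), catalog[f].clade_label or "",
                 "curated" if f in result.curated_additions else "accepted",
                 result.curated_additions.get(f, "")]
                for f in sorted(result.final_families)
            ]
            + [
                [f, catalog.role_of(f), catalog[f].clade_label or "", "excluded", why]
                for f, why in sorted(result.excluded_families.items())
            ],
        )
        _write_tsv(
            outdir / "assignments.tsv",
            ["genome_id", "gene_id", "family_id"],
            [list(t) for t in sorted(result.protein_assignments)],
        )
        matrix = census_mod.phyletic_matrix(genomes, result.final_families)
        matrix.loc["TOTAL"] = matrix.sum()
        matrix["TOTAL"] = matrix.sum(axis=1)
        matrix.to_csv(outdir / "phyletic.tsv", sep="\t", index_label="family_id")
        artifacts += [outdir / "families.tsv", outdir / "assignments.tsv", outdir / "phyletic.tsv"]

        # ---------------- loci ----------------
        stage = "loci"
        templates = loci_mod.load_templates(config.template_library)
        loci_by_genome = {
            g.genome_id: loci_mod.build_loci(
                g, result.final_families, catalog, cfg.max_intervening
            )
            for g in genomes
        }
        loci_mod.classify_all_loci(
            genomes, loci_by_genome, templates, features, catalog
        )
        all_loci = [l for ll in loci_by_genome.values() for l in ll]

        # ---------------- pilin calls ----------------
        stage = "pilin_calls"
        calls = pilins_mod.classify_census_families(
            result.final_families, genomes, all_loci, features
        )
        _write_tsv(
            outdir / "pilin_calls.tsv",
            ["family_id", "call", "class3_fraction", "median_mature_length",
             "standalone_fraction", "max_paralogs_per_genome"],
            [
                [f, c.call, f"{c.evidence.class3_fraction:.3f}",
                 c.evidence.median_mature_length,
                 f"{c.evidence.standalone_fraction:.3f}",
                 c.evidence.max_paralogs_per_genome]
                for f, c in sorted(calls.items())
            ],
        )
        _write_tsv(
            outdir / "loci.tsv",
            ["genome_id", "contig_id", "start_index", "end_index", "n_genes",
             "classification", "score", "families"],
            [
                [l.genome_id, l.contig_id, l.start_index, l.end_index,
                 len(l.gene_ids), l.classification, f"{l.score:.3f}",
                 ",".join(l.families)]
                for l in all_loci
            ],
        )
        with open(outdir / "loci.bed", "w") as fh:
            for line in loci_mod.loci_to_bed(
                [l for l in all_loci if not l.is_standalone], genomes
            ):
                fh.write(line + "\n")
        artifacts += [outdir / "pilin_calls.tsv", outdir / "loci.tsv", outdir / "loci.bed"]

        # ---------------- summary ----------------
        stage = "summary"
        atpase = catalog.families_with_role("secretion_ATPase")
        t4p_counts = census_mod.count_t4p_per_genome(genomes, atpase & result.final_families)
        per_template: dict[str, int] = {}
        for locus in all_loci:
            if not locus.is_standalone:
                per_template[locus.classification] = (
                    per_template.get(locus.classification, 0) + 1
                )
        report = {
            "n_genomes": len(genomes),
            "n_families": result.summary["n_families"],
            "n_proteins": result.summary["n_proteins"],
            "fraction_hypothetical": round(result.summary["fraction_hypothetical"], 4),
            "n_curated": result.summary["n_curated"],
            "n_excluded": result.summary["n_excluded"],
            "per_genome_t4p_counts": dict(sorted(t4p_counts.items())),
            "per_template_locus_counts": dict(sorted(per_template.items())),
            "rng_seed": config.rng_seed,
        }
        with open(outdir / "summary.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        artifacts.append(outdir / "summary.json")
    except Exception as exc:
        _write_manifest(outdir, artifacts, complete=False)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    _write_manifest(outdir, artifacts, complete=True)
    return report


def _write_manifest(outdir: Path, artifacts: list[Path], complete: bool) -> None:
    with open(outdir / "MANIFEST", "w") as fh:
        fh.write(f"status\t{'complete' if complete else 'INCOMPLETE'}\n")
        for path in artifacts:
            if path.exists():
                fh.write(f"{path.name}\t{_sha256(path)}\n")
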