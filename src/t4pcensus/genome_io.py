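"""Gene tables, family catalogs and gene-order neighborhoods.

The substrate of the whole census is the ordered gene table: one record per
gene, ordered along each contig, with an orthologous-family label (arCOG-like)
attached where one is known.  "Neighborhood" is defined on gene order, not on
nucleotide distance -- the census counts genes up- and downstream of a focal
gene, so coordinates are optional and are only consumed by operon prediction.

Two input dialects are supported: a flat TSV (one gene per row, see
``TSV_COLUMNS``) and GFF3 + protein FASTA pairs.  Coordinates are 1-based
inclusive (GFF3 convention); ``order_index`` is 0-based and consecutive within
each contig.  Contigs are linear: neighborhoods truncate at contig ends and
never cross contigs.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

ROLES = frozenset(
    {
        "secretion_ATPase",
        "tadC",
        "flaH",
        "fleN_minD",
        "major_pilin",
        "minor_pilin",
        "archaellin",
        "peptidase_5TM",
        "peptidase_9TM",
        "adhesin",
        "s_layer",
        "membrane_accessory",
        "cytoplasmic_accessory",
        "regulator",
        "unknown",
    }
)

TSV_COLUMNS = [
    "genome_id",
    "lineage",
    "contig_id",
    "order_index",
    "gene_id",
    "strand",
    "start",
    "end",
    "family_id",
    "product",
    "protein_seq",
]


class GeneTableFormatError(ValueError):
    """Structural problem in an input file (bad header, ragged rows)."""


class GeneTableValidationError(ValueError):
    """A row violates a gene-table invariant; message cites line/gene."""


class UnknownGeneError(KeyError):
    """Lookup of a gene_id that is not present in the table."""


@dataclass
class GeneRecord:
    """One gene in a genome, addressed by its position in gene order."""

    genome_id: str
    contig_id: str
    order_index: int
    gene_id: str
    strand: str
    start: int | None = None
    end: int | None = None
    family_id: str | None = None
    product: str = ""
    protein_seq: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GeneTableValidationError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if (self.start is None) != (self.end is None):
            raise GeneTableValidationError(
                f"gene {self.gene_id!r}: start and end must both be present or both absent"
            )
        if self.start is not None and self.start > self.end:  # type: ignore[operator]
            raise GeneTableValidationError(
                f"gene {self.gene_id!r}: start ({self.start}) > end ({self.end})"
            )


@dataclass
class GenomeTable:
    """All genes of one genome, grouped by contig and sorted by gene order."""

    genome_id: str
    lineage: list[str] = field(default_factory=list)
    contigs: dict[str, list[GeneRecord]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index: dict[str, tuple[str, int]] = {}
        self.reindex()

    def reindex(self) -> None:
        """Sort contigs by order_index, renumber 0..n-1, rebuild gene lookup."""
        self._index = {}
        for contig_id, records in self.contigs.items():
            records.sort(key=lambda r: r.order_index)
            for i, rec in enumerate(records):
                rec.order_index = i
                if rec.genome_id != self.genome_id:
                    raise GeneTableValidationError(
                        f"gene {rec.gene_id!r} carries genome_id {rec.genome_id!r}, "
                        f"expected {self.genome_id!r}"
                    )
                if rec.gene_id in self._index:
                    raise GeneTableValidationError(
                        f"duplicate gene_id {rec.gene_id!r} in genome {self.genome_id!r}"
                    )
                self._index[rec.gene_id] = (contig_id, i)

    def genes(self) -> Iterator[GeneRecord]:
        for records in self.contigs.values():
            yield from records

    @property
    def n_genes(self) -> int:
        return sum(len(r) for r in self.contigs.values())

    def get(self, gene_id: str) -> GeneRecord:
        try:
            contig_id, i = self._index[gene_id]
        except KeyError:
            raise UnknownGeneError(
                f"gene {gene_id!r} not found in genome {self.genome_id!r}"
            ) from None
        return self.contigs[contig_id][i]

    def locate(self, gene_id: str) -> tuple[str, int]:
        """Return (contig_id, order_index) for a gene."""
        try:
            return self._index[gene_id]
        except KeyError:
            raise UnknownGeneError(
                f"gene {gene_id!r} not found in genome {self.genome_id!r}"
            ) from None


def neighborhood(genome: GenomeTable, gene_id: str, window: int) -> list[GeneRecord]:
    """Genes within ``window`` positions of the focal gene on its contig.

    Returns up to ``2*window + 1`` records including the focal gene,
    truncated at contig ends.  Never crosses contigs.  The focal strand does
    not reorient the result.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    contig_id, i = genome.locate(gene_id)
    records = genome.contigs[contig_id]
    return records[max(0, i - window) : i + window + 1]


# ---------------------------------------------------------------------------
# Family catalog
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FamilyInfo:
    """Role annotation for one family.

    ``component`` is an optional tag finer than ``role`` (e.g. ``flaI`` on a
    secretion_ATPase family) used by architecture templates that must
    distinguish individual archaellum components.
    """

    role: str = "unknown"
    clade_label: str | None = None
    component: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")


class FamilyCatalog:
    """Mapping family_id -> role annotation; unlisted families are unknown."""

    def __init__(self, entries: Mapping[str, FamilyInfo] | None = None) -> None:
        self.entries: dict[str, FamilyInfo] = dict(entries or {})

    def __contains__(self, family_id: str) -> bool:
        return family_id in self.entries

    def __getitem__(self, family_id: str) -> FamilyInfo:
        return self.entries.get(family_id, FamilyInfo())

    def role_of(self, family_id: str | None) -> str:
        if family_id is None:
            return "unknown"
        return self[family_id].role

    def match_key(self, family_id: str | None) -> str:
        """The key a gene of this family contributes to locus role counting.

        A family with a component tag counts only under its component
        (``flaI`` genes do not satisfy a generic ``secretion_ATPase``
        requirement); otherwise the coarse role is used.
        """
        if family_id is None:
            return "unknown"
        info = self[family_id]
        return info.component if info.component is not None else info.role

    def families_with_role(self, role: str) -> set[str]:
        return {f for f, info in self.entries.items() if info.role == role}

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["family_id", "role", "clade_label", "component"])
            for fam in sorted(self.entries):
                info = self.entries[fam]
                w.writerow([fam, info.role, info.clade_label or "", info.component or ""])

    @classmethod
    def read_tsv(cls, path: str | Path) -> "FamilyCatalog":
        entries: dict[str, FamilyInfo] = {}
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                entries[row["family_id"]] = FamilyInfo(
                    role=row.get("role") or "unknown",
                    clade_label=row.get("clade_label") or None,
                    component=row.get("component") or None,
                )
        return cls(entries)


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------


def _parse_optional_int(value: str, what: str, line_no: int) -> int | None:
    if value == "":
        return None
    try:
        return int(value)
    except ValueError:
        raise GeneTableValidationError(
            f"line {line_no}: {what} must be an integer, got {value!r}"
        ) from None


def read_gene_table(path: str | Path, dialect: str = "tsv") -> list[GenomeTable]:
    """Read a gene-table TSV into one GenomeTable per genome.

    Empty string means "absent".  order_index is re-normalized per contig.
    Malformed rows raise with the offending line number; a duplicate gene_id
    raises naming the id.
    """
    if dialect != "tsv":
        raise ValueError(f"unsupported dialect {dialect!r}")
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise GeneTableFormatError(f"{path}: empty file") from None
        if header != TSV_COLUMNS:
            missing = set(TSV_COLUMNS) - set(header)
            raise GeneTableFormatError(
                f"{path}: bad header; missing columns {sorted(missing)}"
                if missing
                else f"{path}: bad header {header!r}"
            )
        genomes: dict[str, GenomeTable] = {}
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(TSV_COLUMNS):
                raise GeneTableFormatError(
                    f"{path}: line {line_no}: expected {len(TSV_COLUMNS)} fields, got {len(row)}"
                )
            vals = dict(zip(TSV_COLUMNS, row))
            if vals["strand"] not in ("+", "-"):
                raise GeneTableValidationError(
                    f"{path}: line {line_no}: strand must be '+' or '-', got {vals['strand']!r}"
                )
            try:
                rec = GeneRecord(
                    genome_id=vals["genome_id"],
                    contig_id=vals["contig_id"],
                    order_index=int(vals["order_index"]),
                    gene_id=vals["gene_id"],
                    strand=vals["strand"],
                    start=_parse_optional_int(vals["start"], "start", line_no),
                    end=_parse_optional_int(vals["end"], "end", line_no),
                    family_id=vals["family_id"] or None,
                    product=vals["product"],
                    protein_seq=vals["protein_seq"] or None,
                )
            except GeneTableValidationError as exc:
                raise GeneTableValidationError(f"{path}: line {line_no}: {exc}") from None
            table = genomes.get(rec.genome_id)
            if table is None:
                lineage = [t for t in vals["lineage"].split(";") if t]
                table = GenomeTable(genome_id=rec.genome_id, lineage=lineage, contigs={})
                genomes[rec.genome_id] = table
            table.contigs.setdefault(rec.contig_id, []).append(rec)
    for table in genomes.values():
        table.reindex()
    return list(genomes.values())


def write_gene_table(tables: Iterable[GenomeTable], path: str | Path) -> None:
    """Serialize genome tables to the TSV dialect (inverse of read_gene_table)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(TSV_COLUMNS)
        for table in tables:
            lineage = ";".join(table.lineage)
            for contig_id in table.contigs:
                for rec in table.contigs[contig_id]:
                    w.writerow(
                        [
                            table.genome_id,
                            lineage,
                            contig_id,
                            rec.order_index,
                            rec.gene_id,
                            rec.strand,
                            "" if rec.start is None else rec.start,
                            "" if rec.end is None else rec.end,
                            rec.family_id or "",
                            rec.product,
                            rec.protein_seq or "",
                        ]
                    )


# ---------------------------------------------------------------------------
# GFF3 + protein FASTA
# ---------------------------------------------------------------------------


def read_gff_fasta(
    gff_path: str | Path,
    fasta_path: str | Path,
    genome_id: str | None = None,
    family_attr: str = "family",
    lineage: list[str] | None = None,
) -> GenomeTable:
    """Build a GenomeTable from a GFF3 file plus a protein FASTA.

    CDS features are used (falling back to gene features when no CDS is
    present); genes are ordered by start coordinate per contig and
    order_index assigned from that ordering.  The family label is taken from
    the GFF attribute named by ``family_attr``.  FASTA records whose id does
    not match any feature are dropped with a warning.
    """
    import gffutils
    from Bio import SeqIO

    gff_path = Path(gff_path)
    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    feature_types = ["CDS"] if any(True for _ in db.features_of_type("CDS")) else ["gene"]
    if genome_id is None:
        genome_id = gff_path.stem

    proteins: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        proteins[rec.id] = str(rec.seq)

    contigs: dict[str, list[GeneRecord]] = {}
    seen_ids: set[str] = set()
    for feat in db.features_of_type(feature_types):
        gid = feat.attributes.get("ID", [feat.id])[0]
        family = feat.attributes.get(family_attr, [None])[0]
        product = feat.attributes.get("product", [""])[0]
        contigs.setdefault(feat.seqid, []).append(
            GeneRecord(
                genome_id=genome_id,
                contig_id=feat.seqid,
                order_index=0,
                gene_id=gid,
                strand=feat.strand if feat.strand in ("+", "-") else "+",
                start=feat.start,
                end=feat.end,
                family_id=family,
                product=product,
                protein_seq=proteins.get(gid),
            )
        )
        seen_ids.add(gid)

    orphans = set(proteins) - seen_ids
    if orphans:
        warnings.warn(
            f"{fasta_path}: {len(orphans)} FASTA ids absent from GFF; sequences dropped",
            stacklevel=2,
        )

    for contig_id, records in contigs.items():
        records.sort(key=lambda r: (r.start, r.gene_id))
        for i, rec in enumerate(records):
            rec.order_index = i
    return GenomeTable(genome_id=genome_id, lineage=lineage or [], contigs=contigs)


def write_gff_fasta(
    table: GenomeTable,
    gff_path: str | Path,
    fasta_path: str | Path,
    family_attr: str = "family",
) -> None:
    """Emit a GFF3 + protein FASTA pair (inverse of read_gff_fasta).

    Requires coordinates on every gene.
    """
    with open(gff_path, "w") as gff:
        gff.write("##gff-version 3\n")
        for contig_id in table.contigs:
            for rec in table.contigs[contig_id]:
                if rec.start is None:
                    raise GeneTableValidationError(
                        f"gene {rec.gene_id!r}: GFF export requires coordinates"
                    )
                attrs = [f"ID={rec.gene_id}"]
                if rec.family_id:
                    attrs.append(f"{family_attr}={rec.family_id}")
                if rec.product:
                    attrs.append(f"product={rec.product}")
                gff.write(
                    "\t".join(
                        [
                            contig_id,
                            "t4pcensus",
                            "CDS",
                            str(rec.start),
                            str(rec.end),
                            ".",
                            rec.strand,
                            "0",
                            ";".join(attrs),
                        ]
                    )
                    + "\n"
                )
    with open(fasta_path, "w") as fa:
        for rec in table.genes():
            if rec.protein_seq:
                fa.write(f">{rec.gene_id}\n{rec.protein_seq}\n")


def copy_table(table: GenomeTable) -> GenomeTable:
    """Deep-enough copy for tests and round-trip comparisons."""
    return GenomeTable(
        genome_id=table.genome_id,
        lineage=list(table.lineage),
        contigs={c: [replace(r) for r in recs] for c, recs in table.contigs.items()},
    )
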