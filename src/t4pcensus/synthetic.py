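"""Synthetic genome collections with planted pili/archaellum loci.

The generator emulates a multi-genome survey panel: each genome is a single
linear contig of background genes (family labels drawn Zipf-like from a
shared pool, so some background families recur across genomes and exercise
the census's genome-count threshold) into which complete secretion-system
loci are planted according to an architecture plan.  Eleven locus recipes are
shipped, one per architecture template: the complex clade-1 pili system, the
seven-component archaellum, the two euryarchaeal pili variants, and the
crenarchaeal variants (4B/4C/4D/4E/4F/4G plus the simple
Sulfolobales/Desulfurococcales layout).

Protein sequences are emitted from two fixed composition profiles
(hydrophobic-enriched vs hydrophilic-enriched) so that the package's own
feature detectors succeed or fail *by construction*: pilins carry class III
leaders, membrane components carry well-separated TM segments, and
background proteins contain neither a hydrophobic window nor a cleavable
motif.  Every planted locus and every stand-alone pilin group is flanked by
three genome-private background genes, which guarantees that no recurring
background family ever sits inside a census neighborhood in several genomes.

Ground truth (planted ranges, family roles, per-genome system counts, the
operon plan) is returned alongside the tables so that every downstream stage
can be tested as a recovery problem.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genome_io import FamilyCatalog, FamilyInfo, GeneRecord, GenomeTable


class ParameterError(ValueError):
    """Invalid generator parameters."""


# ---------------------------------------------------------------------------
# Residue pools
# ---------------------------------------------------------------------------

#: Strongly hydrophobic residues (KD >= 3.8) used inside TM segments.
HYDROPHOBIC_TM = "IVL"
#: Hydrophobic residues used in signal-peptide cores (KD >= 2.8).
HYDROPHOBIC_CORE = "IVLF"
#: Strongly hydrophilic residues (KD <= -3.5) used between TM segments.
STRICT_HYDROPHILIC = "DEKRNQ"
#: General hydrophilic pool for soluble stretches; every member has a
#: negative hydropathy, so no window over this pool can look like a TM
#: segment or a signal core.
BROAD_HYDROPHILIC = "DEKRNQSTGHP"

#: TM segment length used by the emitter (one membrane-spanning helix).
TM_SEGMENT_LEN = 21
#: Minimum hydrophilic spacing between emitted segments; chosen so the
#: hydropathy caller can never merge two adjacent segments.
TM_MIN_SPACING = 25

#: Shipped peptidase topology templates: 1-based segment start positions and
#: total protein length.  The PibD/FlaK subfamily spans the membrane five
#: times, the EppA subfamily nine times.
PIBD_TOPOLOGY: tuple[int, ...] = (8, 54, 100, 146, 192)
PIBD_LENGTH = 230
EPPA_TOPOLOGY: tuple[int, ...] = (8, 54, 100, 146, 192, 238, 284, 330, 376)
EPPA_LENGTH = 415


def _draw(rng: np.random.Generator, pool: str, n: int) -> str:
    return "".join(rng.choice(list(pool), size=n))


def emit_tm_protein(
    topology: Sequence[int], length: int, rng: np.random.Generator
) -> str:
    """Emit a protein with hydrophobic 21-mers at the requested positions.

    ``topology`` lists 1-based start positions of the TM segments.  The rest
    of the chain is strongly hydrophilic, so the hydropathy TM caller
    recovers exactly ``len(topology)`` segments.  Raises ParameterError when
    the packing is infeasible (overlap, spacing < 25, or overflow).
    """
    starts = sorted(int(s) for s in topology)
    for i, s in enumerate(starts):
        if s < 1:
            raise ParameterError(f"segment start {s} < 1")
        if s + TM_SEGMENT_LEN - 1 > length:
            raise ParameterError(
                f"segment at {s} overflows protein of length {length}"
            )
        if i and s - (starts[i - 1] + TM_SEGMENT_LEN) < TM_MIN_SPACING:
            raise ParameterError(
                f"segments at {starts[i - 1]} and {s} are closer than "
                f"{TM_MIN_SPACING} residues"
            )
    chars = list(_draw(rng, STRICT_HYDROPHILIC, length))
    for s in starts:
        chars[s - 1 : s - 1 + TM_SEGMENT_LEN] = _draw(rng, HYDROPHOBIC_TM, TM_SEGMENT_LEN)
    return "".join(chars)


def emit_prepilin(mature_length: int, rng: np.random.Generator) -> str:
    """Emit a protein with a class III (prepilin) signal peptide.

    Layout: Met, a 2-8 residue positively charged tract, a [KR]G cleavage
    motif, a 20-24 residue hydrophobic tract, then a hydrophilic remainder.
    The mature part (everything after the G) has ``mature_length`` residues.
    Detection by the class III scanner is guaranteed by construction: the
    leader contains no glycine before the motif, the prefix net charge is
    always positive, and the 20 residues after the G are all hydrophobic.
    """
    if mature_length < 30:
        raise ParameterError("mature_length must be >= 30")
    tract_len = int(rng.integers(2, 9))
    tract = "".join(
        rng.choice(list("KR")) if rng.random() < 0.7 else rng.choice(list("ST"))
        for _ in range(tract_len)
    )
    motif = str(rng.choice(["KG", "RG"]))
    hyd_len = int(rng.integers(20, min(25, mature_length - 5)))
    hydrophobic = _draw(rng, HYDROPHOBIC_CORE, hyd_len)
    tail = _draw(rng, BROAD_HYDROPHILIC, mature_length - hyd_len)
    return "M" + tract + motif + hydrophobic + tail


def emit_sec_protein(length: int, rng: np.random.Generator) -> str:
    """Emit a secreted protein with a plain (sec-like) signal peptide.

    The leader has no basic residue, so the class III scanner can never fire;
    the 10-residue hydrophobic core makes the sec-like fallback fire always.
    """
    if length < 45:
        raise ParameterError("length must be >= 45")
    core = _draw(rng, HYDROPHOBIC_CORE, 10)
    return "M" + _draw(rng, "ST", 2) + core + _draw(rng, BROAD_HYDROPHILIC, length - 13)


def emit_cytoplasmic(length: int, rng: np.random.Generator) -> str:
    """Emit a soluble protein with no signal peptide and no TM segment."""
    if length < 45:
        raise ParameterError("length must be >= 45")
    return "M" + _draw(rng, BROAD_HYDROPHILIC, length - 1)


# ---------------------------------------------------------------------------
# Locus recipes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Slot:
    """One family slot of a locus recipe.

    ``count`` is the inclusive range of gene copies planted per locus; copies
    beyond the first are placed adjacently (tandem paralogs).
    """

    family: str
    role: str
    emit: str  # cyto | tm1 | tm2 | tm3 | tm4 | tm5 | tm9 | slayer | prepilin_major | prepilin_minor | prepilin_archaellin | sec_large
    product: str
    count: tuple[int, int] = (1, 1)
    component: str | None = None


# Gene order within each recipe is deliberate: major-pilin slots and S-layer
# slots sit in the locus interior, never at an endpoint, so that a family the
# census later drops (S-layer by role; majors below the genome threshold)
# leaves the recoverable locus range intact.
_RECIPES: dict[str, list[Slot]] = {
    "clade1": [
        Slot("c1_atpase", "secretion_ATPase", "cyto", "type IV pili assembly ATPase, VirB11 family"),
        Slot("c1_major1", "major_pilin", "prepilin_major", "type IV major pilin"),
        Slot("c1_tadc1", "tadC", "tm3", "TadC-like membrane platform protein"),
        Slot("c1_tadc2", "tadC", "tm3", "TadC-like membrane platform protein"),
        Slot("c1_eppA", "peptidase_9TM", "tm9", "prepilin peptidase, 9 TM form (EppA-like)"),
        Slot("c1_mem1", "membrane_accessory", "tm2", "hypothetical membrane protein", (1, 2)),
        Slot("c1_mem2", "membrane_accessory", "tm2", "hypothetical membrane protein"),
        Slot("c1_minor1", "minor_pilin", "prepilin_minor", "hypothetical protein", (1, 3)),
        Slot("c1_minor2", "minor_pilin", "prepilin_minor", "hypothetical protein"),
        Slot("c1_minor3", "minor_pilin", "prepilin_minor", "hypothetical protein"),
        Slot("c1_minor4", "minor_pilin", "prepilin_minor", "hypothetical protein"),
        Slot("c1_minor5", "minor_pilin", "prepilin_minor", "hypothetical protein"),
        Slot("c1_flen", "fleN_minD", "cyto", "FleN/MinD family regulatory ATPase"),
        Slot("c1_adh1", "adhesin", "sec_large", "DUF2341 domain adhesin"),
        Slot("c1_adh2", "adhesin", "sec_large", "DUF2341 domain adhesin", (0, 1)),
    ],
    "archaellum": [
        Slot("arc_flaI", "secretion_ATPase", "cyto", "archaellum assembly ATPase FlaI", component="flaI"),
        Slot("arc_flaH", "flaH", "cyto", "archaellum ATP-binding protein FlaH", component="flaH"),
        Slot("arc_flaJ", "tadC", "tm3", "archaellum membrane platform protein FlaJ", component="flaJ"),
        Slot("arc_flaF", "archaellin", "prepilin_archaellin", "minor archaellin FlaF", component="flaF"),
        Slot("arc_flaG", "archaellin", "prepilin_archaellin", "minor archaellin FlaG", component="flaG"),
        Slot("arc_flaB1", "archaellin", "prepilin_archaellin", "major archaellin FlaB", (1, 9)),
        Slot("arc_flaCDE", "membrane_accessory", "tm1", "archaellum FlaC/D/E protein (fusions occur)", (1, 3), component="flaCDE"),
    ],
    "clade2_pilA": [
        Slot("p2a_atpase", "secretion_ATPase", "cyto", "type IV pili assembly ATPase, VirB11 family"),
        Slot("p2a_major", "major_pilin", "prepilin_major", "PilA family major pilin", (1, 2)),
        Slot("p2a_tadc1", "tadC", "tm3", "TadC-like membrane platform protein"),
        Slot("p2a_tadc2", "tadC", "tm3", "TadC-like membrane platform protein"),
        Slot("p2a_slayer", "s_layer", "slayer", "S-layer like protein"),
        Slot("p2a_minor", "minor_pilin", "prepilin_minor", "hypothetical protein"),
    ],
    "clade2_B": [
        Slot("b2_atpase", "secretion_ATPase", "cyto", "type IV pili assembly ATPase, VirB11 family"),
        Slot("b2_major", "major_pilin", "prepilin_major", "PilA-related major pilin", (1, 2)),
        Slot("b2_tadc", "tadC", "tm3", "TadC-like membrane platform protein"),
        Slot("b2_mem", "membrane_accessory", "tm2", "hypothetical membrane protein"),
        Slot("b2_minor1", "minor_pilin", "prepilin_minor", "hypothetical protein"),
        Slot("b2_minor2", "minor_pilin", "prepilin_minor", "hypothetical protein", (1, 2)),
    ],
    "sub4C": [
        Slot("c4_atpase", "secretion_ATPase", "cyto", "type IV pili assembly ATPase, VirB11 family"),
        Slot("c4_major", "major_pilin", "prepilin_major", "PilA family major pilin"),
        Slot("c4_tadc", "tadC", "tm3", "TadC-like membrane platform protein"),
        Slot("p2a_minor", "minor_pilin", "prepilin_minor", "hypothetical protein"),
        Slot("c4_minor1", "minor_pilin", "prepilin_minor", "hypothetical protein"),
        Slot("c4_minor2", "minor_pilin", "prepilin_minor", "hypothetical protein"),
        Slot("c4_minor3", "minor_pilin", "prepilin_minor", "hypothetical protein", (1, 2)),
    ],
    "sub4F": [
        Slot("f4_atpase", "secretion_ATPase", "cyto", "type IV pili assembly ATPase, VirB11 family"),
        Slot("f4_major", "major_pilin", "prepilin_major", "PilA family major pilin", (1, 2)),
        Slot("f4_tadc", "tadC", "tm3", "TadC-like membrane platform protein"),
        Slot("f4_slayer", "s_layer", "slayer", "S-layer like protein"),
        Slot("f4_cc", "cytoplasmic_accessory", "cyto", "hypothetical coiled-coil protein"),
    ],
    "sulfolobales_simple": [
        Slot("s4_atpase", "secretion_ATPase", "cyto", "type IV pili assembly ATPase, VirB11 family"),
        Slot("s4_major", "major_pilin", "prepilin_major", "PilA family major pilin", (1, 2)),
        Slot("s4_tadc1", "tadC", "tm3", "TadC-like membrane platform protein"),
        Slot("s4_tadc2", "tadC", "tm3", "TadC-like membrane platform protein", (0, 1)),
        Slot("s4_pibD", "peptidase_5TM", "tm5", "prepilin peptidase, 5 TM form (PibD/FlaK-like)"),
    ],
    "sub4B": [
        Slot("b4_atpase", "secretion_ATPase", "cyto", "type IV pili assembly ATPase, VirB11 family"),
        Slot("b4_major1", "major_pilin", "prepilin_major", "PilA family major pilin"),
        Slot("b4_major2", "major_pilin", "prepilin_major", "PilA family major pilin"),
        Slot("b4_tadc1", "tadC", "tm3", "TadC-like membrane platform protein"),
        Slot("b4_tadc2", "tadC", "tm3", "TadC-like membrane platform protein"),
        Slot("b4_slayer", "s_layer", "slayer", "S-layer like protein with C-terminal TM anchor"),
        Slot("b4_adh", "adhesin", "sec_large", "large signal peptide containing protein"),
    ],
    "sub4E": [
        Slot("e4_atpase", "secretion_ATPase", "cyto", "type IV pili assembly ATPase, VirB11 family"),
        Slot("e4_major", "major_pilin", "prepilin_major", "PilA family major pilin"),
        Slot("e4_tadc", "tadC", "tm3", "TadC-like membrane platform protein"),
        Slot("e4_mem", "membrane_accessory", "tm2", "hypothetical membrane protein"),
        Slot("e4_minor", "minor_pilin", "prepilin_minor", "hypothetical protein"),
        Slot("e4_cyto", "cytoplasmic_accessory", "cyto", "hypothetical protein"),
    ],
    "sub4G": [
        Slot("g4_atpase", "secretion_ATPase", "cyto", "type IV pili assembly ATPase, VirB11 family"),
        Slot("g4_major", "major_pilin", "prepilin_major", "PilA family major pilin"),
        Slot("g4_tadc", "tadC", "tm3", "TadC-like membrane platform protein"),
        Slot("g4_mem1", "membrane_accessory", "tm2", "hypothetical membrane protein"),
        Slot("g4_mem2", "membrane_accessory", "tm2", "hypothetical membrane protein"),
        Slot("g4_minor1", "minor_pilin", "prepilin_minor", "hypothetical protein"),
        Slot("g4_minor2", "minor_pilin", "prepilin_minor", "hypothetical protein", (1, 3)),
        Slot("g4_slayer", "s_layer", "slayer", "S-layer like protein"),
        Slot("g4_flen", "fleN_minD", "cyto", "FleN/MinD family regulatory ATPase"),
        Slot("g4_cyto1", "cytoplasmic_accessory", "cyto", "hypothetical alpha-helical protein"),
        Slot("g4_cyto2", "cytoplasmic_accessory", "cyto", "hypothetical alpha-helical protein"),
        Slot("g4_adh", "adhesin", "sec_large", "large signal peptide containing protein"),
    ],
    "sub4D": [
        Slot("d4_atpase", "secretion_ATPase", "cyto", "type IV pili assembly ATPase, VirB11 family"),
        Slot("d4_mem", "membrane_accessory", "tm4", "uncharacterized 4 TM domain membrane protein"),
        Slot("d4_tfiib", "regulator", "cyto", "TFIIB homolog, single cyclin domain"),
    ],
}

_CLADE_LABELS = {
    "clade1": "1",
    "archaellum": "3",
    "clade2_pilA": "2",
    "clade2_B": "2",
    "sub4C": "4C",
    "sub4F": "4F",
    "sulfolobales_simple": "4A",
    "sub4B": "4B",
    "sub4E": "4E",
    "sub4G": "4G",
    "sub4D": "4D",
}

TEMPLATE_NAMES = tuple(sorted(_RECIPES))

#: Architecture plan for the default 30-genome collection: all 11 systems,
#: each carried by at least five genomes, 65 systems altogether so the
#: per-genome count profile can span the full 1..7 range.
DEFAULT_PLAN: dict[str, int] = {
    "archaellum": 8,
    "clade2_pilA": 7,
    "sulfolobales_simple": 7,
    "clade1": 6,
    "clade2_B": 6,
    "sub4D": 6,
    "sub4B": 5,
    "sub4C": 5,
    "sub4E": 5,
    "sub4F": 5,
    "sub4G": 5,
}

_LINEAGES = [
    "Euryarchaeota;Methanococci",
    "Euryarchaeota;Methanobacteria",
    "Euryarchaeota;Thermococci",
    "Euryarchaeota;Halobacteria",
    "Euryarchaeota;Methanomicrobia",
    "Euryarchaeota;Archaeoglobi",
    "Crenarchaeota;Sulfolobales",
    "Crenarchaeota;Desulfurococcales",
    "Crenarchaeota;Thermoproteales",
    "Thaumarchaeota;Nitrososphaerales",
]


@dataclass
class GeneratorParams:
    """Study conditions for one synthetic collection."""

    n_genomes: int = 30
    genes_per_genome: tuple[int, int] = (70, 110)
    background_family_pool: int = 250
    architecture_plan: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_PLAN))
    standalone_major_pilin_rate: float = 0.2
    paralog_expansion_max: int = 9
    hgt_swap_rate: float = 0.05
    rng_seed: int = 17

    def validate(self) -> None:
        if self.n_genomes < 1:
            raise ParameterError("n_genomes must be >= 1")
        if self.paralog_expansion_max < 1:
            raise ParameterError("paralog_expansion_max must be >= 1")
        for p in (self.standalone_major_pilin_rate, self.hgt_swap_rate):
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"probability {p} outside [0, 1]")
        for name, k in self.architecture_plan.items():
            if name not in _RECIPES:
                raise ParameterError(f"unknown template {name!r} in architecture_plan")
            if k > self.n_genomes:
                raise ParameterError(
                    f"architecture_plan[{name!r}] = {k} exceeds n_genomes = {self.n_genomes}"
                )


@dataclass
class PlantedLocus:
    genome_id: str
    contig_id: str
    start_index: int
    end_index: int
    template_name: str
    origin: str = "planted"  # planted | hgt


@dataclass
class SyntheticTruth:
    """Ground truth of a generated collection."""

    planted_loci: list[PlantedLocus] = field(default_factory=list)
    role_of_family: dict[str, str] = field(default_factory=dict)
    expected_t4p_count: dict[str, int] = field(default_factory=dict)
    in_locus_genomes: dict[str, set[str]] = field(default_factory=dict)
    standalone_pilins: list[tuple[str, str, list[str]]] = field(default_factory=list)
    operons: dict[str, list[tuple[str, ...]]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Plan construction
# ---------------------------------------------------------------------------


def _count_profile(n_genomes: int, total: int) -> list[int]:
    """Per-genome system counts; spans 1..7 when the totals allow it."""
    if n_genomes >= 7 and total >= n_genomes + 21:
        profile = [7, 6, 5, 4, 3, 2, 1] + [1] * (n_genomes - 7)
        deficit = total - sum(profile)
        i = 7
        while deficit > 0 and n_genomes > 7:
            if profile[i] < 6:
                profile[i] += 1
                deficit -= 1
            i += 1
            if i >= n_genomes:
                i = 7
                if all(p >= 6 for p in profile[7:]):
                    break
        if deficit == 0:
            return profile
    base, rem = divmod(total, n_genomes)
    return [base + (1 if i < rem else 0) for i in range(n_genomes)]


def _assign_templates(
    plan: dict[str, int], profile: list[int], genome_ids: list[str]
) -> dict[str, list[str]]:
    """Assign each template instance to distinct genomes, filling the profile.

    Greedy: templates in decreasing plan size go to the genomes with the
    largest remaining capacity.  Returns genome_id -> list of template names.
    """
    capacity = list(profile)
    out: dict[str, list[str]] = {g: [] for g in genome_ids}
    for name in sorted(plan, key=lambda n: (-plan[n], n)):
        order = sorted(range(len(genome_ids)), key=lambda i: (-capacity[i], i))
        chosen = [i for i in order if capacity[i] > 0][: plan[name]]
        if len(chosen) < plan[name]:
            raise ParameterError(
                f"cannot place {plan[name]} copies of {name!r} into the "
                f"per-genome capacity profile"
            )
        for i in chosen:
            capacity[i] -= 1
            out[genome_ids[i]].append(name)
    return out


# ---------------------------------------------------------------------------
# Gene materialization
# ---------------------------------------------------------------------------

_EMIT_TOPOLOGIES = {
    "tm1": ((50,), 120),
    "tm2": ((50, 96), 135),
    "tm3": ((50, 96, 142), 180),
    "tm4": ((50, 96, 142, 188), 225),
    "tm5": (PIBD_TOPOLOGY, PIBD_LENGTH),
    "tm9": (EPPA_TOPOLOGY, EPPA_LENGTH),
}


def _emit_protein(kind: str, rng: np.random.Generator) -> str:
    if kind == "cyto":
        return emit_cytoplasmic(int(rng.integers(180, 380)), rng)
    if kind in _EMIT_TOPOLOGIES:
        topology, length = _EMIT_TOPOLOGIES[kind]
        return emit_tm_protein(topology, length, rng)
    if kind == "slayer":
        length = int(rng.integers(380, 440))
        return emit_tm_protein((length - 25,), length, rng)
    if kind == "prepilin_major":
        return emit_prepilin(int(rng.integers(55, 76)), rng)
    if kind == "prepilin_minor":
        return emit_prepilin(int(rng.integers(210, 351)), rng)
    if kind == "prepilin_archaellin":
        return emit_prepilin(int(rng.integers(170, 211)), rng)
    if kind == "sec_large":
        return emit_sec_protein(int(rng.integers(460, 541)), rng)
    raise ParameterError(f"unknown emitter kind {kind!r}")


@dataclass
class _GeneSpec:
    family: str | None
    product: str
    seq: str | None
    planted: bool = False  # part of a planted locus or stand-alone pilin group


def _zipf_probs(pool: int, exponent: float = 1.5) -> np.ndarray:
    ranks = np.arange(1, pool + 1, dtype=float)
    p = ranks ** -exponent
    return p / p.sum()


def build_catalog() -> FamilyCatalog:
    """Role catalog for every family any recipe can plant."""
    entries: dict[str, FamilyInfo] = {}
    for template, slots in _RECIPES.items():
        for slot in slots:
            entries.setdefault(
                slot.family,
                FamilyInfo(
                    role=slot.role,
                    clade_label=_CLADE_LABELS[template],
                    component=slot.component,
                ),
            )
    return FamilyCatalog(entries)


def generate_collection(
    params: GeneratorParams,
) -> tuple[list[GenomeTable], SyntheticTruth, FamilyCatalog]:
    """Generate a genome collection with planted loci and ground truth.

    Deterministic given ``params.rng_seed``.
    """
    params.validate()
    rng = np.random.default_rng(params.rng_seed)
    genome_ids = [f"genome{i:03d}" for i in range(params.n_genomes)]
    total = sum(params.architecture_plan.values())
    profile = _count_profile(params.n_genomes, total)
    assignment = _assign_templates(params.architecture_plan, profile, genome_ids)

    # Horizontal transfer: copy a system into a mid-count recipient genome so
    # the planted per-genome count profile keeps its span.
    by_genome: dict[str, list[tuple[str, str]]] = {
        g: [(t, "planted") for t in assignment[g]] for g in genome_ids
    }
    eligible = [g for g, c in zip(genome_ids, profile) if 2 <= c <= 5]
    for g in genome_ids:
        for template in assignment[g]:
            if eligible and rng.random() < params.hgt_swap_rate:
                recipient = str(rng.choice([e for e in eligible if e != g] or eligible))
                by_genome[recipient].append((template, "hgt"))

    catalog = build_catalog()
    truth = SyntheticTruth(role_of_family={f: i.role for f, i in catalog.entries.items()})
    zipf_p = _zipf_probs(params.background_family_pool)
    first_carrier_seen: set[str] = set()  # major families with a forced tandem pair
    tables: list[GenomeTable] = []

    for gi, genome_id in enumerate(genome_ids):
        lineage = _LINEAGES[gi % len(_LINEAGES)].split(";")
        contig_id = "c1"
        priv_counter = 0

        def private_gene() -> _GeneSpec:
            nonlocal priv_counter
            priv_counter += 1
            return _GeneSpec(
                family=f"priv_{genome_id}_{priv_counter:03d}",
                product="hypothetical protein",
                seq=emit_cytoplasmic(int(rng.integers(100, 260)), rng),
            )

        def background_gene() -> _GeneSpec:
            fam = int(rng.choice(params.background_family_pool, p=zipf_p)) + 1
            return _GeneSpec(
                family=f"bg{fam:04d}",
                product="hypothetical protein",
                seq=emit_cytoplasmic(int(rng.integers(100, 260)), rng),
            )

        # -- plan elements: loci and stand-alone pilin groups ---------------
        # element := ("locus", template, origin, [genes]) or ("standalone", family, [genes])
        elements: list[tuple] = []
        for template, origin in by_genome[genome_id]:
            locus_genes: list[_GeneSpec] = []
            standalone_groups: list[tuple[str, list[_GeneSpec]]] = []
            # One draw per system: either all of this system's majors are
            # encoded in trans (stand-alone) or all sit in the locus.  A
            # per-gene draw could leave a partial in-locus major complement,
            # which is not an architecture the survey describes.
            system_standalone = bool(
                rng.random() < params.standalone_major_pilin_rate
            )
            for slot in _RECIPES[template]:
                lo, hi = slot.count
                n_copies = int(rng.integers(lo, hi + 1)) if hi > lo else lo
                if slot.role == "major_pilin":
                    # Every major family's first carrying genome gets a forced
                    # stand-alone tandem pair (majors are duplication-prone
                    # stand-alone genes).
                    if slot.family not in first_carrier_seen:
                        first_carrier_seen.add(slot.family)
                        pair = [
                            _GeneSpec(slot.family, slot.product,
                                      _emit_protein(slot.emit, rng), planted=True)
                            for _ in range(2)
                        ]
                        standalone_groups.append((slot.family, pair))
                    if system_standalone:
                        genes = [
                            _GeneSpec(slot.family, slot.product,
                                      _emit_protein(slot.emit, rng), planted=True)
                            for _ in range(min(n_copies, 2))
                        ]
                        standalone_groups.append((slot.family, genes))
                        continue
                    n_copies = min(n_copies, 2)  # keep interior runs mergeable
                n_copies = min(n_copies, params.paralog_expansion_max)
                for _ in range(n_copies):
                    locus_genes.append(
                        _GeneSpec(slot.family, slot.product,
                                  _emit_protein(slot.emit, rng), planted=True)
                    )
            elements.append(("locus", template, origin, locus_genes))
            for fam, genes in standalone_groups:
                elements.append(("standalone", fam, genes))

        # -- interleave with background -------------------------------------
        lo, hi = params.genes_per_genome
        n_bg = int(rng.integers(lo, hi + 1))
        n_chunks = len(elements) + 1
        splits = rng.multinomial(n_bg, np.full(n_chunks, 1.0 / n_chunks))

        genes: list[_GeneSpec] = []
        locus_spans: list[tuple[str, str, int, int]] = []  # template, origin, first, last
        standalone_spans: list[tuple[str, int, int]] = []
        operon_break: list[bool] = []  # True when gene starts a new operon

        def append_background(n: int) -> None:
            for _ in range(n):
                genes.append(background_gene())
                operon_break.append(
                    len(operon_break) == 0 or bool(rng.random() < 0.75)
                )

        def append_buffer() -> None:
            for _ in range(3):
                genes.append(private_gene())
                operon_break.append(len(operon_break) == 0 or bool(rng.random() < 0.75))

        for k, element in enumerate(elements):
            append_background(int(splits[k]))
            append_buffer()
            first = len(genes)
            if element[0] == "locus":
                _, template, origin, locus_genes = element
                for j, spec in enumerate(locus_genes):
                    genes.append(spec)
                    operon_break.append(j == 0)
                locus_spans.append((template, origin, first, len(genes) - 1))
            else:
                _, fam, group = element
                for j, spec in enumerate(group):
                    genes.append(spec)
                    operon_break.append(j == 0)
                standalone_spans.append((fam, first, len(genes) - 1))
            append_buffer()
        append_background(int(splits[-1]))

        # -- coordinates, strands, operon blocks -----------------------------
        records: list[GeneRecord] = []
        operon_blocks: list[tuple[str, ...]] = []
        pos = 0
        strand = "+"
        current_block: list[str] = []
        for i, spec in enumerate(genes):
            gene_id = f"{genome_id}_g{i:04d}"
            new_operon = operon_break[i] if i > 0 else True
            if new_operon:
                gap = int(rng.integers(200, 801))
                strand = "+" if rng.random() < 0.5 else "-"
                if current_block:
                    operon_blocks.append(tuple(current_block))
                current_block = [gene_id]
            else:
                gap = int(rng.integers(1, 51))
                current_block.append(gene_id)
            plen = len(spec.seq) if spec.seq else 100
            start = pos + gap
            end = start + 3 * (plen + 1) - 1
            pos = end
            records.append(
                GeneRecord(
                    genome_id=genome_id,
                    contig_id=contig_id,
                    order_index=i,
                    gene_id=gene_id,
                    strand=strand,
                    start=start,
                    end=end,
                    family_id=spec.family,
                    product=spec.product,
                    protein_seq=spec.seq,
                )
            )
        if current_block:
            operon_blocks.append(tuple(current_block))

        table = GenomeTable(genome_id=genome_id, lineage=lineage,
                            contigs={contig_id: records})
        tables.append(table)

        # -- truth ------------------------------------------------------------
        truth.operons[genome_id] = operon_blocks
        truth.expected_t4p_count[genome_id] = len(by_genome[genome_id])
        for template, origin, first, last in locus_spans:
            truth.planted_loci.append(
                PlantedLocus(genome_id, contig_id, first, last, template, origin)
            )
            for spec in genes[first : last + 1]:
                truth.in_locus_genomes.setdefault(spec.family, set()).add(genome_id)
        for fam, first, last in standalone_spans:
            truth.standalone_pilins.append(
                (genome_id, fam, [records[i].gene_id for i in range(first, last + 1)])
            )

    return tables, truth, catalog


def acceptance_params(seed: int = 17) -> GeneratorParams:
    """The default 30-genome acceptance collection (all 11 architectures)."""
    return GeneratorParams(rng_seed=seed)


def confusion_params(seed: int = 17) -> GeneratorParams:
    """A larger panel (>= 200 planted loci) for classifier evaluation."""
    plan = {name: 19 for name in TEMPLATE_NAMES}
    return GeneratorParams(
        n_genomes=90,
        architecture_plan=plan,
        rng_seed=seed,
    )
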