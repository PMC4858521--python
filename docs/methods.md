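# Methods

## Problem and approach

Archaeal surface structures — adhesion pili of several kinds and the
archaellum (the archaeal motility apparatus) — are built by homologous
machineries of the type IV pili (T4P) class: an energizing secretion ATPase
(VirB11/FlaI family), a polytopic membrane platform (TadC/FlaJ), pilin
subunits carrying class III (prepilin) signal peptides, and a dedicated
A24-family prepilin peptidase.  Most components beyond the ATPase are poorly
conserved, so the systems cannot be found by sequence search alone; they
can, however, be found by *gene-neighborhood association*: components of one
system cluster in genomic loci, and a family that repeatedly appears next to
known components across many genomes is very likely itself a component.

`t4pcensus` implements that census as a reproducible pipeline over ordered
gene tables (one gene per row with an orthologous-family label, arCOG-style)
and evaluates every stage against synthetic genome collections with planted
ground truth.

## The census

`expand_once` adds to the accepted family set every family that occurs
within `window` genes (default 3, counted on gene order, not nucleotide
distance) of a gene of an accepted family in at least `min_genomes` distinct
genomes (default 5; occurrences are deduplicated per genome).  The default
run applies three iterations, seeded from the families whose role is
recognizable a priori: secretion ATPases, TadC/FlaJ platforms, FlaH,
FleN/MinD regulatory ATPases and the prepilin peptidases.  Seeding from all
known component families rather than the ATPases alone matters: expansion
reach grows by `window` genes per iteration, and the longest loci
(~15 genes) are only fully covered within three iterations when seeds are
spread along them.

Families seen in neighborhoods but below the genome threshold go through an
automated stand-in for manual curation (`curate_candidates`).  A candidate
is accepted when (a) at least 80% of its members are predicted secreted or
membrane proteins, (b) the fraction of members inside candidate loci is at
least `context_exclusivity_min` (default 1.0 — the family "never occurs in a
different gene context"), and (c) at least one member shares a predicted
operon with an accepted family's gene.  Reason codes record the clause
values for every decision.  Families whose catalog role is on the exclusion
list (S-layer proteins by default) are removed from the final set but
retained as "potential components".

Design notes:

* The genome threshold is applied to candidates only; accepted families
  persist (the alternative — re-testing accepted families every iteration —
  could oscillate and has no textual support).
* Per-genome system counts use secretion-ATPase *genes*, not families, as
  the proxy: a duplicated ATPase gene marks a duplicated system
  (`distinct_families=True` switches to family counting).
* `fraction_hypothetical` is a case-insensitive substring match of
  "hypothetical"/"uncharacterized" in product annotations.

## Sequence-feature heuristics

The census needs localization calls, and pilin calling needs class III
leader detection.  Both are fully specified rules rather than wrappers
around external predictors, so results are reproducible from this package
alone:

* **Hydropathy**: mean Kyte–Doolittle index in a sliding window of 19.
  Unknown letters score 0.0 with a warning (tolerates X in real data).
* **TM segments**: windows with mean hydropathy >= 1.6, merged when
  overlapping or separated by < 5 residues; merged runs shorter than 15
  residues are dropped.  Window 19 / threshold 1.6 / merge gap 5 / minimum
  15 are standard hydropathy-analysis practice; all are keyword arguments.
* **Class III signal peptide**: scan positions 2..35 for a [KR]G motif;
  accept the first position where the prefix net charge through the K/R
  (K/R = +1, D/E = −1) is >= +1 and the mean hydropathy of the 20 residues
  after the G is >= 1.0 — i.e. cleavage removes only the charged N-terminus
  and leaves a ~20-residue hydrophobic mature N-terminus.  Leftmost
  acceptable motif wins.  Failing that, a plain hydrophobic core (8 residues
  with mean >= 1.5 within the first 40) yields a sec-like call.
* **Localization**: membrane if any TM segment remains after discounting a
  single N-terminal (start <= 45) segment on a protein with a detected
  signal peptide (that segment is the leader's own hydrophobic domain);
  else secreted if any signal; else cytoplasmic; unknown without sequence.

## Pilin calling

Per census family: class III fraction, median mature length (length after
the predicted cleavage site), stand-alone fraction (members outside all
multi-family loci; tandem same-family runs count as stand-alone) and maximum
paralog count per genome.  Majors are class III positive (>= 0.8), short
(median mature length <= 160 aa) and stand-alone-prone (>= 0.5) or
paralogous (>= 2 somewhere); class III positive families failing the major
test are minors; the rest are non-pilin.  The 160 aa boundary separates the
~70 aa major pilin regime from the 250–550 aa recurring minor-pilin regime;
no sharper boundary is defined in the literature, so the threshold is
config-exposed and the call is documented as a surrogate.

## Loci and architecture templates

Loci are maximal runs of census genes separated by at most 2 non-census
genes; single-family groups are flagged stand-alone rather than treated as
loci.  Operons are maximal same-strand runs with intergenic distance
<= 100 bp (same-strand adjacency when coordinates are absent).

Eleven architecture templates ship as editable YAML: the complex clade-1
system, the archaellum, two euryarchaeal variants, and seven
crenarchaeal/halobacterial variants including the two-component sub4D
system that forbids pilins.  A template scores
`satisfied required-role ranges / total required roles`, minus 1.0 (floored
at 0) if a forbidden role is present; the best-scoring template wins, ties
going to the template with more required roles, then lexicographic order;
scores below 0.6 are "unclassified".  Two matching rules deserve note:

* **Component-aware counting.**  A family may carry a component tag finer
  than its role (`flaI`, `flaJ`, `flaF`, `flaG`, `flaCDE`); such genes count
  only under their tag.  This lets the archaellum template demand its seven
  components individually and prevents generic pili templates from claiming
  archaellum parts (and vice versa).  Forbidden-role checks use coarse roles.
* **In-trans majors.**  Several systems keep their major pilins elsewhere in
  the genome; a `major_pilin` requirement with zero in-locus copies is
  satisfied when the genome carries stand-alone class III genes of mature
  length <= 160 outside every locus.

S-layer proteins appear in several described architectures but are excluded
from the census final set by role, so no template *requires* them (they are
optional components); a required S-layer role could never be satisfied.

Archaellum completeness is checked genome-wide — FlaI, FlaH, FlaJ, FlaF,
FlaG exactly once, archaellins 1–9, FlaC/D/E genes 1–3 (C/D/E fusions count
once per gene) — because archaellins are frequently encoded away from the
main locus as stand-alone genes.

## Alignment-site filter

Columns are scored by gap fraction (`-` and `.`) and homogeneity.  The
homogeneity statistic is the mean pairwise identity among the column's
non-gap residues (1.0 for a single distinct residue, 0.0 for an all-gap
column): a bounded [0, 1] conservation proxy; the exact statistic used
elsewhere in the literature is not uniquely defined, so the function is
pluggable.  A column is removed when gap fraction > 0.5 OR homogeneity
< 0.1 (union reading — standard practice removes both gappy and
heterogeneous sites); an intersection mode implements the literal
conjunctive reading.  The filter is idempotent and monotone in both
thresholds.

## Synthetic collections

The generator emulates a survey panel: 30 single-contig genomes (defaults),
70–110 background genes each with family labels drawn Zipf-like (exponent
1.5) from a 250-family pool — so some background families recur across
genomes and genuinely stress the census threshold — plus planted loci
according to an architecture plan covering all 11 templates (65 systems).
Per-genome system counts follow a profile spanning 1..7 systems, the range
observed across sequenced archaea.  Horizontal transfer is modeled by
copying a system into a mid-count recipient genome (rate 0.05 per system),
so the count profile keeps its span; transfers are recorded in the truth.
Majors are duplication-prone stand-alone genes: each major family's first
carrying genome receives a stand-alone tandem pair, and each system's
majors are encoded in trans with probability `standalone_major_pilin_rate`
(default 0.2, applied per system so a locus never carries a partial major
complement).

Protein sequences come from two fixed composition profiles rather than an
evolutionary model:

* pilins/archaellins: Met + charged tract (K/R-rich, 2–8 residues) + [KR]G
  + 20–24 hydrophobic residues + hydrophilic remainder — class III by
  construction (no glycine before the motif, positive prefix, hydrophobic
  mature N-terminus);
* membrane proteins: hydrophobic 21-mers from {I,V,L} at template-defined
  positions spaced >= 25 hydrophilic residues apart, which the TM caller
  can neither miss nor merge;
* adhesins: sec-like leaders without basic residues (never class III);
* background/cytoplasmic proteins: drawn from residues with negative
  hydropathy only, so no window can resemble a TM segment or a signal core.

Planted loci and stand-alone pilin groups are flanked by three
genome-private background genes, which guarantees no recurring background
family sits inside a census neighborhood in several genomes.  Within loci,
genes the census may legitimately drop (S-layer members, sub-threshold
majors) are placed interior, never at locus endpoints, so recoverable
ranges equal planted ranges.

**What passing tests do and do not show.**  Detector sensitivity/false-
positive rates of exactly 1.0/0.0, full family recall, and a clean template
confusion diagonal are properties of this separable construction; they
demonstrate that the pipeline's logic is correct, not that the heuristics
match black-box predictors on real proteomes, where hydrophobicity and
leader motifs are far noisier.  Real headline statistics (family counts,
protein counts, hypothetical fractions) depend on a real multi-genome
arCOG-annotated dataset and are out of desk-scale scope.

## Problem sizes and determinism

Default analyses use 30 genomes (~3,900 genes); the classifier-confusion
panel uses 90 genomes with 224 planted loci (~12,000 genes).  These sizes
give every census rule multiple decisions per genome while a full test run
completes in seconds.  All randomness flows through a single
`numpy.random.default_rng` seed; identical seeds yield byte-identical gene
tables and pipeline outputs (verified by content hash in the MANIFEST).

## Known limitations

* Contigs are linear; neighborhoods truncate at contig ends (no circular
  wrap-around; a future flag could add it).
* Family labels are taken as input; no profile-based family assignment.
* Clade labels are input metadata; no tree inference.
* The curation rules are numeric surrogates for expert judgment; their
  thresholds (80% localization, exclusivity 1.0) are documented contracts,
  not fitted values.
* The generator emits no nucleotide sequences and models no sequence
  evolution; paralogs are independent draws from the same emitter.
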