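"""Sequence-feature heuristics: hydropathy, TM segments, class III leaders.

These are deliberately simple, fully specified stand-ins for the black-box
predictors normally used in this kind of survey (TM topology predictors,
signal-peptide predictors, archaellin-signature scanners).  Three calls are
made per protein:

* a sliding-window Kyte-Doolittle hydropathy profile;
* transmembrane segments: windows whose mean hydropathy clears a threshold,
  merged into maximal runs;
* a class III (prepilin) signal peptide: a short positively charged
  N-terminal leader ending in a [KR]G motif, cleaved after the glycine so
  that a hydrophobic stretch of about 20 residues remains at the mature
  N-terminus.  Proteins failing that test but carrying a plain hydrophobic
  core near the N-terminus are called sec-like.

All thresholds are keyword arguments with documented defaults, so the rules
are the contract rather than an approximation of someone else's binary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

#: Kyte & Doolittle (1982) hydropathy index.
KYTE_DOOLITTLE: dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

_POSITIVE = frozenset("KR")
_NEGATIVE = frozenset("DE")


@dataclass(frozen=True)
class TMProfile:
    """Predicted transmembrane segments, 1-based inclusive residue ranges."""

    segments: tuple[tuple[int, int], ...] = ()

    @property
    def count(self) -> int:
        return len(self.segments)


@dataclass(frozen=True)
class SignalPeptideCall:
    """Signal-peptide call for one protein.

    ``cleavage_pos`` is the 1-based position of the last leader residue (the
    G of the [KR]G motif for class III); it is present iff klass != none.
    """

    klass: str  # none | sec_like | class_III
    cleavage_pos: int | None = None
    leader_net_charge: int = 0
    downstream_hydrophobicity: float = 0.0


def _kd_values(seq: str) -> np.ndarray:
    vals = np.empty(len(seq), dtype=float)
    unknown = []
    for i, aa in enumerate(seq):
        v = KYTE_DOOLITTLE.get(aa)
        if v is None:
            unknown.append(aa)
            v = 0.0
        vals[i] = v
    if unknown:
        warnings.warn(
            f"unknown residue letters {sorted(set(unknown))} scored as 0.0",
            stacklevel=3,
        )
    return vals


def kd_profile(seq: str, window: int = 19) -> np.ndarray:
    """Mean Kyte-Doolittle hydropathy over each window of ``window`` residues.

    Element i covers residues i..i+window-1 (0-based); the output has length
    ``len(seq) - window + 1``.  Unknown letters score 0.0 with a warning.
    """
    if len(seq) < window:
        raise ValueError(f"sequence length {len(seq)} < window {window}")
    vals = _kd_values(seq)
    kernel = np.full(window, 1.0 / window)
    return np.convolve(vals, kernel, mode="valid")


def predict_tm_segments(
    seq: str,
    window: int = 19,
    threshold: float = 1.6,
    merge_gap: int = 5,
    min_length: int = 15,
) -> TMProfile:
    """Call TM segments from the hydropathy profile.

    Candidate windows with mean hydropathy >= ``threshold`` are merged when
    they overlap or are separated by fewer than ``merge_gap`` residues; each
    merged run is one segment.  Segments shorter than ``min_length`` residues
    are dropped.
    """
    profile = kd_profile(seq, window=window)
    starts = np.flatnonzero(profile >= threshold)
    if starts.size == 0:
        return TMProfile()
    segments: list[tuple[int, int]] = []
    run_first = run_last = int(starts[0])
    for s in starts[1:]:
        s = int(s)
        # windows [run_last, run_last+window) and [s, s+window) merge when
        # the gap between them, s - (run_last + window), is < merge_gap
        if s - run_last < window + merge_gap:
            run_last = s
        else:
            segments.append((run_first + 1, run_last + window))
            run_first = run_last = s
    segments.append((run_first + 1, run_last + window))
    kept = tuple(s for s in segments if s[1] - s[0] + 1 >= min_length)
    return TMProfile(segments=kept)


def detect_class3(
    seq: str,
    max_leader: int = 35,
    min_charge: int = 1,
    min_hydrophobicity: float = 1.0,
    sec_core_len: int = 8,
    sec_core_kd: float = 1.5,
    sec_scan_len: int = 40,
) -> SignalPeptideCall:
    """Detect a class III (prepilin) signal peptide.

    Positions 2..max_leader (1-based) are scanned for a [KR]G motif.  The
    first position where (a) the net charge of the prefix through the K/R
    (K/R = +1, D/E = -1) is >= ``min_charge`` and (b) the mean hydropathy of
    the 20 residues after the G is >= ``min_hydrophobicity`` is accepted, and
    cleavage is placed at the G.  Otherwise a sec-like leader is reported if
    any ``sec_core_len``-residue window within the first ``sec_scan_len``
    residues has mean hydropathy >= ``sec_core_kd``; else no signal.
    """
    if len(seq) < 45:
        raise ValueError("detect_class3 requires sequences of >= 45 residues")
    vals = _kd_values(seq)
    charge = 0
    for p in range(2, max_leader + 1):  # 1-based position of the candidate G
        prev = seq[p - 2]
        if prev in _POSITIVE:
            charge_prefix = charge + 1
        else:
            charge_prefix = charge  # not used unless motif matches
        if seq[p - 1] == "G" and prev in _POSITIVE and charge_prefix >= min_charge:
            if p + 20 <= len(seq):
                hyd = float(np.mean(vals[p : p + 20]))
                if hyd >= min_hydrophobicity:
                    return SignalPeptideCall(
                        klass="class_III",
                        cleavage_pos=p,
                        leader_net_charge=charge_prefix,
                        downstream_hydrophobicity=hyd,
                    )
        # accumulate charge of the prefix ending at position p-1
        if prev in _POSITIVE:
            charge += 1
        elif prev in _NEGATIVE:
            charge -= 1
    # sec-like fallback: a plain hydrophobic core near the N-terminus
    limit = min(sec_scan_len, len(seq))
    for i in range(0, limit - sec_core_len + 1):
        core = vals[i : i + sec_core_len]
        if float(np.mean(core)) >= sec_core_kd:
            cleave = i + sec_core_len  # 1-based position of last core residue
            down = vals[cleave : cleave + 20]
            prefix_charge = sum(
                1 if aa in _POSITIVE else (-1 if aa in _NEGATIVE else 0)
                for aa in seq[:cleave]
            )
            return SignalPeptideCall(
                klass="sec_like",
                cleavage_pos=cleave,
                leader_net_charge=prefix_charge,
                downstream_hydrophobicity=float(np.mean(down)) if down.size else 0.0,
            )
    return SignalPeptideCall(klass="none")


def classify_localization(
    seq: str | None,
    tm: TMProfile | None,
    sp: SignalPeptideCall | None,
) -> str:
    """Coarse localization: secreted / membrane / cytoplasmic / unknown.

    A single TM segment that starts within the first 45 residues of a protein
    with a detected signal peptide is taken to be the leader's hydrophobic
    domain rather than a true anchor.
    """
    if seq is None:
        return "unknown"
    tm = tm or TMProfile()
    sp = sp or SignalPeptideCall(klass="none")
    tm_count = tm.count
    if tm_count == 1 and sp.klass != "none" and tm.segments[0][0] <= 45:
        tm_count = 0
    if tm_count >= 1:
        return "membrane"
    if sp.klass != "none":
        return "secreted"
    return "cytoplasmic"


@dataclass(frozen=True)
class ProteinFeatures:
    """Bundle of per-protein calls used by census curation and pilin calling."""

    tm: TMProfile | None = None
    signal: SignalPeptideCall | None = None
    localization: str = "unknown"

    @property
    def is_class3(self) -> bool:
        return self.signal is not None and self.signal.klass == "class_III"


def compute_features(
    tables: Iterable["GenomeTable"],  # noqa: F821 - forward ref, see genome_io
    tm_kwargs: Mapping[str, object] | None = None,
    sp_kwargs: Mapping[str, object] | None = None,
) -> dict[tuple[str, str], ProteinFeatures]:
    """Run all detectors over every protein-bearing gene of a collection.

    Returns a mapping keyed by (genome_id, gene_id).  Genes without a protein
    sequence get localization "unknown".  Proteins too short for a detector
    are scored with whatever detectors do apply.
    """
    tm_kwargs = dict(tm_kwargs or {})
    sp_kwargs = dict(sp_kwargs or {})
    out: dict[tuple[str, str], ProteinFeatures] = {}
    for table in tables:
        for rec in table.genes():
            seq = rec.protein_seq
            if not seq:
                out[(table.genome_id, rec.gene_id)] = ProteinFeatures()
                continue
            window = int(tm_kwargs.get("window", 19))
            tm = predict_tm_segments(seq, **tm_kwargs) if len(seq) >= window else TMProfile()
            sp = (
                detect_class3(seq, **sp_kwargs)
                if len(seq) >= 45
                else SignalPeptideCall(klass="none")
            )
            out[(table.genome_id, rec.gene_id)] = ProteinFeatures(
                tm=tm,
                signal=sp,
                localization=classify_localization(seq, tm, sp),
            )
    return out
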