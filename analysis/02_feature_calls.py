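#!/usr/bin/env python
"""Run the sequence-feature detectors over the simulated proteomes.

Reads results/genes.tsv (from 01_simulate.py), calls signal peptides, TM
segments and localization for every protein, and writes the per-protein
table plus a localization breakdown.
"""

from collections import Counter
from pathlib import Path

from t4pcensus.features import compute_features
from t4pcensus.genome_io import read_gene_table

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    genomes = read_gene_table(OUT / "genes.tsv")
    features = compute_features(genomes)
    with open(OUT / "feature_calls.tsv", "w") as fh:
        fh.write("genome_id\tgene_id\tsignal\tcleavage_pos\ttm_count\tlocalization\n")
        for (genome_id, gene_id), f in sorted(features.items()):
            sp = f.signal
            fh.write(
                f"{genome_id}\t{gene_id}\t{sp.klass if sp else 'none'}"
                f"\t{sp.cleavage_pos if sp and sp.cleavage_pos else ''}"
                f"\t{f.tm.count if f.tm else 0}\t{f.localization}\n"
            )
    print(f"scored {len(features)} proteins")
    print("localization:", dict(Counter(f.localization for f in features.values())))
    print("class III calls:", sum(1 for f in features.values() if f.is_class3))


if __name__ == "__main__":
    main()
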