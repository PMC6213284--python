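"""Differential 6-8 nt k-mer enrichment between Class I and Class II
element sequences."""

from pathlib import Path

import pandas as pd

from occudyn.formats_io import read_bed, read_fasta
from occudyn.motifs import differential_kmers

ROOT = Path(__file__).resolve().parent.parent
BUNDLE = ROOT / "results" / "bundle"
OUT = ROOT / "results"


def main() -> None:
    classes = {
        (r.chrom, r.start, r.end): r.name
        for r in read_bed(OUT / "cobound_elements.bed")
    }
    fg, bg = [], []
    for seq_id, seq in read_fasta(BUNDLE / "element_sequences.fa").items():
        if "|" not in seq_id:
            continue
        chrom, span = seq_id.split("|", 1)[1].rsplit(":", 1)
        start, end = (int(x) for x in span.split("-"))
        label = classes.get((chrom, start, end))
        if label == "ClassI":
            fg.append(seq)
        elif label == "ClassII":
            bg.append(seq)
    for name, a, b in (("ClassI_vs_ClassII", fg, bg), ("ClassII_vs_ClassI", bg, fg)):
        results = differential_kmers(a, b, k_range=(6, 7, 8))
        pd.DataFrame(
            [(r.kmer, r.k, r.fg_count, r.bg_count, r.p_value, r.e_value) for r in results[:100]],
            columns=["kmer", "k", "fg_count", "bg_count", "p_value", "e_value"],
        ).to_csv(OUT / f"kmers_{name}.tsv", sep="\t", index=False)
        print(f"{name}: top k-mer {results[0].kmer} (E = {results[0].e_value:.3g})")


if __name__ == "__main__":
    main()
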