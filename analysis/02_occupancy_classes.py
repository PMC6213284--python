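"""Quantify occupancy over merged peaks, compute retention, and classify
co-bound elements; writes the occupancy/retention/class tables."""

from pathlib import Path

import pandas as pd
import yaml

from occudyn.binding import build_occupancy_table, class_count_table, cobound_elements
from occudyn.formats_io import GenomicRegion, read_bed, read_bedgraph, write_bed

ROOT = Path(__file__).resolve().parent.parent
BUNDLE = ROOT / "results" / "bundle"
OUT = ROOT / "results"


def main() -> None:
    manifest = yaml.safe_load((BUNDLE / "manifest.yaml").read_text())
    igg = {
        cond: read_bedgraph(BUNDLE / e["track"], e["library_size"], label=f"IgG_{cond}")
        for cond, e in manifest["igg"].items()
    }
    tables = {}
    for factor, by_cond in manifest["factors"].items():
        peaks = {c: read_bed(BUNDLE / e["peaks"]) for c, e in by_cond.items()}
        tracks = {
            c: (read_bedgraph(BUNDLE / e["chip"], e["library_size"]), igg[c])
            for c, e in by_cond.items()
        }
        table = build_occupancy_table(factor, peaks, tracks)
        tables[factor] = table
        table.to_frame().to_csv(OUT / f"occupancy_{factor}.tsv", sep="\t")
        ret = table.retention_table()
        status = table.status_table(manifest["reference"])
        pd.concat(
            [ret.add_prefix("retention_"), status.add_prefix("status_")], axis=1
        ).to_csv(OUT / f"retention_{factor}.tsv", sep="\t")

    elements = cobound_elements(
        tables["OCT4"], tables["NANOG"], manifest["reference"], manifest["terminal"]
    )
    counts = pd.Series([e.class_label for e in elements]).value_counts().to_dict()
    table = class_count_table(counts)
    table.to_csv(OUT / "class_counts.tsv", sep="\t")
    write_bed(
        OUT / "cobound_elements.bed",
        [
            GenomicRegion(e.region.chrom, e.region.start, e.region.end, e.class_label)
            for e in elements
        ],
    )
    print(table)


if __name__ == "__main__":
    main()
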