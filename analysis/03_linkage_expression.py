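"""Link classified elements to nearby genes, run differential expression,
summarize class-wise fold changes, and test ranked-tail target enrichment."""

from pathlib import Path

import pandas as pd
import yaml

from occudyn.binding import CoboundElement
from occudyn.formats_io import read_bed, read_expression_matrix, read_gene_table
from occudyn.linkage import (
    class_expression_summary,
    link_elements_to_genes,
    simple_de,
    target_rank_enrichment,
)

ROOT = Path(__file__).resolve().parent.parent
BUNDLE = ROOT / "results" / "bundle"
OUT = ROOT / "results"
TAIL_K = 50


def main() -> None:
    manifest = yaml.safe_load((BUNDLE / "manifest.yaml").read_text())
    reference, terminal = manifest["reference"], manifest["terminal"]
    elements = [
        CoboundElement(region=r, class_label=r.name)
        for r in read_bed(OUT / "cobound_elements.bed")
    ]
    genes = read_gene_table(BUNDLE / manifest["genes"])
    expr = read_expression_matrix(BUNDLE / manifest["expression"])

    links = link_elements_to_genes(elements, genes)
    pd.DataFrame(
        [(l.element_id, l.gene_id, l.distance, l.class_label) for l in links],
        columns=["element_id", "gene_id", "distance", "class_label"],
    ).to_csv(OUT / "gene_links.tsv", sep="\t", index=False)

    de = simple_de(expr, terminal, reference)
    de.to_csv(OUT / "de_results.tsv", sep="\t", index_label="gene_id")

    summaries = class_expression_summary(links, de, expr, reference=reference)
    rows = []
    for name, s in summaries.items():
        for cond, st in s.per_condition.items():
            rows.append({"class": name, "condition": cond, "n_linked": s.n_linked, "n_de": s.n_de} | st)
    pd.DataFrame(rows).to_csv(OUT / "class_expression_summary.tsv", sep="\t", index=False)

    targets = sorted({l.gene_id for l in links if bool(de.loc[l.gene_id, "is_de"])})
    frac, p = target_rank_enrichment(de, targets, TAIL_K)
    pd.DataFrame(
        [{"n_targets": len(targets), "tail_k": TAIL_K, "fraction_in_tails": frac, "hypergeometric_p": p}]
    ).to_csv(OUT / "target_enrichment.tsv", sep="\t", index=False)
    print(f"{len(links)} links, {int(de['is_de'].sum())} DE genes")
    print(f"fraction of linked DE genes in top/bottom {TAIL_K}: {frac:.3f} (P = {p:.3g})")


if __name__ == "__main__":
    main()
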