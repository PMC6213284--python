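"""Percent CpG methylation from restriction-protection qPCR Ct values for a
small worked example panel."""

from pathlib import Path

import pandas as pd

from occudyn.assays import methylation_table

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"

# worked example: Ct shifts chosen to span full protection to near-complete
# digestion across the reference -> terminal transition
CT_PANEL = pd.DataFrame(
    {
        "site": ["siteA", "siteA", "siteA", "siteB", "siteB", "siteB"],
        "condition": ["EH", "EM", "EN", "EH", "EM", "EN"],
        "ct_digested": [25.1, 25.9, 28.2, 24.3, 24.5, 25.3],
        "ct_mock": [25.2, 25.0, 24.9, 24.4, 24.2, 24.4],
    }
)


def main() -> None:
    table = methylation_table(CT_PANEL)
    table.to_csv(OUT / "methylation.tsv", sep="\t", index=False)
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
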