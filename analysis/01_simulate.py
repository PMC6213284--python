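"""Generate the synthetic input bundle (peaks, tracks, genes, expression,
sequences, stage profiles) with ground truth into results/bundle/."""

from pathlib import Path

from occudyn.formats_io import write_expression_matrix
from occudyn.synthetic import (
    StageConfig,
    SyntheticConfig,
    generate_dataset,
    generate_stage_profiles,
)

SEED = 1
ROOT = Path(__file__).resolve().parent.parent
BUNDLE = ROOT / "results" / "bundle"


def main() -> None:
    ds = generate_dataset(SyntheticConfig(), seed=SEED)
    ds.write(BUNDLE)
    profiles, queries, truth = generate_stage_profiles(StageConfig(), seed=SEED)
    write_expression_matrix(BUNDLE / "stage_profiles.tsv", profiles.as_expression_matrix())
    write_expression_matrix(BUNDLE / "stage_queries.tsv", queries)
    truth.to_csv(BUNDLE / "truth_stages.tsv", sep="\t", index=False)
    print(f"wrote bundle to {BUNDLE}")
    print(ds.truth.class_counts())


if __name__ == "__main__":
    main()
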