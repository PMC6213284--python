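"""Stage query transcriptomes against the reference stage profiles using
Pearson correlation over the top stage-discriminating genes."""

from pathlib import Path

from occudyn.formats_io import read_expression_matrix
from occudyn.staging import StageProfileSet, hotelling_rank, select_top_k, stage_samples

ROOT = Path(__file__).resolve().parent.parent
BUNDLE = ROOT / "results" / "bundle"
OUT = ROOT / "results"


def main() -> None:
    prof_expr = read_expression_matrix(BUNDLE / "stage_profiles.tsv")
    profiles = StageProfileSet(
        stages=list(dict.fromkeys(prof_expr.conditions)),
        values=prof_expr.values,
        stage_of=prof_expr.conditions,
    )
    subset = select_top_k(hotelling_rank(profiles), 500)
    queries = read_expression_matrix(BUNDLE / "stage_queries.tsv")
    result = stage_samples(queries, profiles, subset)
    out = result.correlation.copy()
    out["best_stage"] = result.best_stage
    out.to_csv(OUT / "staging.tsv", sep="\t", index_label="sample")
    print(out["best_stage"].to_string())


if __name__ == "__main__":
    main()
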