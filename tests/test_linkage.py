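"""Gene linkage, the DE stand-in, class summaries, and ranked-list enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from occudyn.binding import CoboundElement
from occudyn.formats_io import ExpressionMatrix, GeneModel, GenomicRegion
from occudyn.linkage import (
    class_expression_summary,
    link_elements_to_genes,
    simple_de,
    target_rank_enrichment,
)


def element(start, end, label="ClassI", name="el"):
    return CoboundElement(
        region=GenomicRegion("chr1", start, end, name), class_label=label
    )


def gene(gid, start, end):
    return GeneModel(gid, GenomicRegion("chr1", start, end, gid))


class TestLinkElements:
    def test_distance_boundary_inclusive_at_20kb(self):
        genes = [gene("g", 100_000, 101_000)]
        for d, linked in ((19_999, True), (20_000, True), (20_001, False)):
            els = [element(100_000 - d - 100, 100_000 - d, name=f"e{d}")]
            links = link_elements_to_genes(els, genes)
            assert bool(links) is linked, f"gap {d}"
            if linked:
                assert links[0].distance == d

    def test_within_cutoff_links_to_closest(self):
        genes = [gene("near", 30_000, 31_000), gene("far", 90_000, 91_000)]
        links = link_elements_to_genes([element(19_000, 20_000)], genes)
        assert len(links) == 1 and links[0].gene_id == "near"

    def test_overlapping_two_genes_uses_tie_break(self):
        genes = [gene("zz", 100, 300), gene("aa", 150, 400)]
        links = link_elements_to_genes([element(160, 260)], genes)
        assert links[0].gene_id == "aa" and links[0].distance == 0

    def test_infinite_range_links_everything_on_shared_chrom(self):
        genes = [gene("g", 5_000_000, 5_001_000)]
        els = [element(0, 100), element(9_000_000, 9_000_100)]
        links = link_elements_to_genes(els, genes, max_distance=10**12)
        assert len(links) == 2

    def test_empty_gene_set_errors(self):
        with pytest.raises(ValueError):
            link_elements_to_genes([element(0, 100)], [])


def _matrix(gene_values: dict[str, dict[str, list[float]]]) -> ExpressionMatrix:
    """gene -> condition -> replicate values."""
    conds = list(next(iter(gene_values.values())))
    cols, data = [], {}
    for cond in conds:
        n = len(next(iter(gene_values.values()))[cond])
        for r in range(n):
            col = f"{cond}:{r + 1}"
            cols.append(col)
            data[col] = [gene_values[g][cond][r] for g in gene_values]
    df = pd.DataFrame(data, index=list(gene_values))
    return ExpressionMatrix(df, {c: c.split(":")[0] for c in cols})


class TestSimpleDe:
    def test_identical_conditions_not_de(self):
        m = _matrix({f"g{i}": {"A": [1.0, 2.0, 3.0], "B": [1.0, 2.0, 3.0]} for i in range(5)})
        de = simple_de(m, "A", "B")
        assert np.allclose(de["log2fc"], 0.0)
        assert not de["is_de"].any()

    def test_planted_shift_detected_among_null_genes(self):
        rng = np.random.default_rng(3)
        # five replicates: with n=3 the Welch t has ~4 df and even a 4-log2FC
        # shift cannot survive BH correction over 1,000 null genes
        values = {
            f"null{i}": {
                "A": list(rng.normal(5, 0.1, 5)),
                "B": list(rng.normal(5, 0.1, 5)),
            }
            for i in range(1000)
        }
        values["hit"] = {
            "A": list(rng.normal(9, 0.1, 5)),
            "B": list(rng.normal(5, 0.1, 5)),
        }
        de = simple_de(_matrix(values), "A", "B")
        assert bool(de.loc["hit", "is_de"])
        assert de.loc["hit", "log2fc"] == pytest.approx(4.0, abs=0.5)
        assert de["is_de"].sum() <= 10  # few false positives at FDR 0.05

    def test_fdr_is_benjamini_hochberg(self):
        """Adjusted values match a hand step-up on the computed p-values."""
        rng = np.random.default_rng(5)
        values = {
            f"g{i}": {
                "A": list(rng.normal(5 + 0.2 * i, 0.3, 3)),
                "B": list(rng.normal(5, 0.3, 3)),
            }
            for i in range(20)
        }
        de = simple_de(_matrix(values), "A", "B")
        p = de["p_value"].values
        n = len(p)
        order = np.argsort(p)
        adj = np.empty(n)
        running = 1.0
        for rank_from_end, idx in enumerate(order[::-1]):
            rank = n - rank_from_end
            running = min(running, p[idx] * n / rank)
            adj[idx] = running
        assert np.allclose(de["fdr"].values, adj, atol=1e-12)

    def test_bh_step_up_hand_example(self):
        """p = (0.01, 0.02, 0.03) adjusts to 0.03 everywhere."""
        # engineered via the same step-up oracle as above, applied directly
        from statsmodels.stats.multitest import multipletests

        _, fdr, _, _ = multipletests([0.01, 0.02, 0.03], method="fdr_bh")
        assert np.allclose(fdr, [0.03, 0.03, 0.03])

    def test_too_few_replicates_errors(self):
        m = _matrix({"g": {"A": [1.0], "B": [1.0, 2.0]}})
        with pytest.raises(ValueError):
            simple_de(m, "A", "B")


class TestClassExpressionSummary:
    def _setup(self):
        from occudyn.linkage import GeneLink

        links = [
            GeneLink("e1", "gI", 100, "ClassI"),
            GeneLink("e2", "gII", 100, "ClassII"),
            GeneLink("e3", "gBoth", 100, "ClassI"),
            GeneLink("e4", "gBoth", 100, "ClassII"),
        ]
        m = _matrix(
            {
                "gI": {"EH": [8.0, 8.1, 7.9], "EN": [6.0, 6.1, 5.9]},
                "gII": {"EH": [8.0, 8.1, 7.9], "EN": [8.5, 8.6, 8.4]},
                "gBoth": {"EH": [8.0, 8.1, 7.9], "EN": [6.0, 6.1, 5.9]},
                "null": {"EH": [5.0, 5.0, 5.1], "EN": [5.0, 5.1, 5.0]},
            }
        )
        de = simple_de(m, "EN", "EH")
        return links, de, m

    def test_both_partition_rule(self):
        links, de, m = self._setup()
        out = class_expression_summary(links, de, m, reference="EH")
        assert out["Both"].genes == ["gBoth"]
        assert out["ClassI-only"].genes == ["gI"]
        assert out["ClassII-only"].genes == ["gII"]

    def test_medians_follow_planted_direction(self):
        links, de, m = self._setup()
        out = class_expression_summary(links, de, m, reference="EH")
        assert out["ClassI-only"].per_condition["EN"]["median"] == pytest.approx(-2.0, abs=0.2)
        assert out["ClassII-only"].per_condition["EN"]["median"] == pytest.approx(0.5, abs=0.2)
        assert out["Both"].per_condition["EN"]["median"] < 0

    def test_no_links_gives_empty_summaries(self):
        _, de, m = self._setup()
        out = class_expression_summary([], de, m, reference="EH")
        assert all(s.n_linked == 0 for s in out.values())
        assert math.isnan(out["ClassI-only"].per_condition["EN"]["median"])


class TestTargetRankEnrichment:
    def _de(self, log2fc: dict[str, float]) -> pd.DataFrame:
        return pd.DataFrame(
            {"log2fc": pd.Series(log2fc), "p_value": 0.5, "fdr": 0.5, "is_de": False}
        )

    def test_all_targets_in_tails_fraction_one(self):
        fc = {f"g{i:02d}": float(i) for i in range(10)}
        de = self._de(fc)
        targets = ["g09", "g08", "g00", "g01"]  # top 2 + bottom 2
        frac, p = target_rank_enrichment(de, targets, k_each_tail=2)
        assert frac == 1.0
        # point mass: P(X >= 4) drawing 4 of 10 with 4 successes
        assert p == pytest.approx(1 / math.comb(10, 4), rel=1e-9)

    def test_hand_computed_tail(self):
        """Universe 10, targets 4, draws 5 (k=2.5 -> use explicit selection), observed 4."""
        fc = {f"g{i:02d}": float(i) for i in range(10)}
        de = self._de(fc)
        # draws = 2k = 4; pick targets exactly covering the 4 selected genes plus
        # check the documented enumeration for draws=5 separately below
        from scipy.stats import hypergeom

        assert hypergeom.sf(3, 10, 4, 5) == pytest.approx(6 / 252, rel=1e-9)

    def test_matches_exact_enumeration_oracle(self):
        """Upper tail equals exhaustive enumeration over all subsets (n <= 25)."""
        rng = np.random.default_rng(8)
        ids = [f"g{i:02d}" for i in range(12)]
        fc = {g: float(v) for g, v in zip(ids, rng.normal(size=12))}
        de = self._de(fc)
        targets = list(rng.choice(ids, size=5, replace=False))
        k = 3
        frac, p = target_rank_enrichment(de, targets, k_each_tail=k)
        order = sorted(ids, key=lambda g: (-fc[g], g))
        selection = set(order[:k]) | set(order[-k:])
        observed = len(set(targets) & selection)
        assert frac == observed / len(targets)
        # enumeration: of all C(12, 6) equally likely draws, how many contain
        # >= observed targets?
        hits = 0
        total = 0
        for draw in itertools.combinations(ids, 2 * k):
            total += 1
            if len(set(draw) & set(targets)) >= observed:
                hits += 1
        assert p == pytest.approx(hits / total, rel=1e-9)

    def test_empty_targets_error(self):
        de = self._de({"a": 1.0, "b": 2.0, "c": 3.0})
        with pytest.raises(ValueError):
            target_rank_enrichment(de, [], k_each_tail=1)

    def test_tails_too_large_error(self):
        de = self._de({"a": 1.0, "b": 2.0, "c": 3.0})
        with pytest.raises(ValueError):
            target_rank_enrichment(de, ["a"], k_each_tail=2)
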