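"""S-chimera calling: binning, Fisher's exact test, merging, gene assignment."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rilpipe.annotation import Feature, FeatureSet
from rilpipe.calling import (
    AnalysisParams,
    annotate_s_chimeras,
    assign_genes,
    bin_chimeras,
    call_s_chimeras,
    circos_links,
    filter_nonsignificant,
    fisher_one_sided,
    interaction_table,
    score_window_pairs,
    write_interaction_table,
)
from rilpipe.fragments import Fragment, Locus

from helpers import fisher_upper_tail_exact


def chimera(mid1, mid2, rid="r", strand1="+", strand2="+", half=10):
    return Fragment(
        rid,
        "Chimeric",
        Locus("chr", mid1 - half, mid1 + half, strand1),
        Locus("chr", mid2 - half, mid2 + half, strand2),
    )


class TestParams:
    @pytest.mark.parametrize(
        "kwargs", [{"alpha": 0.0}, {"alpha": 1.0}, {"assign_ratio": 1.0},
                   {"min_chimeras": 0}, {"window": 0}]
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AnalysisParams(**kwargs)


class TestBinning:
    def test_single_chimera_gives_unit_counts(self):
        counts = bin_chimeras([chimera(150, 950)], AnalysisParams())
        assert counts.total == 1
        ((key, n),) = counts.pair_counts.items()
        assert n == 1
        assert key == (("chr", "+", 1), ("chr", "+", 9))

    def test_pair_counts_conserve_chimera_total(self):
        rng = np.random.default_rng(0)
        frags = [
            chimera(int(rng.integers(50, 5000)), int(rng.integers(50, 5000)), f"r{i}")
            for i in range(500)
        ]
        counts = bin_chimeras(frags, AnalysisParams())
        assert sum(counts.pair_counts.values()) == 500
        assert sum(counts.n1.values()) == sum(counts.n2.values()) == 500

    def test_same_window_midpoints_collapse_to_one_key(self):
        frags = [chimera(110, 950, "a"), chimera(190, 960, "b")]
        counts = bin_chimeras(frags, AnalysisParams())
        assert len(counts.pair_counts) == 1
        assert counts.pair_counts[(("chr", "+", 1), ("chr", "+", 9))] == 2


class TestFisher:
    def test_zero_overlap_gives_p_one(self):
        _, p = fisher_one_sided(0, 3, 4, 10)
        assert p == pytest.approx(1.0)

    def test_single_most_extreme_table(self):
        # a=2, b=0, c=0, d=3: P(X >= 2) = 1/C(5,2) = 0.1
        odds, p = fisher_one_sided(2, 2, 2, 5)
        assert p == pytest.approx(0.1)
        assert odds == math.inf

    def test_matches_enumeration_oracle(self):
        _, p = fisher_one_sided(5, 10, 10, 100)
        assert p == pytest.approx(fisher_upper_tail_exact(5, 100, 10, 10), abs=1e-12)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            fisher_one_sided(5, 3, 10, 100)

    def test_degenerate_odds_ratio_is_nan(self):
        odds, p = fisher_one_sided(0, 0, 0, 10)
        assert math.isnan(odds) and p == pytest.approx(1.0)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.data())
    def test_p_monotone_decreasing_in_overlap_at_fixed_margins(self, data):
        total = data.draw(st.integers(2, 80))
        n_a = data.draw(st.integers(1, total))
        n_b = data.draw(st.integers(1, total))
        lo = max(0, n_a + n_b - total)
        hi = min(n_a, n_b)
        ps = [fisher_one_sided(a, n_a, n_b, total)[1] for a in range(lo, hi + 1)]
        assert all(p1 >= p2 - 1e-12 for p1, p2 in zip(ps, ps[1:]))


class TestCalling:
    def test_count_floor_blocks_sparse_but_extreme_pairs(self):
        # 4 repeats of one pair against a diffuse background: tiny p but
        # below the 5-fragment floor
        frags = [chimera(150, 950, f"a{i}") for i in range(4)]
        frags += [
            chimera(5000 + 200 * i, 9000 + 200 * i, f"b{i}") for i in range(400)
        ]
        counts = bin_chimeras(frags, AnalysisParams())
        tested = score_window_pairs(counts, AnalysisParams())
        target = [t for t in tested if t.n_ab == 4]
        assert target and target[0].p_value < 1e-6
        called = call_s_chimeras(counts, AnalysisParams())
        assert all(s.interactions >= 5 for s in called)
        assert not any(s.candidate.n_ab == 4 for s in called)

    def test_concentrated_pair_in_diffuse_background_is_called(self):
        frags = [chimera(150, 950, f"a{i}") for i in range(50)]
        rng = np.random.default_rng(7)
        frags += [
            chimera(int(rng.integers(2000, 100_000)), int(rng.integers(2000, 100_000)),
                    f"b{i}")
            for i in range(1000)
        ]
        called = call_s_chimeras(bin_chimeras(frags, AnalysisParams()), AnalysisParams())
        hits = [s for s in called if s.interactions >= 50]
        assert len(hits) == 1
        p_oracle = fisher_upper_tail_exact(
            hits[0].candidate.n_ab, hits[0].candidate.total,
            hits[0].candidate.n_a, hits[0].candidate.n_b,
        )
        assert hits[0].candidate.p_value < 0.05
        assert hits[0].candidate.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_adjacent_significant_windows_merge_into_one_region_pair(self):
        # the same interaction straddles a window boundary on side 1
        frags = [chimera(195, 950, f"a{i}") for i in range(10)]
        frags += [chimera(205, 950, f"b{i}") for i in range(10)]
        rng = np.random.default_rng(3)
        frags += [
            chimera(int(rng.integers(5000, 80_000)), int(rng.integers(5000, 80_000)),
                    f"c{i}")
            for i in range(500)
        ]
        called = call_s_chimeras(bin_chimeras(frags, AnalysisParams()), AnalysisParams())
        merged = [s for s in called if s.interactions == 20]
        assert len(merged) == 1
        r1 = merged[0].candidate.region1
        assert (r1[2], r1[3]) == (100, 300)  # two merged 100-nt windows

    def test_retained_chimeras_equal_summed_interactions(self):
        rng = np.random.default_rng(11)
        frags = [chimera(150, 950, f"a{i}") for i in range(30)]
        frags += [
            chimera(int(rng.integers(2000, 50_000)), int(rng.integers(2000, 50_000)),
                    f"b{i}")
            for i in range(300)
        ]
        params = AnalysisParams()
        called = call_s_chimeras(bin_chimeras(frags, params), params)
        retained = filter_nonsignificant(frags, called)
        assert len(retained) == sum(s.interactions for s in called)

    def test_no_s_chimeras_retains_nothing(self):
        frags = [chimera(150, 950, "a")]
        assert filter_nonsignificant(frags, []) == []


class TestGeneAssignment:
    @pytest.fixture
    def two_genes(self):
        feats = [
            Feature("geneA", "chr", 0, 100, "+", "gene", "geneA"),
            Feature("geneB", "chr", 200, 300, "+", "gene", "geneB"),
        ]
        return FeatureSet(feats, {"chr": 1000})

    def reads(self, n_a, n_b):
        return [(10, 30)] * n_a + [(210, 230)] * n_b

    def test_dominant_gene_assigned_exclusively(self, two_genes):
        assert assign_genes(self.reads(80, 20), "chr", "+", two_genes) == ["geneA"]

    def test_shared_region_keeps_all_genes_by_share(self, two_genes):
        assert assign_genes(self.reads(60, 40), "chr", "+", two_genes) == [
            "geneA",
            "geneB",
        ]

    def test_exact_boundary_share_keeps_both(self, two_genes):
        # 0.70 is not strictly greater than 0.7
        assert assign_genes(self.reads(70, 30), "chr", "+", two_genes) == [
            "geneA",
            "geneB",
        ]

    def test_region_overlapping_nothing_gets_nearest_with_suffix(self, two_genes):
        assert assign_genes([(120, 140)], "chr", "+", two_genes) == ["geneA.near"]


class TestOutput:
    def make_called(self):
        frags = [chimera(150, 950, f"a{i}") for i in range(20)]
        rng = np.random.default_rng(5)
        frags += [
            chimera(int(rng.integers(2000, 50_000)), int(rng.integers(2000, 50_000)),
                    f"b{i}")
            for i in range(200)
        ]
        params = AnalysisParams()
        called = call_s_chimeras(bin_chimeras(frags, params), params)
        ann = FeatureSet(
            [
                Feature("m1", "chr", 100, 400, "+", "gene", "m1"),
                Feature("s1", "chr", 900, 1000, "+", "sRNA", "s1"),
            ],
            {"chr": 200_000},
        )
        annotate_s_chimeras(called, filter_nonsignificant(frags, called), ann, params)
        return called

    def test_table_roundtrip_preserves_counts(self, tmp_path):
        import pandas as pd

        called = self.make_called()
        path = tmp_path / "interactions.tsv"
        df = write_interaction_table(called, path)
        back = pd.read_csv(path, sep="\t")
        assert list(back["interactions"]) == [s.interactions for s in called]
        assert back.shape[0] == len(called)
        focal = back[back["interactions"] == 20].iloc[0]
        assert focal["RNA1_name"] == "m1"
        assert focal["RNA2_name"] == "s1"

    def test_empty_call_set_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.tsv"
        df = write_interaction_table([], path)
        assert df.empty
        assert path.read_text().count("\n") == 1

    def test_circos_links_one_line_per_s_chimera(self, tmp_path):
        called = self.make_called()
        path = tmp_path / "links.txt"
        circos_links(called, path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == len(called)
        assert all(len(l.split()) == 7 for l in lines)
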