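"""Annotation construction: predicted UTRs, antisense, IGR/TU, GFF3 I/O."""

import pytest

from rilpipe.annotation import (
    AnnotationError,
    Feature,
    FeatureSet,
    build_antisense,
    build_igrs_and_tus,
    build_predicted_utrs,
    compose_annotation,
)
from rilpipe.simulate import SimulationConfig, simulate_genome

from conftest import make_feature
from helpers import feature_free_gap_length


class TestGFF3IO:
    def test_one_based_inclusive_to_half_open(self, tmp_path):
        gff = tmp_path / "a.gff3"
        gff.write_text("chr\tsrc\tgene\t1\t100\t.\t+\t.\tID=g1;Name=geneA\n")
        fs = FeatureSet.load_gff3(gff, {"chr": 1000})
        (f,) = fs
        assert (f.start, f.end, f.strand, f.name) == (0, 100, "+", "geneA")

    def test_empty_file_gives_empty_set(self, tmp_path):
        gff = tmp_path / "empty.gff3"
        gff.write_text("")
        assert len(FeatureSet.load_gff3(gff, {"chr": 1000})) == 0

    def test_malformed_line_names_line_number(self, tmp_path):
        gff = tmp_path / "bad.gff3"
        gff.write_text("chr\tsrc\tgene\t1\t100\t.\t+\t.\tID=ok\nnot a gff line\n")
        with pytest.raises(AnnotationError, match="line 2"):
            FeatureSet.load_gff3(gff, {"chr": 1000})

    def test_out_of_bounds_feature_rejected(self, tmp_path):
        gff = tmp_path / "oob.gff3"
        gff.write_text("chr\tsrc\tgene\t1\t5000\t.\t+\t.\tID=g1\n")
        with pytest.raises(AnnotationError, match="beyond"):
            FeatureSet.load_gff3(gff, {"chr": 1000})

    def test_roundtrip_is_identity(self, tmp_path):
        _, fs = simulate_genome(SimulationConfig(seed=3, genome_length=60_000,
                                                 n_mrna=10, n_srna=6, n_trna=3,
                                                 n_rrna=1))
        path = tmp_path / "rt.gff3"
        fs.write_gff3(path)
        again = FeatureSet.load_gff3(path, fs.genome_lengths)
        assert again == fs


class TestPredictedUTRs:
    def base(self, upstream_end):
        # the upstream neighbour is non-coding so it spawns no UTR of its
        # own: the gap belongs entirely to g's predicted 5'UTR
        feats = [
            make_feature("up", 500, upstream_end, "+", ftype="sRNA"),
            make_feature("g", 1000, 2000, "+"),
        ]
        return FeatureSet(feats, {"chr": 10_000})

    def test_full_length_when_gap_is_wide(self):
        utrs = build_predicted_utrs(self.base(750))
        five = [f for f in utrs if f.ftype == "EST5UTR" and "g.EST" in f.name]
        assert [(f.start, f.end) for f in five] == [(900, 1000)]

    def test_truncated_to_gap(self):
        utrs = build_predicted_utrs(self.base(940))
        five = [f for f in utrs if f.ftype == "EST5UTR" and f.name == "g.EST5UTR"]
        assert [(f.start, f.end) for f in five] == [(940, 1000)]

    def test_zero_gap_emits_nothing(self):
        utrs = build_predicted_utrs(self.base(1000))
        assert not [f for f in utrs if f.name == "g.EST5UTR"]

    def test_minus_strand_directions_mirrored(self):
        fs = FeatureSet([make_feature("g", 1000, 2000, "-")], {"chr": 10_000})
        utrs = build_predicted_utrs(fs)
        by_type = {f.ftype: (f.start, f.end) for f in utrs}
        # 5'UTR of a minus-strand gene lies to the right of its end
        assert by_type["EST5UTR"] == (2000, 2100)
        assert by_type["EST3UTR"] == (900, 1000)

    def test_facing_genes_share_a_narrow_gap_without_overlap(self):
        fs = FeatureSet(
            [make_feature("a", 0, 1000, "+"), make_feature("b", 1150, 2000, "+")],
            {"chr": 10_000},
        )
        utrs = sorted(
            (f for f in build_predicted_utrs(fs) if f.end <= 1150),
            key=lambda f: f.start,
        )
        a3, b5 = utrs
        assert a3.end <= b5.start  # split, never overlapping
        assert (a3.end - a3.start) + (b5.end - b5.start) == 150


class TestAntisense:
    def test_mirrors_coordinates_and_names(self, toy_genes):
        asf = {f.name: f for f in build_antisense(toy_genes)}
        assert (asf["g1.AS"].start, asf["g1.AS"].end, asf["g1.AS"].strand) == (
            1000,
            2000,
            "-",
        )
        assert asf["g4.AS"].strand == "+"

    def test_overlapping_genes_keep_separate_as_features(self):
        fs = FeatureSet(
            [make_feature("a", 100, 300, "+"), make_feature("b", 200, 400, "+")],
            {"chr": 1000},
        )
        asf = build_antisense(fs)
        assert len(asf) == 2
        assert {f.strand for f in asf} == {"-"}

    def test_non_coding_features_get_no_antisense(self):
        fs = FeatureSet(
            [make_feature("s", 100, 200, "+", ftype="sRNA")], {"chr": 1000}
        )
        assert len(build_antisense(fs)) == 0


class TestIGRsAndTUs:
    @pytest.mark.parametrize(
        "gap,expected_type",
        [(50, "TU"), (150, "IGR"), (100, "IGR"), (99, "TU")],
    )
    def test_tu_igr_boundary_is_strictly_less_than(self, gap, expected_type):
        fs = FeatureSet(
            [make_feature("a", 0, 1000, "+"), make_feature("b", 1000 + gap, 2000, "+")],
            {"chr": 10_000},
        )
        (igr,) = build_igrs_and_tus(fs)
        assert igr.ftype == expected_type
        assert (igr.start, igr.end) == (1000, 1000 + gap)
        assert igr.name == f"a.b.{expected_type}"

    def test_strand_specific_gaps(self, toy_genes):
        igrs = build_igrs_and_tus(toy_genes)
        # + strand: g1..g2 (500 nt IGR), g2..g3 (50 nt TU); - strand: no
        # internal gap (single feature)
        assert sorted((f.ftype, f.length) for f in igrs) == [("IGR", 500), ("TU", 50)]


class TestCompose:
    def test_toy_feature_count_by_hand(self, toy_genes):
        composed = compose_annotation(toy_genes)
        # 4 genes + 8 EST-UTRs (both ends of every gene are open) + 4 AS
        # + strand-specific gaps recomputed over all stranded features
        by_type = {}
        for f in composed:
            by_type[f.ftype] = by_type.get(f.ftype, 0) + 1
        assert by_type["gene"] == 4
        assert by_type["EST5UTR"] == 4
        assert by_type["EST3UTR"] == 4
        assert by_type["AS"] == 4
        assert by_type.get("IGR", 0) + by_type.get("TU", 0) == len(composed) - 16

    def test_deterministic_and_idempotent_on_derived_features(self, toy_genes):
        a = compose_annotation(toy_genes)
        b = compose_annotation(toy_genes)
        assert a == b

    def test_empty_base_gives_empty_output(self):
        fs = FeatureSet([], {"chr": 1000})
        assert len(compose_annotation(fs)) == 0

    def test_period_in_gene_name_rejected(self):
        fs = FeatureSet(
            [make_feature("g", 0, 100, "+", name="bad.name")], {"chr": 1000}
        )
        with pytest.raises(AnnotationError, match="period"):
            compose_annotation(fs)

    def test_duplicate_feature_id_rejected(self):
        with pytest.raises(AnnotationError, match="duplicate"):
            FeatureSet(
                [make_feature("g", 0, 100), make_feature("g", 200, 300)],
                {"chr": 1000},
            )


class TestComposedInvariants:
    """Structural invariants on composed annotations of simulated genomes."""

    @pytest.mark.parametrize("seed", range(5))
    def test_utr_length_overlap_and_tiling(self, seed):
        _, base = simulate_genome(
            SimulationConfig(seed=seed, genome_length=50_000, n_mrna=8,
                             n_srna=4, n_trna=2, n_rrna=1)
        )
        composed = compose_annotation(base)
        utrs = [f for f in composed if f.ftype in ("EST5UTR", "EST3UTR")]
        others = [f for f in composed if f.ftype not in ("IGR", "TU")]
        for u in utrs:
            assert u.length <= 100
            overlaps = [
                f for f in others if f is not u and u.overlaps(f)
            ]
            assert not overlaps, (u, overlaps)
        for strand in "+-":
            gap_space = feature_free_gap_length(
                others, "chr", strand, base.genome_lengths["chr"]
            )
            igr_tu = sum(
                f.length
                for f in composed
                if f.ftype in ("IGR", "TU") and f.strand == strand
            )
            assert gap_space == igr_tu
        for a in composed:
            if a.ftype == "AS":
                assert any(
                    f.ftype in ("gene", "CDS")
                    and f.start == a.start
                    and f.end == a.end
                    and f.strand != a.strand
                    for f in composed
                )
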