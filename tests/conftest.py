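import pytest

from rilpipe.annotation import Feature, FeatureSet


def make_feature(
    feature_id,
    start,
    end,
    strand="+",
    ftype="gene",
    chrom="chr",
    name=None,
):
    return Feature(
        feature_id=feature_id,
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        ftype=ftype,
        name=name or feature_id,
    )


@pytest.fixture
def toy_genes():
    """Three + strand genes and one - strand gene on a 10 kb chromosome."""
    feats = [
        make_feature("g1", 1000, 2000, "+"),
        make_feature("g2", 2500, 3200, "+"),
        make_feature("g3", 3250, 4000, "+"),
        make_feature("g4", 5000, 6000, "-"),
    ]
    return FeatureSet(feats, {"chr": 10_000})
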