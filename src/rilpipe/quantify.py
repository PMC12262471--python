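"""Feature-level quantification, normalization, and enrichment ratios.

Fragments (single and chimeric alike; a chimera contributes each locus
once) are counted per annotation feature with multi-overlap semantics: a
fragment overlapping k same-strand features increments all k.  Libraries
are normalized with median-of-ratios size factors, fold changes are
pseudocounted mean ratios against a reference sample group, and IP/Total
enrichment is reported as a log2 ratio (positive = bound to the
immunoprecipitated protein).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation import FeatureSet
from .fragments import Fragment

UNASSIGNED = "unassigned"


def count_features(
    fragments: Iterable[Fragment], annotation: FeatureSet
) -> pd.Series:
    """Per-feature fragment counts (multi-overlap, strand-specific).

    Overlap is >=1 shared base on the same strand.  Fragments whose loci
    overlap no feature are tallied under the reserved ``unassigned`` row.
    """
    index = annotation.interval_index()
    counts: dict[str, int] = {f.name: 0 for f in annotation}
    unassigned = 0
    for frag in fragments:
        for loc in (frag.locus1, frag.locus2):
            if loc is None:
                continue
            tree = index.get((loc.chrom, loc.strand))
            hits = tree.overlap(loc.start, loc.end) if tree is not None else ()
            if not hits:
                unassigned += 1
                continue
            for iv in hits:
                counts[iv.data.name] += 1
    ser = pd.Series(counts, dtype=np.int64)
    ser[UNASSIGNED] = unassigned
    ser.index.name = "feature"
    return ser


def count_matrix(columns: dict[str, pd.Series]) -> pd.DataFrame:
    """Assemble per-sample count columns into one matrix (missing -> 0)."""
    df = pd.DataFrame(columns).fillna(0).astype(np.int64)
    df.index.name = "feature"
    return df


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For each feature with nonzero counts in every sample, the ratio of
    its count to its across-sample geometric mean is formed; the factor
    of a sample is the median of these ratios.  Exact scalar multiples
    between samples are recovered up to a common constant.
    """
    mat = counts.to_numpy(dtype=float)
    everywhere = (mat > 0).all(axis=1)
    if not everywhere.any():
        raise ValueError(
            "no feature has nonzero counts in all samples; add a pseudocount "
            "to the matrix before computing size factors"
        )
    sub = mat[everywhere]
    log_gm = np.log(sub).mean(axis=1, keepdims=True)
    ratios = sub / np.exp(log_gm)
    return pd.Series(np.median(ratios, axis=0), index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Counts divided by their median-of-ratios size factors."""
    factors = size_factors(counts)
    return counts / factors, factors


def fold_change_vs_reference(
    norm: pd.DataFrame,
    samples: Sequence[str],
    reference: Sequence[str],
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-feature pseudocounted ratio of group means against a reference.

    ratio_f = (mean over ``samples`` + pc) / (mean over ``reference`` + pc);
    the reference against itself is identically 1.
    """
    if not len(reference):
        raise ValueError("reference sample group is empty")
    num = norm[list(samples)].mean(axis=1) + pseudocount
    den = norm[list(reference)].mean(axis=1) + pseudocount
    out = num / den
    out.name = "fold_change"
    return out


def enrichment_ratio(
    ip: pd.Series, total: pd.Series, pseudocount: float = 1.0
) -> pd.DataFrame:
    """IP/Total enrichment per feature.

    Returns both the linear ratio and its log2; a ratio above 1 (log2
    above 0) means most of the RNA is associated with the protein.
    Antisymmetric in log2 under swapping ip and total.
    """
    if not ip.index.equals(total.index):
        raise ValueError("ip and total columns must share the same feature index")
    linear = (ip + pseudocount) / (total + pseudocount)
    return pd.DataFrame(
        {"ratio": linear, "log2_ratio": np.log2(linear)}, index=ip.index
    )


def normalize_chimera_counts(
    pair_counts: pd.DataFrame, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Normalize per-pair chimera count columns by each library's total.

    Used for the fold-change-vs-reference display of sRNA-mRNA pair
    counts across strains; each column is scaled to the mean library
    depth so ratios are comparable.
    """
    totals = pair_counts.sum(axis=0)
    scale = totals.mean() / totals
    return pair_counts * scale
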