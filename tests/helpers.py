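"""Independent oracles used by the test suite.

These deliberately avoid the library code paths they check: the Fisher
oracle enumerates the hypergeometric upper tail with exact integer
binomial coefficients, and the annotation-space oracle recomputes
feature-free gaps by a direct base-resolution sweep.
"""

from math import comb

import numpy as np


def fisher_upper_tail_exact(a: int, total: int, n_a: int, n_b: int) -> float:
    """P(X >= a) for X ~ Hypergeometric(total, n_a, n_b), by enumeration."""
    hi = min(n_a, n_b)
    num = sum(comb(n_a, k) * comb(total - n_a, n_b - k) for k in range(a, hi + 1))
    return num / comb(total, n_b)


def feature_free_gap_length(features, chrom, strand, genome_length) -> int:
    """Total internal feature-free space on a strand, by boolean mask sweep."""
    mask = np.zeros(genome_length, dtype=bool)
    starts = [f.start for f in features if f.chrom == chrom and f.strand == strand]
    ends = [f.end for f in features if f.chrom == chrom and f.strand == strand]
    for s, e in zip(starts, ends):
        mask[s:e] = True
    if not starts:
        return 0
    lo, hi = min(starts), max(ends)
    return int((~mask[lo:hi]).sum())
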