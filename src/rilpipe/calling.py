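"""Significant-chimera (S-chimera) calling.

Chimeric fragments are binned onto ordered pairs of fixed genomic
windows (RNA1 window, RNA2 window) by the midpoint of each locus.  For
each observed window pair the 2x2 contingency table

    a = chimeras joining this RNA1 window to this RNA2 window
    b = other chimeras with RNA1 in this window      (n_a - a)
    c = other chimeras with RNA2 in this window      (n_b - a)
    d = remaining chimeras                           (T - n_a - n_b + a)

is scored by a one-sided Fisher's exact test for over-representation:
p = P(X >= a) for X hypergeometric with population T, n_a successes and
n_b draws.  Adjacent significant window pairs are merged into maximal
region pairs; a merged region pair with at least ``min_chimeras``
supporting fragments and p below ``alpha`` is one S-chimera -- one
distinct pair of interacting RNAs.  Chimeras outside every S-chimera
region pair are treated as non-specific ligation noise and filtered.

Gene assignment follows the read-share rule: if a single feature
accounts for a share of the region's overlapping reads strictly greater
than ``assign_ratio`` (default 0.7) it is assigned exclusively,
otherwise all overlapping features are retained in decreasing share
order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .annotation import FeatureSet
from .fragments import Fragment

WindowKey = tuple[str, str, int]  # (chrom, strand, window index)


@dataclass(frozen=True)
class AnalysisParams:
    """Tunable interaction-calling parameters.

    window        -- window size in nucleotides for chimera binning
    min_chimeras  -- minimum supporting fragments per S-chimera
    alpha         -- one-sided Fisher significance level
    assign_ratio  -- exclusive gene-assignment share threshold (strict >)
    max_gap       -- Single/Chimeric inter-mate distance cutoff
    bh_correction -- apply Benjamini-Hochberg across tested window pairs
    """

    window: int = 100
    min_chimeras: int = 5
    alpha: float = 0.05
    assign_ratio: float = 0.7
    max_gap: int = 1000
    bh_correction: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not (0 < self.assign_ratio < 1):
            raise ValueError("assign_ratio must be in (0, 1)")
        if self.min_chimeras < 1:
            raise ValueError("min_chimeras must be >= 1")
        if self.window < 1:
            raise ValueError("window must be >= 1")


@dataclass
class ChimeraCounts:
    """Binned chimera counts over ordered window pairs, with marginals."""

    pair_counts: dict[tuple[WindowKey, WindowKey], int]
    n1: dict[WindowKey, int]
    n2: dict[WindowKey, int]
    total: int


@dataclass
class InteractionCandidate:
    region1: tuple[str, str, int, int]  # chrom, strand, start, end
    region2: tuple[str, str, int, int]
    n_ab: int
    n_a: int
    n_b: int
    total: int
    odds_ratio: float
    p_value: float


@dataclass
class SChimera:
    candidate: InteractionCandidate
    interactions: int
    rna1_names: list[str] = field(default_factory=list)
    rna2_names: list[str] = field(default_factory=list)


# ------------------------------------------------------------------ binning


def _window_of(chrom: str, strand: str, midpoint: int, window: int) -> WindowKey:
    return (chrom, strand, midpoint // window)


def bin_chimeras(
    chimeras: Iterable[Fragment], params: AnalysisParams
) -> ChimeraCounts:
    """Count chimeras per ordered (RNA1 window, RNA2 window) pair.

    Each chimera is assigned by the midpoint of each locus; marginals
    and the library total are accumulated alongside.  Ordered pairs are
    not symmetrized: (A, B) and (B, A) are distinct interactions.
    """
    pair_counts: dict[tuple[WindowKey, WindowKey], int] = {}
    n1: dict[WindowKey, int] = {}
    n2: dict[WindowKey, int] = {}
    total = 0
    w = params.window
    for frag in chimeras:
        if not frag.is_chimeric:
            continue
        l1, l2 = frag.locus1, frag.locus2
        k1 = _window_of(l1.chrom, l1.strand, l1.midpoint, w)
        k2 = _window_of(l2.chrom, l2.strand, l2.midpoint, w)
        pair_counts[(k1, k2)] = pair_counts.get((k1, k2), 0) + 1
        n1[k1] = n1.get(k1, 0) + 1
        n2[k2] = n2.get(k2, 0) + 1
        total += 1
    return ChimeraCounts(pair_counts, n1, n2, total)


# ------------------------------------------------------------------ Fisher


def hypergeom_upper_tail(a, total, n_a, n_b):
    """Vectorized one-sided p-value P(X >= a), X ~ Hypergeom(total, n_a, n_b)."""
    a = np.asarray(a)
    return hypergeom.sf(a - 1, np.asarray(total), np.asarray(n_a), np.asarray(n_b))


def fisher_one_sided(
    n_ab: int, n_a: int, n_b: int, total: int
) -> tuple[float, float]:
    """One-sided Fisher's exact test for chimera over-representation.

    Returns (odds_ratio, p_value) for the table (a, b, c, d) =
    (n_ab, n_a - n_ab, n_b - n_ab, total - n_a - n_b + n_ab).  The odds
    ratio is (a*d)/(b*c), with the convention +inf when b*c == 0 and
    a*d > 0, and nan for the all-degenerate 0/0 case.
    """
    a = n_ab
    b = n_a - n_ab
    c = n_b - n_ab
    d = total - n_a - n_b + n_ab
    if min(a, b, c, d) < 0:
        raise ValueError(
            f"negative contingency cell from (n_ab={n_ab}, n_a={n_a}, "
            f"n_b={n_b}, total={total})"
        )
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    p = float(hypergeom.sf(a - 1, total, n_a, n_b))
    return odds, p


# ------------------------------------------------------------------ calling


def score_window_pairs(
    counts: ChimeraCounts, params: AnalysisParams
) -> list[InteractionCandidate]:
    """Fisher-test every observed window pair (no count floor, no merging).

    Window keys are converted to genomic coordinates; the floor and
    merging are applied downstream by :func:`call_s_chimeras`.  Exposed
    separately so the per-test error rate of the statistic can be
    measured on null libraries.
    """
    w = params.window
    out = []
    keys = sorted(counts.pair_counts)
    p_values = []
    for k1, k2 in keys:
        n_ab = counts.pair_counts[(k1, k2)]
        odds, p = fisher_one_sided(n_ab, counts.n1[k1], counts.n2[k2], counts.total)
        p_values.append(p)
    if params.bh_correction and p_values:
        p_values = _benjamini_hochberg(p_values)
    for (k1, k2), p in zip(keys, p_values):
        n_ab = counts.pair_counts[(k1, k2)]
        odds, _ = fisher_one_sided(n_ab, counts.n1[k1], counts.n2[k2], counts.total)
        out.append(
            InteractionCandidate(
                region1=(k1[0], k1[1], k1[2] * w, (k1[2] + 1) * w),
                region2=(k2[0], k2[1], k2[2] * w, (k2[2] + 1) * w),
                n_ab=n_ab,
                n_a=counts.n1[k1],
                n_b=counts.n2[k2],
                total=counts.total,
                odds_ratio=odds,
                p_value=p,
            )
        )
    return out


def _benjamini_hochberg(p: Sequence[float]) -> list[float]:
    p = np.asarray(p, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj.tolist()


def call_s_chimeras(
    counts: ChimeraCounts, params: AnalysisParams
) -> list[SChimera]:
    """Call S-chimeras: significant, merged, count-floored region pairs.

    Window pairs with p < alpha are merged when adjacent in both
    dimensions (window indices differing by at most 1, same chromosome
    and strand on each side).  Each merged region pair sums its
    supporting chimeras (``interactions``) and keeps the minimum p and
    the odds ratio of its best window; merged region pairs with fewer
    than ``min_chimeras`` supporting fragments are dropped.  The count
    floor is applied to the merged total, matching the per-reported-pair
    reading of the >=5-fragment threshold.
    """
    tested = score_window_pairs(counts, params)
    sig = [c for c in tested if c.p_value < params.alpha]
    if not sig:
        return []
    w = params.window

    # adjacency graph over significant window pairs -> connected components
    by_key: dict[tuple[WindowKey, WindowKey], int] = {}
    keys = []
    for i, c in enumerate(sig):
        k1 = (c.region1[0], c.region1[1], c.region1[2] // w)
        k2 = (c.region2[0], c.region2[1], c.region2[2] // w)
        by_key[(k1, k2)] = i
        keys.append((k1, k2))
    parent = list(range(len(sig)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for i, (k1, k2) in enumerate(keys):
        for d1 in (-1, 0, 1):
            for d2 in (-1, 0, 1):
                if d1 == 0 and d2 == 0:
                    continue
                nb = (
                    (k1[0], k1[1], k1[2] + d1),
                    (k2[0], k2[1], k2[2] + d2),
                )
                j = by_key.get(nb)
                if j is not None:
                    union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(len(sig)):
        groups.setdefault(find(i), []).append(i)

    out: list[SChimera] = []
    for members in groups.values():
        cands = [sig[i] for i in members]
        interactions = sum(c.n_ab for c in cands)
        if interactions < params.min_chimeras:
            continue
        best = min(cands, key=lambda c: c.p_value)
        r1 = (
            cands[0].region1[0],
            cands[0].region1[1],
            min(c.region1[2] for c in cands),
            max(c.region1[3] for c in cands),
        )
        r2 = (
            cands[0].region2[0],
            cands[0].region2[1],
            min(c.region2[2] for c in cands),
            max(c.region2[3] for c in cands),
        )
        merged = InteractionCandidate(
            region1=r1,
            region2=r2,
            n_ab=interactions,
            n_a=best.n_a,
            n_b=best.n_b,
            total=counts.total,
            odds_ratio=best.odds_ratio,
            p_value=best.p_value,
        )
        out.append(SChimera(candidate=merged, interactions=interactions))
    out.sort(
        key=lambda s: (s.candidate.region1[:3], s.candidate.region2[:3])
    )
    return out


def _in_region(
    chrom: str, strand: str, pos: int, region: tuple[str, str, int, int]
) -> bool:
    return (
        chrom == region[0]
        and strand == region[1]
        and region[2] <= pos < region[3]
    )


def filter_nonsignificant(
    chimeras: Iterable[Fragment], s_chimeras: Sequence[SChimera]
) -> list[Fragment]:
    """Retain only chimeras lying inside some S-chimera's region pair.

    Membership follows the binning rule (locus midpoints, RNA1/RNA2
    orientation respected), so the retained count equals the summed
    ``interactions`` over S-chimeras.
    """
    out = []
    for frag in chimeras:
        if not frag.is_chimeric:
            continue
        l1, l2 = frag.locus1, frag.locus2
        for s in s_chimeras:
            if _in_region(
                l1.chrom, l1.strand, l1.midpoint, s.candidate.region1
            ) and _in_region(l2.chrom, l2.strand, l2.midpoint, s.candidate.region2):
                out.append(frag)
                break
    return out


# ------------------------------------------------------------------ genes


def assign_genes(
    read_intervals: Sequence[tuple[int, int]],
    chrom: str,
    strand: str,
    annotation: FeatureSet,
    assign_ratio: float = 0.7,
    index=None,
) -> list[str]:
    """Assign feature names to a region from its overlapping reads.

    Overlap is >=1 shared base on the same strand.  If the top feature's
    share of feature-overlapping reads is strictly greater than
    ``assign_ratio``, only that feature is returned; otherwise all
    overlapping features in decreasing share order (name as tiebreak).
    A region overlapping no feature falls back to the nearest same-strand
    feature, flagged with a ``.near`` suffix.
    """
    if index is None:
        index = annotation.interval_index()
    tree = index.get((chrom, strand))
    per_feature: dict[str, int] = {}
    for start, end in read_intervals:
        if tree is None:
            continue
        for iv in tree.overlap(start, end):
            name = iv.data.name
            per_feature[name] = per_feature.get(name, 0) + 1
    if not per_feature:
        lo = min((s for s, _ in read_intervals), default=0)
        hi = max((e for _, e in read_intervals), default=0)
        nearest = None
        best_dist = None
        for f in annotation.by_strand(chrom, strand):
            dist = max(f.start - hi, lo - f.end, 0)
            if best_dist is None or dist < best_dist:
                best_dist, nearest = dist, f
        return [f"{nearest.name}.near"] if nearest else []
    denom = sum(
        1
        for start, end in read_intervals
        if tree is not None and tree.overlap(start, end)
    )
    ranked = sorted(per_feature.items(), key=lambda kv: (-kv[1], kv[0]))
    top_name, top_count = ranked[0]
    if denom > 0 and top_count / denom > assign_ratio:
        return [top_name]
    return [name for name, _ in ranked]


def annotate_s_chimeras(
    s_chimeras: Sequence[SChimera],
    retained: Sequence[Fragment],
    annotation: FeatureSet,
    params: AnalysisParams,
) -> None:
    """Fill rna1_names/rna2_names in place from each S-chimera's own reads."""
    index = annotation.interval_index()
    for s in s_chimeras:
        reads1: list[tuple[int, int]] = []
        reads2: list[tuple[int, int]] = []
        for frag in retained:
            l1, l2 = frag.locus1, frag.locus2
            if _in_region(
                l1.chrom, l1.strand, l1.midpoint, s.candidate.region1
            ) and _in_region(l2.chrom, l2.strand, l2.midpoint, s.candidate.region2):
                reads1.append((l1.start, l1.end))
                reads2.append((l2.start, l2.end))
        r1, r2 = s.candidate.region1, s.candidate.region2
        s.rna1_names = assign_genes(
            reads1, r1[0], r1[1], annotation, params.assign_ratio, index=index
        )
        s.rna2_names = assign_genes(
            reads2, r2[0], r2[1], annotation, params.assign_ratio, index=index
        )


# ------------------------------------------------------------------ output

_TABLE_COLUMNS = [
    "chrom1",
    "strand1",
    "start1",
    "end1",
    "chrom2",
    "strand2",
    "start2",
    "end2",
    "RNA1_name",
    "RNA2_name",
    "interactions",
    "odds_ratio",
    "p_value",
]


def interaction_table(s_chimeras: Sequence[SChimera]) -> pd.DataFrame:
    rows = []
    for s in s_chimeras:
        c = s.candidate
        rows.append(
            {
                "chrom1": c.region1[0],
                "strand1": c.region1[1],
                "start1": c.region1[2],
                "end1": c.region1[3],
                "chrom2": c.region2[0],
                "strand2": c.region2[1],
                "start2": c.region2[2],
                "end2": c.region2[3],
                "RNA1_name": ";".join(s.rna1_names),
                "RNA2_name": ";".join(s.rna2_names),
                "interactions": s.interactions,
                "odds_ratio": c.odds_ratio,
                "p_value": c.p_value,
            }
        )
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def write_interaction_table(
    s_chimeras: Sequence[SChimera], path: str | Path
) -> pd.DataFrame:
    df = interaction_table(s_chimeras)
    df.to_csv(path, sep="\t", index=False)
    return df


def circos_links(s_chimeras: Sequence[SChimera], path: str | Path) -> None:
    """One link line per S-chimera: chrom start end chrom start end count."""
    with open(path, "w") as fh:
        for s in s_chimeras:
            c = s.candidate
            fh.write(
                f"{c.region1[0]} {c.region1[2]} {c.region1[3]} "
                f"{c.region2[0]} {c.region2[2]} {c.region2[3]} "
                f"{s.interactions}\n"
            )


def significant_regions_bed(
    s_chimeras: Sequence[SChimera], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for i, s in enumerate(s_chimeras):
            for side, region in (("RNA1", s.candidate.region1), ("RNA2", s.candidate.region2)):
                chrom, strand, start, end = region
                fh.write(
                    f"{chrom}\t{start}\t{end}\tS{i}.{side}\t{s.interactions}\t{strand}\n"
                )
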