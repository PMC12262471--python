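"""Comprehensive bacterial genome feature annotation.

Starting from a base gene annotation (mRNA/CDS genes, sRNAs, tRNAs,
rRNAs, curated UTRs), this module derives the additional feature classes
used to assign every transcribed signal on a bacterial chromosome to a
named element:

* ``EST5UTR`` / ``EST3UTR`` -- predicted untranslated regions obtained by
  extending up to ``utr_len`` nucleotides upstream of each start codon and
  downstream of each stop codon, truncated so they never overlap another
  same-strand feature.
* ``AS`` -- antisense features mirroring each coding region on the
  opposite strand.
* ``IGR`` / ``TU`` -- strand-specific inter-feature regions; gaps shorter
  than ``tu_max`` are labelled ``TU`` (likely internal to one
  transcription unit), the rest ``IGR``.

Derived feature names follow the period-joined convention
(``geneA.EST5UTR``, ``geneA.AS``, ``geneA.geneB.IGR``).

Coordinates are 0-based half-open internally; GFF3 I/O converts to and
from the 1-based inclusive file convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

from gffutils.feature import feature_from_line
from intervaltree import IntervalTree

CODING_TYPES = frozenset({"gene", "CDS"})
KNOWN_UTR_TYPES = frozenset({"5UTR", "3UTR"})
DERIVED_TYPES = frozenset({"EST5UTR", "EST3UTR", "AS", "IGR", "TU"})
FEATURE_TYPES = frozenset(
    {"gene", "CDS", "sRNA", "tRNA", "rRNA", "5UTR", "3UTR"} | DERIVED_TYPES
)


class AnnotationError(ValueError):
    """Raised for malformed or out-of-range annotation input."""


@dataclass(frozen=True)
class Feature:
    """One stranded genomic annotation element (0-based, half-open)."""

    feature_id: str
    chrom: str
    start: int
    end: int
    strand: str
    ftype: str
    name: str
    description: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise AnnotationError(
                f"feature {self.feature_id}: invalid interval "
                f"[{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"feature {self.feature_id}: strand must be + or -, "
                f"got {self.strand!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Feature") -> bool:
        return (
            self.chrom == other.chrom
            and self.strand == other.strand
            and self.start < other.end
            and other.start < self.end
        )


class FeatureSet:
    """An ordered, validated collection of :class:`Feature`.

    Features are kept sorted by (chrom, start, end, strand); feature ids
    must be unique and all coordinates must lie within the declared
    chromosome lengths.
    """

    def __init__(
        self, features: Iterable[Feature], genome_lengths: dict[str, int]
    ) -> None:
        feats = sorted(features, key=lambda f: (f.chrom, f.start, f.end, f.strand))
        seen: set[str] = set()
        for f in feats:
            if f.feature_id in seen:
                raise AnnotationError(f"duplicate feature_id {f.feature_id!r}")
            seen.add(f.feature_id)
            if f.chrom not in genome_lengths:
                raise AnnotationError(
                    f"feature {f.feature_id}: unknown chromosome {f.chrom!r}"
                )
            if f.end > genome_lengths[f.chrom]:
                raise AnnotationError(
                    f"feature {f.feature_id}: end {f.end} beyond chromosome "
                    f"length {genome_lengths[f.chrom]}"
                )
        self.features: list[Feature] = feats
        self.genome_lengths: dict[str, int] = dict(genome_lengths)

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self) -> Iterator[Feature]:
        return iter(self.features)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureSet):
            return NotImplemented
        return (
            self.features == other.features
            and self.genome_lengths == other.genome_lengths
        )

    def by_strand(self, chrom: str, strand: str) -> list[Feature]:
        return [
            f for f in self.features if f.chrom == chrom and f.strand == strand
        ]

    def by_type(self, *ftypes: str) -> list[Feature]:
        want = set(ftypes)
        return [f for f in self.features if f.ftype in want]

    def merged_footprint(self, chrom: str, strand: str) -> list[tuple[int, int]]:
        """Union of same-strand feature intervals as disjoint sorted blocks."""
        out: list[tuple[int, int]] = []
        for f in self.by_strand(chrom, strand):
            if out and f.start <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], f.end))
            else:
                out.append((f.start, f.end))
        return out

    def interval_index(self) -> dict[tuple[str, str], IntervalTree]:
        """Per (chrom, strand) interval tree keyed to features, for overlap queries."""
        index: dict[tuple[str, str], IntervalTree] = {}
        for f in self.features:
            index.setdefault((f.chrom, f.strand), IntervalTree()).addi(
                f.start, f.end, f
            )
        return index

    # ---------------------------------------------------------------- GFF3 I/O

    @classmethod
    def load_gff3(
        cls, path: str | Path, genome_lengths: dict[str, int]
    ) -> "FeatureSet":
        """Read a GFF3 file (1-based inclusive) into a FeatureSet.

        Column 3 carries the feature type; ``ID``/``Name``/``description``
        attributes populate the identifier, name, and description.
        """
        feats: list[Feature] = []
        auto = 0
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                if len(line.split("\t")) != 9:
                    raise AnnotationError(
                        f"{path}: malformed GFF3 at line {lineno}: "
                        "expected 9 tab-separated columns"
                    )
                try:
                    g = feature_from_line(line)
                except Exception as exc:  # noqa: BLE001 - rewrap with context
                    raise AnnotationError(
                        f"{path}: malformed GFF3 at line {lineno}: {exc}"
                    ) from exc
                attrs = g.attributes
                fid = attrs["ID"][0] if "ID" in attrs else f"feat{auto}"
                auto += 1
                name = attrs["Name"][0] if "Name" in attrs else fid
                desc = attrs["description"][0] if "description" in attrs else ""
                try:
                    feats.append(
                        Feature(
                            feature_id=fid,
                            chrom=g.seqid,
                            start=g.start - 1,
                            end=g.end,
                            strand=g.strand,
                            ftype=g.featuretype,
                            name=name,
                            description=desc,
                        )
                    )
                except AnnotationError as exc:
                    raise AnnotationError(f"{path}: line {lineno}: {exc}") from exc
        return cls(feats, genome_lengths)

    def write_gff3(self, path: str | Path, source: str = "rilpipe") -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for chrom in sorted(self.genome_lengths):
                fh.write(
                    f"##sequence-region {chrom} 1 {self.genome_lengths[chrom]}\n"
                )
            for f in self.features:
                attrs = f"ID={f.feature_id};Name={f.name}"
                if f.description:
                    attrs += f";description={f.description}"
                fh.write(
                    "\t".join(
                        (
                            f.chrom,
                            source,
                            f.ftype,
                            str(f.start + 1),
                            str(f.end),
                            ".",
                            f.strand,
                            ".",
                            attrs,
                        )
                    )
                    + "\n"
                )


# ------------------------------------------------------------------ builders


def _gaps_with_flanks(
    fs: FeatureSet, chrom: str, strand: str
) -> list[tuple[int, int, Feature | None, Feature | None]]:
    """Internal inter-feature gaps with the flanking features, per strand.

    Returns (gap_start, gap_end, left_flank, right_flank) for every
    maximal feature-free gap between consecutive merged feature blocks.
    Terminal regions (before the first / after the last block) are
    returned with a ``None`` outer flank and are used only for UTR
    extension, never for IGR/TU construction.
    """
    feats = fs.by_strand(chrom, strand)
    blocks = fs.merged_footprint(chrom, strand)
    if not blocks:
        return []

    def left_flank(pos: int) -> Feature | None:
        cands = [f for f in feats if f.end == pos]
        return min(cands, key=lambda f: f.name) if cands else None

    def right_flank(pos: int) -> Feature | None:
        cands = [f for f in feats if f.start == pos]
        return min(cands, key=lambda f: f.name) if cands else None

    out: list[tuple[int, int, Feature | None, Feature | None]] = []
    glen = fs.genome_lengths[chrom]
    if blocks[0][0] > 0:
        out.append((0, blocks[0][0], None, right_flank(blocks[0][0])))
    for (s1, e1), (s2, _e2) in zip(blocks, blocks[1:]):
        if s2 > e1:
            out.append((e1, s2, left_flank(e1), right_flank(s2)))
    if blocks[-1][1] < glen:
        out.append((blocks[-1][1], glen, left_flank(blocks[-1][1]), None))
    return out


def _has_known_utr(fs: FeatureSet, gene: Feature, which: str) -> bool:
    # A curated UTR is taken to belong to a gene when its name mentions it.
    for f in fs.features:
        if f.ftype == which and f.strand == gene.strand and gene.name in f.name:
            return True
    return False


def build_predicted_utrs(
    fs: FeatureSet, utr_len: int = 100, skip_if_known: bool = True
) -> FeatureSet:
    """Predicted EST5UTR/EST3UTR features extending from coding gene ends.

    Each coding gene is extended up to ``utr_len`` nt upstream of its
    start and downstream of its stop, truncated at the nearest
    same-strand feature.  When the predicted UTRs of two facing genes
    would overlap inside a shared gap, the gap is split between them
    (each side capped at half, with unused room ceded to the other).
    Zero-length extensions are omitted.
    """
    proposals: list[Feature] = []
    for chrom in fs.genome_lengths:
        for strand in "+-":
            genes = [f for f in fs.by_strand(chrom, strand) if f.ftype in CODING_TYPES]
            if not genes:
                continue
            for gap_s, gap_e, lf, rf in _gaps_with_flanks(fs, chrom, strand):
                gap = gap_e - gap_s
                # Extension rightward from the left flank (3'UTR on +, 5'UTR on -)
                # and leftward from the right flank.
                left_gene = lf if lf is not None and lf.ftype in CODING_TYPES else None
                right_gene = rf if rf is not None and rf.ftype in CODING_TYPES else None
                l_type = ("EST3UTR" if strand == "+" else "EST5UTR")
                r_type = ("EST5UTR" if strand == "+" else "EST3UTR")
                if left_gene is not None and skip_if_known and _has_known_utr(
                    fs, left_gene, l_type.removeprefix("EST")
                ):
                    left_gene = None
                if right_gene is not None and skip_if_known and _has_known_utr(
                    fs, right_gene, r_type.removeprefix("EST")
                ):
                    right_gene = None
                want_l = min(utr_len, gap) if left_gene is not None else 0
                want_r = min(utr_len, gap) if right_gene is not None else 0
                if want_l + want_r > gap:
                    half = gap // 2
                    got_l = min(want_l, max(gap - want_r, half))
                    got_r = min(want_r, gap - got_l)
                else:
                    got_l, got_r = want_l, want_r
                if left_gene is not None and got_l > 0:
                    proposals.append(
                        Feature(
                            feature_id=f"{left_gene.feature_id}.{l_type}",
                            chrom=chrom,
                            start=gap_s,
                            end=gap_s + got_l,
                            strand=strand,
                            ftype=l_type,
                            name=f"{left_gene.name}.{l_type}",
                        )
                    )
                if right_gene is not None and got_r > 0:
                    proposals.append(
                        Feature(
                            feature_id=f"{right_gene.feature_id}.{r_type}",
                            chrom=chrom,
                            start=gap_e - got_r,
                            end=gap_e,
                            strand=strand,
                            ftype=r_type,
                            name=f"{right_gene.name}.{r_type}",
                        )
                    )
    return FeatureSet(proposals, fs.genome_lengths)


def build_antisense(fs: FeatureSet) -> FeatureSet:
    """One AS feature per coding region: same coordinates, opposite strand.

    Overlapping genes yield overlapping AS features; no merging, so the
    per-gene ``<gene>.AS`` naming stays unambiguous.
    """
    out = [
        Feature(
            feature_id=f"{f.feature_id}.AS",
            chrom=f.chrom,
            start=f.start,
            end=f.end,
            strand="-" if f.strand == "+" else "+",
            ftype="AS",
            name=f"{f.name}.AS",
        )
        for f in fs.features
        if f.ftype in CODING_TYPES
    ]
    return FeatureSet(out, fs.genome_lengths)


def build_igrs_and_tus(fs: FeatureSet, tu_max: int = 100) -> FeatureSet:
    """Strand-specific inter-feature regions.

    Every maximal gap between consecutive same-strand features (merged
    footprint, so no IGR/TU ever overlaps a feature) becomes one
    feature: ``TU`` when the gap is strictly shorter than ``tu_max``
    nucleotides, ``IGR`` otherwise.  Names join both flanking feature
    names in genomic order (``left.right.IGR``).
    """
    out: list[Feature] = []
    for chrom in fs.genome_lengths:
        for strand in "+-":
            for gap_s, gap_e, lf, rf in _gaps_with_flanks(fs, chrom, strand):
                if lf is None or rf is None:
                    continue  # terminal region on a linear chromosome
                ftype = "TU" if (gap_e - gap_s) < tu_max else "IGR"
                name = f"{lf.name}.{rf.name}.{ftype}"
                out.append(
                    Feature(
                        feature_id=f"{chrom}:{gap_s}-{gap_e}({strand}).{ftype}",
                        chrom=chrom,
                        start=gap_s,
                        end=gap_e,
                        strand=strand,
                        ftype=ftype,
                        name=name,
                    )
                )
    return FeatureSet(out, fs.genome_lengths)


def compose_annotation(
    base: FeatureSet,
    utr_len: int = 100,
    tu_max: int = 100,
    skip_if_known: bool = True,
) -> FeatureSet:
    """Union of base features, predicted UTRs, antisense, and IGR/TU.

    IGR/TU gaps are recomputed against the union of all stranded
    features (base + predicted UTRs + AS), so the inter-feature features
    exactly tile the remaining feature-free space on each strand.
    Deterministic ordering by (chrom, start, end, strand).
    """
    for f in base:
        if "." in f.name and f.ftype not in DERIVED_TYPES:
            raise AnnotationError(
                f"gene name {f.name!r} contains a period, which is reserved "
                "as the derived-feature name delimiter"
            )
    utrs = build_predicted_utrs(base, utr_len=utr_len, skip_if_known=skip_if_known)
    asf = build_antisense(base)
    stranded = FeatureSet(
        list(base) + list(utrs) + list(asf), base.genome_lengths
    )
    igrs = build_igrs_and_tus(stranded, tu_max=tu_max)
    return FeatureSet(
        list(stranded) + list(igrs), base.genome_lengths
    )


def rename(feature: Feature, **kwargs) -> Feature:
    return replace(feature, **kwargs)
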