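"""Classification of mapped paired-end records into Single and Chimeric fragments.

An IP'd proximity-ligation sequencing library yields mate pairs that
either derive from one RNA molecule (Single) or from two distinct RNAs
joined by the ligase (Chimeric).  A pair is Single when both mates map
to the same chromosome and transcript strand, face inward in transcript
orientation (mate 1 is the 5'-most piece of the construct), and are
separated by at most ``max_gap`` nucleotides; everything else is a
chimera, ordered RNA1-RNA2 by the position of each piece in the
sequenced construct.

Reverse-stranded library designs (the sequenced strand is the reverse
complement of the transcript) are handled by :func:`transcript_strand`,
which flips aligned strands to transcript strands before classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np


@dataclass(frozen=True)
class Locus:
    """A mapped interval on a transcript strand (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid locus [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def flipped(self) -> "Locus":
        return replace(self, strand="-" if self.strand == "+" else "+")


@dataclass(frozen=True)
class MatePair:
    read_id: str
    mate1: Locus
    mate2: Locus
    library_reverse: bool = False


@dataclass(frozen=True)
class Fragment:
    """A classified fragment: one locus (Single) or an ordered pair (Chimeric).

    For chimeras, ``locus1`` is RNA1 (the ligation-upstream piece of the
    sequenced construct) and ``locus2`` is RNA2.  In Hfq interactomes
    the convention puts the mRNA region in RNA1 and the sRNA in RNA2.
    """

    read_id: str
    kind: str  # "Single" | "Chimeric"
    locus1: Locus
    locus2: Locus | None = None

    @property
    def is_chimeric(self) -> bool:
        return self.kind == "Chimeric"


@dataclass(frozen=True)
class LibraryStats:
    n_single: int
    n_chimeric: int

    @property
    def chimera_fraction(self) -> float:
        total = self.n_single + self.n_chimeric
        if total == 0:
            warnings.warn("empty library: chimera fraction undefined, reporting 0")
            return 0.0
        return self.n_chimeric / total


def transcript_strand(pair: MatePair) -> MatePair:
    """Resolve aligned strands to transcript strands.

    When the library is reverse-stranded, the aligned strand of each
    mate is the complement of the transcript strand, so both are
    flipped; coordinates are untouched.  Applying the function twice is
    the identity.
    """
    if not pair.library_reverse:
        return pair
    return replace(pair, mate1=pair.mate1.flipped(), mate2=pair.mate2.flipped())


def _inner_gap(a: Locus, b: Locus) -> int:
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def classify_fragment(pair: MatePair, max_gap: int = 1000) -> Fragment:
    """Classify one mate pair as a Single or Chimeric fragment.

    Single requires same chromosome, same transcript strand, inward
    orientation (mate 1 is the transcript-5' piece) and an inter-mate
    gap of at most ``max_gap``; its locus is the merged interval.  Pairs
    that fail only the orientation check (a self-ligation candidate) are
    reported Chimeric with loci ordered by (chrom, start); all other
    chimeras keep construct order (RNA1 = mate 1).
    """
    m1, m2 = pair.mate1, pair.mate2
    same_locus = (
        m1.chrom == m2.chrom
        and m1.strand == m2.strand
        and _inner_gap(m1, m2) <= max_gap
    )
    if same_locus:
        if m1.strand == "+":
            inward = m1.start <= m2.start
        else:
            inward = m1.end >= m2.end
        if inward:
            merged = Locus(
                m1.chrom, min(m1.start, m2.start), max(m1.end, m2.end), m1.strand
            )
            return Fragment(pair.read_id, "Single", merged)
        # proximal but outward-facing: a chimera with ambiguous construct
        # order; break the tie deterministically by genomic position
        first, second = sorted((m1, m2), key=lambda m: (m.chrom, m.start))
        return Fragment(pair.read_id, "Chimeric", first, second)
    return Fragment(pair.read_id, "Chimeric", m1, m2)


def classify_pairs(
    pairs: Iterable[MatePair], max_gap: int = 1000
) -> list[Fragment]:
    return [classify_fragment(transcript_strand(p), max_gap=max_gap) for p in pairs]


def library_stats(fragments: Iterable[Fragment]) -> LibraryStats:
    n_single = n_chim = 0
    for f in fragments:
        if f.is_chimeric:
            n_chim += 1
        else:
            n_single += 1
    return LibraryStats(n_single=n_single, n_chimeric=n_chim)


def mask_fragments(
    fragments: Iterable[Fragment],
    mask: Sequence[tuple[str, int, int]],
) -> list[Fragment]:
    """Drop fragments with any locus overlapping a masked region.

    Used to exclude rRNA-derived reads up front (the equivalent of a
    ribosomal-depletion mask); strand-agnostic.
    """

    def hit(loc: Locus) -> bool:
        return any(
            loc.chrom == c and loc.start < e and s < loc.end for c, s, e in mask
        )

    out = []
    for f in fragments:
        loci = [f.locus1] + ([f.locus2] if f.locus2 else [])
        if not any(hit(l) for l in loci):
            out.append(f)
    return out


# ------------------------------------------------------------------ coverage


def coverage_track(
    fragments: Iterable[Fragment], genome_lengths: dict[str, int]
) -> dict[tuple[str, str], np.ndarray]:
    """Per-strand, per-base fragment coverage.

    Each fragment locus adds 1 to every base it spans; chimeric
    fragments contribute both loci.  The summed track therefore equals
    the summed locus lengths (conservation).
    """
    tracks = {
        (chrom, strand): np.zeros(length, dtype=np.int64)
        for chrom, length in genome_lengths.items()
        for strand in "+-"
    }
    for f in fragments:
        for loc in (f.locus1, f.locus2):
            if loc is None:
                continue
            key = (loc.chrom, loc.strand)
            if key not in tracks or loc.end > genome_lengths[loc.chrom]:
                raise ValueError(
                    f"fragment {f.read_id}: locus {loc} outside the genome"
                )
            tracks[key][loc.start : loc.end] += 1
    return tracks


def write_wiggle(
    tracks: dict[tuple[str, str], np.ndarray], prefix: str | Path
) -> list[Path]:
    """Write one fixedStep wiggle file per strand."""
    paths = []
    for strand, tag in (("+", "fwd"), ("-", "rev")):
        path = Path(f"{prefix}.{tag}.wig")
        with open(path, "w") as fh:
            for (chrom, s), vec in sorted(tracks.items()):
                if s != strand:
                    continue
                fh.write(f"fixedStep chrom={chrom} start=1 step=1\n")
                fh.write("\n".join(str(int(v)) for v in vec))
                fh.write("\n")
        paths.append(path)
    return paths


# ------------------------------------------------------------------ I/O

_FRAG_COLUMNS = (
    "read_id kind chrom1 start1 end1 strand1 chrom2 start2 end2 strand2".split()
)


def read_bedpe(path: str | Path, library_reverse: bool = False) -> list[MatePair]:
    """Read mate pairs from BEDPE (0-based half-open, strands in cols 9-10)."""
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 10:
                raise ValueError(f"{path}: line {lineno}: expected >=10 BEDPE columns")
            c1, s1, e1, c2, s2, e2, name, _score, st1, st2 = parts[:10]
            pairs.append(
                MatePair(
                    read_id=name,
                    mate1=Locus(c1, int(s1), int(e1), st1),
                    mate2=Locus(c2, int(s2), int(e2), st2),
                    library_reverse=library_reverse,
                )
            )
    return pairs


def write_bedpe(pairs: Iterable[MatePair], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(
                "\t".join(
                    (
                        p.mate1.chrom,
                        str(p.mate1.start),
                        str(p.mate1.end),
                        p.mate2.chrom,
                        str(p.mate2.start),
                        str(p.mate2.end),
                        p.read_id,
                        ".",
                        p.mate1.strand,
                        p.mate2.strand,
                    )
                )
                + "\n"
            )


def write_fragments_tsv(fragments: Iterable[Fragment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_FRAG_COLUMNS) + "\n")
        for f in fragments:
            l2 = f.locus2
            fh.write(
                "\t".join(
                    (
                        f.read_id,
                        f.kind,
                        f.locus1.chrom,
                        str(f.locus1.start),
                        str(f.locus1.end),
                        f.locus1.strand,
                        l2.chrom if l2 else ".",
                        str(l2.start) if l2 else ".",
                        str(l2.end) if l2 else ".",
                        l2.strand if l2 else ".",
                    )
                )
                + "\n"
            )


def read_fragments_tsv(path: str | Path) -> list[Fragment]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _FRAG_COLUMNS:
            raise ValueError(f"{path}: unexpected fragment TSV header")
        for line in fh:
            (
                rid,
                kind,
                c1,
                s1,
                e1,
                st1,
                c2,
                s2,
                e2,
                st2,
            ) = line.rstrip("\n").split("\t")
            locus2 = None
            if c2 != ".":
                locus2 = Locus(c2, int(s2), int(e2), st2)
            out.append(Fragment(rid, kind, Locus(c1, int(s1), int(e1), st1), locus2))
    return out
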