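"""DASH sgRNA pool design for targeted depletion of abundant sequences.

DASH (depletion of abundant sequences by hybridization) removes unwanted
cDNA -- typically rRNA -- by Cas9 cleavage before library amplification.
This module designs the guide pool: it scans target regions for Cas9 PAM
sites (NGG) on both strands, extracts the 20-nt protospacer 5' of each
PAM, filters candidates on GC content, heterodimer melting temperature
against the library-amplification primer, and 3'-end duplex stability,
discards guides with any exact genomic occurrence outside the target
regions, and emits the final oligo pool with the in-vitro-transcription
affixes:

    oligo = T7 promoter + protospacer + scaffold   (20 + 20 + 20 = 60 nt)

Melting temperatures use the nearest-neighbor model of
``Bio.SeqUtils.MeltingTemp.Tm_NN`` with its default salt and strand
concentrations; a candidate passes a Tm filter when its metric is at or
below the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio.Seq import Seq
from Bio.SeqUtils import MeltingTemp, gc_fraction

T7_PROMOTER = "TTCTAATACGACTCACTATA"
SCAFFOLD = "GTTTTAGAGCTAGAAATAGC"
PROTOSPACER_LEN = 20
NO_DUPLEX_TM = -100.0  # reported when no hybridizing stretch exists


@dataclass
class GuideCandidate:
    target_region_id: str
    chrom: str
    strand: str
    protospacer: str  # 20 nt, 5'->3' on the targeted strand
    pam: str  # 3 nt NGG
    pam_pos: int  # genomic start of the PAM (0-based, + strand coords)
    gc_fraction: float = 0.0
    heterodimer_tm: float = NO_DUPLEX_TM
    end_stability_tm: float = NO_DUPLEX_TM
    off_target_hits: int = 0
    pass_flags: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.protospacer) != PROTOSPACER_LEN:
            raise ValueError("protospacer must be exactly 20 nt")
        if self.pam[1:3] != "GG":
            raise ValueError(f"PAM {self.pam!r} does not match NGG")


@dataclass(frozen=True)
class OligoRecord:
    protospacer: str
    oligo: str


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def scan_pam_sites(
    genome: dict[str, str],
    target_regions: Sequence[tuple[str, int, int]],
) -> list[GuideCandidate]:
    """All NGG-adjacent 20-mers whose protospacer overlaps a target region.

    Both strands are scanned; reverse-strand protospacers are reported
    as the reverse complement (the sequence the guide RNA carries).
    Candidates containing N are skipped, and at least 20 nt must be
    available 5' of the PAM on the targeted strand.
    """
    out: list[GuideCandidate] = []
    regions = [
        (i, chrom, int(s), int(e)) for i, (chrom, s, e) in enumerate(target_regions)
    ]
    for chrom, seq in genome.items():
        seq = seq.upper()
        n = len(seq)
        my_regions = [(i, s, e) for i, c, s, e in regions if c == chrom]
        if not my_regions:
            continue

        def overlapping(start: int, end: int) -> int | None:
            for i, s, e in my_regions:
                if start < e and s < end:
                    return i
            return None

        for pos in range(n - 2):
            # + strand: PAM at [pos, pos+3), protospacer immediately 5'
            if seq[pos + 1 : pos + 3] == "GG" and pos >= PROTOSPACER_LEN:
                proto = seq[pos - PROTOSPACER_LEN : pos]
                rid = overlapping(pos - PROTOSPACER_LEN, pos)
                if rid is not None and "N" not in proto and "N" not in seq[pos : pos + 3]:
                    out.append(
                        GuideCandidate(
                            target_region_id=f"region{rid}",
                            chrom=chrom,
                            strand="+",
                            protospacer=proto,
                            pam=seq[pos : pos + 3],
                            pam_pos=pos,
                        )
                    )
            # - strand: CCN at [pos, pos+3) is an NGG PAM on the reverse
            # strand; the protospacer lies 3' of it in + coordinates
            if seq[pos : pos + 2] == "CC" and pos + 3 + PROTOSPACER_LEN <= n:
                proto_fwd = seq[pos + 3 : pos + 3 + PROTOSPACER_LEN]
                rid = overlapping(pos + 3, pos + 3 + PROTOSPACER_LEN)
                if (
                    rid is not None
                    and "N" not in proto_fwd
                    and "N" not in seq[pos : pos + 3]
                ):
                    out.append(
                        GuideCandidate(
                            target_region_id=f"region{rid}",
                            chrom=chrom,
                            strand="-",
                            protospacer=_revcomp(proto_fwd),
                            pam=_revcomp(seq[pos : pos + 3]),
                            pam_pos=pos,
                        )
                    )
    return out


def _duplex_tm(seq: str) -> float:
    if len(seq) < 2:
        return NO_DUPLEX_TM
    return float(MeltingTemp.Tm_NN(Seq(seq)))


def _longest_hybridizing_stretch(a: str, b_revcomp: str) -> str:
    """Longest common substring of ``a`` and the reverse complement of b.

    This is the longest contiguous stretch over which the two oligos can
    form a perfect heteroduplex.
    """
    best = ""
    m, n = len(a), len(b_revcomp)
    prev = [0] * (n + 1)
    for i in range(1, m + 1):
        cur = [0] * (n + 1)
        for j in range(1, n + 1):
            if a[i - 1] == b_revcomp[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > len(best):
                    best = a[i - cur[j] : i]
        prev = cur
    return best


def compute_metrics(
    candidates: Iterable[GuideCandidate],
    primer: str,
    end_len: int = 5,
) -> list[GuideCandidate]:
    """Fill GC and nearest-neighbor Tm metrics in place.

    heterodimer_tm: Tm of the longest perfect heteroduplex between the
    protospacer and the amplification primer.  end_stability_tm: Tm of a
    perfect duplex over the protospacer's 3'-terminal ``end_len`` bases
    (how tightly the extensible end anneals).
    """
    primer = primer.upper()
    primer_rc = _revcomp(primer)
    cands = list(candidates)
    for c in cands:
        c.gc_fraction = gc_fraction(c.protospacer)
        stretch = _longest_hybridizing_stretch(c.protospacer, primer_rc)
        c.heterodimer_tm = _duplex_tm(stretch)
        c.end_stability_tm = _duplex_tm(c.protospacer[-end_len:])
    return cands


def filter_guides(
    candidates: Iterable[GuideCandidate],
    gc_min: float = 0.30,
    gc_max: float = 0.80,
    heterodimer_tm_max: float = 40.0,
    end_stability_tm_max: float = 30.0,
) -> list[GuideCandidate]:
    """Composition/thermodynamic filters: gc_min < GC < gc_max (strict)
    and both Tm metrics at or below their thresholds.  Per-criterion
    outcomes are recorded in ``pass_flags``; only fully passing
    candidates are returned.  Order-independent and idempotent.
    """
    passed = []
    for c in candidates:
        c.pass_flags = {
            "gc": gc_min < c.gc_fraction < gc_max,
            "heterodimer_tm": c.heterodimer_tm <= heterodimer_tm_max,
            "end_stability_tm": c.end_stability_tm <= end_stability_tm_max,
        }
        if all(c.pass_flags.values()):
            passed.append(c)
    return passed


def _occurrences(genome: dict[str, str], pattern20: str) -> list[tuple[str, int, int]]:
    """Exact genomic occurrences of protospacer+NGG on either strand.

    Returned intervals span protospacer plus PAM in + strand coordinates.
    """
    hits = []
    rc = _revcomp(pattern20)
    for chrom, seq in genome.items():
        seq = seq.upper()
        start = seq.find(pattern20)
        while start != -1:
            pam = seq[start + 20 : start + 23]
            if len(pam) == 3 and pam[1:3] == "GG" and "N" not in pam:
                hits.append((chrom, start, start + 23))
            start = seq.find(pattern20, start + 1)
        start = seq.find(rc)
        while start != -1:
            pam = seq[start - 3 : start]
            if start >= 3 and pam[0:2] == "CC" and "N" not in pam:
                hits.append((chrom, start - 3, start + 20))
            start = seq.find(rc, start + 1)
    return hits


def off_target_filter(
    candidates: Iterable[GuideCandidate],
    genome: dict[str, str],
    target_regions: Sequence[tuple[str, int, int]],
) -> list[GuideCandidate]:
    """Discard guides with any protospacer+PAM occurrence outside the targets.

    Repeated occurrences are fine as long as every one lies inside a
    target region (rRNA operons are near-identical repeats).
    """

    def inside(chrom: str, s: int, e: int) -> bool:
        return any(c == chrom and s >= rs and e <= re for c, rs, re in target_regions)

    out = []
    for c in candidates:
        occ = _occurrences(genome, c.protospacer)
        c.off_target_hits = sum(0 if inside(*h) else 1 for h in occ)
        if c.off_target_hits == 0:
            out.append(c)
    return out


def emit_oligos(candidates: Iterable[GuideCandidate]) -> list[OligoRecord]:
    """Final pool: T7 + protospacer + scaffold, deduplicated, in
    deterministic (region, chrom, PAM position) order."""
    seen: set[str] = set()
    out = []
    for c in sorted(
        candidates, key=lambda c: (c.target_region_id, c.chrom, c.pam_pos, c.strand)
    ):
        if c.protospacer in seen:
            continue
        seen.add(c.protospacer)
        out.append(
            OligoRecord(
                protospacer=c.protospacer,
                oligo=T7_PROMOTER + c.protospacer + SCAFFOLD,
            )
        )
    return out


def design_pool(
    genome: dict[str, str],
    target_regions: Sequence[tuple[str, int, int]],
    primer: str,
    gc_min: float = 0.30,
    gc_max: float = 0.80,
    heterodimer_tm_max: float = 40.0,
    end_stability_tm_max: float = 30.0,
) -> tuple[list[OligoRecord], list[GuideCandidate]]:
    """Full design pipeline: scan, metrics, filters, off-target, oligos."""
    cands = scan_pam_sites(genome, target_regions)
    cands = compute_metrics(cands, primer)
    passed = filter_guides(
        cands,
        gc_min=gc_min,
        gc_max=gc_max,
        heterodimer_tm_max=heterodimer_tm_max,
        end_stability_tm_max=end_stability_tm_max,
    )
    retained = off_target_filter(passed, genome, target_regions)
    return emit_oligos(retained), cands


def candidates_table(candidates: Sequence[GuideCandidate]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        row = {
            "target_region_id": c.target_region_id,
            "chrom": c.chrom,
            "strand": c.strand,
            "pam_pos": c.pam_pos,
            "protospacer": c.protospacer,
            "pam": c.pam,
            "gc_fraction": c.gc_fraction,
            "heterodimer_tm": c.heterodimer_tm,
            "end_stability_tm": c.end_stability_tm,
            "off_target_hits": c.off_target_hits,
        }
        for k, v in c.pass_flags.items():
            row[f"pass_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def write_pool(
    oligos: Sequence[OligoRecord], tsv_path: str | Path, fasta_path: str | Path
) -> None:
    pd.DataFrame(
        [{"protospacer": o.protospacer, "oligo": o.oligo} for o in oligos]
    ).to_csv(tsv_path, sep="\t", index=False)
    with open(fasta_path, "w") as fh:
        for i, o in enumerate(oligos):
            fh.write(f">guide{i} {o.protospacer}\n{o.oligo}\n")
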