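"""Synthetic interactome libraries from a generative capture model.

The simulator emulates an IP'd proximity-ligation experiment on a small
bacterial genome.  Each captured event becomes one mate pair:

* with probability ``p_lig * rho * (1 - epsilon)`` a planted sRNA-mRNA
  pair is drawn with probability proportional to its intensity lambda
  and emitted as a chimera (one mate per partner, scattered around a
  fixed interaction site within each feature);
* with probability ``p_lig * epsilon`` a background chimera joins two
  abundance-weighted random transcript positions (random-ligation noise);
* otherwise a single fragment is emitted within one feature chosen
  proportionally to expression weight.

``rho`` is the chimera retention probability and carries the strain
effect: a wild-type chaperone holds sRNA-mRNA pairs through capture,
while a rim-face mutant loses them (about 100-fold under the in-vitro
ligation protocol, about 10-fold when ligation happens in vivo before
the IP).  ``p_lig`` is the protocol ligation efficiency; the RIP-like
protocol performs no ligation at all, so it forces ``p_lig = 0``.
Expression weights are log-uniform across features so abundant species
dominate the background, as tRNA/rRNA chimeras do in real libraries.

Everything is deterministic given the configuration and seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import Feature, FeatureSet
from .fragments import Locus, MatePair

PROTOCOL_P_LIG = {"rilseq": 0.20, "irilseq": 0.022, "ripseq": 0.0}
MUTANT_RHO_FACTOR = {"rilseq": 0.01, "irilseq": 0.1, "ripseq": 1.0}

_LEN_RANGES = {
    "gene": (300, 3000),
    "sRNA": (50, 300),
    "tRNA": (70, 95),
    "rRNA": (1500, 2900),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Generative-model parameters for one simulated library."""

    genome_length: int = 200_000
    n_mrna: int = 40
    n_srna: int = 20
    n_trna: int = 5
    n_rrna: int = 2
    n_planted: int = 20
    planted_pairs: tuple[tuple[str, str, float], ...] | None = None
    rho: float = 0.75
    epsilon: float = 0.03
    p_lig: float | None = None
    n_fragments: int = 20_000
    frag_len_mean: float = 25.0
    frag_len_sd: float = 5.0
    site_jitter: int = 30
    seed: int = 0
    protocol: str = "rilseq"
    library_reverse: bool = True
    chrom: str = "chr"

    def __post_init__(self) -> None:
        if self.protocol not in PROTOCOL_P_LIG:
            raise ValueError(f"unknown protocol {self.protocol!r}")
        for name, value in (("rho", self.rho), ("epsilon", self.epsilon)):
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_fragments < 0:
            raise ValueError("n_fragments must be >= 0")

    @property
    def effective_p_lig(self) -> float:
        if self.protocol == "ripseq":
            return 0.0
        if self.p_lig is not None:
            return self.p_lig
        return PROTOCOL_P_LIG[self.protocol]

    def chimera_probability(self, planted_available: bool = True) -> float:
        """Expected chimera fraction: p_lig * (rho*(1-eps) + eps)."""
        p = self.effective_p_lig
        planted = self.rho * (1.0 - self.epsilon) if planted_available else 0.0
        return p * (planted + self.epsilon)


@dataclass
class TruthTable:
    """Planted ground truth: per-pair expectations and per-fragment origins."""

    pairs: pd.DataFrame  # pair_id, srna, target, lam, expected, realized
    fragments: pd.DataFrame  # read_id, origin, pair_id

    def write(self, pairs_path: str | Path, fragments_path: str | Path) -> None:
        self.pairs.to_csv(pairs_path, sep="\t", index=False)
        self.fragments.to_csv(fragments_path, sep="\t", index=False)


# ------------------------------------------------------------------ genome


def simulate_genome(config: SimulationConfig) -> tuple[dict[str, str], FeatureSet]:
    """A random genome with non-overlapping stranded features.

    Features (mRNA genes, sRNAs, tRNAs, rRNAs) are shuffled, then placed
    left to right with random inter-feature gaps.  Errors out if the
    requested features cannot fit.
    """
    rng = np.random.default_rng([config.seed, 0])
    specs: list[tuple[str, str]] = (
        [("gene", f"mgene{i:03d}") for i in range(config.n_mrna)]
        + [("sRNA", f"srna{i:03d}") for i in range(config.n_srna)]
        + [("tRNA", f"trna{i:03d}") for i in range(config.n_trna)]
        + [("rRNA", f"rrna{i:03d}") for i in range(config.n_rrna)]
    )
    order = rng.permutation(len(specs))
    feats: list[Feature] = []
    pos = int(rng.integers(100, 300))
    for idx in order:
        ftype, name = specs[idx]
        lo, hi = _LEN_RANGES[ftype]
        length = int(rng.integers(lo, hi + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        if pos + length > config.genome_length - 100:
            raise ValueError(
                "features do not fit in the genome; increase genome_length"
            )
        feats.append(
            Feature(
                feature_id=name,
                chrom=config.chrom,
                start=pos,
                end=pos + length,
                strand=strand,
                ftype=ftype,
                name=name,
            )
        )
        pos += length + int(rng.integers(150, 400))
    annotation = FeatureSet(feats, {config.chrom: config.genome_length})
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = bases[rng.integers(0, 4, size=config.genome_length)].tobytes().decode()
    return {config.chrom: seq}, annotation


def default_planted_pairs(
    config: SimulationConfig, annotation: FeatureSet
) -> tuple[tuple[str, str, float], ...]:
    """Draw n_planted distinct sRNA-mRNA pairs with intensities in [0.5, 2]."""
    rng = np.random.default_rng([config.seed, 1])
    srnas = [f for f in annotation if f.ftype == "sRNA"]
    genes = [f for f in annotation if f.ftype == "gene"]
    # partners closer than the Single/Chimeric distance cutoff on the same
    # strand would be read as one fragment, so keep planted pairs resolvable
    combos = [
        (s.name, g.name)
        for s in srnas
        for g in genes
        if s.strand != g.strand
        or min(abs(s.start - g.end), abs(g.start - s.end)) > 2000
    ]
    if len(combos) < config.n_planted:
        raise ValueError("not enough sRNA-mRNA combinations to plant")
    chosen = rng.choice(len(combos), size=config.n_planted, replace=False)
    lams = rng.uniform(0.5, 2.0, size=config.n_planted)
    return tuple(
        (combos[i][0], combos[i][1], float(lam)) for i, lam in zip(chosen, lams)
    )


# ------------------------------------------------------------------ library


def _fragment_interval(
    rng: np.random.Generator,
    feat: Feature,
    config: SimulationConfig,
    center: int | None = None,
) -> tuple[int, int]:
    length = int(round(rng.normal(config.frag_len_mean, config.frag_len_sd)))
    length = max(15, min(length, feat.length))
    if center is None:
        start = int(rng.integers(feat.start, feat.end - length + 1))
    else:
        start = center - length // 2
        start = max(feat.start, min(start, feat.end - length))
    return start, start + length


def _mates_for_single(
    rng: np.random.Generator, feat: Feature, config: SimulationConfig
) -> tuple[Locus, Locus]:
    start, end = _fragment_interval(rng, feat, config)
    rl = min(20, end - start)
    if feat.strand == "+":
        five = Locus(feat.chrom, start, start + rl, feat.strand)
        three = Locus(feat.chrom, end - rl, end, feat.strand)
    else:
        five = Locus(feat.chrom, end - rl, end, feat.strand)
        three = Locus(feat.chrom, start, start + rl, feat.strand)
    return five, three


def _aligned(locus: Locus, library_reverse: bool) -> Locus:
    return locus.flipped() if library_reverse else locus


def simulate_library(
    config: SimulationConfig, annotation: FeatureSet
) -> tuple[list[MatePair], TruthTable]:
    """Draw one library of ``n_fragments`` mate pairs plus its ground truth.

    Planted chimeras follow the mRNA-first convention: the mate carrying
    the construct 5' side (mate 1, RNA1) comes from the mRNA target and
    mate 2 (RNA2) from the sRNA.  Mate strands are written as aligned
    strands: the complement of the transcript strand when the library is
    reverse-stranded.
    """
    rng = np.random.default_rng([config.seed, 2])
    feats = list(annotation)
    by_name = {f.name: f for f in feats}
    weights = 10.0 ** rng.uniform(0.0, 2.0, size=len(feats))
    weights /= weights.sum()

    planted = config.planted_pairs
    if planted is None and config.n_planted > 0:
        planted = default_planted_pairs(config, annotation)
    planted = planted or ()
    lam = np.array([p[2] for p in planted], dtype=float)
    lam_share = lam / lam.sum() if len(lam) else lam
    # one fixed interaction site per partner, at the feature midpoint
    sites = [
        (
            by_name[target],
            (by_name[target].start + by_name[target].end) // 2,
            by_name[srna],
            (by_name[srna].start + by_name[srna].end) // 2,
        )
        for srna, target, _ in planted
    ]

    p_lig = config.effective_p_lig
    p_planted = p_lig * config.rho * (1.0 - config.epsilon) if planted else 0.0
    p_bg = p_lig * config.epsilon
    origins = rng.choice(
        3, size=config.n_fragments, p=[1.0 - p_planted - p_bg, p_planted, p_bg]
    )

    jitter = config.site_jitter
    pairs_out: list[MatePair] = []
    origin_labels = []
    pair_ids = []
    realized = np.zeros(len(planted), dtype=int)
    for i, origin in enumerate(origins):
        rid = f"r{i:07d}"
        if origin == 1:
            k = int(rng.choice(len(planted), p=lam_share))
            realized[k] += 1
            target, t_site, srna, s_site = sites[k]
            t_center = t_site + int(rng.integers(-jitter, jitter + 1))
            s_center = s_site + int(rng.integers(-jitter, jitter + 1))
            ts, te = _fragment_interval(rng, target, config, center=t_center)
            ss, se = _fragment_interval(rng, srna, config, center=s_center)
            mate1 = Locus(target.chrom, ts, te, target.strand)
            mate2 = Locus(srna.chrom, ss, se, srna.strand)
            origin_labels.append("planted")
            pair_ids.append(f"pair{k:03d}")
        elif origin == 2:
            fa = feats[int(rng.choice(len(feats), p=weights))]
            fb = feats[int(rng.choice(len(feats), p=weights))]
            s1, e1 = _fragment_interval(rng, fa, config)
            s2, e2 = _fragment_interval(rng, fb, config)
            mate1 = Locus(fa.chrom, s1, e1, fa.strand)
            mate2 = Locus(fb.chrom, s2, e2, fb.strand)
            origin_labels.append("background")
            pair_ids.append("")
        else:
            feat = feats[int(rng.choice(len(feats), p=weights))]
            mate1, mate2 = _mates_for_single(rng, feat, config)
            origin_labels.append("single")
            pair_ids.append("")
        pairs_out.append(
            MatePair(
                read_id=rid,
                mate1=_aligned(mate1, config.library_reverse),
                mate2=_aligned(mate2, config.library_reverse),
                library_reverse=config.library_reverse,
            )
        )

    expected = (
        config.n_fragments * p_planted * lam_share
        if len(planted)
        else np.zeros(0)
    )
    truth = TruthTable(
        pairs=pd.DataFrame(
            {
                "pair_id": [f"pair{k:03d}" for k in range(len(planted))],
                "srna": [p[0] for p in planted],
                "target": [p[1] for p in planted],
                "lam": [p[2] for p in planted],
                "expected": expected,
                "realized": realized,
            }
        ),
        fragments=pd.DataFrame(
            {
                "read_id": [p.read_id for p in pairs_out],
                "origin": origin_labels,
                "pair_id": pair_ids,
            }
        ),
    )
    return pairs_out, truth


# ------------------------------------------------------------------ scenarios


def strain_scenarios(
    base: SimulationConfig, mutant_factor: float | None = None
) -> dict[str, SimulationConfig]:
    """Wild-type vs. rim-mutant configurations.

    The mutant is modeled purely as retention scaling: rho is divided by
    100 under the in-vitro-ligation protocol and by 10 under in-vivo
    ligation, reflecting pair dissociation from the mutant chaperone
    during the longer capture procedure.
    """
    factor = (
        mutant_factor if mutant_factor is not None else MUTANT_RHO_FACTOR[base.protocol]
    )
    return {"WT": base, "R16A": replace(base, rho=base.rho * factor)}


# ------------------------------------------------------------------ output


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_config(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(config), fh, indent=2, default=str)
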