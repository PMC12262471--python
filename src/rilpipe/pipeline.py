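"""End-to-end orchestration: simulate -> annotate -> fragments -> call -> quantify.

A run is described by a :class:`RunConfig` (typically loaded from YAML):
either a synthetic scenario (a base :class:`SimulationConfig` plus
per-sample strain/protocol assignments) or real inputs (a BEDPE per
sample and a GFF3 annotation).  All randomness flows from the single
root seed; per-sample seeds are derived deterministically from it.

Outputs per sample: fragments TSV, interactions TSV, Circos link file,
significant-region BED; per run: a counts matrix and a summary JSON with
the per-sample single/chimeric totals, chimera fraction, and S-chimera
count.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import calling, fragments as frag_mod, quantify
from .annotation import FeatureSet, compose_annotation
from .calling import AnalysisParams
from .simulate import (
    MUTANT_RHO_FACTOR,
    SimulationConfig,
    simulate_genome,
    simulate_library,
    write_fasta,
)

log = logging.getLogger("rilpipe")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class SampleSpec:
    name: str
    strain: str = "WT"  # "WT" or "R16A" (retention-scaled)
    protocol: str = "rilseq"
    bedpe: str | None = None  # real input; otherwise simulated
    total_of: str | None = None  # name of the matched Total sample (IP/Total)


@dataclass
class RunConfig:
    outdir: Path
    seed: int = 0
    params: AnalysisParams = field(default_factory=AnalysisParams)
    simulation: SimulationConfig | None = None
    samples: list[SampleSpec] = field(default_factory=list)
    annotation_gff: str | None = None
    genome_lengths: dict[str, int] | None = None
    library_reverse: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw: dict[str, Any] = yaml.safe_load(fh)
        sim = (
            SimulationConfig(**raw["simulation"]) if raw.get("simulation") else None
        )
        return cls(
            outdir=Path(raw["outdir"]),
            seed=int(raw.get("seed", 0)),
            params=AnalysisParams(**raw.get("params", {})),
            simulation=sim,
            samples=[SampleSpec(**s) for s in raw.get("samples", [])],
            annotation_gff=raw.get("annotation_gff"),
            genome_lengths=raw.get("genome_lengths"),
            library_reverse=bool(raw.get("library_reverse", True)),
        )

    def validate(self) -> None:
        names = [s.name for s in self.samples]
        if len(names) != len(set(names)):
            raise PipelineError("config", "sample names must be unique")
        if not self.samples:
            raise PipelineError("config", "no samples configured")
        for s in self.samples:
            if s.bedpe is not None and not Path(s.bedpe).exists():
                raise PipelineError("config", f"missing input file {s.bedpe}")
            if s.bedpe is None and self.simulation is None:
                raise PipelineError(
                    "config",
                    f"sample {s.name}: no BEDPE and no simulation configured",
                )
        if self.simulation is None:
            if self.annotation_gff is None or self.genome_lengths is None:
                raise PipelineError(
                    "config",
                    "real-input runs need annotation_gff and genome_lengths",
                )
            if not Path(self.annotation_gff).exists():
                raise PipelineError(
                    "config", f"missing annotation file {self.annotation_gff}"
                )


def _sample_config(run: RunConfig, spec: SampleSpec, index: int) -> SimulationConfig:
    assert run.simulation is not None
    cfg = replace(
        run.simulation,
        protocol=spec.protocol,
        seed=(run.seed * 1000 + index) % (2**31),
    )
    if spec.strain == "R16A":
        cfg = replace(cfg, rho=cfg.rho * MUTANT_RHO_FACTOR[spec.protocol])
    elif spec.strain != "WT":
        raise PipelineError("config", f"unknown strain {spec.strain!r}")
    return cfg


def run_pipeline(run: RunConfig) -> dict[str, Any]:
    """Execute every stage for every sample; return the summary dict.

    Stage failures raise :class:`PipelineError` with the stage name.
    The summary (also written to ``summary.json``) records every
    parameter alongside the per-sample fragment and S-chimera totals.
    """
    run.validate()
    outdir = Path(run.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # ---------------------------------------------------------- annotation
    if run.simulation is not None:
        # the genome layout is shared across samples: derive it from the
        # root seed, not from per-sample seeds
        genome_cfg = replace(run.simulation, seed=run.seed)
        genome, base = simulate_genome(genome_cfg)
        annotation = compose_annotation(base)
        write_fasta(genome, outdir / "genome.fa")
        base.write_gff3(outdir / "genes.gff3")
        annotation.write_gff3(outdir / "all_features.gff3")
    else:
        annotation = FeatureSet.load_gff3(run.annotation_gff, run.genome_lengths)

    summary: dict[str, Any] = {
        "seed": run.seed,
        "params": {
            "window": run.params.window,
            "min_chimeras": run.params.min_chimeras,
            "alpha": run.params.alpha,
            "assign_ratio": run.params.assign_ratio,
            "max_gap": run.params.max_gap,
        },
        "samples": {},
    }
    count_columns: dict[str, pd.Series] = {}

    for index, spec in enumerate(run.samples):
        log.info("sample %s: start", spec.name)
        try:
            if spec.bedpe is not None:
                pairs = frag_mod.read_bedpe(
                    spec.bedpe, library_reverse=run.library_reverse
                )
            else:
                cfg = _sample_config(run, spec, index)
                pairs, truth = simulate_library(cfg, _base_features(annotation))
                truth.write(
                    outdir / f"{spec.name}.truth_pairs.tsv",
                    outdir / f"{spec.name}.truth_fragments.tsv",
                )
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("input", f"sample {spec.name}: {exc}") from exc

        try:
            frags = frag_mod.classify_pairs(pairs, max_gap=run.params.max_gap)
            stats = frag_mod.library_stats(frags)
            frag_mod.write_fragments_tsv(frags, outdir / f"{spec.name}.fragments.tsv")
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("fragments", f"sample {spec.name}: {exc}") from exc

        try:
            chimeras = [f for f in frags if f.is_chimeric]
            counts = calling.bin_chimeras(chimeras, run.params)
            s_chimeras = calling.call_s_chimeras(counts, run.params)
            retained = calling.filter_nonsignificant(chimeras, s_chimeras)
            calling.annotate_s_chimeras(s_chimeras, retained, annotation, run.params)
            calling.write_interaction_table(
                s_chimeras, outdir / f"{spec.name}.interactions.tsv"
            )
            calling.circos_links(s_chimeras, outdir / f"{spec.name}.links.txt")
            calling.significant_regions_bed(
                s_chimeras, outdir / f"{spec.name}.regions.bed"
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("calling", f"sample {spec.name}: {exc}") from exc

        try:
            count_columns[spec.name] = quantify.count_features(frags, annotation)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("quantify", f"sample {spec.name}: {exc}") from exc

        summary["samples"][spec.name] = {
            "strain": spec.strain,
            "protocol": spec.protocol,
            "n_single": stats.n_single,
            "n_chimeric": stats.n_chimeric,
            "chimera_fraction": stats.chimera_fraction,
            "n_s_chimeras": len(s_chimeras),
        }
        log.info(
            "sample %s: %d single, %d chimeric, %d S-chimeras",
            spec.name,
            stats.n_single,
            stats.n_chimeric,
            len(s_chimeras),
        )

    matrix = quantify.count_matrix(count_columns)
    matrix.to_csv(outdir / "counts.tsv", sep="\t")

    # IP/Total enrichment for declared pairings
    enrich_frames = {}
    for spec in run.samples:
        if spec.total_of and spec.total_of in count_columns:
            norm, _ = quantify.normalize(matrix + 1)
            enrich_frames[spec.name] = quantify.enrichment_ratio(
                norm[spec.name], norm[spec.total_of]
            )["log2_ratio"]
    if enrich_frames:
        pd.DataFrame(enrich_frames).to_csv(outdir / "enrichment.tsv", sep="\t")

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary


def _base_features(annotation: FeatureSet) -> FeatureSet:
    """The primary (non-derived) features, used as simulation transcripts."""
    from .annotation import DERIVED_TYPES

    feats = [f for f in annotation if f.ftype not in DERIVED_TYPES]
    return FeatureSet(feats, annotation.genome_lengths)
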