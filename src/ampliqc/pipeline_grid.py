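"""End-to-end orchestration and the QFM x AFM x TIM sensitivity grid.

One pipeline run takes a raw read pool through demultiplexing, quality
filtering, dereplication, abundance filtering, 97% OTU clustering,
chimera removal, optional DTU collapse, optional control subtraction and
optional panel assignment, logging stage-by-stage counts.  The grid runs
the full cross-product of filtering variants and reports the spread of
taxonomic-unit counts per method — the analysis-parameter sensitivity
check that shows how strongly unit counts depend on filtering choices.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from ._core import Read
from .clustering import UniqueSeq, cluster_otus, dereplicate, detect_chimeras
from .controls import assign_to_panel, subtract_controls
from .demux import DemuxReport, SampleSheet, demultiplex
from .dtu import collapse_otus
from .qc_filters import AFM_PRESETS, QFM_PRESETS, AFMSpec, QFMSpec, filter_abundance, filter_qscore
from .synthetic_data import ReferencePanel

logger = logging.getLogger("ampliqc")

TIMS = ("OTU", "DTU")


@dataclass(frozen=True)
class PipelineConfig:
    qfm: QFMSpec = QFM_PRESETS["QFM1"]
    afm: AFMSpec = AFM_PRESETS["AFM_none"]
    tim: str = "OTU"
    otu_threshold: float = 0.97
    dtu_threshold: float = 0.03
    afm_stage: str = "pre_cluster"  # or post_cluster
    remove_chimeras: bool = True
    chimera_min_fold: float = 2.0
    chimera_min_improve: int = 3
    control_seqs: tuple[str, ...] = ()
    control_mode: str = "cluster97"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tim not in TIMS:
            raise ValueError(f"tim must be one of {TIMS}")
        if self.afm_stage not in ("pre_cluster", "post_cluster"):
            raise ValueError("afm_stage must be pre_cluster or post_cluster")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["qfm"] = dataclasses.asdict(self.qfm)
        d["afm"] = dataclasses.asdict(self.afm)
        return d

    @property
    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class SampleResult:
    sample_id: str
    stage_counts: dict[str, int]
    otus: list
    dtu_groups: list[list[str]] | None
    assignments: list | None
    drop_pct: float | None

    @property
    def otu_count(self) -> int:
        return len(self.otus)

    @property
    def dtu_count(self) -> int | None:
        return len(self.dtu_groups) if self.dtu_groups is not None else None


@dataclass
class PipelineResult:
    config: PipelineConfig
    demux_report: DemuxReport
    samples: dict[str, SampleResult]


def _cluster_stage(
    reads: Sequence[Read], config: PipelineConfig
) -> tuple[dict[str, int], list]:
    """Quality filter -> dereplicate -> AFM -> OTU -> chimera removal for one sample."""
    counts: dict[str, int] = {"input": len(reads)}
    kept = filter_qscore(reads, config.qfm)
    counts["after_qfm"] = len(kept)
    uniques = dereplicate(kept)
    counts["uniques"] = len(uniques)
    if config.afm_stage == "pre_cluster":
        uniques = filter_abundance(uniques, config.afm, total_reads=len(kept))
        counts["uniques_after_afm"] = len(uniques)
    if config.remove_chimeras and uniques:
        flags = detect_chimeras(
            uniques, config.chimera_min_fold, config.chimera_min_improve
        )
        uniques = [u for u, f in zip(uniques, flags) if not f]
        counts["uniques_after_chimera"] = len(uniques)
    otus = cluster_otus(uniques, config.otu_threshold)
    counts["otus"] = len(otus)
    if config.afm_stage == "post_cluster":
        reads_surviving = sum(o.abundance for o in otus)
        pseudo = [UniqueSeq(o.centroid, o.abundance) for o in otus]
        keep_set = {
            u.sequence
            for u in filter_abundance(pseudo, config.afm, total_reads=reads_surviving)
        }
        otus = [o for o in otus if o.centroid in keep_set]
        counts["otus_after_afm"] = len(otus)
    counts["reads_surviving"] = sum(o.abundance for o in otus)
    return counts, otus


def run_pipeline(
    reads: Sequence[Read],
    sheet: SampleSheet,
    config: PipelineConfig = PipelineConfig(),
    panel: ReferencePanel | None = None,
) -> PipelineResult:
    """Run the full per-sample QC pipeline over a raw read pool."""
    by_sample, demux_report = demultiplex(
        reads, sheet, primer_mismatch=config.qfm.primer_mismatch
    )
    logger.info(
        "demux: %d assigned / %d unassigned / %d discarded of %d",
        demux_report.assigned, demux_report.unassigned,
        demux_report.discarded_ambiguous, demux_report.total,
    )
    results: dict[str, SampleResult] = {}
    for sample_id, sample_reads in by_sample.items():
        counts, otus = _cluster_stage(sample_reads, config)
        drop_pct = None
        if config.control_seqs:
            otus, _removed, drop_pct = subtract_controls(
                otus, list(config.control_seqs), mode=config.control_mode
            )
            counts["otus_after_controls"] = len(otus)
        else:
            logger.info("%s: control stage skipped (no control sequences)", sample_id)
        dtu_groups = None
        if config.tim == "DTU":
            dtu_groups = collapse_otus(otus, config.dtu_threshold).groups
            counts["dtus"] = len(dtu_groups)
        assignments = assign_to_panel(otus, panel) if panel is not None else None
        logger.info("%s: %s", sample_id, counts)
        results[sample_id] = SampleResult(
            sample_id, counts, otus, dtu_groups, assignments, drop_pct
        )
    return PipelineResult(config, demux_report, results)


@dataclass
class GridResult:
    table: pd.DataFrame  # columns: qfm, afm, tim, sample, unit_count, reads_surviving
    provenance: dict

    def summary(self) -> pd.DataFrame:
        """Min/max unit counts per TIM over the grid — the headline spread."""
        return (
            self.table.groupby("tim")["unit_count"].agg(["min", "max"]).reset_index()
        )


def sensitivity_grid(
    reads: Sequence[Read],
    sheet: SampleSheet,
    qfms: Sequence[QFMSpec],
    afms: Sequence[AFMSpec],
    tims: Sequence[str] = TIMS,
    base_config: PipelineConfig = PipelineConfig(),
    panel: ReferencePanel | None = None,
) -> GridResult:
    """Run the full QFM x AFM x TIM cross-product on one read pool."""
    rows = []
    for qfm in qfms:
        for afm in afms:
            for tim in tims:
                config = dataclasses.replace(base_config, qfm=qfm, afm=afm, tim=tim)
                result = run_pipeline(reads, sheet, config, panel=panel)
                for sample_id, sr in result.samples.items():
                    rows.append(
                        {
                            "qfm": qfm.name,
                            "afm": afm.name,
                            "tim": tim,
                            "sample": sample_id,
                            "unit_count": sr.dtu_count if tim == "DTU" else sr.otu_count,
                            "reads_surviving": sr.stage_counts["reads_surviving"],
                        }
                    )
    table = pd.DataFrame(
        rows, columns=["qfm", "afm", "tim", "sample", "unit_count", "reads_surviving"]
    )
    provenance = {"config_hash": base_config.hash, "seed": base_config.seed}
    return GridResult(table, provenance)


def write_reports(result: GridResult, outdir: str | Path) -> dict[str, Path]:
    """Write the grid as TSV plus a JSON report embedding provenance."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"grid": outdir / "grid.tsv", "report": outdir / "report.json"}
    result.table.to_csv(paths["grid"], sep="\t", index=False)
    payload = {
        "provenance": result.provenance,
        "summary": result.summary().to_dict(orient="records"),
        "cells": result.table.to_dict(orient="records"),
    }
    with open(paths["report"], "w") as fh:
        json.dump(payload, fh, indent=2)
    return paths


def read_grid(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
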