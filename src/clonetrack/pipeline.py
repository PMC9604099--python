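"""End-to-end orchestration: simulate -> call -> assemble -> classify -> report.

Each run is parameterised by a :class:`PipelineConfig`; all outputs embed the
seed and a hash of the configuration, and identical configurations produce
byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .assembly import Clone, assemble_clones, clone_table
from .calling import (DEFAULT_K, DEFAULT_NUCLEAR_RATIO_MIN, CallingResult,
                      call_table)
from .classify import (MorphologyFeatures, classify_cell_type,
                       classify_clone_layers, classify_clone_potency)
from .report import CohortSummary, summarize_cohort
from .simulate import GroundTruth, SimConfig, cohort_frame, simulate_cohort
from .tables import read_cell_table, write_cell_table

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline",
           "classify_cells", "classify_clones", "DependencyError"]

log = logging.getLogger("clonetrack")

STAGES = ("simulate", "call", "assemble", "classify", "report")


class DependencyError(RuntimeError):
    """A stage was requested without its upstream inputs."""


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the analysis pipeline.

    ``seed`` drives the simulation stage (it overrides ``sim.seed``); the
    analysis stages are deterministic.
    """

    sim: SimConfig = field(default_factory=SimConfig)
    k: float = DEFAULT_K
    nuclear_ratio_min: float = DEFAULT_NUCLEAR_RATIO_MIN
    min_complexity: int = 1
    inner_depth_max: float = 0.25
    outer_depth_min: float = 0.75
    glia_counts_as_differentiated: bool = False
    span: float = 0.75
    degree: int = 2
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """In-memory artifact bundle of one pipeline run."""

    config: PipelineConfig
    cells: pd.DataFrame | None = None
    labeled: pd.DataFrame | None = None
    calling: CallingResult | None = None
    clones: list[Clone] | None = None
    summary: CohortSummary | None = None
    ground_truth: GroundTruth | None = None
    paths: dict[str, Path] = field(default_factory=dict)


def classify_cells(cells: pd.DataFrame, inner_depth_max: float = 0.25,
                   outer_depth_min: float = 0.75) -> pd.DataFrame:
    """Fill the ``cell_type`` column from the morphology columns."""
    out = cells.copy()
    types = []
    for _, row in out.iterrows():
        f = MorphologyFeatures(
            layer=str(row["layer"]),
            soma_relative_depth=float(row["soma_relative_depth"]),
            soma_size=str(row["soma_size"]),
            apical_process_extent=float(row["apical_process_extent"]),
            basal_process_extent=float(row["basal_process_extent"]),
            process_orientation=str(row["process_orientation"]))
        types.append(classify_cell_type(f, inner_depth_max=inner_depth_max,
                                        outer_depth_min=outer_depth_min))
    out["cell_type"] = types
    return out


def classify_clones(clones: list[Clone], labeled: pd.DataFrame,
                    glia_counts_as_differentiated: bool = False) -> list[Clone]:
    """Attach member types and assign layer/potency classes in place."""
    type_of = dict(zip(labeled["cell_id"].astype(str), labeled["cell_type"]))
    layer_of = dict(zip(labeled["cell_id"].astype(str), labeled["layer"]))
    for clone in clones:
        clone.member_types = [type_of[cid] for cid in clone.cell_ids]
        clone.member_layers = [layer_of[cid] for cid in clone.cell_ids]
        clone.layer_class = classify_clone_layers(clone.member_layers)
        clone.potency_class = classify_clone_potency(
            clone.member_types,
            glia_counts_as_differentiated=glia_counts_as_differentiated)
    return clones


def run_pipeline(
    config: PipelineConfig,
    stages: tuple[str, ...] = STAGES,
    cells: pd.DataFrame | None = None,
    outdir: Path | str | None = None,
) -> PipelineResult:
    """Execute the enabled stages in order and (optionally) persist outputs.

    ``cells`` seeds the run when the simulate stage is disabled (e.g. a
    table read from disk).  With ``outdir`` set, the run writes
    ``cells.csv``, ``clones.csv``, ``report.json``, ground-truth sidecars
    (when simulating) and ``pipeline.log``; every file embeds the seed and
    config hash.
    """
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    stages = tuple(s for s in STAGES if s in stages)
    chash = config.config_hash()
    result = PipelineResult(config=config)

    handlers: list[logging.Handler] = []
    if not log.handlers:
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(logging.Formatter("%(name)s %(levelname)s: %(message)s"))
        log.addHandler(h)
        handlers.append(h)
    log.setLevel(logging.INFO)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fh = logging.FileHandler(outdir / "pipeline.log", mode="w")
        fh.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        log.addHandler(fh)
        handlers.append(fh)

    try:
        if "simulate" in stages:
            sim = config.sim.with_seed(config.seed)
            embryos, truth = simulate_cohort(sim)
            cells = cohort_frame(embryos)
            result.ground_truth = truth
            log.info("simulate: %d embryos, %d cells, %d labeled progenitors",
                     len(embryos), len(cells),
                     int(truth.progenitors["labeled"].sum()))
        if cells is None and set(stages) & {"call", "assemble", "classify",
                                            "report"}:
            raise DependencyError(
                "no cell table: enable the simulate stage or supply cells")
        result.cells = cells

        labeled = None
        if "call" in stages:
            calling = call_table(cells, k=config.k,
                                 nuclear_ratio_min=config.nuclear_ratio_min)
            result.calling = calling
            result.cells = calling.cells
            labeled = calling.labeled
            log.info("call: %d cells in, %d labeled, %d excluded, "
                     "%d ambiguous nuclear calls",
                     len(cells), len(labeled), calling.n_excluded,
                     len(calling.ambiguous))

        clones = None
        if "assemble" in stages:
            if labeled is None:
                raise DependencyError("assemble requires the call stage")
            clones = assemble_clones(labeled,
                                     min_complexity=config.min_complexity)
            log.info("assemble: %d clones from %d labeled cells",
                     len(clones), len(labeled))

        if "classify" in stages:
            if clones is None:
                raise DependencyError("classify requires the assemble stage")
            labeled = classify_cells(
                labeled, inner_depth_max=config.inner_depth_max,
                outer_depth_min=config.outer_depth_min)
            classify_clones(
                clones, labeled,
                glia_counts_as_differentiated=config.glia_counts_as_differentiated)
            # propagate types back into the full table
            type_of = dict(zip(labeled["cell_id"].astype(str),
                               labeled["cell_type"]))
            full = result.cells.copy()
            full["cell_type"] = [
                type_of.get(str(cid), "") for cid in full["cell_id"]]
            result.cells = full
            log.info("classify: %d cells typed, %d clones classed",
                     len(labeled), len(clones))
        result.labeled = labeled
        result.clones = clones

        if "report" in stages:
            if clones is None or labeled is None or \
                    "cell_type" not in labeled.columns or \
                    (labeled["cell_type"] == "").all():
                raise DependencyError(
                    "report requires called, assembled and classified clones")
            result.summary = summarize_cohort(
                labeled, clones, n_cells_analyzed=len(result.cells),
                span=config.span, degree=config.degree)
            log.info("report: %d cells analysed, %d assigned, %d clones",
                     result.summary.n_cells_analyzed,
                     result.summary.n_cells_assigned, result.summary.n_clones)

        if outdir is not None:
            _persist(result, outdir, chash)
    finally:
        for h in handlers:
            log.removeHandler(h)
            h.close()
    return result


def _persist(result: PipelineResult, outdir: Path, chash: str) -> None:
    seed = result.config.seed
    if result.cells is not None:
        write_cell_table(result.cells, outdir / "cells.csv", seed=seed,
                         config_hash=chash)
        result.paths["cells"] = outdir / "cells.csv"
    if result.ground_truth is not None:
        write_cell_table(result.ground_truth.cells,
                         outdir / "ground_truth_cells.csv", seed=seed,
                         config_hash=chash)
        write_cell_table(result.ground_truth.progenitors,
                         outdir / "ground_truth_progenitors.csv", seed=seed,
                         config_hash=chash)
        result.paths["ground_truth_cells"] = outdir / "ground_truth_cells.csv"
        result.paths["ground_truth_progenitors"] = (
            outdir / "ground_truth_progenitors.csv")
    if result.clones is not None:
        write_cell_table(clone_table(result.clones), outdir / "clones.csv",
                         seed=seed, config_hash=chash)
        result.paths["clones"] = outdir / "clones.csv"
    if result.summary is not None:
        payload = {
            "_meta": {"tool": f"clonetrack {__version__}", "seed": seed,
                      "config_hash": chash},
            **result.summary.to_dict(),
        }
        (outdir / "report.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n")
        result.paths["report"] = outdir / "report.json"


def run_from_table(path, config: PipelineConfig,
                   stages: tuple[str, ...] = ("call", "assemble", "classify",
                                              "report"),
                   outdir=None) -> PipelineResult:
    """Run analysis stages on a persisted cell table."""
    return run_pipeline(config, stages=stages, cells=read_cell_table(path),
                        outdir=outdir)
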