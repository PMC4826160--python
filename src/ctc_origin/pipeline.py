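"""End-to-end orchestration: simulate -> segment/quantify -> phenotype -> classify.

One YAML-driven configuration runs the whole workflow the way a two-tube
blood draw is processed: capture (here, simulation or a directory of real
images in the same TIFF + sidecar layout), per-cell quantification,
phenotyping, and tissue-of-origin classification, with every intermediate
written to the output directory.  A two-draw mode runs a second scene
(typically with altered marker frequencies, e.g. an ER fraction that has
shifted between draws) and reports both population summaries side by side;
classification pools the evaluable CTCs from both draws.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from . import __version__
from .errors import ConfigurationError, CTCOriginError
from .frequency import (
    FrequencyTable,
    default_frequency_table,
    load_frequency_table,
    panel_for_sex,
)
from .inference import DEFAULT_CALL_MARGIN, OriginPosterior, population_posterior
from .phenotyping import (
    CellPhenotype,
    PopulationSummary,
    assemble_phenotypes,
    phenotypes_to_frame,
    summarize,
)
from .scene import NUCLEAR_CHANNEL, SceneConfig, generate_scene, read_scene, write_scene
from .segmentation import ThresholdPolicy, measure_scene, segment_nuclei

logger = logging.getLogger("ctc_origin")


@dataclass
class PipelineConfig:
    """Configuration of one full run.

    ``scene`` is a :class:`SceneConfig` for simulated input or a path to a
    scene directory (``scene.tif`` + ``channels.json``) for real images.
    ``two_draw`` holds field overrides applied to the first scene config to
    produce the second draw's scene.
    """

    scene: SceneConfig | str | Path
    sex: str = "female"
    threshold: ThresholdPolicy = field(default_factory=lambda: ThresholdPolicy.kfold(1.0))
    ctc_rule: str = "epithelial"
    classify_cells: str = "marker_positive"
    table: FrequencyTable | str | Path | None = None
    prior: Mapping[str, float] | str = "uniform"
    call_margin: float = DEFAULT_CALL_MARGIN
    min_area: float = 30.0
    max_area: float = 8000.0
    split_watershed: bool = False
    two_draw: Mapping | None = None
    output_dir: str | Path = "ctc_origin_run"
    seed: int | None = None
    log_level: str = "INFO"

    def resolved_table(self) -> FrequencyTable:
        if self.table is None:
            return default_frequency_table()
        if isinstance(self.table, FrequencyTable):
            return self.table
        return load_frequency_table(self.table)

    def validate(self) -> None:
        if self.sex not in ("female", "male"):
            raise ConfigurationError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if self.classify_cells not in ("ctc", "marker_positive", "all"):
            raise ConfigurationError(
                "classify_cells must be 'ctc', 'marker_positive' or 'all', "
                f"got {self.classify_cells!r}"
            )
        if isinstance(self.scene, SceneConfig):
            if self.scene.sex != self.sex:
                raise ConfigurationError(
                    f"scene sex {self.scene.sex!r} conflicts with pipeline sex {self.sex!r}"
                )
        else:
            scene_dir = Path(self.scene)
            if not (scene_dir / "channels.json").exists():
                raise ConfigurationError(
                    f"scene directory {scene_dir} has no channels.json sidecar"
                )
            sidecar = json.loads((scene_dir / "channels.json").read_text())
            panel = [c for c in sidecar["channels"] if c != NUCLEAR_CHANNEL]
            expected = list(panel_for_sex(self.sex))
            if sorted(panel) != sorted(expected):
                raise ConfigurationError(
                    f"scene channels {panel} do not match the {self.sex} panel {expected}"
                )
        table = self.resolved_table()
        for m in panel_for_sex(self.sex):
            if m not in table.markers:
                raise ConfigurationError(
                    f"frequency table lacks panel marker {m!r} required for sex {self.sex!r}"
                )
        if self.two_draw is not None and not isinstance(self.scene, SceneConfig):
            raise ConfigurationError("two-draw mode requires a simulated scene config")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: Mapping) -> "PipelineConfig":
        doc = dict(doc)
        scene = doc.pop("scene", None)
        if scene is None:
            raise ConfigurationError("pipeline config requires a 'scene' entry")
        if isinstance(scene, Mapping):
            scene = SceneConfig.from_dict(scene)
        thr = doc.pop("threshold", None)
        if isinstance(thr, Mapping):
            thr = ThresholdPolicy(**thr)
        elif thr is None:
            thr = ThresholdPolicy.kfold(1.0)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigurationError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(scene=scene, threshold=thr, **doc)

    def echo(self) -> dict:
        """JSON-serialisable copy of the configuration, for the run report."""
        d: dict = {
            "sex": self.sex,
            "threshold": self.threshold.to_dict(),
            "ctc_rule": self.ctc_rule,
            "classify_cells": self.classify_cells,
            "prior": self.prior if isinstance(self.prior, str) else dict(self.prior),
            "call_margin": self.call_margin,
            "min_area": self.min_area,
            "max_area": self.max_area,
            "split_watershed": self.split_watershed,
            "two_draw": None if self.two_draw is None else dict(self.two_draw),
            "output_dir": str(self.output_dir),
            "seed": self.seed,
        }
        if isinstance(self.scene, SceneConfig):
            d["scene"] = self.scene.to_dict()
        else:
            d["scene"] = str(self.scene)
        d["table"] = (
            self.resolved_table().to_dict()
            if self.table is None or isinstance(self.table, FrequencyTable)
            else str(self.table)
        )
        return d


@dataclass
class RunReport:
    """Machine-readable record of one pipeline run."""

    config: dict
    summaries: list[dict]
    posterior: OriginPosterior
    panel: list[str]
    warnings: list[str]
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "summaries": self.summaries,
            "posterior": self.posterior.to_dict(),
            "panel": self.panel,
            "warnings": self.warnings,
            "provenance": self.provenance,
        }


def _run_draw(
    config: PipelineConfig,
    scene_config: SceneConfig | str | Path,
    table: FrequencyTable,
    out_dir: Path,
    draw_name: str,
) -> tuple[PopulationSummary, list[CellPhenotype]]:
    """Run one draw (one scene) through quantification and phenotyping."""
    draw_dir = out_dir / draw_name
    draw_dir.mkdir(parents=True, exist_ok=True)
    if isinstance(scene_config, SceneConfig):
        logger.info("[stage:simulate] %s: generating scene (seed=%s)", draw_name, scene_config.seed)
        images, truth = generate_scene(scene_config, table)
        write_scene(images, truth, draw_dir)
        channels = list(scene_config.channels)
    else:
        logger.info("[stage:load] %s: reading scene from %s", draw_name, scene_config)
        images, sidecar = read_scene(scene_config)
        channels = list(sidecar["channels"])
    logger.info("[stage:segment] %s: segmenting nuclei", draw_name)
    rois = segment_nuclei(
        images[NUCLEAR_CHANNEL],
        min_area=config.min_area,
        max_area=config.max_area,
        split_watershed=config.split_watershed,
    )
    logger.info("[stage:quantify] %s: %d ROIs, %d channels", draw_name, len(rois), len(channels))
    measurements = measure_scene(images, rois, config.threshold, channels=channels)
    measurements.to_csv(draw_dir / "measurements.csv", index=False)
    panel = [c for c in channels if c != NUCLEAR_CHANNEL]
    logger.info("[stage:phenotype] %s: assembling phenotypes", draw_name)
    phenotypes = assemble_phenotypes(measurements, panel, ctc_rule=config.ctc_rule)
    phenotypes_to_frame(phenotypes).to_csv(draw_dir / "phenotypes.csv", index=False)
    summary = summarize(phenotypes)
    (draw_dir / "summary.json").write_text(json.dumps(summary.to_dict(), indent=2))
    return summary, phenotypes


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full workflow and write all artifacts.

    Stage order: simulate (or load), segment, quantify, phenotype,
    classify.  Raises with the failing stage named; whatever was written
    before the failure is left in the output directory.
    """
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, str(config.log_level).upper(), logging.INFO),
        format="%(name)s %(levelname)s %(message)s",
    )
    config.validate()
    table = config.resolved_table()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    scene_a = config.scene
    if isinstance(scene_a, SceneConfig) and config.seed is not None:
        scene_a = dataclasses.replace(scene_a, seed=config.seed)
    draws: list[tuple[str, SceneConfig | str | Path]] = [("draw_a", scene_a)]
    if config.two_draw is not None:
        overrides = dict(config.two_draw)
        overrides.setdefault("seed", (scene_a.seed + 1) % 2**31)
        scene_b = dataclasses.replace(scene_a, **overrides)
        draws.append(("draw_b", scene_b))

    warnings: list[str] = []
    summaries: list[dict] = []
    all_phenotypes: list[CellPhenotype] = []
    panel = list(panel_for_sex(config.sex))
    stage = "setup"
    t0 = time.time()
    try:
        for draw_name, scene_cfg in draws:
            stage = draw_name
            summary, phenotypes = _run_draw(config, scene_cfg, table, out_dir, draw_name)
            summaries.append({"draw": draw_name, **summary.to_dict()})
            all_phenotypes.extend(phenotypes)
            if summary.n_objects and summary.n_ctc < 0.5 * summary.n_nuclear_positive:
                warnings.append(
                    f"{draw_name}: only {summary.n_ctc} of {summary.n_nuclear_positive} "
                    "nuclear-positive objects met the CTC rule"
                )
        stage = "classify"
        # Enumeration uses the (epithelial) CTC rule; the likelihood, by
        # default, votes every nucleated cell bearing at least one panel
        # marker, so marker profiles atypical for their tissue (e.g. the
        # mostly cytokeratin-negative prostate phenotype) are not silently
        # selected out of the evidence.  All-negative objects are
        # leukocyte-like and never vote under "marker_positive".
        if config.classify_cells == "marker_positive":
            voters = [
                ph for ph in all_phenotypes
                if ph.nuclear_positive and any(ph.marker_calls.values())
            ]
            use_ctc_only = False
        elif config.classify_cells == "all":
            voters, use_ctc_only = all_phenotypes, False
        else:
            voters, use_ctc_only = all_phenotypes, True
        logger.info("[stage:classify] pooling %d of %d cells", len(voters), len(all_phenotypes))
        posterior = population_posterior(
            voters,
            table,
            prior=config.prior,
            use_ctc_only=use_ctc_only,
            call_margin=config.call_margin,
            sex=config.sex,
        )
    except CTCOriginError as exc:
        raise type(exc)(f"pipeline stage {stage!r} failed: {exc}") from exc
    if posterior.tie:
        warnings.append("posterior tie at the top; call broken by tissue order")
    if posterior.reason:
        warnings.append(posterior.reason)
    report = RunReport(
        config=config.echo(),
        summaries=summaries,
        posterior=posterior,
        panel=panel,
        warnings=warnings,
        provenance={
            "package": "ctc-origin",
            "version": __version__,
            "seed": config.seed,
            "elapsed_seconds": round(time.time() - t0, 3),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        },
    )
    (out_dir / "classification.json").write_text(json.dumps(posterior.to_dict(), indent=2))
    (out_dir / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
    (out_dir / "report.txt").write_text(render_report(report))
    return report


def render_report(report: RunReport) -> str:
    """Deterministic human-readable summary of a run."""
    lines = []
    lines.append("CTC origin report")
    lines.append(f"panel: {', '.join(report.panel)}")
    total_ctc = sum(s["n_ctc"] for s in report.summaries)
    for s in report.summaries:
        lines.append(
            f"{s['draw']}: {s['n_objects']} objects, "
            f"{s['n_nuclear_positive']} nuclear-positive, {s['n_ctc']} CTCs"
        )
        for m, pct in s.get("marker_percent_positive", {}).items():
            k = s["marker_positive_counts"][m]
            lines.append(f"  {m}: {k}/{s['n_ctc']} CTCs positive ({pct}%)")
        for pattern, count in s.get("pattern_counts", {}).items():
            lines.append(f"  pattern {pattern}: {count}")
        for pattern, count in s.get("non_ctc_pattern_counts", {}).items():
            lines.append(f"  non-CTC pattern {pattern}: {count}")
    post = report.posterior
    lines.append(f"{total_ctc} CTCs; call: {post.call}")
    top2 = post.top(2)
    if top2:
        lines.append(
            "top posteriors: "
            + ", ".join(f"{t}={p:.4f}" for t, p in top2)
            + f" (margin {post.margin:.4f})"
        )
    for w in report.warnings:
        lines.append(f"warning: {w}")
    return "\n".join(lines) + "\n"
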