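"""Pipeline orchestration and reporting.

``run_pipeline`` chains generate -> analyze for a named preset and
writes every table/summary with provenance stamps (config hash, seed,
software version, thresholds).  ``make_report`` aggregates analysis
summaries and draws the box-and-whisker panels used in this field
(boxes 25th-75th percentile, whiskers 5th-95th, line at median).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as jio
from .geometry import RegionSpec
from .gaps import (DEFAULT_THRESHOLD_FRACTION, associate_aj_tj, detect_gaps,
                   gap_table, merge_overlapping_gaps, region_gap_count,
                   stratify_gap_frequency)
from .graph import cell_area_stats, extract_graph, junction_census
from .intensity import estimate_background, planar_polarity, tcj_ratio
from .synth import generate_field, preset, write_truth

log = logging.getLogger("junctionscope")


@dataclass
class RunConfig:
    """Configuration for one analysis run."""

    labels_path: str | None = None
    channel_paths: dict[str, str] = field(default_factory=dict)
    preset_name: str | None = None       # generate instead of reading files
    pixel_size_um: float | None = None
    ml_axis: str = "x"
    region_origin_um: tuple[float, float] = (5.0, 5.0)
    region_size_um: tuple[float, float] = (50.0, 50.0)
    gap_threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION
    tcj_disk_radius_um: float = 0.5
    vertex_exclusion_um: float = 1.0
    stats: tuple[str, ...] = ("census", "areas", "polarity", "tcj", "gaps")
    seed: int = 0
    out_dir: str = "junctionscope_out"

    def to_dict(self):
        return dataclasses.asdict(self)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested static-analysis stages in dependency order.

    Returns the summary document (also written to ``out_dir``); partial
    outputs are kept if a later stage fails.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    region = RegionSpec(config.region_origin_um, config.region_size_um)
    summary: dict = {"stats": {}, "thresholds": {
        "gap_threshold_fraction": config.gap_threshold_fraction,
        "tcj_disk_radius_um": config.tcj_disk_radius_um,
        "vertex_exclusion_um": config.vertex_exclusion_um,
    }}

    if config.preset_name:
        gen = preset(config.preset_name, seed=config.seed)
        fieldset = generate_field(gen, seed=config.seed, channels=("aj", "tj"))
        labels = fieldset.mesh.label_image
        px = fieldset.mesh.pixel_size_um
        channels = fieldset.channels
        graph = fieldset.graph
        jio.write_image(out / "labels.tif", labels, px, as_labels=True)
        for name, img in channels.items():
            jio.write_image(out / f"{name}.tif", img, px)
        write_truth(fieldset.truth, out / "truth.csv")
        gen.to_json(out / "generator_config.json")
    else:
        if config.labels_path is None:
            raise ValueError("either preset_name or labels_path is required")
        labels, px = jio.read_image_stack(config.labels_path,
                                          config.pixel_size_um,
                                          expect_labels=True)
        channels = {}
        for name, p in config.channel_paths.items():
            channels[name], _ = jio.read_image_stack(p, px)
        graph = extract_graph(labels, px, ml_axis=config.ml_axis)

    jio.graph_to_json(graph, out / "graph.json")
    jio.edge_table_csv(graph, out / "edges.csv")

    aj = channels.get("aj")
    background = None
    if aj is not None:
        background = estimate_background(aj, graph, seed=config.seed)
        summary["background"] = dataclasses.asdict(background)

    for stat in config.stats:
        try:
            if stat == "census":
                summary["stats"]["census"] = junction_census(graph, region)
            elif stat == "areas":
                res = cell_area_stats(graph, region)
                summary["stats"]["areas"] = {
                    "mean_um2": res["mean_um2"], "n_cells": res["n_cells"]}
            elif stat == "polarity":
                _require_channel(aj, stat)
                pol = planar_polarity(aj, graph, region, background.value,
                                      vertex_exclusion_um=config.vertex_exclusion_um)
                summary["stats"]["polarity"] = dataclasses.asdict(pol)
            elif stat == "tcj":
                _require_channel(aj, stat)
                ratios = []
                v3 = graph.vertices[graph.vertices["order"] == 3]
                for vid in v3["id"]:
                    try:
                        ratios.append(tcj_ratio(
                            aj, graph, int(vid), background.value,
                            disk_radius_um=config.tcj_disk_radius_um,
                            vertex_exclusion_um=config.vertex_exclusion_um).ratio)
                    except ValueError:
                        continue
                summary["stats"]["tcj"] = {
                    "mean_ratio": float(np.mean(ratios)) if ratios else None,
                    "n_vertices": len(ratios)}
            elif stat == "gaps":
                _require_channel(aj, stat)
                aj_gaps = merge_overlapping_gaps(detect_gaps(
                    aj, graph, background.value,
                    threshold_fraction=config.gap_threshold_fraction))
                doc = {
                    "n_gaps_region": region_gap_count(aj_gaps, region),
                    "stratified": {
                        k: v for k, v in stratify_gap_frequency(
                            aj_gaps, graph, region).items() if k != "census"},
                }
                gap_table(aj_gaps, region_id="r0").to_csv(
                    out / "gaps_aj.csv", index=False)
                if "tj" in channels:
                    tj_gaps = merge_overlapping_gaps(detect_gaps(
                        channels["tj"], graph, background.value,
                        threshold_fraction=config.gap_threshold_fraction,
                        channel="TJ"))
                    _, assoc = associate_aj_tj(aj_gaps, tj_gaps)
                    doc["aj_tj_association"] = assoc
                    gap_table(tj_gaps, region_id="r0").to_csv(
                        out / "gaps_tj.csv", index=False)
                summary["stats"]["gaps"] = doc
            else:
                raise ValueError(f"unknown stat {stat!r}")
        except Exception:
            jio.write_json(jio.stamp(summary, config.to_dict(), config.seed),
                           out / "summary.json")
            log.exception("stage %r failed; partial outputs kept", stat)
            raise

    doc = jio.stamp(summary, config.to_dict(), config.seed)
    jio.write_json(doc, out / "summary.json")
    return doc


def _require_channel(img, stat):
    if img is None:
        raise ValueError(f"stat {stat!r} needs an 'aj' intensity channel")


def box_whisker_stats(values) -> dict:
    """The panel convention: median, 25-75 box, 5-95 whiskers, mean."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if not len(v):
        return {k: np.nan for k in
                ("median", "q25", "q75", "w5", "w95", "mean", "n")}
    return {
        "median": float(np.median(v)),
        "q25": float(np.percentile(v, 25)),
        "q75": float(np.percentile(v, 75)),
        "w5": float(np.percentile(v, 5)),
        "w95": float(np.percentile(v, 95)),
        "mean": float(np.mean(v)),
        "n": int(len(v)),
    }


def make_report(summaries: list[dict], out_dir, plot: bool = True) -> dict:
    """Aggregate per-region/per-run summaries into one report with the
    standard box/whisker panels."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"n_runs": len(summaries), "panels": {}}
    series: dict[str, list[float]] = {}
    for s in summaries:
        stats = s.get("stats", {})
        if "polarity" in stats:
            series.setdefault("polarity_ratio", []).append(
                stats["polarity"]["ratio"])
        if "tcj" in stats and stats["tcj"].get("mean_ratio") is not None:
            series.setdefault("tcj_ratio", []).append(stats["tcj"]["mean_ratio"])
        if "gaps" in stats:
            series.setdefault("gaps_per_region", []).append(
                stats["gaps"]["n_gaps_region"])
        if "areas" in stats:
            series.setdefault("cell_area_um2", []).append(
                stats["areas"]["mean_um2"])
    for name, vals in series.items():
        report["panels"][name] = box_whisker_stats(vals)
    if plot and series:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, axes = plt.subplots(1, len(series),
                                 figsize=(2.2 * len(series), 3.2))
        axes = np.atleast_1d(axes)
        for ax, (name, vals) in zip(axes, series.items()):
            ax.boxplot([vals], whis=(5, 95), showmeans=True)
            ax.set_title(name, fontsize=8)
            ax.set_xticks([])
        fig.tight_layout()
        fig.savefig(out / "report.png", dpi=120)
        plt.close(fig)
    jio.write_json(report, out / "report.json")
    return report
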