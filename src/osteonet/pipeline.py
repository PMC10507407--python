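"""End-to-end orchestration: network analysis and colony morphometry runs.

Both pipelines read a flat config (YAML file or dict), run their stages in a
fixed order, and write machine-readable reports plus a run log.  Reports
embed the resolved configuration and its hash, the package version, and the
seed, and contain no timestamps — rerunning the same config on the same
inputs is bit-identical.  A failure in any stage removes partial outputs and
re-raises tagged with the stage name.

Network run:   read edges -> confidence filter -> connected-core reduction
               -> topology -> role classification.
Morphometry:   segment -> measure -> summarize per condition -> CFE ->
               ANOVA + SNK (+ chi-squared on proportion counts).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .backbone import classify_roles
from .morphometry import (
    ColonyImage,
    colony_forming_efficiency,
    measure_colony,
    segment_colonies,
)
from .network_io import (
    assign_origins,
    filter_by_confidence,
    read_roster,
    read_string_tsv,
    reduce_to_connected_core,
)
from .stats import GroupData, chi_squared_proportions, one_way_anova, snk_test
from .topology import compute_topology

__all__ = [
    "RunConfig",
    "PipelineError",
    "load_config",
    "run_network_pipeline",
    "run_morphometry_pipeline",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Flat run configuration; defaults follow the study settings
    (confidence 0.9, top-decile fraction 0.10, alpha 0.05)."""

    mode: str = "network"
    out_dir: str = "."
    seed: int = 0
    # network mode
    edges: Optional[str] = None
    seeds: Optional[str] = None
    partners: Optional[str] = None
    min_score: float = 0.9
    decile_fraction: float = 0.10
    max_partners: int = 10
    # morphometry mode
    image_groups: dict = field(default_factory=dict)  # condition -> [paths]
    counts: Optional[str] = None  # CSV: condition, n_colonies, n_seeded, ...
    intensity_threshold: float = 0.5
    min_area: int = 50
    pixel_size: Optional[float] = None
    alpha: float = 0.05

    def validate(self) -> None:
        if self.mode not in ("network", "morphometry"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "network":
            for name in ("edges", "seeds"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"config.{name}: missing file {p}")
        else:
            for cond, paths in self.image_groups.items():
                for p in paths:
                    if not Path(p).exists():
                        raise FileNotFoundError(f"image {p} ({cond}) missing")
            if self.counts is not None and not Path(self.counts).exists():
                raise FileNotFoundError(f"counts table {self.counts} missing")


def load_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig(**data)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


class _Run:
    """Tracks outputs of one run so failures can clean up after themselves."""

    def __init__(self, config: RunConfig):
        config.validate()
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.created: list[Path] = []
        self.log_lines: list[str] = [
            f"osteonet {__version__}",
            f"config_hash {_config_hash(config)}",
            f"seed {config.seed}",
        ]
        self.stage_name = "init"

    def stage(self, name: str) -> None:
        self.stage_name = name
        self.log_lines.append(f"stage {name}")

    def log(self, msg: str) -> None:
        self.log_lines.append(msg)

    def path(self, name: str) -> Path:
        p = self.out / name
        self.created.append(p)
        return p

    def fail(self, exc: Exception) -> None:
        for p in self.created:
            p.unlink(missing_ok=True)
        raise PipelineError(f"stage {self.stage_name!r}: {exc}") from exc

    def finish(self) -> Path:
        log_path = self.path("run.log")
        log_path.write_text("\n".join(self.log_lines) + "\n")
        return log_path


def _report_header(run: _Run) -> dict:
    return {
        "package_version": __version__,
        "seed": run.config.seed,
        "config_hash": _config_hash(run.config),
        "config": asdict(run.config),
    }


def run_network_pipeline(config: RunConfig) -> dict[str, Path]:
    """Edge list + rosters -> per-node CSV, global JSON summary, run log."""
    run = _Run(config)
    try:
        run.stage("read")
        net = read_string_tsv(config.edges)
        seeds = read_roster(config.seeds)
        partners = read_roster(config.partners) if config.partners else []
        assign_origins(net, seeds, partners)
        run.log(f"read {net.n_nodes} nodes, {net.n_edges} edges, {len(seeds)} seeds")

        run.stage("filter")
        net = filter_by_confidence(net, config.min_score)
        run.log(f"{net.n_edges} edges at score >= {config.min_score}")

        run.stage("reduce")
        net = reduce_to_connected_core(net, seeds, config.max_partners)
        run.log(f"core: {net.n_nodes} nodes, {net.n_edges} edges")

        run.stage("topology")
        topo = compute_topology(net)

        run.stage("roles")
        roles = classify_roles(topo, config.decile_fraction)
        role_map = {r.identifier: r for r in roles}

        run.stage("report")
        frame = topo.as_frame()
        frame["origin"] = [net.node(v).origin for v in frame["identifier"]]
        for flag in ("is_hub", "is_bottleneck", "is_backbone", "is_upstream_signal"):
            frame[flag] = [getattr(role_map[v], flag) for v in frame["identifier"]]
        nodes_csv = run.path("nodes.csv")
        frame.to_csv(nodes_csv, index=False)

        summary = {
            **_report_header(run),
            **topo.global_summary(),
            "hubs": sorted(v for v, r in role_map.items() if r.is_hub),
            "bottlenecks": sorted(v for v, r in role_map.items() if r.is_bottleneck),
            "backbone": sorted(v for v, r in role_map.items() if r.is_backbone),
            "upstream_signals": sorted(
                v for v, r in role_map.items() if r.is_upstream_signal
            ),
            "isolated_nodes": net.isolated_nodes(),
        }
        summary_json = run.path("network_summary.json")
        summary_json.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
        log = run.finish()
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - deliberate stage tagging
        run.fail(exc)
    return {"nodes_csv": nodes_csv, "summary_json": summary_json, "log": log}


def _load_image(path: str | Path, field_id: str, pixel_size: Optional[float]) -> ColonyImage:
    arr = np.asarray(iio.imread(path), dtype=float)
    if arr.ndim == 3:  # collapse RGB(A) to grayscale
        arr = arr[..., :3].mean(axis=-1)
    if arr.max() > 1.0:
        arr = arr / 255.0
    return ColonyImage(pixels=np.clip(arr, 0.0, 1.0), pixel_size=pixel_size, field_id=field_id)


def run_morphometry_pipeline(config: RunConfig) -> dict[str, Path]:
    """Culture images + count tables -> per-colony CSV, summary JSON, log."""
    run = _Run(config)
    try:
        run.stage("segment")
        records = []
        for cond in sorted(config.image_groups):
            for path in config.image_groups[cond]:
                image = _load_image(path, Path(path).stem, config.pixel_size)
                masks = segment_colonies(
                    image, config.intensity_threshold, config.min_area
                )
                run.log(f"{cond}/{image.field_id}: {len(masks)} colonies")
                for i, mask in enumerate(masks):
                    rec = measure_colony(mask, config.pixel_size)
                    records.append(
                        {
                            "condition": cond,
                            "field_id": image.field_id,
                            "colony_id": i,
                            "area_px": rec.area_px,
                            "area_um2": rec.area_um2,
                            "perimeter": rec.perimeter,
                            "circularity": rec.circularity,
                        }
                    )
        colonies = pd.DataFrame(
            records,
            columns=[
                "condition", "field_id", "colony_id",
                "area_px", "area_um2", "perimeter", "circularity",
            ],
        )

        run.stage("measure")
        colonies_csv = run.path("colonies.csv")
        colonies.to_csv(colonies_csv, index=False)

        run.stage("summarize")
        conditions = {}
        for cond, sub in colonies.groupby("condition"):
            conditions[cond] = {
                "n_colonies": int(len(sub)),
                "mean_area_px": float(sub["area_px"].mean()),
                "mean_circularity": float(sub["circularity"].mean()),
            }

        run.stage("cfe")
        if config.counts:
            table = pd.read_csv(config.counts)
            for _, row in table.iterrows():
                cond = str(row["condition"])
                entry = conditions.setdefault(cond, {})
                if {"n_colonies", "n_seeded"} <= set(table.columns):
                    entry["cfe"] = colony_forming_efficiency(
                        int(row["n_colonies"]), int(row["n_seeded"])
                    )
            if {"n_positive", "n_total"} <= set(table.columns) and len(table) == 2:
                t = [
                    [int(r["n_positive"]), int(r["n_total"]) - int(r["n_positive"])]
                    for _, r in table.iterrows()
                ]
                chi2 = chi_squared_proportions(t)
                conditions["_chi_squared"] = {
                    "chi2": chi2.chi2, "df": chi2.df, "p": chi2.p,
                }

        run.stage("tests")
        tests: dict = {}
        groups_by_metric = {
            metric: [
                sub[metric].to_numpy()
                for _, sub in colonies.groupby("condition")
                if len(sub) >= 2
            ]
            for metric in ("area_px", "circularity")
        }
        labels = [c for c, sub in colonies.groupby("condition") if len(sub) >= 2]
        for metric, groups in groups_by_metric.items():
            if len(groups) >= 2:
                res = one_way_anova(groups)
                gd = [GroupData(labels[i], groups[i]) for i in range(len(groups))]
                pairs = snk_test(gd, config.alpha)
                tests[metric] = {
                    "anova_F": res.F,
                    "df": [res.df_between, res.df_within],
                    "p": res.p,
                    "snk_significant_pairs": sorted(map(list, pairs)),
                }

        run.stage("report")
        summary = {
            **_report_header(run),
            "conditions": conditions,
            "tests": tests,
            "n_colonies_total": int(len(colonies)),
        }
        summary_json = run.path("morphometry_summary.json")
        summary_json.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
        log = run.finish()
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        run.fail(exc)
    return {"colonies_csv": colonies_csv, "summary_json": summary_json, "log": log}
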