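"""Run configuration, run reports, and the stage dispatcher.

The CLI is a thin wrapper over :func:`run_pipeline`, which dispatches one
named stage (simulate | segment | maturity | zones | frap | penetration |
cytometry | stall), writes its CSV/JSON outputs into the configured output
directory, and returns a :class:`RunReport` — tool version, the effective
configuration, input digests, per-stage record counts, structured warnings
and an output manifest. All randomness flows through the single configured
seed. Outputs are deterministic: rerunning an identical configuration on
identical inputs reproduces the CSVs byte for byte (the report timestamp
aside).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import cytometry as cyt
from . import scenes
from .errors import ChannelRoleError, InclusionToolsError
from .frap import assign_frap_rois, extract_trace, mobility_summary, relative_recovery
from .image import (MultiChannelImage, read_frame_series, read_tiff, write_tiff,
                    write_frame_series)
from .maturity import classify_population
from .penetration import measure_penetration
from .roi import auto_threshold, largest_component, mean_intensity
from .table_schemas import validate
from .zones import partition_zones, zone_profile

log = logging.getLogger("inclusiontools")

STAGES = ("simulate", "segment", "maturity", "zones", "frap", "penetration",
          "cytometry", "stall")

#: default channel roles: role name -> channel name in the TIFF
DEFAULT_ROLES = {"cerulean": "cerulean", "flash": "flash", "tmr": "tmr",
                 "antibody": "antibody", "fusion": "mcherry", "hoechst": "hoechst"}


@dataclass
class RunConfig:
    """Effective configuration of one pipeline run.

    Defaults are the analysis constants of the assays: 110% boundary scaling,
    25 px background circle, 20 expression bins by 4 modifier categories.
    """

    stage_inputs: dict = field(default_factory=dict)  # stage-specific paths
    channel_roles: dict = field(default_factory=lambda: dict(DEFAULT_ROLES))
    threshold_method: str = "otsu"
    zone_fractions: tuple = (0.5, 1.0)
    scale_factor: float = 1.10
    background_radius: float = 25.0
    background_center: tuple | None = None  # None = darkest corner
    n_cerulean_bins: int = 20
    n_tmr_levels: int = 4
    seed: int = 0
    out_dir: str = "out"
    simulate: dict = field(default_factory=dict)  # kind + parameter overrides

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InclusionToolsError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.channel_roles = {**DEFAULT_ROLES, **(cfg.channel_roles or {})}
        cfg.zone_fractions = tuple(cfg.zone_fractions)
        if cfg.background_center is not None:
            cfg.background_center = tuple(cfg.background_center)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["zone_fractions"] = list(self.zone_fractions)
        return d


@dataclass
class RunReport:
    version: str
    stage: str
    config: dict
    input_digests: dict = field(default_factory=dict)
    record_counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    outputs: list = field(default_factory=list)
    timestamp: float = field(default_factory=time.time)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         default=str))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _resolve_channel(image: MultiChannelImage, roles: dict, role: str) -> np.ndarray:
    name = roles.get(role, role)
    if name not in image:
        raise ChannelRoleError(
            f"channel role {role!r} -> {name!r} not present "
            f"(channels: {image.channel_names})"
        )
    return image[name]


def _write_csv(df: pd.DataFrame, path: Path, schema: str, report: RunReport) -> None:
    validate(df, schema)
    df.to_csv(path, index=False)
    report.outputs.append(str(path))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_simulate(cfg: RunConfig, out: Path, report: RunReport) -> None:
    sim = dict(cfg.simulate)
    kind = sim.pop("kind", "scene")
    sim.setdefault("seed", cfg.seed)
    if kind == "scene":
        ratio = sim.pop("ratio_target", 0.3)
        spec = scenes.maturity_scene_spec(ratio, seed=sim.pop("seed"), **sim)
        image, truth = scenes.render_scene(spec)
        write_tiff(image, out / "scene.tif")
        truth.to_json(out / "scene_truth.json")
        report.outputs += [str(out / "scene.tif"), str(out / "scene_truth.json")]
        report.record_counts["channels"] = len(image.channels)
        report.record_counts["inclusion_px"] = truth.inclusion_roi.area
    elif kind == "frap":
        frap_spec = scenes.FrapSpec(**sim)
        series = scenes.simulate_frap(frap_spec)
        for channel in series.frames[0].channel_names:
            path = out / f"frap_{channel}.tif"
            write_frame_series(series.frames, channel, path,
                               times=list(series.times))
            report.outputs.append(str(path))
        series.truth.to_json(out / "frap_truth.json")
        report.outputs.append(str(out / "frap_truth.json"))
        report.record_counts["frames"] = len(series.frames)
    elif kind in ("population", "stall"):
        if kind == "stall":
            constructs = sim.pop("constructs",
                                 {"control": 0.0, "25Q": 0.0, "97Q": 0.0,
                                  "20K": 0.9})
            frames = [scenes.stall_population(name, eff, seed=sim["seed"] + i,
                                              **{k: v for k, v in sim.items()
                                                 if k != "seed"})
                      for i, (name, eff) in enumerate(constructs.items())]
            events = pd.concat(frames, ignore_index=True)
            events["event_id"] = np.arange(len(events))
        else:
            events = scenes.simulate_population(scenes.PopulationSpec(**sim))
        path = out / "events.csv"
        _write_csv(events, path, "events", report)
        report.record_counts["events"] = len(events)
    else:
        raise InclusionToolsError(f"unknown simulate kind {kind!r}")


def _stage_segment(cfg: RunConfig, out: Path, report: RunReport) -> None:
    image = read_tiff(cfg.stage_inputs["image"])
    channel = _resolve_channel(image, cfg.channel_roles, "cerulean")
    roi = largest_component(auto_threshold(channel, cfg.threshold_method))
    roi.to_json(out / "inclusion_roi.json")
    report.outputs.append(str(out / "inclusion_roi.json"))
    report.record_counts["inclusion_px"] = roi.area


def _stage_maturity(cfg: RunConfig, out: Path, report: RunReport) -> None:
    if "table" in cfg.stage_inputs:
        table = pd.read_csv(cfg.stage_inputs["table"])
    else:
        # measure means from one or more scene TIFFs
        rows = []
        for i, path in enumerate(sorted(map(str, cfg.stage_inputs["images"]))):
            image = read_tiff(path)
            cer = _resolve_channel(image, cfg.channel_roles, "cerulean")
            fla = _resolve_channel(image, cfg.channel_roles, "flash")
            roi = largest_component(auto_threshold(cer, cfg.threshold_method))
            rows.append({"inclusion_id": Path(path).stem,
                         "flash_mean": mean_intensity(fla, roi),
                         "cerulean_mean": mean_intensity(cer, roi)})
        table = pd.DataFrame(rows)
    result = classify_population(table)
    _write_csv(result, out / "maturity.csv", "maturity", report)
    counts = result["label"].value_counts().to_dict()
    report.record_counts.update({f"label_{k}": int(v) for k, v in counts.items()})
    if counts.get("INTERMEDIATE"):
        report.warnings.append({
            "code": "intermediate_band",
            "n": int(counts["INTERMEDIATE"]),
            "message": "inclusions inside the +/-SEM band were labelled "
                       "INTERMEDIATE (excluded from HBR/PBR contrasts)",
        })


def _stage_zones(cfg: RunConfig, out: Path, report: RunReport) -> None:
    image = read_tiff(cfg.stage_inputs["image"])
    cer = _resolve_channel(image, cfg.channel_roles, "cerulean")
    inclusion = largest_component(auto_threshold(cer, cfg.threshold_method))
    part = partition_zones(inclusion, cfg.zone_fractions, cfg.scale_factor)
    rows = []
    for channel_name in image.channel_names:
        prof = zone_profile(image[channel_name], part, channel_name)
        for zone, val in prof.as_dict().items():
            rows.append({"inclusion_id": Path(str(cfg.stage_inputs["image"])).stem,
                         "channel": channel_name, "zone": zone,
                         "mean_intensity": val, "ratio": np.nan, "label": ""})
    _write_csv(pd.DataFrame(rows), out / "zones.csv", "zones", report)
    report.record_counts["zones_rows"] = len(rows)


def _stage_frap(cfg: RunConfig, out: Path, report: RunReport) -> None:
    fusion_stack, meta = read_frame_series(cfg.stage_inputs["fusion_series"])
    flash_stack, _ = read_frame_series(cfg.stage_inputs["flash_series"])
    times = meta.get("times_min")
    if times is None:
        times = list(range(-1, fusion_stack.shape[0] - 1))
    # ROIs fixed from the first post-bleach frame (index 1; frame 0 is pre-bleach)
    rois = assign_frap_rois(fusion_stack[1], flash_stack[1],
                            background_center=cfg.background_center,
                            background_radius=cfg.background_radius,
                            method=cfg.threshold_method)
    trace = extract_trace(list(fusion_stack), rois, times, n_prebleach=1)
    curve = relative_recovery(trace)
    summary = mobility_summary(curve)
    df = pd.DataFrame({"inclusion_id": Path(str(cfg.stage_inputs["fusion_series"])).stem,
                       "time_min": curve.times,
                       "relative_recovery": curve.relative_recovery})
    _write_csv(df, out / "frap_recovery.csv", "frap", report)
    (out / "frap_summary.json").write_text(json.dumps(summary, indent=2))
    report.outputs.append(str(out / "frap_summary.json"))
    from .plots import plot_recovery

    plot_recovery(curve, out / "frap_recovery.png")
    report.outputs.append(str(out / "frap_recovery.png"))
    report.record_counts["frames"] = len(curve.times)
    if not summary["fit_ok"]:
        report.warnings.append({"code": "frap_fit_failed",
                                "message": "exponential fit failed; delta only"})


def _stage_penetration(cfg: RunConfig, out: Path, report: RunReport) -> None:
    image = read_tiff(cfg.stage_inputs["image"])
    cer = _resolve_channel(image, cfg.channel_roles, "cerulean")
    ab = _resolve_channel(image, cfg.channel_roles, "antibody")
    m = measure_penetration(cer, ab, cfg.scale_factor, cfg.threshold_method,
                            inclusion_id=Path(str(cfg.stage_inputs["image"])).stem)
    df = pd.DataFrame([{"inclusion_id": m.inclusion_id, "ratio": np.nan,
                        "external_mean_distance": m.external_mean_distance,
                        "internal_mean_distance": m.internal_mean_distance,
                        "penetration_px": m.penetration}])
    _write_csv(df, out / "penetration.csv", "penetration", report)
    report.record_counts["inclusions"] = 1


def _stage_cytometry(cfg: RunConfig, out: Path, report: RunReport) -> None:
    events = pd.read_csv(cfg.stage_inputs["events"])
    validate(events, "events")
    negative = pd.read_csv(cfg.stage_inputs["negative"])
    positive = pd.read_csv(cfg.stage_inputs["positive"])
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        flags = cyt.pulsa_gate(events,
                               {"negative": negative, "positive": positive})
        for w in caught:
            report.warnings.append({"code": "separability",
                                    "message": str(w.message)})
    edges = cyt.make_bins(events, cfg.n_cerulean_bins)
    grids = cyt.inclusion_fraction(events, flags, edges)
    tidy = pd.concat([g.to_tidy() for g in grids.values()], ignore_index=True)
    _write_csv(tidy, out / "bin_grid.csv", "bingrid", report)
    from .plots import plot_bin_grid

    for construct, grid in grids.items():
        path = out / f"bin_grid_{construct}.json"
        grid.to_json(path)
        report.outputs.append(str(path))
        plot_bin_grid(grid, out / f"bin_grid_{construct}.png")
        report.outputs.append(str(out / f"bin_grid_{construct}.png"))
        empty = int((grid.counts == 0).sum())
        if empty:
            report.warnings.append({"code": "empty_bins",
                                    "construct": construct, "n": empty,
                                    "message": f"{empty} empty grid cells"})
    report.record_counts["events"] = len(events)
    report.record_counts["gated_inclusion"] = int(np.asarray(flags).sum())


def _stage_stall(cfg: RunConfig, out: Path, report: RunReport) -> None:
    events = pd.read_csv(cfg.stage_inputs["events"])
    validate(events, "events")
    summary = cyt.stall_ratios(events)
    _write_csv(summary.table, out / "stall_summary.csv", "stall", report)
    report.record_counts["constructs"] = len(summary.table)


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "segment": _stage_segment,
    "maturity": _stage_maturity,
    "zones": _stage_zones,
    "frap": _stage_frap,
    "penetration": _stage_penetration,
    "cytometry": _stage_cytometry,
    "stall": _stage_stall,
}


def run_pipeline(config: RunConfig, stage: str) -> RunReport:
    """Run one named stage and write its outputs plus a run report."""
    if stage not in STAGES:
        raise InclusionToolsError(f"unknown stage {stage!r}; choose from {STAGES}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(version=__version__, stage=stage, config=config.to_dict())
    for key, val in config.stage_inputs.items():
        paths = val if isinstance(val, (list, tuple)) else [val]
        for p in paths:
            p = Path(str(p))
            if not p.exists():
                raise FileNotFoundError(f"input {key!r}: {p} not readable")
            report.input_digests[str(p)] = _digest(p)
    log.info("running stage %s -> %s", stage, out)
    _STAGE_FNS[stage](config, out, report)
    report.to_json(out / f"report_{stage}.json")
    return report
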