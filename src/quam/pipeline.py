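"""Stage orchestration: simulate -> segment -> quantify -> classify -> wells.

Each stage reads its inputs from and writes its outputs into one artifact
directory, so any contiguous subset of stages can be run (e.g. `classify` on
a pre-measured cell table). A manifest records the package version, all
seeds, the parameters used and a checksum of every output file; reruns with
the same configuration are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as qio
from .classify import classify_responders
from .errors import ConfigurationError
from .quantify import measure_objects, normalize_to_control
from .segmentation import DetectionParams, segment_field
from .synthetic import FieldSpec, ScenarioConfig, generate_population, render_fields
from .wells import sensitivity_table

log = logging.getLogger("quam")

STAGES = ("simulate", "segment", "quantify", "classify", "wells")


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    out_dir: Path
    stages: tuple[str, ...] = STAGES
    seed: int = 0
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    field_spec: FieldSpec = field(default_factory=FieldSpec)
    detection: DetectionParams = field(default_factory=DetectionParams)
    exposure_s: float = 0.96
    conditions: tuple[str, str] = ("control", "stimulated")
    classify_channel: str = "perk"
    well_sizes: tuple[int, ...] = (250, 1000, 5000)
    n_wells: int = 2000
    cells_path: Path | None = None  # entry point for partial runs

    @classmethod
    def from_dict(cls, cfg: dict, out_dir) -> "RunConfig":
        known = {"stages", "seed", "scenario", "field_spec", "detection",
                 "exposure_s", "conditions", "classify_channel",
                 "well_sizes", "n_wells", "cells_path"}
        bad = set(cfg) - known
        if bad:
            raise ConfigurationError(f"unknown config keys: {sorted(bad)}")
        stages = tuple(cfg.get("stages", STAGES))
        unknown_stages = set(stages) - set(STAGES)
        if unknown_stages:
            raise ConfigurationError(f"unknown stages: {sorted(unknown_stages)}")
        idx = [STAGES.index(s) for s in stages]
        if idx != sorted(idx) or (idx and idx != list(range(idx[0], idx[-1] + 1))):
            raise ConfigurationError(
                f"stages must be a contiguous ordered subset of {STAGES}")
        scen = ScenarioConfig.from_dict(cfg.get("scenario", {}))
        fs = FieldSpec(**{k: tuple(v) if isinstance(v, list) else v
                          for k, v in cfg.get("field_spec", {}).items()}).validate()
        det = DetectionParams(**cfg.get("detection", {})).validate()
        return cls(out_dir=Path(out_dir), stages=stages,
                   seed=int(cfg.get("seed", 0)), scenario=scen, field_spec=fs,
                   detection=det, exposure_s=float(cfg.get("exposure_s", 0.96)),
                   conditions=tuple(cfg.get("conditions", ("control", "stimulated"))),
                   classify_channel=cfg.get("classify_channel", "perk"),
                   well_sizes=tuple(cfg.get("well_sizes", (250, 1000, 5000))),
                   n_wells=int(cfg.get("n_wells", 2000)),
                   cells_path=Path(cfg["cells_path"]) if cfg.get("cells_path") else None)


def _stage_simulate(cfg: RunConfig, outputs: list[Path]) -> None:
    pop = generate_population(cfg.scenario.with_(seed=cfg.seed))
    pop.attrs["glia_density"] = cfg.scenario.glia_density
    pop.attrs["debris_density"] = cfg.scenario.debris_density
    qio.write_cells(cfg.out_dir / "population.csv", pop)
    outputs.append(cfg.out_dir / "population.csv")
    for ci, cond in enumerate(cfg.conditions):
        cmap = {"pgp": "intensity_pgp", "ib4": "intensity_ib4",
                "perk": ("intensity_perk_stimulated" if cond != cfg.conditions[0]
                         else "intensity_perk_baseline")}
        fields = render_fields(pop, cfg.field_spec, cfg.exposure_s,
                               channel_map=cmap, seed=cfg.seed + 1000 + ci)
        for f in fields:
            p = cfg.out_dir / "images" / f"{cond}_field{f.field_id:03d}.tif"
            qio.write_field_tiff(p, f.images)
            outputs.append(p)
            tp = cfg.out_dir / "truth" / f"{cond}_field{f.field_id:03d}.csv"
            qio.write_cells(tp, f.truth)
            outputs.append(tp)


def _iter_fields(cfg: RunConfig):
    img_dir = cfg.out_dir / "images"
    if not img_dir.is_dir():
        raise ConfigurationError(
            "no images/ directory in the artifact dir; run the simulate "
            "stage first or point the pipeline at rendered fields")
    for p in sorted(img_dir.glob("*.tif")):
        cond, _, fid = p.stem.rpartition("_field")
        yield cond, int(fid), p, qio.read_field_tiff(p)


def _stage_segment(cfg: RunConfig, outputs: list[Path]) -> None:
    rows = []
    for cond, fid, path, images in _iter_fields(cfg):
        marker = images[cfg.field_spec.channels[0]]
        accepted, rejected = segment_field(marker, cfg.detection)
        for obj in accepted + rejected:
            rows.append({"condition": cond, "field_id": fid, "label": obj.label,
                         "area_um2": obj.area_um2,
                         "equivalent_diameter_um": obj.equivalent_diameter_um,
                         "aspect_ratio": obj.aspect_ratio,
                         "concavity_depth": obj.concavity_depth,
                         "contrast": obj.contrast,
                         "touches_border": obj.touches_border,
                         "in_cluster": obj.in_cluster,
                         "accepted": obj.accepted,
                         "rejection_reasons": ";".join(obj.rejection_reasons)})
    table = pd.DataFrame(rows)
    qio.write_cells(cfg.out_dir / "objects.csv", table)
    outputs.append(cfg.out_dir / "objects.csv")


def _stage_quantify(cfg: RunConfig, outputs: list[Path]) -> None:
    tables = []
    for cond, fid, path, images in _iter_fields(cfg):
        marker = images[cfg.field_spec.channels[0]]
        accepted, _ = segment_field(marker, cfg.detection)
        if not accepted:
            continue
        t = measure_objects(accepted, images, cfg.exposure_s,
                            gain=cfg.field_spec.gain, condition=cond,
                            field_id=fid)
        tables.append(t)
    if not tables:
        raise ConfigurationError("quantify produced no cells; check inputs")
    cells = pd.concat(tables, ignore_index=True)
    cells = normalize_to_control(cells, cfg.conditions[0])
    qio.write_cells(cfg.out_dir / "cells.csv", cells)
    outputs.append(cfg.out_dir / "cells.csv")


def _load_cells(cfg: RunConfig) -> pd.DataFrame:
    path = cfg.cells_path or (cfg.out_dir / "cells.csv")
    if not Path(path).is_file():
        raise ConfigurationError(
            f"no cell table at {path}; run the quantify stage first or set "
            "cells_path")
    return qio.read_cells(path)


def _stage_classify(cfg: RunConfig, outputs: list[Path]) -> None:
    cells = _load_cells(cfg)
    ctrl, test = cfg.conditions[0], cfg.conditions[1]
    res = classify_responders(cells, ctrl, test, cfg.classify_channel,
                              min_cells=2, warn_below=0)
    test_idx = cells.index[cells["condition"] == test]
    cells["responder"] = False
    cells.loc[test_idx, "responder"] = res.labels
    qio.write_cells(cfg.out_dir / "cells_classified.csv", cells)
    outputs.append(cfg.out_dir / "cells_classified.csv")
    summary = pd.DataFrame([{"cutoff": res.cutoff, "diagnostic": res.diagnostic,
                             "fraction_above_test": res.fraction_above_test,
                             "fraction_above_control": res.fraction_above_control,
                             "n_crossings": res.n_crossings}])
    qio.write_cells(cfg.out_dir / "classification.csv", summary)
    outputs.append(cfg.out_dir / "classification.csv")


def _stage_wells(cfg: RunConfig, outputs: list[Path]) -> None:
    cells = _load_cells(cfg)
    ctrl = cells[cells["condition"] == cfg.conditions[0]]
    col = f"intensity_{cfg.classify_channel}"
    sizes = [n for n in cfg.well_sizes if n <= len(ctrl)] or [max(1, len(ctrl) // 2)]
    table = sensitivity_table(ctrl[col].to_numpy(), sizes,
                              n_wells=cfg.n_wells, seed=cfg.seed + 2000)
    qio.write_cells(cfg.out_dir / "wells.csv", table)
    outputs.append(cfg.out_dir / "wells.csv")


_STAGE_FN = {"simulate": _stage_simulate, "segment": _stage_segment,
             "quantify": _stage_quantify, "classify": _stage_classify,
             "wells": _stage_wells}


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages and write a manifest; returns out_dir."""
    cfg = config
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    for stage in cfg.stages:
        log.info("stage %s", stage)
        _STAGE_FN[stage](cfg, outputs)
    qio.write_manifest(
        cfg.out_dir,
        seeds={"seed": cfg.seed, "scenario_seed": cfg.scenario.seed},
        parameters={"scenario": asdict(cfg.scenario),
                    "field_spec": asdict(cfg.field_spec),
                    "detection": asdict(cfg.detection),
                    "exposure_s": cfg.exposure_s,
                    "stages": list(cfg.stages),
                    "conditions": list(cfg.conditions),
                    "well_sizes": list(cfg.well_sizes),
                    "n_wells": cfg.n_wells},
        files=outputs)
    return cfg.out_dir
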