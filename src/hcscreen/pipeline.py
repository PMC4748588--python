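"""Pipeline driver: configuration, stage graph, manifests, CSV outputs.

Stages run in dependency order — simulate (optional) → segment →
{gate, cellcycle, damage, growth} → stats — each reading/writing the CSV
interfaces of the analysis modules, so any stage can be re-run from the
intermediate files of the previous one.  A stage executes when any of its
outputs is missing or an upstream stage was re-executed; a JSON manifest
(seed, parameters, input hashes, package version) makes a run reproducible
bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .cellcycle import fit_wells
from .gating import (classify_cells, fit_row_gates, frequency_table,
                     gates_to_frame)
from .layout import FieldGrid, PlateLayout, load_layout, make_row_layout
from .segment import CELLS_COLUMNS, SegmentationParams, segment_and_measure_field
from .simulate import (CHANNEL_NAMES, DnaContentModel, GammaKinetics, Geometry,
                       GrowthModel, MarkerModel, SimulationConfig,
                       generate_plate, generate_well)
from .stats import (fit_growth, one_way_anova_and_sem, plate_column_adjust,
                    row_normalize_gamma, split_plot_interaction)

log = logging.getLogger("hcscreen")

STAGE_ORDER = ["simulate", "segment", "gate", "cellcycle", "damage",
               "growth", "stats"]
STAGE_DEPS = {
    "simulate": [],
    "segment": ["simulate"],
    "gate": ["segment"],
    "cellcycle": ["segment"],
    "damage": ["segment"],
    "growth": ["segment"],
    "stats": ["gate", "cellcycle"],
}
STAGE_OUTPUTS = {
    "simulate": ["truth.csv", "layout.csv"],
    "segment": ["cells.csv"],
    "gate": ["gates.csv", "phenotypes.csv", "frequencies.csv"],
    "cellcycle": ["cellcycle_fits.csv", "phases.csv"],
    "damage": ["gamma_normalized.csv"],
    "growth": ["growth_fits.csv"],
    "stats": ["splitplot_results.csv", "anova_results.csv"],
}


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

def simulation_config_from_dict(d: dict) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a plain (YAML) mapping."""
    d = dict(d or {})
    kwargs = {}
    if "markers" in d:
        kwargs["markers"] = {
            name: MarkerModel(**m) for name, m in d.pop("markers").items()
        }
    for key, cls in [("dna_content", DnaContentModel),
                     ("gamma_h2ax", GammaKinetics),
                     ("growth", GrowthModel), ("geometry", Geometry)]:
        if key in d:
            sub = dict(d.pop(key))
            if key == "geometry" and "grid" in sub:
                sub["grid"] = tuple(sub["grid"])
            kwargs[key] = cls(**sub)
    d.pop("conditions", None)
    kwargs.update(d)
    cfg = SimulationConfig(**kwargs)
    cfg.validate()
    return cfg


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# --------------------------------------------------------------------------
# in-memory simulate + segment (no image files touch disk)
# --------------------------------------------------------------------------

def simulate_and_measure(config: SimulationConfig,
                         layout: PlateLayout | None = None,
                         seed: int | None = None,
                         params: SegmentationParams | None = None):
    """Stream a simulated plate through segmentation well by well.

    Renders each field, segments it and measures cells immediately, so no
    more than one field of images is ever held in memory.  Returns
    (cells DataFrame in the cells.csv schema, truth DataFrame, layout).
    """
    config.validate()
    if layout is None:
        layout = make_row_layout(
            n_replicates=config.wells_per_condition,
            grid=FieldGrid(*config.geometry.grid,
                           config.geometry.field_spacing_um),
        )
    params = params or SegmentationParams(
        pixel_size=config.geometry.pixel_size_um)
    frames = []
    truths = []
    for _, wmeta in layout.wells.iterrows():
        meta = wmeta.to_dict()
        truth, fields = generate_well(config, meta, seed)
        truths.append(truth)
        offset = 0
        for f, stack in fields:
            df = segment_and_measure_field(
                stack, CHANNEL_NAMES, params,
                plate=meta["plate"], well=meta["well"], field=f,
                gamma_channel="FITC" if config.fitc_content == "gamma"
                else None,
                cell_id_offset=offset,
            )
            offset += len(df)
            frames.append(df)
    cells = pd.concat(frames, ignore_index=True)
    return cells, pd.concat(truths, ignore_index=True), layout


# --------------------------------------------------------------------------
# stage implementations (file based)
# --------------------------------------------------------------------------

def _stage_simulate(cfg: dict, out: Path, seed: int) -> None:
    sim_cfg = simulation_config_from_dict(cfg.get("simulate", {}))
    conditions = cfg.get("simulate", {}).get("conditions")
    layout = None
    if conditions:
        layout = make_row_layout(
            n_replicates=sim_cfg.wells_per_condition, conditions=conditions,
            grid=FieldGrid(*sim_cfg.geometry.grid,
                           sim_cfg.geometry.field_spacing_um),
        )
    generate_plate(sim_cfg, layout=layout, seed=seed, out_dir=out)


def _stage_segment(cfg: dict, out: Path, seed: int) -> None:
    layout = load_layout(out / "layout.csv")
    params = SegmentationParams(**cfg.get("segmentation", {}))
    channel_names = cfg.get("channels", CHANNEL_NAMES)
    image_dir = Path(cfg.get("image_dir", out / "fields"))
    frames = []
    for _, w in layout.wells.iterrows():
        wdir = image_dir / str(w["well"])
        offset = 0
        for tif in sorted(wdir.glob("*.tif")):
            stack = tifffile.imread(tif)
            fnum = int("".join(ch for ch in tif.stem if ch.isdigit()) or 0)
            df = segment_and_measure_field(
                stack, channel_names, params, plate=w["plate"],
                well=w["well"], field=fnum, cell_id_offset=offset,
            )
            offset += len(df)
            frames.append(df)
    cells = (pd.concat(frames, ignore_index=True) if frames
             else pd.DataFrame(columns=CELLS_COLUMNS))
    cells.to_csv(out / "cells.csv", index=False)


def _stage_gate(cfg: dict, out: Path, seed: int) -> None:
    cells = pd.read_csv(out / "cells.csv")
    layout = load_layout(out / "layout.csv")
    gcfg = cfg.get("gating", {})
    gates = fit_row_gates(cells, layout, k=gcfg.get("k", 2))
    gates_to_frame(gates).to_csv(out / "gates.csv", index=False)
    merged = cells.merge(
        layout.wells[["plate", "well", "replicate_row"]],
        on=["plate", "well"], how="left",
    )
    calls = classify_cells(merged, gates)
    calls.to_csv(out / "phenotypes.csv", index=False)
    freqs = frequency_table(calls, layout)
    freqs.to_csv(out / "frequencies.csv", index=False)


def _stage_cellcycle(cfg: dict, out: Path, seed: int) -> None:
    cells = pd.read_csv(out / "cells.csv")
    ccfg = cfg.get("cellcycle", {})
    fits, phases = fit_wells(cells, z=ccfg.get("z", 2.0),
                             min_cells=ccfg.get("min_cells", 200))
    fits.to_csv(out / "cellcycle_fits.csv", index=False)
    phases.to_csv(out / "phases.csv", index=False)


def _stage_damage(cfg: dict, out: Path, seed: int) -> None:
    cells = pd.read_csv(out / "cells.csv")
    layout = load_layout(out / "layout.csv")
    normed = row_normalize_gamma(cells, layout)
    try:
        normed = plate_column_adjust(normed)
    except Exception as exc:  # single-plate runs may lack t0 anchoring
        log.warning("plate/column adjustment skipped: %s", exc)
        normed["gamma_adjusted"] = np.nan
    normed.to_csv(out / "gamma_normalized.csv", index=False)


def _stage_growth(cfg: dict, out: Path, seed: int) -> None:
    cells = pd.read_csv(out / "cells.csv")
    layout = load_layout(out / "layout.csv")
    counts = cells.groupby(["plate", "well"]).size().rename("count")
    wells = layout.wells.merge(counts, left_on=["plate", "well"],
                               right_index=True, how="left")
    wells = wells[~wells["is_control"]].dropna(subset=["count"])
    rows = []
    for dose, grp in wells.groupby("dose_gy"):
        if grp["time_h"].nunique() < 3:
            continue
        fit = fit_growth(grp["count"].to_numpy(), grp["time_h"].to_numpy())
        rows.append({
            "dose_gy": dose, "a": fit.a, "b": fit.b,
            "doubling_time_h": fit.doubling_time_h,
            "doubling_time_legacy_convention":
                fit.doubling_time_legacy_convention,
            "residual_se": fit.residual_se, "n_points": fit.n_points,
        })
    pd.DataFrame(rows, columns=["dose_gy", "a", "b", "doubling_time_h",
                                "doubling_time_legacy_convention",
                                "residual_se", "n_points"]) \
        .to_csv(out / "growth_fits.csv", index=False)


def _stage_stats(cfg: dict, out: Path, seed: int) -> None:
    calls = pd.read_csv(out / "phenotypes.csv")
    layout = load_layout(out / "layout.csv")
    freqs = frequency_table(calls, layout,
                            grouping=["plate", "well", "dose_gy", "time_h"])
    class_cols = [c[:-9] for c in freqs.columns if c.endswith("_mean_pct")]
    long = freqs.melt(
        id_vars=["plate", "well", "dose_gy", "time_h"],
        value_vars=[f"{c}_mean_pct" for c in class_cols],
        var_name="phenotype", value_name="proportion",
    )
    long["phenotype"] = long["phenotype"].str.replace("_mean_pct", "",
                                                      regex=False)
    sp_rows = []
    if long["plate"].nunique() >= 2 and long["time_h"].nunique() >= 2:
        try:
            results = split_plot_interaction(long,
                                             phenotype_column="phenotype")
            sp_rows = [dataclasses.asdict(r) for r in results]
        except Exception as exc:
            log.warning("split-plot not estimable: %s", exc)
    pd.DataFrame(sp_rows, columns=["f_statistic", "p_value", "df_num",
                                   "df_den", "phenotype"]) \
        .to_csv(out / "splitplot_results.csv", index=False)

    an_rows = []
    for (ph, t), grp in long.groupby(["phenotype", "time_h"]):
        groups = {
            str(d): g["proportion"].to_numpy()
            for d, g in grp.groupby("dose_gy") if len(g) >= 2
        }
        if len(groups) >= 2:
            f, p, summary = one_way_anova_and_sem(groups)
            for _, srow in summary.iterrows():
                an_rows.append({
                    "phenotype": ph, "time_h": t, "dose_gy": srow["group"],
                    "mean": srow["mean"], "sem": srow["sem"],
                    "n": srow["n"], "F": f, "p": p,
                })
    pd.DataFrame(an_rows, columns=["phenotype", "time_h", "dose_gy", "mean",
                                   "sem", "n", "F", "p"]) \
        .to_csv(out / "anova_results.csv", index=False)


_STAGE_FN = {
    "simulate": _stage_simulate,
    "segment": _stage_segment,
    "gate": _stage_gate,
    "cellcycle": _stage_cellcycle,
    "damage": _stage_damage,
    "growth": _stage_growth,
    "stats": _stage_stats,
}


def run_pipeline(config: dict | str | Path, out_dir, seed: int = 0,
                 stages: list[str] | None = None) -> dict:
    """Execute the pipeline into ``out_dir`` and return the run manifest.

    Stages whose outputs already exist are skipped unless an upstream stage
    re-executed (delete an intermediate CSV to resume from that point).
    A failing stage raises, after logging the stage name.
    """
    cfg = load_config(config) if not isinstance(config, dict) else config
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    requested = stages or STAGE_ORDER
    if "simulate" not in cfg and "simulate" in requested:
        requested = [s for s in requested if s != "simulate"]

    executed: list[str] = []
    for stage in STAGE_ORDER:
        if stage not in requested:
            continue
        outputs = [out / f for f in STAGE_OUTPUTS[stage]]
        upstream_ran = any(d in executed for d in STAGE_DEPS[stage])
        if all(p.exists() for p in outputs) and not upstream_ran:
            log.info("stage %s: outputs present, skipped", stage)
            continue
        log.info("stage %s: running", stage)
        try:
            _STAGE_FN[stage](cfg, out, seed)
        except Exception:
            log.error("stage %s failed", stage)
            raise
        executed.append(stage)

    manifest = {
        "package": "hcscreen",
        "version": __version__,
        "seed": int(seed),
        "stages_executed": executed,
        "config": _jsonable(cfg),
        "outputs": {
            f: _hash_file(out / f)
            for s in requested for f in STAGE_OUTPUTS[s]
            if (out / f).exists()
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def recover_class_frequencies(proportions: dict[str, float] | None = None,
                              seed: int = 0,
                              config: SimulationConfig | None = None):
    """Full-pipeline phenotype-recovery experiment.

    Simulates a plate row (replicate wells plus a secondary-only control)
    with the given generating class proportions, renders and segments every
    field, fits the row-wise control-anchored gates, classifies cells and
    returns (mean percentage per class across wells, number of cells
    analysed).  Used to verify that the pipeline recovers known population
    compositions.
    """
    config = config or SimulationConfig()
    if proportions is not None:
        from .simulate import sorted_culture_config
        config = sorted_culture_config(config, proportions)
    cells, _, layout = simulate_and_measure(config, seed=seed)
    gates = fit_row_gates(cells, layout)
    merged = cells.merge(layout.wells[["plate", "well", "replicate_row"]],
                         on=["plate", "well"], how="left")
    calls = classify_cells(merged, gates)
    freq = frequency_table(calls, layout, grouping=["donor"])
    means = {c[:-9]: float(freq[c].iloc[0])
             for c in freq.columns if c.endswith("_mean_pct")}
    return means, int(len(cells))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
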