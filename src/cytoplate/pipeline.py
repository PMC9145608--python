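"""End-to-end plate analysis: segment -> quantify -> gate -> report.

Given a plate layout and a directory of per-well TIFFs, the pipeline builds
the plate-wide per-cell table, anchors one gate per marker on the pooled CT
wells, computes per-condition marker statistics and fold changes versus
untreated, and optionally adds cell-cycle fits, quadrant multiplexing and a
dose-response analysis. Every open parameter (gate quantile, window widths,
histogram bins, segmentation settings) is echoed into the report summary so
a run is fully reconstructable; report bodies contain no timestamps, so a
rerun with the same inputs is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cell_cycle as cc
from . import gating, segmentation, viability
from .layout import PlateLayout, validate_layout
from .simulate import read_well_images

log = logging.getLogger("cytoplate")

DEFAULT_CONFIG: dict = {
    "segmentation": {
        "smooth_sigma": 2.0,
        "threshold_method": "otsu",
        "min_area": 40,
        "split_touching": True,
        "tail_capture": True,
    },
    "background": "median_outside_mask",
    "gating": {"q": 0.99, "min_ct_cells": 100},
    "cell_cycle": {
        "enabled": False,
        "bins": 256,
        "window_halfwidth_frac": 0.15,
        "min_cells": 200,
    },
    "quadrant": {"enabled": False},
    "dose_response": {"enabled": False, "live_mode": "hoechst_subtraction"},
}


def _merged_config(config: dict | None) -> dict:
    merged = {k: (dict(v) if isinstance(v, dict) else v)
              for k, v in DEFAULT_CONFIG.items()}
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(merged.get(key), dict):
            merged[key].update(val)
        else:
            merged[key] = val
    return merged


@dataclass
class PipelineReport:
    """Bundle of everything one plate run produced."""

    plate_id: str
    cell_table: pd.DataFrame
    gates: gating.GateSet
    marker_stats: pd.DataFrame
    fold_changes: pd.DataFrame
    cycle_fits: dict[str, cc.CellCycleFit] = field(default_factory=dict)
    quadrants: dict[str, gating.QuadrantResult] = field(default_factory=dict)
    dose_response: dict[str, viability.DoseResponseResult] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)

    def write(self, output_dir: str | Path) -> dict[str, Path]:
        """Write the machine-readable report bundle (CSV / YAML / JSON)."""
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        paths["cells"] = out / "cells.csv"
        self.cell_table.to_csv(paths["cells"], index=False)
        paths["gates"] = out / "gates.yaml"
        self.gates.to_yaml(paths["gates"])
        paths["marker_stats"] = out / "marker_stats.csv"
        self.marker_stats.to_csv(paths["marker_stats"], index=False)
        paths["fold_changes"] = out / "fold_changes.csv"
        self.fold_changes.to_csv(paths["fold_changes"], index=False)

        if self.cycle_fits:
            paths["cycle"] = out / "cell_cycle.json"
            paths["cycle"].write_text(json.dumps(
                {cond: fit.to_dict() for cond, fit in self.cycle_fits.items()},
                indent=2, sort_keys=True,
            ))
        if self.quadrants:
            frames = []
            for cond, res in self.quadrants.items():
                t = res.table.copy()
                t.insert(0, "condition", cond)
                frames.append(t)
            paths["quadrants"] = out / "quadrants.csv"
            pd.concat(frames, ignore_index=True).to_csv(paths["quadrants"], index=False)
        if self.dose_response:
            payload = {}
            for drug, res in self.dose_response.items():
                payload[drug] = {
                    "concentrations": res.concentrations.tolist(),
                    "growth_percent_mean": res.growth_percent_mean.tolist(),
                    "params": res.params,
                    "ic50": res.ic50,
                    "ic50_label": res.ic50_label,
                    "percent_dead_at_reference": res.percent_dead_at_reference,
                    "reference_concentration": res.reference_concentration,
                    "mechanism_class": res.mechanism_class,
                    "flags": res.flags,
                }
            paths["dose_response"] = out / "dose_response.json"
            paths["dose_response"].write_text(json.dumps(payload, indent=2,
                                                         sort_keys=True))

        paths["summary"] = out / "summary.json"
        paths["summary"].write_text(json.dumps(self.summary, indent=2,
                                               sort_keys=True))
        return paths


def _condition_key(well) -> str:
    if well.role == "treated":
        return f"{well.drug}@{well.concentration:g}"
    return well.role


def run_pipeline(
    layout: PlateLayout,
    image_root: str | Path,
    config: dict | None = None,
) -> PipelineReport:
    """Execute the full analysis over one plate of well images.

    Raises on layout violations (before any image is read), on missing CT
    wells when marker gates are requested, and on missing untreated wells
    when fold changes or dose-response are computed.
    """
    cfg = _merged_config(config)
    if not layout.wells:
        raise ValueError("plate layout contains no wells")
    violations = validate_layout(layout)
    if violations:
        raise ValueError("invalid plate layout: " + "; ".join(violations))

    channels = list(layout.channels)
    seg_cfg = cfg["segmentation"]

    tables = []
    for well in layout.wells:
        images = read_well_images(image_root, well.address, channels)
        mask = segmentation.segment_nuclei(images["hoechst"], **seg_cfg)
        table = segmentation.apply_mask(
            mask, images, background=cfg["background"], well_id=well.address
        )
        table["condition"] = _condition_key(well)
        table["role"] = well.role
        table["drug"] = well.drug
        table["concentration"] = well.concentration
        table["replicate"] = well.replicate
        log.info("well %s (%s): %d cells", well.address, well.role, len(table))
        tables.append(table)
    cell_table = pd.concat(tables, ignore_index=True)

    markers = layout.marker_channels
    gates = gating.GateSet()
    if markers:
        ct = cell_table[cell_table["role"] == "CT"]
        if len(ct) == 0:
            raise ValueError("marker gates requested but no CT cells found")
        for marker in markers:
            gates.add(gating.define_gate(
                ct, marker, q=cfg["gating"]["q"],
                min_cells=cfg["gating"]["min_ct_cells"],
            ))

    stat_rows = []
    conditions = sorted(cell_table["condition"].unique())
    for cond in conditions:
        sub = cell_table[cell_table["condition"] == cond]
        for marker in markers:
            s = gating.percent_positive(sub, gates[marker], condition=cond)
            stat_rows.append({
                "condition": cond,
                "channel": marker,
                "n_cells": s.n_cells,
                "percent_positive": s.percent_positive,
                "mean_intensity_positives": s.mean_integrated_intensity_of_positives,
            })
    marker_stats = pd.DataFrame(
        stat_rows,
        columns=["condition", "channel", "n_cells", "percent_positive",
                 "mean_intensity_positives"],
    )

    fc_rows = []
    if markers and (marker_stats["condition"] == "untreated").any():
        for marker in markers:
            base = marker_stats[
                (marker_stats["condition"] == "untreated")
                & (marker_stats["channel"] == marker)
            ].iloc[0]
            base_stat = gating.percent_positive(
                cell_table[cell_table["role"] == "untreated"], gates[marker]
            )
            for cond in conditions:
                if cond == "untreated":
                    continue
                sub = cell_table[cell_table["condition"] == cond]
                s = gating.percent_positive(sub, gates[marker], condition=cond)
                fc = (s.percent_positive / base["percent_positive"]
                      if base["percent_positive"] > 0 else float("inf"))
                fc_rows.append({
                    "condition": cond,
                    "channel": marker,
                    "percent_positive": s.percent_positive,
                    "untreated_percent_positive": base_stat.percent_positive,
                    "fold_change": fc,
                })
    fold_changes = pd.DataFrame(
        fc_rows,
        columns=["condition", "channel", "percent_positive",
                 "untreated_percent_positive", "fold_change"],
    )

    cycle_fits: dict[str, cc.CellCycleFit] = {}
    if cfg["cell_cycle"]["enabled"]:
        cc_cfg = cfg["cell_cycle"]
        for cond in conditions:
            sub = cell_table[cell_table["condition"] == cond]
            if len(sub) >= cc_cfg["min_cells"]:
                cycle_fits[cond] = cc.fit_dna_histogram(
                    sub["hoechst_integrated"].to_numpy(),
                    bins=cc_cfg["bins"],
                    window_halfwidth_frac=cc_cfg["window_halfwidth_frac"],
                    min_cells=cc_cfg["min_cells"],
                )

    quadrants: dict[str, gating.QuadrantResult] = {}
    if cfg["quadrant"]["enabled"] and len(markers) >= 2:
        for cond in conditions:
            sub = cell_table[cell_table["condition"] == cond]
            if len(sub):
                quadrants[cond] = gating.quadrant_analysis(sub, gates)

    dose_response: dict[str, viability.DoseResponseResult] = {}
    if cfg["dose_response"]["enabled"]:
        if "pi" not in layout.channels:
            raise ValueError("dose-response requested but no 'pi' channel")
        pi_gate = gating.otsu_gate(cell_table, "pi")
        gates.add(pi_gate)
        drugs = sorted({w.drug for w in layout.wells if w.role == "treated" and w.drug})
        for drug in drugs:
            rows = []
            series = [
                w for w in layout.wells
                if w.role == "untreated" or (w.role == "treated" and w.drug == drug)
            ]
            for well in series:
                sub = cell_table[cell_table["well_id"] == well.address]
                if len(sub) == 0:
                    # fully inhibited well: zero growth, no dead-cell estimate
                    rows.append({"well_id": well.address,
                                 "concentration": well.concentration,
                                 "n_total": 0, "percent_dead": float("nan")})
                    continue
                wv = viability.quantify_live_dead(
                    sub, pi_gate, live_mode=cfg["dose_response"]["live_mode"]
                )
                rows.append({
                    "well_id": well.address,
                    "concentration": well.concentration,
                    "n_total": wv.n_total,
                    "percent_dead": wv.percent_dead,
                })
            dose_response[drug] = viability.dose_response_from_wells(
                pd.DataFrame(rows)
            )

    summary = {
        "schema_version": 1,
        "plate_id": layout.plate_id,
        "n_wells": len(layout.wells),
        "n_cells": int(len(cell_table)),
        "channels": dict(layout.channels),
        "config": cfg,
        "gates": {ch: g.threshold for ch, g in gates.items()},
        "conditions": conditions,
    }

    return PipelineReport(
        plate_id=layout.plate_id,
        cell_table=cell_table,
        gates=gates,
        marker_stats=marker_stats,
        fold_changes=fold_changes,
        cycle_fits=cycle_fits,
        quadrants=quadrants,
        dose_response=dose_response,
        summary=summary,
    )
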