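"""The hierarchical screening cascade over a framework library.

Each structure flows through biocompatibility (building-block verdicts),
then the porosity gate (PLD vs each guest's minimal diameter), then GCMC
loading per surviving (structure, drug) pair, then the loading threshold
(default 1 g drug per g MOF = 1000 mg/g = 50 wt.%).  Failures are recorded
with reasons, never dropped; the report is deterministic for fixed seeds
and invariant to the order of the input library.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .deconstruct import split_building_blocks
from .gcmc import ForceField, GCMCConfig, RigidGuest, run_gcmc
from .pores import (
    accessible_pore_volume,
    compute_distance_grid,
    largest_cavity_diameter,
    pore_limiting_diameter,
)
from .structures import PeriodicStructure
from .toxicity import MetalToxicityRecord, ToxicityClassifier, assess_mof_biocompatibility

__all__ = [
    "ScreeningConfig",
    "ScreeningRecord",
    "ScreeningReport",
    "screen_library",
    "apply_loading_threshold",
    "loading_volume_regression",
    "export_report",
    "load_report",
]


@dataclass
class ScreeningConfig:
    threshold_mg_per_g: float = 1000.0  # 1 g/g = 50 wt.%
    temperature: float = 298.0
    fugacity: float = 1e5
    grid_spacing: float = 0.5
    volume_samples: int = 20000
    gcmc_cycles: int = 20000
    gcmc_equilibration: int = 5000
    seed: int = 0
    metal_whitelist: tuple[str, ...] = ("Fe", "Zn")
    require_all_drugs: bool = True

    def __post_init__(self):
        if self.threshold_mg_per_g <= 0:
            raise ValueError("threshold must be positive")


@dataclass
class ScreeningRecord:
    """Full audit trail of one framework through the cascade."""

    name: str
    stage_reached: str  # "error" | "biocompat" | "porosity" | "loading" | "passed"
    reason: str = ""
    biocompat_verdict: str | None = None
    biocompat_detail: dict | None = None
    pld: float | None = None
    lcd: float | None = None
    pore_volumes: dict[str, float] = field(default_factory=dict)  # per drug, cm^3/g
    loadings_mg_per_g: dict[str, float] = field(default_factory=dict)
    loadings_wt_percent: dict[str, float] = field(default_factory=dict)
    passes_threshold: dict[str, bool] = field(default_factory=dict)
    porosity_pass: dict[str, bool] = field(default_factory=dict)
    seed: int = 0


@dataclass
class ScreeningReport:
    records: list[ScreeningRecord]
    survivors: dict[str, int]  # per-stage survivor counts
    scatter: pd.DataFrame  # one row per structure x drug
    config: ScreeningConfig

    def record(self, name: str) -> ScreeningRecord:
        for r in self.records:
            if r.name == name:
                return r
        raise KeyError(name)


def apply_loading_threshold(
    loadings_mg_per_g: dict[str, float], threshold: float
) -> dict[str, bool]:
    """Pass iff loading >= threshold (inclusive), per drug."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return {drug: loading >= threshold for drug, loading in loadings_mg_per_g.items()}


def screen_library(
    structures: list[PeriodicStructure],
    drugs: list[RigidGuest],
    classifier: ToxicityClassifier,
    metal_table: dict[str, MetalToxicityRecord],
    ff: ForceField,
    config: ScreeningConfig = ScreeningConfig(),
) -> ScreeningReport:
    """Run the full cascade; every input structure ends in exactly one state."""
    if not structures:
        raise ValueError("empty structure library")
    if not drugs:
        raise ValueError("empty drug list")
    min_diams = {d.name: d.minimal_diameter(ff) for d in drugs}

    records: list[ScreeningRecord] = []
    scatter_rows = []
    for structure in sorted(structures, key=lambda s: s.name):
        rec = ScreeningRecord(name=structure.name, stage_reached="error", seed=config.seed)
        records.append(rec)
        try:
            blocks = split_building_blocks(structure)
            bio = assess_mof_biocompatibility(
                blocks, metal_table, classifier, whitelist=config.metal_whitelist
            )
        except Exception as exc:
            rec.reason = f"{type(exc).__name__}: {exc}"
            continue
        rec.biocompat_verdict = bio.verdict
        rec.biocompat_detail = {
            "metals": bio.metal_verdicts,
            "linkers": bio.linker_verdicts,
            "whitelisted": bio.whitelisted,
        }
        if not bio.accepted:
            rec.stage_reached = "biocompat"
            rec.reason = "; ".join(bio.failing_blocks)
            continue

        grid = compute_distance_grid(structure, spacing=config.grid_spacing)
        rec.lcd = largest_cavity_diameter(grid)
        rec.pld = pore_limiting_diameter(grid)
        for drug in drugs:
            probe = min_diams[drug.name] / 2
            vol, _, _ = accessible_pore_volume(
                structure,
                probe_radius=probe,
                samples=config.volume_samples,
                seed=config.seed,
                grid=grid,
            )
            rec.pore_volumes[drug.name] = vol
            rec.porosity_pass[drug.name] = rec.pld >= min_diams[drug.name] and vol > 0
        if not any(rec.porosity_pass.values()):
            rec.stage_reached = "porosity"
            rec.reason = (
                f"pld {rec.pld:.2f} A below every guest minimal diameter"
            )
            continue

        gcfg = replace(
            GCMCConfig(),
            temperature=config.temperature,
            fugacity=config.fugacity,
            cycles=config.gcmc_cycles,
            equilibration=config.gcmc_equilibration,
            seed=config.seed,
        )
        for drug in drugs:
            if not rec.porosity_pass[drug.name]:
                rec.loadings_mg_per_g[drug.name] = 0.0
                rec.loadings_wt_percent[drug.name] = 0.0
                continue
            result = run_gcmc(structure, drug, ff, gcfg)
            rec.loadings_mg_per_g[drug.name] = result.loading_mg_per_g
            rec.loadings_wt_percent[drug.name] = result.loading_wt_percent
        rec.passes_threshold = apply_loading_threshold(
            rec.loadings_mg_per_g, config.threshold_mg_per_g
        )
        per_drug_pass = [
            rec.passes_threshold[d.name] for d in drugs
        ]
        overall = all(per_drug_pass) if config.require_all_drugs else any(per_drug_pass)
        rec.stage_reached = "passed" if overall else "loading"
        if not overall:
            failed = [d.name for d in drugs if not rec.passes_threshold[d.name]]
            rec.reason = f"loading below threshold for: {', '.join(failed)}"
        for drug in drugs:
            scatter_rows.append(
                {
                    "structure": structure.name,
                    "drug": drug.name,
                    "pore_volume_cm3_per_g": rec.pore_volumes.get(drug.name, 0.0),
                    "pld": rec.pld,
                    "lcd": rec.lcd,
                    "guest_min_diameter": min_diams[drug.name],
                    "loading_mg_per_g": rec.loadings_mg_per_g.get(drug.name, 0.0),
                }
            )

    n = len(records)
    past_bio = sum(r.stage_reached in ("porosity", "loading", "passed") for r in records)
    past_por = sum(r.stage_reached in ("loading", "passed") for r in records)
    passed = sum(r.stage_reached == "passed" for r in records)
    survivors = {
        "input": n,
        "biocompat": past_bio,
        "porosity": past_por,
        "threshold": passed,
    }
    scatter = pd.DataFrame(
        scatter_rows,
        columns=[
            "structure", "drug", "pore_volume_cm3_per_g", "pld", "lcd",
            "guest_min_diameter", "loading_mg_per_g",
        ],
    )
    return ScreeningReport(records=records, survivors=survivors, scatter=scatter, config=config)


def loading_volume_regression(report: ScreeningReport, drug: str):
    """Least-squares loading vs accessible pore volume above the PLD knee.

    Only rows whose PLD admits the guest (PLD >= its minimal diameter)
    enter the fit — the knee the loading-capacity scatter shows before
    uptake scales linearly with pore volume.  Returns (slope, intercept,
    r_squared, n_points); raises a flagging ValueError below 3 points.
    """
    rows = report.scatter
    sel = rows[(rows["drug"] == drug) & (rows["pld"].notna())]
    sel = sel[sel["pld"] >= sel["guest_min_diameter"]]
    if len(sel) < 3:
        raise ValueError("insufficient data: need >= 3 records above the PLD knee")
    x = sel["pore_volume_cm3_per_g"].to_numpy()
    y = sel["loading_mg_per_g"].to_numpy()
    if np.allclose(y, y[0]):
        return 0.0, float(y[0]), 1.0, len(sel)
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue ** 2), len(sel)


# ---------------------------------------------------------------------------
# Export / re-ingest
# ---------------------------------------------------------------------------


def export_report(report: ScreeningReport, out_prefix: str) -> dict[str, str]:
    """Write report.csv (structure x drug rows), report.json (full audit),
    scatter.csv.  Deterministic field order; re-export is byte-identical."""
    csv_path = f"{out_prefix}report.csv"
    json_path = f"{out_prefix}report.json"
    scatter_path = f"{out_prefix}scatter.csv"
    report.scatter.to_csv(csv_path, index=False, float_format="%.6f")
    report.scatter.to_csv(scatter_path, index=False, float_format="%.6f")
    payload = {
        "survivors": report.survivors,
        "config": asdict(report.config),
        "records": [asdict(r) for r in report.records],
        "scatter": report.scatter.to_dict(orient="records"),
    }
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, default=float)
    return {"csv": csv_path, "json": json_path, "scatter": scatter_path}


def load_report(json_path: str) -> ScreeningReport:
    """Reconstruct a :class:`ScreeningReport` from its JSON export."""
    with open(json_path, encoding="utf-8") as fh:
        payload = json.load(fh)
    cfg = payload["config"]
    cfg["metal_whitelist"] = tuple(cfg["metal_whitelist"])
    config = ScreeningConfig(**cfg)
    records = [ScreeningRecord(**r) for r in payload["records"]]
    scatter = pd.DataFrame(
        payload["scatter"],
        columns=[
            "structure", "drug", "pore_volume_cm3_per_g", "pld", "lcd",
            "guest_min_diameter", "loading_mg_per_g",
        ],
    )
    return ScreeningReport(
        records=records,
        survivors=payload["survivors"],
        scatter=scatter,
        config=config,
    )
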