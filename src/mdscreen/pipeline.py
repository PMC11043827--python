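"""Configuration, plate-map handling and the end-to-end pipeline.

A single YAML config governs every stage (simulate → quantify →
screen-stats, and the recovery/pools branches); there are no hidden
defaults outside the spec dataclasses.  Every output table carries the
config hash so tables from different runs cannot be mixed silently,
and a manifest records inputs, hash, seed and library versions for
exact re-runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .imaging import QuantParams, quantify_fields
from .recovery import QpcrMeasurement
from .screen import summarize_screen
from .synthetic import (FieldSpec, PoolSpec, RecoverySpec,
                        enumerate_supplement_conditions,
                        generate_screen_dataset)

logger = logging.getLogger("mdscreen")

SERUM_VOCAB = (10.0, 0.1)
CONCENTRATION_VOCAB = (50.0, 200.0)
PLATEMAP_COLUMNS = ["well_id", "cell_line", "run", "serum", "supplements",
                    "concentration_um", "day", "treated"]


class PlateMapError(ValueError):
    """Raised when a plate map fails validation; carries the report."""

    def __init__(self, report: list):
        self.report = report
        super().__init__("invalid plate map:\n" + "\n".join(report))


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------

@dataclass
class ScreenConfig:
    """Which supplement conditions to simulate and with what effects."""

    nucleosides: tuple = ("A", "T", "G", "C")
    concentrations: tuple = (200.0,)
    serum: float = 10.0
    fields_per_well: int = 9
    runs: int = 2
    run_sigma: float = 0.1
    cell_line: str = "CTRL1"
    # label -> [effect_mtdna, effect_cells, effect_mmp]
    effects: dict = dc_field(default_factory=dict)


@dataclass
class PipelineConfig:
    """Full pipeline configuration; round-trips losslessly through YAML."""

    seed: int = 0
    verbosity: str = "INFO"
    save_images: bool = False
    field: FieldSpec = dc_field(default_factory=FieldSpec)
    screen: ScreenConfig = dc_field(default_factory=ScreenConfig)
    quant: QuantParams = dc_field(default_factory=QuantParams)
    recovery: RecoverySpec = dc_field(default_factory=RecoverySpec)
    pools: PoolSpec = dc_field(default_factory=PoolSpec)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(_listify(self.to_dict()), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return _build_dataclass(cls, data, path="config")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @property
    def config_hash(self) -> str:
        canonical = yaml.safe_dump(_listify(self.to_dict()), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def _listify(obj):
    """YAML-safe copy: tuples/frozensets to lists, numpy scalars to python."""
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_listify(v) for v in obj]
    if isinstance(obj, frozenset):
        return sorted(obj)
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _build_dataclass(cls, data: dict, path: str):
    """Construct a (possibly nested) dataclass, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping, got {type(data).__name__}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"{path}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        target = _nested_dataclass(cls, name)
        if target is not None:
            kwargs[name] = _build_dataclass(target, value, f"{path}.{name}")
        elif isinstance(value, list) and "tuple" in str(ftype):
            kwargs[name] = tuple(tuple(v) if isinstance(v, list) else v
                                 for v in value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


def _nested_dataclass(cls, name):
    mapping = {
        "field": FieldSpec, "screen": ScreenConfig, "quant": QuantParams,
        "recovery": RecoverySpec, "pools": PoolSpec,
    }
    return mapping.get(name) if cls is PipelineConfig else None


# ---------------------------------------------------------------------------
# plate maps
# ---------------------------------------------------------------------------

def validate_platemap(platemap: pd.DataFrame,
                      serum_vocab=SERUM_VOCAB,
                      concentration_vocab=CONCENTRATION_VOCAB) -> list:
    """Validate a plate map; returns a report of violations (row-numbered)."""
    report: list[str] = []
    missing = set(PLATEMAP_COLUMNS) - set(platemap.columns)
    if missing:
        return [f"missing columns: {sorted(missing)}"]
    dup = platemap["well_id"][platemap["well_id"].duplicated()]
    for idx, well in dup.items():
        report.append(f"row {idx}: duplicate well_id {well!r}")
    for idx, row in platemap.iterrows():
        sup = str(row["supplements"])
        if sup != "DMSO" and (not sup or set(sup) - set("ATGC")):
            report.append(f"row {idx}: unknown supplement {sup!r}")
        if float(row["serum"]) not in serum_vocab:
            report.append(f"row {idx}: serum {row['serum']!r} not in "
                          f"{sorted(serum_vocab)}")
        if float(row["concentration_um"]) not in concentration_vocab:
            report.append(f"row {idx}: concentration {row['concentration_um']!r}"
                          f" not in {sorted(concentration_vocab)}")
    return report


def read_platemap(path) -> pd.DataFrame:
    """Read and validate a plate-map CSV; refuses to load on violations."""
    platemap = pd.read_csv(path)
    report = validate_platemap(platemap)
    if report:
        raise PlateMapError(report)
    return platemap


def condition_contexts(platemap: pd.DataFrame) -> pd.DataFrame:
    """Distinct (supplements, concentration, serum) contexts in a plate map."""
    return (platemap[["supplements", "concentration_um", "serum"]]
            .drop_duplicates().reset_index(drop=True))


# ---------------------------------------------------------------------------
# qPCR / isotope CSV formats
# ---------------------------------------------------------------------------

def write_qpcr_csv(measurements: list, path) -> None:
    """Long-format qPCR CSV: one row per (sample, target)."""
    rows = []
    for m in measurements:
        for target, ct in (("mt", m.ct_mt), ("b2m", m.ct_b2m)):
            rows.append({"sample": m.sample, "line": m.line,
                         "treated": m.treated, "day": m.day,
                         "replicate": m.replicate,
                         "is_reference": m.is_reference,
                         "target": target, "ct": ct})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_qpcr_csv(path) -> list:
    """Parse the long-format qPCR CSV back into measurements."""
    df = pd.read_csv(path)
    out = []
    keys = ["sample", "line", "treated", "day", "replicate", "is_reference"]
    for vals, g in df.groupby(keys, sort=False):
        cts = dict(zip(g["target"], g["ct"]))
        rec = dict(zip(keys, vals))
        out.append(QpcrMeasurement(
            sample=str(rec["sample"]), line=str(rec["line"]),
            treated=bool(rec["treated"]), day=float(rec["day"]),
            ct_mt=float(cts.get("mt", float("nan"))),
            ct_b2m=float(cts.get("b2m", float("nan"))),
            replicate=int(rec["replicate"]),
            is_reference=bool(rec["is_reference"])))
    return out


def read_isotope_csv(path) -> pd.DataFrame:
    """Isotope peak CSV (nucleoside, isotopologue, area) -> wide areas."""
    df = pd.read_csv(path)
    wide = (df.pivot_table(index="nucleoside", columns="isotopologue",
                           values="area", aggfunc="sum")
            .rename(columns={"heavy": "heavy_area", "light": "light_area"})
            .reset_index())
    return wide[["nucleoside", "heavy_area", "light_area"]]


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

def _stamp(table: pd.DataFrame, config_hash: str) -> pd.DataFrame:
    table = table.copy()
    table["config_hash"] = config_hash
    return table


def check_hashes(*tables: pd.DataFrame) -> str:
    """Refuse to combine tables produced under different configs."""
    hashes = set()
    for t in tables:
        if "config_hash" in t.columns:
            hashes.update(t["config_hash"].unique())
    if len(hashes) > 1:
        raise ValueError(f"tables carry different config hashes: {sorted(hashes)}")
    return next(iter(hashes)) if hashes else ""


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Simulate a screen, quantify it and compute screen statistics.

    Writes plate map, ground truth, per-cell records and the
    condition-level summary as CSV (each stamped with the config
    hash), plus a manifest enabling exact re-runs.  Deterministic:
    identical config and seed give byte-identical CSV outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash
    logging.basicConfig(level=getattr(logging, config.verbosity, logging.INFO))

    logger.info("stage 1/3: simulate")
    effects = {k: tuple(v) for k, v in config.screen.effects.items()}
    conditions = enumerate_supplement_conditions(
        config.screen.nucleosides, config.screen.concentrations,
        serum=config.screen.serum, effects=effects)
    try:
        dataset = generate_screen_dataset(
            conditions, config.field,
            fields_per_well=config.screen.fields_per_well,
            runs=config.screen.runs, seed=config.seed,
            run_sigma=config.screen.run_sigma,
            cell_line=config.screen.cell_line)
    except Exception as exc:
        raise RuntimeError(f"[simulate] {exc}") from exc

    artifacts = []
    for name, table in (("platemap.csv", dataset.platemap),
                        ("truth.csv", dataset.truth)):
        _stamp(table, chash).to_csv(out / name, index=False)
        artifacts.append(name)
    if config.save_images:
        img_dir = out / "images"
        img_dir.mkdir(exist_ok=True)
        for img in dataset.fields:
            name = f"{img.run_id}_{img.well_id}_f{img.field_index}.tif"
            img.to_tiff(img_dir / name)
            artifacts.append(f"images/{name}")

    logger.info("stage 2/3: quantify (%d fields)", len(dataset.fields))
    try:
        cells = quantify_fields(dataset.fields, config.quant)
    except Exception as exc:
        raise RuntimeError(f"[quantify] {exc}") from exc
    well_meta = dataset.platemap.set_index("well_id")
    cells["condition"] = cells["well_id"].map(well_meta["supplements"])
    cells["concentration_um"] = cells["well_id"].map(
        well_meta["concentration_um"])
    cells["serum"] = cells["well_id"].map(well_meta["serum"])
    _stamp(cells, chash).to_csv(out / "cells.csv", index=False)
    artifacts.append("cells.csv")

    logger.info("stage 3/3: screen-stats (%d cells)", len(cells))
    try:
        summary = summarize_screen(cells)
    except Exception as exc:
        raise RuntimeError(f"[screen-stats] {exc}") from exc
    _stamp(summary, chash).to_csv(out / "screen_summary.csv", index=False)
    artifacts.append("screen_summary.csv")

    manifest = {
        "config_hash": chash,
        "seed": config.seed,
        "config": _listify(config.to_dict()),
        "artifacts": artifacts,
        "versions": _versions(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return out


def _versions() -> dict:
    import scipy
    import skimage
    import statsmodels
    return {
        "mdscreen": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-image": skimage.__version__,
        "statsmodels": statsmodels.__version__,
    }


def demo_config(seed: int = 0) -> PipelineConfig:
    """Small two-condition screen used by the one-command demo."""
    return PipelineConfig(
        seed=seed,
        field=FieldSpec(field_size=(384, 384), n_cells=10,
                        nucleoid_count_mean=40.0),
        screen=ScreenConfig(nucleosides=("T",), concentrations=(200.0,),
                            fields_per_well=3, runs=2,
                            effects={"T": [1.5, 1.0, 1.0]}),
    )
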