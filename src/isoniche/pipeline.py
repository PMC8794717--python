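"""End-to-end orchestration: simulate/load → normalize → chronology →
specialization → isoscape → drivers, driven by one YAML/dict config.

Every run emits a manifest (config hash, input checksums, per-stage row
counts, output paths, warnings) so outputs are traceable and reruns with
identical inputs are reproducible modulo timestamps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import chronology as chron
from . import drivers as drv
from . import io as iio
from . import isoscape as iso
from . import simulate as sim
from .exceptions import ConfigError, DataError
from .specialization import SpecializationModel

logger = logging.getLogger(__name__)

_KNOWN_BLOCKS = {"seed", "outdir", "simulate", "io", "chronology",
                 "specialization", "isoscape", "drivers"}

#: fixed per-stage seed offsets so disabling one stage never reseeds another
_STAGE_SEED = {"simulate": 11, "normalize": 23, "chronology": 31,
               "si": 47, "isoscape": 59, "drivers": 71}


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config_hash: str
    seed: int | None
    started: str
    stages: list[str] = field(default_factory=list)
    input_checksums: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    row_counts: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2))


def load_config(source) -> dict:
    """Load and validate a pipeline config (YAML path, stream or dict)."""
    if isinstance(source, Mapping):
        cfg = dict(source)
    else:
        text = Path(source).read_text() if isinstance(
            source, (str, Path)) else source.read()
        cfg = yaml.safe_load(text) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(cfg) - _KNOWN_BLOCKS
    if unknown:
        raise ConfigError(f"unknown config block(s): {sorted(unknown)}")
    for block in _KNOWN_BLOCKS - {"seed", "outdir"}:
        if block in cfg and not isinstance(cfg[block], Mapping):
            raise ConfigError(f"config block {block!r} must be a mapping")
    if "seed" in cfg and cfg["seed"] is not None \
            and not isinstance(cfg["seed"], int):
        raise ConfigError("seed must be an integer")
    return cfg


def _config_hash(cfg: Mapping) -> str:
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path, manifest: RunManifest,
           name: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    df.to_csv(tmp, index=False)
    tmp.replace(path)  # atomic on POSIX
    manifest.outputs[name] = str(path)
    manifest.row_counts[name] = len(df)


def growth_model_from_config(block: Mapping) -> chron.GrowthModel:
    return chron.GrowthModel(
        L_inf=float(block.get("L_inf_mm", 70.0)),
        k=float(block.get("k_per_day", 0.022)),
        t0=float(block.get("t0_days", 0.0)),
        mode=block.get("mode", "continuous"),
    )


def density_model_from_config(block: Mapping) -> chron.DensityModel:
    dens = block.get("density", {})
    return chron.DensityModel(
        profile=dens.get("profile", "uniform"),
        linear_density=dens.get("linear_density", 0.30),
        total_mass_mg=dens.get("total_mass_mg"),
        taper_ratio=dens.get("taper_ratio", 1.0),
    )


def run_pipeline(config, outdir=None) -> RunManifest:
    """Run the configured stages in order; any failure aborts with the
    stage name in the message. Returns the manifest (also written to
    ``manifest.json`` in the output directory)."""
    cfg = load_config(config)
    outdir = Path(outdir or cfg.get("outdir", "."))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = cfg.get("seed")
    manifest = RunManifest(
        config_hash=_config_hash(cfg),
        seed=seed,
        started=datetime.now().isoformat(timespec="seconds"),
    )

    stage = "config"
    try:
        tables: dict[str, pd.DataFrame] = {}

        # -- simulate -------------------------------------------------
        if "simulate" in cfg:
            stage = "simulate"
            block = {k: v for k, v in cfg["simulate"].items()}
            if "collection_start" in block:
                block["collection_start"] = date.fromisoformat(
                    str(block["collection_start"]))
            if "collection_stop" in block:
                block["collection_stop"] = date.fromisoformat(
                    str(block["collection_stop"]))
            for tup in ("sites", "lowered_sites", "si_link_N", "si_link_C"):
                if tup in block:
                    block[tup] = tuple(block[tup])
            try:
                gen = sim.GeneratorConfig(**block)
            except TypeError as exc:
                raise ConfigError(f"simulate block: {exc}") from exc
            if seed is None and gen.seed is None:
                raise ConfigError("simulate stage needs a seed")
            pop = sim.simulate_population(
                gen, seed=None if gen.seed is not None
                else seed + _STAGE_SEED["simulate"])
            tables["segments"] = pop.segments
            tables["covariates"] = pop.covariates
            tables["whiskers"] = pop.whiskers
            _write(pop.segments, outdir / "segments.csv", manifest,
                   "segments")
            _write(pop.covariates, outdir / "covariates.csv", manifest,
                   "covariates")
            _write(pop.whiskers, outdir / "whiskers.csv", manifest,
                   "whiskers")
            _write(pop.truth, outdir / "truth.csv", manifest, "truth")
            manifest.stages.append(stage)

        # -- load inputs ----------------------------------------------
        stage = "io"
        io_block = cfg.get("io", {})
        colmap = io_block.get("column_map")
        consumer = {"segments": "si", "covariates": "drivers",
                    "whiskers": "chronology", "food_samples": "isoscape",
                    "raw_run": "normalize"}
        for name in ("segments", "covariates", "whiskers", "food_samples",
                     "raw_run"):
            if name in tables or name not in io_block:
                continue
            path = Path(io_block[name])
            if not path.exists():
                stage = consumer[name]
                raise DataError(
                    f"{consumer[name]} stage input {name!r} not found: "
                    f"{path}")
            manifest.input_checksums[name] = _checksum(path)
            if name == "segments":
                table, rejections = iio.read_sample_table(path, colmap)
                for rej in rejections:
                    manifest.warnings.append(
                        f"segments row={rej.row}: {rej.reason}")
                tables[name] = table
            else:
                tables[name] = pd.read_csv(path)

        # -- normalize ------------------------------------------------
        if "raw_run" in tables:
            stage = "normalize"
            run = tables["raw_run"]
            corrected = iio.two_point_normalize(
                run[~run["sample_id"].isin(["USGS40", "USGS41a"])],
                standards=_standards_from_run(run),
            )
            _write(corrected, outdir / "normalized_run.csv", manifest,
                   "normalized_run")
            manifest.stages.append(stage)

        if "segments" not in tables:
            raise DataError("no segment table available (supply io.segments "
                            "or a simulate block)")

        # -- chronology -----------------------------------------------
        if "whiskers" in tables:
            stage = "chronology"
            block = cfg.get("chronology", {})
            model = growth_model_from_config(block)
            density = density_model_from_config(block)
            intradermal = block.get("intradermal_mm")
            plans = []
            for _, row in tables["whiskers"].iterrows():
                extra = row.get("intradermal_length")
                if intradermal is not None:
                    if isinstance(intradermal, Mapping):
                        extra = intradermal.get(
                            str(row.get("position_label", "A")), 0.0)
                    else:
                        extra = float(intradermal)
                whisker = chron.WhiskerRecord(
                    individual_id=str(row["individual_id"]),
                    observed_length=float(row["observed_length"]),
                    intradermal_length=float(extra),
                    collection_date=_as_date(row["collection_date"]),
                    position_label=str(row.get("position_label", "A")),
                )
                plan = chron.plan_segments(
                    whisker, model, density,
                    n_isotope=int(block.get("n_isotope", 3)),
                    mass_window=tuple(block.get("mass_window_mg",
                                                (0.2, 0.5))),
                    buffer_days_target=float(block.get("buffer_days", 11.3)),
                )
                plans.append(plan.to_frame())
            plan_table = pd.concat(plans, ignore_index=True)
            _write(plan_table, outdir / "segment_plans.csv", manifest,
                   "segment_plans")
            manifest.stages.append(stage)

        # -- specialization -------------------------------------------
        stage = "si"
        block = cfg.get("specialization", {})
        model = SpecializationModel.from_dataframe(
            tables["segments"],
            dialect=block.get("dialect", "between-means"),
            ddof=int(block.get("ddof", 1)),
            thresholds=tuple(block.get("thresholds", (0.2, 0.5))),
        )
        si_res = model.fit()
        _write(si_res.per_individual, outdir / "specialization.csv",
               manifest, "specialization")
        _write(si_res.population_summary(),
               outdir / "population_summary.csv", manifest,
               "population_summary")
        manifest.stages.append(stage)

        # -- isoscape -------------------------------------------------
        if "food_samples" in tables:
            stage = "isoscape"
            block = cfg.get("isoscape", {})
            factors = iso.DiscriminationFactors(
                delta_N=float(block.get("delta_N", 3.5)),
                delta_C=float(block.get("delta_C", 2.2)),
            )
            summary = iso.summarize_food_items(
                tables["food_samples"], grouping=block.get("grouping"))
            corrected = iso.apply_discrimination(summary, factors)
            biplot = iso.build_isoscape(tables["segments"], corrected)
            _write(biplot, outdir / "isoscape.csv", manifest, "isoscape")
            if block.get("figure"):
                fig = iso.plot_isoscape(biplot,
                                        outdir / str(block["figure"]))
                manifest.outputs["isoscape_figure"] = str(
                    outdir / str(block["figure"]))
            manifest.stages.append(stage)

        # -- drivers --------------------------------------------------
        if "drivers" in cfg:
            stage = "drivers"
            if "covariates" not in tables:
                raise DataError(
                    "drivers stage enabled but no covariate table supplied"
                )
            block = cfg.get("drivers", {})
            responses = block.get("responses",
                                  {"NSI": "identity", "CSI": "auto"})
            wide = si_res.pivot("SI").reset_index()
            merged = wide.merge(tables["covariates"], on="individual_id")
            drv_seed = (None if seed is None
                        else seed + _STAGE_SEED["drivers"])
            for resp, transform in responses.items():
                if resp not in merged.columns:
                    manifest.warnings.append(
                        f"drivers: response {resp} not available; skipped")
                    continue
                auto = transform == "auto"
                sel = drv.DriverSelection.from_dataframe(
                    merged, response=resp,
                    terms=tuple(block.get("terms", drv.DEFAULT_TERMS)),
                    interactions=tuple(
                        tuple(ix) for ix in
                        block.get("interactions", drv.DEFAULT_INTERACTIONS)
                    ),
                    transform="identity" if auto else transform,
                    delta_support=float(block.get("delta_support", 2.0)),
                )
                res = sel.fit(
                    check_normality=True, auto_log=auto,
                    n_sim=int(block.get("n_sim", 500)), seed=drv_seed,
                )
                if sel.n_dropped:
                    manifest.warnings.append(
                        f"drivers[{resp}]: dropped {sel.n_dropped} row(s) "
                        f"with missing data (n={res.top.n})")
                _write(res.frame, outdir / f"model_table_{resp}.csv",
                       manifest, f"model_table_{resp}")
            manifest.stages.append(stage)

    except ConfigError:
        raise
    except Exception as exc:
        raise type(exc)(f"stage {stage!r} failed: {exc}") from exc

    manifest.to_json(outdir / "manifest.json")
    manifest.outputs["manifest"] = str(outdir / "manifest.json")
    return manifest


def _as_date(value) -> date:
    if isinstance(value, date) and not isinstance(value, datetime):
        return value
    if isinstance(value, datetime):
        return value.date()
    return date.fromisoformat(str(value))


def _standards_from_run(run: pd.DataFrame):
    """Extract USGS40/USGS41a readings from a raw run table whose
    ``sample_id`` column names the standards."""
    standards = []
    for std in (iio.USGS40, iio.USGS41A):
        rows = run[run["sample_id"] == std.name]
        if rows.empty:
            raise DataError(f"normalize: no readings for {std.name} in run")
        readings = {
            el: grp["raw_value"].tolist()
            for el, grp in rows.groupby("element")
        }
        standards.append((std, readings))
    return standards
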