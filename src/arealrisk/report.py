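"""Pipeline driver and analysis deliverables.

Runs the full chain — aggregate events, internal standardization, SIR,
one MCMC fit per requested spatial family, model selection, relative
risk / exceedance export — from a single validated configuration, and
writes every artifact with a content hash into a manifest so a run is
reproducible and auditable end to end.

Artifacts are data files (CSV / GeoJSON / JSON), not styled figures:
a coefficient table in the familiar covariate-rows x model-columns
layout with criteria footer rows, per-cell SIR/RR/exceedance tables,
and a choropleth-ready GeoJSON when geometry is available.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import mapping as _shapely_mapping
from shapely.geometry.base import BaseGeometry

from . import standardize as std
from .inference import ModelSpec, exceedance, fit, fitted_rr, rr_covariates
from .lattice import (
    Lattice,
    build_adjacency,
    grid_lattice,
    read_adjacency_csv,
    read_geojson_areas,
)
from .selection import compare
from .synthetic import (
    HOUSTON_COVARIATES,
    TruthSpec,
    simulate_counts,
    simulate_covariates,
)

__all__ = ["RunConfig", "run_pipeline", "export_surfaces", "PipelineError"]

_FAMILIES = ("bym", "besag_proper", "leroux", "iid", "none")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    ``lattice`` selects exactly one graph source (``grid``,
    ``adjacency_csv`` or ``geojson``); ``data`` selects either
    event/panel CSV inputs or the built-in synthetic scenario.
    """

    seed: int
    years: list
    output_dir: str
    lattice: dict
    data: dict
    families: list
    covariates: list
    interaction: bool = True
    mcmc: dict = field(default_factory=lambda: {"chains": 2, "iters": 1500})
    exceedance_threshold: float = 1.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base: Path | None = None) -> "RunConfig":
        errors = []
        for key in ("seed", "years", "output_dir", "lattice", "data", "families"):
            if key not in raw:
                errors.append(f"missing required key {key!r}")
        if errors:
            raise ValueError("invalid config: " + "; ".join(errors))
        years = list(raw["years"])
        if years != list(range(years[0], years[0] + len(years))):
            errors.append("years must form a consecutive range")
        for fam in raw["families"]:
            if fam not in _FAMILIES:
                errors.append(f"unknown spatial family {fam!r}")
        lat = raw["lattice"]
        if sum(k in lat for k in ("grid", "adjacency_csv", "geojson")) != 1:
            errors.append(
                "lattice must specify exactly one of grid/adjacency_csv/geojson"
            )
        data = raw["data"]
        if not (data.get("synthetic") or "events_csv" in data or "panel_csv" in data):
            errors.append("data must give events_csv, panel_csv, or synthetic: true")
        # resolve and check paths relative to the config file
        base = Path(".") if base is None else base
        for section, key in (
            ("lattice", "adjacency_csv"), ("lattice", "geojson"),
            ("data", "events_csv"), ("data", "panel_csv"),
            ("data", "covariates_csv"),
        ):
            val = raw[section].get(key)
            if val is not None:
                p = Path(val) if Path(val).is_absolute() else base / val
                if not p.exists():
                    errors.append(f"{section}.{key}: path {p} does not exist")
                raw[section][key] = str(p)
        if errors:
            raise ValueError("invalid config: " + "; ".join(errors))
        return cls(
            seed=int(raw["seed"]),
            years=years,
            output_dir=str(raw["output_dir"]),
            lattice=lat,
            data=data,
            families=list(raw["families"]),
            covariates=list(raw.get("covariates", [])),
            interaction=bool(raw.get("interaction", True)),
            mcmc=dict(raw.get("mcmc", {"chains": 2, "iters": 1500})),
            exceedance_threshold=float(raw.get("exceedance_threshold", 1.0)),
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _build_lattice(cfg: RunConfig):
    lat_cfg = cfg.lattice
    geometry = None
    if "grid" in lat_cfg:
        g = lat_cfg["grid"]
        lattice = grid_lattice(
            int(g["rows"]), int(g["cols"]), g.get("contiguity", "rook")
        )
    elif "adjacency_csv" in lat_cfg:
        lattice = read_adjacency_csv(lat_cfg["adjacency_csv"])
    else:
        polys = read_geojson_areas(
            lat_cfg["geojson"], lat_cfg.get("id_property", "area_id")
        )
        lattice = build_adjacency(polys, lat_cfg.get("contiguity", "queen"))
        geometry = polys
    return lattice, geometry


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and return the artifact manifest.

    The manifest maps artifact names to relative paths and SHA-256
    content hashes.  Any stage failure raises :class:`PipelineError`
    naming the stage; artifacts already written are kept alongside a
    ``FAILED`` marker file.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "files": {}}

    def record(name: str, path: Path):
        manifest["files"][name] = {
            "path": str(path.relative_to(out)),
            "sha256": _sha256(path),
        }

    stage = "validate"
    try:
        for fam in config.families:
            if fam not in _FAMILIES:
                raise ValueError(f"unknown spatial family {fam!r}")

        stage = "lattice"
        lattice, geometry = _build_lattice(config)

        stage = "data"
        if config.data.get("synthetic"):
            covariates = simulate_covariates(
                lattice, config.years, HOUSTON_COVARIATES, seed=config.seed
            )
            truth_kwargs = config.data.get("truth", {})
            panel, truth = simulate_counts(
                lattice, covariates, TruthSpec(**truth_kwargs), seed=config.seed + 1
            )
        else:
            truth = None
            if "events_csv" in config.data:
                events = std.read_events_csv(config.data["events_csv"])
                panel, n_excl = std.aggregate_events(events, lattice, config.years)
                manifest["excluded_events"] = n_excl
                pops = pd.read_csv(
                    config.data["covariates_csv"], dtype={"area_id": str}
                )
                panel = panel.merge(
                    pops[["area_id", "year", "population"]].rename(
                        columns={"population": "N"}
                    ),
                    on=["area_id", "year"],
                )
            else:
                panel = std.read_panel_csv(config.data["panel_csv"])
            if "covariates_csv" in config.data:
                covariates = pd.read_csv(
                    config.data["covariates_csv"], dtype={"area_id": str}
                )
            else:
                covariates = None

        stage = "standardize"
        panel = std.expected_counts(panel)
        panel = std.sir(panel)
        panel_path = out / "panel.csv"
        std.write_panel_csv(panel, panel_path)
        record("panel", panel_path)

        stage = "fit"
        mcmc = dict(config.mcmc)
        fits = {}
        for fam in config.families:
            spec = ModelSpec(
                spatial_family=fam,
                interaction=config.interaction,
                covariates=tuple(config.covariates),
            )
            post = fit(
                panel, covariates, lattice, spec,
                chains=int(mcmc.get("chains", 2)),
                iters=int(mcmc.get("iters", 1500)),
                warmup=mcmc.get("warmup"),
                thin=int(mcmc.get("thin", 1)),
                seed=config.seed,
            )
            fits[fam] = post
            fam_dir = out / f"fit_{fam}"
            fam_dir.mkdir(exist_ok=True)
            if config.covariates:
                rr = rr_covariates(post)
                rr_path = fam_dir / "rr_covariates.csv"
                rr.to_csv(rr_path, index=False)
                record(f"rr_covariates_{fam}", rr_path)
            diag_path = fam_dir / "diagnostics.json"
            diag_path.write_text(
                json.dumps(post.diagnostics, indent=2, sort_keys=True)
            )
            record(f"diagnostics_{fam}", diag_path)

        stage = "selection"
        report = compare(fits)
        sel_path = out / "selection.csv"
        report.table.to_csv(sel_path, index=False)
        record("selection", sel_path)
        best = report.best["dic"]
        manifest["best_model"] = {"by": "dic", "model": best}

        stage = "summaries"
        post = fits[best]
        fitted = fitted_rr(post)
        fitted_path = out / "fitted_rr.csv"
        fitted.to_csv(fitted_path, index=False)
        record("fitted_rr", fitted_path)
        exc = exceedance(post, config.exceedance_threshold)
        exc_path = out / "exceedance.csv"
        exc.to_csv(exc_path, index=False)
        record("exceedance", exc_path)
        if config.covariates:
            t2_path = out / "table2.csv"
            _coefficient_table(fits, config.covariates).to_csv(t2_path, index=False)
            record("coefficient_table", t2_path)

        stage = "surfaces"
        if geometry is not None:
            gj = export_surfaces(panel, fitted, exc, geometry)
            gj_path = out / "surfaces.geojson"
            gj_path.write_text(json.dumps(gj, sort_keys=True))
            record("surfaces", gj_path)

        manifest_path = out / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return manifest
    except Exception as exc_:
        (out / "FAILED").write_text(f"stage: {stage}\ncause: {exc_}\n")
        raise PipelineError(stage, exc_) from exc_


def _coefficient_table(fits: dict, covariates: list) -> pd.DataFrame:
    """Covariate rows (RR with 95% CI) plus criteria footer per model."""
    from .selection import cpo_score, dic, loglik_matrix, waic

    cols: dict = {"term": list(covariates) + ["WAIC", "DIC", "CPO"]}
    for name, post in fits.items():
        rr = rr_covariates(post).set_index("covariate")
        ll = loglik_matrix(post)
        entries = [
            f"{rr.loc[c, 'RR']:.2f} ({rr.loc[c, 'RR_lo']:.2f}, {rr.loc[c, 'RR_hi']:.2f})"
            for c in covariates
        ]
        entries.append(f"{waic(ll)[0]:.0f}")
        entries.append(f"{dic(post)[0]:.0f}")
        entries.append(f"{cpo_score(ll)[0]:.0f}")
        cols[name] = entries
    return pd.DataFrame(cols)


def export_surfaces(
    panel: pd.DataFrame,
    fitted: pd.DataFrame,
    exceedance_table: pd.DataFrame,
    geometry: dict,
) -> dict:
    """Choropleth-ready GeoJSON with year-indexed surfaces per area.

    Each feature carries properties ``SIR_<year>``, ``RR_<year>`` and
    ``PexcRR1_<year>`` rounded to 4 decimals.  Every area in the panel
    must have a geometry.
    """
    ids = list(dict.fromkeys(panel["area_id"].astype(str)))
    missing = [a for a in ids if a not in {str(k) for k in geometry}]
    if missing:
        raise ValueError(f"areas without geometry: {missing}")
    geo = {str(k): v for k, v in geometry.items()}
    sir_ix = panel.set_index(["area_id", "year"])["SIR"]
    rr_ix = fitted.set_index(["area_id", "year"])["RR"]
    exc_ix = exceedance_table.set_index(["area_id", "year"])["P_exceed"]
    years = sorted(panel["year"].unique())
    features = []
    for a in ids:
        props = {"area_id": a}
        for t in years:
            props[f"SIR_{t}"] = round(float(sir_ix.loc[(a, t)]), 4)
            props[f"RR_{t}"] = round(float(rr_ix.loc[(a, t)]), 4)
            props[f"PexcRR1_{t}"] = round(float(exc_ix.loc[(a, t)]), 4)
        g = geo[a]
        gdict = _shapely_mapping(g) if isinstance(g, BaseGeometry) else g
        gdict = json.loads(json.dumps(gdict))  # tuples -> JSON-native lists
        features.append(
            {"type": "Feature", "geometry": gdict, "properties": props}
        )
    return {"type": "FeatureCollection", "features": features}
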