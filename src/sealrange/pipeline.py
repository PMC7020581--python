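"""Configuration-driven orchestration of the full analysis.

Stages — simulate, filter, hmm, hulls, isopleths, classify, budgets,
stats — each read the previous stage's CSV outputs from the output
directory, write their own, and record a manifest entry (parameter hash,
input hashes, seed, timestamp).  Re-running a stage whose inputs and
parameters are unchanged is a no-op, so a pipeline can be resumed after
interruption.  Two full runs with the same configuration and seed produce
byte-identical CSVs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import hull_behaviour as hb
from . import movement_hmm as mh
from . import stats_models as sm
from . import synth_forager as sf
from . import tlocoh_core as tl
from . import track_io as tio

__all__ = ["PipelineConfig", "Pipeline", "STAGES", "DependencyError"]

logger = logging.getLogger(__name__)

STAGES = ["simulate", "filter", "hmm", "hulls", "isopleths", "classify", "budgets", "stats"]

_DEPS = {
    "simulate": [],
    "filter": ["simulate"],
    "hmm": ["filter"],
    "hulls": ["hmm"],
    "isopleths": ["filter"],
    "classify": ["hulls"],
    "budgets": ["classify"],
    "stats": ["isopleths"],
}

_OUTPUTS = {
    "simulate": ["fixes.csv", "metadata.csv", "truth.csv", "bathymetry.asc"],
    "filter": ["filtered_fixes.csv", "filter_report.json"],
    "hmm": ["hmm_fixes.csv", "hmm_params.yaml"],
    "hulls": ["hull_metrics.csv"],
    "isopleths": ["isopleth_areas.csv", "isopleths.geojson"],
    "classify": ["classified_hulls.csv", "classification_thresholds.json", "classified_fixes.geojson"],
    "budgets": ["time_budget.csv", "time_budget_summary.csv"],
    "stats": ["selection_home_range.csv", "selection_core_area.csv", "selection_mass_gain.csv"],
}


class DependencyError(RuntimeError):
    """An upstream stage's outputs are missing."""


@dataclass
class PipelineConfig:
    """Everything a full run needs; loadable from YAML."""

    outdir: str = "sealrange_out"
    seed: int = 0
    # simulate
    n_males: int = 3
    n_females: int = 3
    start: str = "2014-06-01"
    end: str = "2014-12-04"
    fix_interval_min: float = 15.0
    colony: tuple[float, float] = sf.DEFAULT_COLONY
    # filter
    min_sats: int = 5
    max_residual: float = 30.0
    max_speed_kmh: float = 10.0
    # hmm
    gap_threshold_h: float = 2.0
    hmm_tol: float = 1e-6
    hmm_max_iter: int = 500
    # t-locoh
    s: float = 0.05
    k: int = 15
    method: str = "a"   # adaptive hulls (budget a_k15) for final isopleths
    ivg_h: float = 12.0
    levels: tuple[float, float] = (0.30, 0.95)
    min_season_fixes: int = 100
    # classification
    colony_exclusion_km: float = 15.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.colony = tuple(cfg.colony)  # YAML lists -> tuple
        cfg.levels = tuple(cfg.levels)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def tlocoh(self) -> tl.TLoCoHConfig:
        return tl.TLoCoHConfig(
            s=self.s, k=self.k, method=self.method, ivg_h=self.ivg_h,
            levels=tuple(self.levels), min_season_fixes=self.min_season_fixes,
        )


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


class Pipeline:
    """Stage runner bound to one config and output directory."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.outdir / "manifest.json"
        self.manifest: dict = {}
        if self.manifest_path.exists():
            self.manifest = json.loads(self.manifest_path.read_text())

    # -- manifest bookkeeping ------------------------------------------------

    def _params_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self.config), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def _inputs_hash(self, stage: str) -> str:
        parts = []
        for dep in _DEPS[stage]:
            for name in _OUTPUTS[dep]:
                p = self.outdir / name
                if p.exists():
                    parts.append(f"{name}:{_hash_file(p)}")
        return hashlib.sha256("|".join(parts).encode()).hexdigest()[:16]

    def _check_deps(self, stage: str) -> None:
        for dep in _DEPS[stage]:
            missing = [n for n in _OUTPUTS[dep] if not (self.outdir / n).exists()]
            if missing:
                raise DependencyError(
                    f"stage '{stage}' requires outputs of stage '{dep}' "
                    f"(missing: {', '.join(missing)}); run '{dep}' first"
                )

    def _up_to_date(self, stage: str) -> bool:
        entry = self.manifest.get(stage)
        if entry is None:
            return False
        if entry["params"] != self._params_hash() or entry["inputs"] != self._inputs_hash(stage):
            return False
        return all((self.outdir / n).exists() for n in _OUTPUTS[stage])

    def _record(self, stage: str) -> None:
        self.manifest[stage] = {
            "params": self._params_hash(),
            "inputs": self._inputs_hash(stage),
            "seed": self.config.seed,
            "timestamp": datetime.now(timezone.utc).isoformat(),
            "outputs": _OUTPUTS[stage],
        }
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2))

    def run_stage(self, stage: str, force: bool = False) -> bool:
        """Run one stage; returns True if work was done, False if skipped."""
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}; stages are {STAGES}")
        self._check_deps(stage)
        if not force and self._up_to_date(stage):
            logger.info("stage %s up to date; skipping", stage)
            return False
        logger.info("running stage %s", stage)
        getattr(self, f"_stage_{stage}")()
        self._record(stage)
        return True

    def run_all(self, force: bool = False) -> None:
        for stage in STAGES:
            self.run_stage(stage, force=force)

    # -- stages --------------------------------------------------------------

    def _stage_simulate(self) -> None:
        cfg = self.config
        sim = sf.SimConfig(
            seed=cfg.seed, colony=cfg.colony, start=cfg.start, end=cfg.end,
            fix_interval_min=cfg.fix_interval_min,
        )
        tracks = sf.simulate_population(sim, cfg.n_males, cfg.n_females, inject=True)
        sf.write_population_csvs(tracks, self.outdir)
        patches = []
        for tr in tracks:
            patches.extend(tr.meta.get("patches", []))
        seen, uniq = set(), []
        for p in patches:
            key = (round(p.lon, 6), round(p.lat, 6))
            if key not in seen:
                seen.add(key)
                uniq.append(p)
        grid = sf.make_bathymetry(uniq, colony=cfg.colony, seed=cfg.seed)
        grid.to_ascii(self.outdir / "bathymetry.asc")

    def _load_tracks(self, name: str) -> list[tio.Track]:
        return tio.read_fixes(self.outdir / name, self.outdir / "metadata.csv")

    def _stage_filter(self) -> None:
        cfg = self.config
        grid = tio.BathymetryGrid.from_ascii(self.outdir / "bathymetry.asc")
        tracks = self._load_tracks("fixes.csv")
        frames, report = [], {}
        for tr in tracks:
            tr = tio.project(tr, cfg.colony)
            filt, rep = tio.filter_fixes(
                tr, min_sats=cfg.min_sats, max_residual=cfg.max_residual, max_speed=cfg.max_speed_kmh
            )
            filt = tio.annotate_track(filt, cfg.colony, bathymetry=None)
            try:
                filt.fixes["depth"] = grid.lookup(
                    filt.fixes["lon"].to_numpy(), filt.fixes["lat"].to_numpy()
                )
            except ValueError:
                filt.fixes["depth"] = np.nan
            df = filt.fixes.copy()
            if "animal_id" not in df.columns:
                df.insert(0, "animal_id", tr.animal_id)
            frames.append(df)
            report[tr.animal_id] = {
                "n_input": rep.n_input,
                "removed_sats": rep.n_removed_sats,
                "removed_residual": rep.n_removed_residual,
                "removed_speed": rep.n_removed_speed,
                "fraction_removed": rep.fraction_removed,
            }
        out = pd.concat(frames, ignore_index=True)
        out.to_csv(self.outdir / "filtered_fixes.csv", index=False)
        (self.outdir / "filter_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))

    def _filtered_tracks(self, name: str = "filtered_fixes.csv") -> list[tio.Track]:
        df = pd.read_csv(self.outdir / name, parse_dates=["timestamp"])
        meta = pd.read_csv(self.outdir / "metadata.csv")
        tracks = []
        for animal_id, sub in df.groupby("animal_id", sort=True):
            sub = sub.reset_index(drop=True)
            row = meta[meta["animal_id"] == animal_id]
            tr = tio.Track(
                animal_id=str(animal_id),
                fixes=sub,
                sex=str(row["sex"].iloc[0]) if len(row) else None,
                deployment_mass=float(row["deploy_mass_kg"].iloc[0]) if len(row) else None,
                recapture_mass=float(row["recapture_mass_kg"].iloc[0]) if len(row) else None,
            )
            tracks.append(tr)
        return tracks

    def _stage_hmm(self) -> None:
        cfg = self.config
        tracks = self._filtered_tracks()
        frames, params = [], {}
        for tr in tracks:
            series = mh.compute_speeds(tr, gap_threshold_h=cfg.gap_threshold_h)
            if len(series) < 50:
                tr.fixes["pars"] = np.nan
            else:
                fit = mh.fit_hmm2(series, tol=cfg.hmm_tol, max_iter=cfg.hmm_max_iter, seed=cfg.seed)
                pars = mh.posterior_pars(fit, series, accept_unconverged=True)
                tr = mh.attach_pars(tr, series, pars)
                params[tr.animal_id] = fit.to_dict()
            df = tr.fixes.copy()
            if "animal_id" not in df.columns:
                df.insert(0, "animal_id", tr.animal_id)
            frames.append(df)
        pd.concat(frames, ignore_index=True).to_csv(self.outdir / "hmm_fixes.csv", index=False)
        with open(self.outdir / "hmm_params.yaml", "w") as fh:
            yaml.safe_dump(params, fh, sort_keys=True)

    def _stage_hulls(self) -> None:
        cfg = self.config
        tl_cfg = self.config.tlocoh()
        tracks = self._filtered_tracks("hmm_fixes.csv")
        tables = []
        for tr in tracks:
            for season, sub in tl._season_subtracks(tr).items():
                if len(sub.fixes) < cfg.min_season_fixes:
                    continue
                hulls = tl.build_hulls(sub, tl_cfg)
                hb.compute_enclosed_points(hulls, sub)
                hb.compute_visits(hulls, sub, ivg_h=cfg.ivg_h)
                pars = sub.fixes["pars"].to_numpy() if "pars" in sub.fixes.columns else None
                table = hb.hull_metrics_table(hulls, sub, pars=pars, with_eccentricity=True)
                tables.append(table)
        if not tables:
            raise RuntimeError("no animal-season had enough fixes to build hulls")
        pd.concat(tables, ignore_index=True).to_csv(self.outdir / "hull_metrics.csv", index=False)

    def _stage_isopleths(self) -> None:
        from .exports import polygon_to_geojson_feature, write_geojson

        cfg = self.config
        tl_cfg = cfg.tlocoh()
        tracks = self._filtered_tracks()
        rows, features = [], []
        for tr in tracks:
            hr = tl.home_range_95(tr, tl_cfg)
            core = tl.core_area_30(tr, tl_cfg)
            for kind, result in (("home_range_95", hr), ("core_area_30", core)):
                for season, entry in result.items():
                    rows.append({
                        "animal_id": tr.animal_id,
                        "sex": tr.sex,
                        "season": season.value,
                        "kind": kind,
                        "area_km2": entry.entry.area_km2 if entry.entry else np.nan,
                        "achieved_fraction": entry.entry.achieved_fraction if entry.entry else np.nan,
                        "n_fixes": entry.n_fixes,
                        "insufficient_data": entry.insufficient,
                        "deploy_mass_kg": tr.deployment_mass,
                        "recapture_mass_kg": tr.recapture_mass,
                    })
                    if entry.entry is not None:
                        features.append(polygon_to_geojson_feature(
                            entry.entry.polygon, cfg.colony,
                            {"animal_id": tr.animal_id, "season": season.value, "kind": kind},
                        ))
        pd.DataFrame(rows).to_csv(self.outdir / "isopleth_areas.csv", index=False)
        write_geojson(features, self.outdir / "isopleths.geojson")

    def _stage_classify(self) -> None:
        from .exports import write_geojson

        cfg = self.config
        metrics = pd.read_csv(self.outdir / "hull_metrics.csv", parse_dates=["parent_time"])
        retained = metrics[metrics["dist_colony"] >= cfg.colony_exclusion_km]
        cls = hb.classify_categories(retained)
        cls.table.to_csv(self.outdir / "classified_hulls.csv", index=False)
        (self.outdir / "classification_thresholds.json").write_text(json.dumps({
            "q1_nsv_km2": cls.q1,
            "q3_nsv_km2": cls.q3,
            "band_medians_mnlv_km2": cls.band_medians,
            "colony_exclusion_km": cfg.colony_exclusion_km,
        }, indent=2, sort_keys=True))
        # classified parent fixes as colour-banded points (1-2 / 3-4 / 5-6)
        fixes = pd.read_csv(self.outdir / "filtered_fixes.csv", parse_dates=["timestamp"])
        merged = cls.table.merge(
            fixes[["animal_id", "timestamp", "lon", "lat"]],
            left_on=["animal_id", "parent_time"],
            right_on=["animal_id", "timestamp"],
            how="inner",
        )
        band_colour = {1: "darkorange", 2: "darkorange", 3: "green", 4: "green", 5: "blue", 6: "blue"}
        feats = [
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [float(r["lon"]), float(r["lat"])]},
                "properties": {
                    "animal_id": r["animal_id"],
                    "category": int(r["category"]),
                    "colour": band_colour[int(r["category"])],
                },
            }
            for _, r in merged.iterrows()
        ]
        write_geojson(feats, self.outdir / "classified_fixes.geojson")

    def _stage_budgets(self) -> None:
        classified = pd.read_csv(self.outdir / "classified_hulls.csv")
        budget = hb.time_budget(classified)
        budget.proportions.to_csv(self.outdir / "time_budget.csv", index=False)
        budget.summary.to_csv(self.outdir / "time_budget_summary.csv", index=False)

    def _stage_stats(self) -> None:
        areas = pd.read_csv(self.outdir / "isopleth_areas.csv")
        areas = areas[~areas["insufficient_data"] & np.isfinite(areas["area_km2"])]
        out = {}
        for kind, fname in (
            ("home_range_95", "selection_home_range.csv"),
            ("core_area_30", "selection_core_area.csv"),
        ):
            sub = areas[areas["kind"] == kind].copy()
            sub["log_area"] = np.log10(sub["area_km2"].clip(lower=1e-6))
            sub["Bm"] = (sub["deploy_mass_kg"] - sub["deploy_mass_kg"].mean())
            sub = sub.rename(columns={"season": "Sn", "sex": "Sx"})
            try:
                models = sm.fit_candidates(
                    sub, sm.HOME_RANGE_CANDIDATES, response="log_area", group="animal_id"
                )
                table = sm.build_selection_table(models)
                table.to_csv(self.outdir / fname)
                out[kind] = table
            except ValueError:
                pd.DataFrame().to_csv(self.outdir / fname, index=False)
        # mass gain ~ home-range size + sex (per-animal, summer+fall mean area)
        meta = pd.read_csv(self.outdir / "metadata.csv")
        hr = areas[areas["kind"] == "home_range_95"].groupby("animal_id")["area_km2"].mean()
        rows = []
        for _, m in meta.iterrows():
            if m["animal_id"] not in hr.index or not np.isfinite(m["recapture_mass_kg"]):
                continue
            days = (pd.Timestamp(m["recapture_date"]) - pd.Timestamp(m["deploy_date"])).days
            if days <= 0:
                continue
            rows.append({
                "animal_id": m["animal_id"],
                "Sx": m["sex"],
                "Hr": float(hr.loc[m["animal_id"]]),
                "gain": sm.mass_gain_rate(m["deploy_mass_kg"], m["recapture_mass_kg"], days),
            })
        gain = pd.DataFrame(rows)
        specs = {"Sx": "Sx", "Hr + Sx": "Hr + Sx", "Hr + Sx + Hr*Sx": "Hr + Sx + Hr:Sx", "~": "1", "Hr": "Hr"}
        if len(gain) >= 8:
            models = sm.fit_candidates(gain, specs, response="gain", group=None)
            sm.build_selection_table(models).to_csv(self.outdir / "selection_mass_gain.csv")
        else:
            pd.DataFrame().to_csv(self.outdir / "selection_mass_gain.csv", index=False)
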