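"""Config-driven orchestration of the full analysis.

Stage order mirrors the analysis workflow: simulate (or load) ->
preprocess -> encounters -> home ranges -> habitat selection ->
activity -> report.  Every random step is seeded from the config seed;
rerunning an identical config reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import activity as act
from . import dyads as dy
from . import gamm
from . import homerange as hr
from . import issa as ssa
from . import scenarios, synthetic, tracking

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    scenario: str | None = "lag1-effect"
    fixes_path: str | None = None
    habitat_path: str | None = None
    temperature_path: str | None = None
    sun_path: str | None = None
    exclusions_path: str | None = None
    outdir: str = "thermoguild_out"
    seed: int = 0
    encounter_threshold: float = 400.0
    encounter_threshold_grid: tuple = (400.0, 600.0, 800.0, 1000.0)
    exclusion_floor: float = 1000.0
    isopleth_level: float = 0.95
    bbmm_delta: float = 20.0
    bbmm_cellsize: float = 150.0
    n_available: int = 150
    max_strata_per_individual: int = 250
    gamm_maxfev: int = 50
    activity_maxfev: int = 30
    activity_k_sun: int = 6
    activity_k_tensor: tuple = (6, 4)
    overlap_draws: int = 500
    both_directions: bool = False

    def __post_init__(self) -> None:
        for v in (self.encounter_threshold, self.exclusion_floor):
            if v <= 0:
                raise ValueError("thresholds must be positive")
        if self.scenario is None and not (
            self.fixes_path and self.habitat_path and self.temperature_path and self.sun_path
        ):
            raise ValueError("either a scenario or all four input paths are required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


class Pipeline:
    """Holds intermediate state between stages; see :func:`run_pipeline`."""

    def __init__(self, config: PipelineConfig):
        self.cfg = config
        self.out = Path(config.outdir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.report: dict = {"seed": config.seed, "scenario": config.scenario,
                             "row_counts": {}}

    # -- stage: simulate / load -------------------------------------------
    def simulate(self) -> None:
        cfg = self.cfg
        if cfg.scenario is not None:
            wcfg, agents = scenarios.scenario_config(cfg.scenario, seed=cfg.seed)
            env = synthetic.generate_environment(wcfg)
            self.habitat, self.temperature_raw, self.sun = env
            self.fixes, self.ledger = synthetic.simulate_dyad_tracks(wcfg, agents, env)
            synthetic.write_world(
                self.out, self.habitat, self.temperature_raw, self.sun,
                self.fixes, self.ledger,
            )
        else:
            from .raster import Raster

            self.fixes = tracking.read_fixes(cfg.fixes_path)
            self.habitat = Raster.read_ascii(cfg.habitat_path)
            self.temperature_raw = tracking.read_temperature(cfg.temperature_path)
            self.sun = tracking.read_sun_table(cfg.sun_path)
            self.ledger = None
        self.report["row_counts"]["fixes_raw"] = int(len(self.fixes))

    # -- stage: preprocess -------------------------------------------------
    def preprocess(self) -> None:
        cfg = self.cfg
        fixes = tracking.validate_fixes(self.fixes)
        if "role" not in fixes or not (fixes["role"] == "dominant").any():
            raise StageError("preprocess", "no dominant-species data in fix table")
        if cfg.exclusions_path:
            fixes = tracking.apply_exclusions(
                fixes, tracking.read_exclusions(cfg.exclusions_path)
            )
        # pseudoreplication filter within dominant social groups
        dom = fixes[fixes["role"] == "dominant"]
        retained = tracking.filter_pseudoreplicates(dom, seed=cfg.seed)
        removed = set(dom["individual_id"]) - set(retained)
        if removed:
            logger.info("pseudoreplication filter removed %s", sorted(removed))
            fixes = fixes[~fixes["individual_id"].isin(removed)]
        self.fixes = fixes.reset_index(drop=True)
        self.temperature = tracking.prepare_temperatures(self.temperature_raw)
        self.hourly = tracking.regularize_hourly(self.fixes)
        meta = self.fixes.groupby("individual_id")[["species", "role", "group_id"]].first()
        self.hourly = self.hourly.drop(
            columns=[c for c in ("species", "role", "group_id") if c in self.hourly],
        ).join(meta, on="individual_id")
        self.activity_table = tracking.classify_activity(self.hourly)
        self.report["row_counts"].update(
            fixes_after_filters=int(len(self.fixes)),
            hourly=int(len(self.hourly)),
            activity=int(len(self.activity_table)),
        )
        self.seasons = sorted(self.temperature["season"].unique())
        # species-season scaling metadata for fold-change machinery
        self._scalings = {}
        for season in self.seasons:
            t = self.temperature[self.temperature["season"] == season]["t_max"]
            self._scalings[season] = {
                "t_max": t.tolist(),
                "mean": float(t.mean()),
                "sd": float(t.std(ddof=1)),
            }

    # -- stage: encounters -------------------------------------------------
    def encounters(self) -> None:
        cfg = self.cfg
        dyad_days = dy.build_all_dyads(
            self.fixes, self.temperature, encounter_threshold=cfg.encounter_threshold
        )
        if dyad_days.empty:
            raise StageError("encounters", "no dyad-days could be formed")
        dyad_days = dy.apply_dyad_exclusion(dyad_days, cfg.exclusion_floor)
        self.dyad_days = dyad_days
        _write_csv(dyad_days, self.out / "dyad_days.csv")
        _write_csv(dy.dyad_summary(dyad_days), self.out / "dyad_summary.csv")
        self.report["row_counts"]["dyad_days"] = int(len(dyad_days))

        # sensitivity grid: encounter-day sets must nest across thresholds
        grid_rows = []
        prev_sets: dict = {}
        nested = True
        for thr in sorted(cfg.encounter_threshold_grid):
            enc = dyad_days[dyad_days["min_distance"] <= thr]
            for (pair, season), sub in enc.groupby(["species_pair", "season"]):
                grid_rows.append(
                    {"species_pair": pair, "season": season,
                     "threshold_m": thr, "n_encounter_days": int(len(sub))}
                )
            eset = set(zip(enc["dyad_id"], enc["date"]))
            for key, s_prev in prev_sets.items():
                pass
            if prev_sets.get("all") is not None and not prev_sets["all"] <= eset:
                nested = False
            prev_sets["all"] = eset
        self.report["threshold_sensitivity"] = {
            "grid": grid_rows, "nested": bool(nested),
        }

        results: dict = {}
        self.encounter_fits: dict = {}
        for (pair, season), sub in dyad_days.groupby(["species_pair", "season"]):
            key = f"{pair}|{season}"
            entry: dict = {
                "n_dyad_days": int(len(sub)),
                "n_encounters": int(sub["encounter"].sum()),
            }
            try:
                fit = gamm.fit_encounter_model(
                    sub, maxfev=cfg.gamm_maxfev, scaling=self._scalings[season]
                )
                self.encounter_fits[key] = fit
                entry["model"] = fit.summary()
                entry["diagnostics"] = gamm.diagnostics(fit)
                entry["fold_changes"] = _fold_change_table(fit)
            except gamm.NoContrastError as e:
                entry["model"] = None
                entry["note"] = str(e)
            results[key] = entry
        self.report["encounters"] = results

    # -- stage: home ranges -------------------------------------------------
    def homerange(self) -> None:
        cfg = self.cfg
        roles = self.hourly.groupby("individual_id")["role"].first()
        dominants = roles[roles == "dominant"].index.tolist()
        subs = roles[roles != "dominant"].index.tolist()
        pairs = [(s, d) for s in subs for d in dominants]
        if cfg.both_directions:
            pairs += [(d, s) for s in subs for d in dominants]
        ud_cache: dict[str, dict] = {}
        prop_rows = []
        for focal_id, comp_id in pairs:
            comp = self.hourly[self.hourly["individual_id"] == comp_id]
            if comp_id not in ud_cache:
                try:
                    s2 = hr.fit_bbmm_sigma(comp, delta=cfg.bbmm_delta)
                except ValueError as e:
                    logger.warning("sigma fit failed for %s: %s", comp_id, e)
                    continue
                ud_cache[comp_id] = hr.rolling_home_ranges(
                    comp, s2, delta=cfg.bbmm_delta, cellsize=cfg.bbmm_cellsize,
                    individual_id=comp_id,
                )
            focal = self.hourly[self.hourly["individual_id"] == focal_id]
            props = hr.rolling_proportion_in_range(
                focal, ud_cache[comp_id], level=cfg.isopleth_level
            )
            if props.empty:
                continue
            props["competitor_id"] = comp_id
            props["focal_role"] = roles[focal_id]
            sp = self.hourly.groupby("individual_id")["species"].first()
            props["species_pair"] = f"{sp[focal_id]}-{sp[comp_id]}"
            prop_rows.append(props)
        if not prop_rows:
            raise StageError("homerange", "no proportion-in-range rows produced")
        props = pd.concat(prop_rows, ignore_index=True)
        tcols = self.temperature.set_index("date")[
            ["season", "z_lag0", "z_lag1", "day_of_year"]
        ]
        props = props.join(tcols, on="date").dropna(subset=["z_lag0", "z_lag1"])
        self.proportions = props
        _write_csv(props, self.out / "proportions.csv")
        self.report["row_counts"]["proportion_days"] = int(len(props))

        results: dict = {}
        self.overlap_fits: dict = {}
        for (pair, season), sub in props.groupby(["species_pair", "season"]):
            key = f"{pair}|{season}"
            entry = {"n_rows": int(len(sub)),
                     "mean_proportion": float(sub["proportion"].mean())}
            try:
                fit = gamm.fit_overlap_model(
                    sub, maxfev=cfg.gamm_maxfev, scaling=self._scalings[season]
                )
                self.overlap_fits[key] = fit
                entry["model"] = fit.summary()
                entry["fold_changes"] = _fold_change_table(fit)
            except gamm.NoContrastError as e:
                entry["model"] = None
                entry["note"] = str(e)
            results[key] = entry
        self.report["spatial_overlap"] = results

    # -- stage: habitat selection -------------------------------------------
    def issa(self) -> None:
        cfg = self.cfg
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
        results: dict = {}
        self.issa_fits: dict = {}
        steps_all = ssa.build_steps(self.hourly)
        tcols = self.temperature.set_index("date")["season"]
        steps_all = steps_all.join(tcols, on="date")
        meta = self.hourly.groupby("individual_id")["species"].first()
        steps_all["species"] = steps_all["individual_id"].map(meta)
        for (species, season), sub in steps_all.groupby(["species", "season"]):
            key = f"{species}|{season}"
            try:
                dists = ssa.fit_step_distributions(sub, species=species, season=season)
            except ValueError as e:
                results[key] = {"note": str(e)}
                continue
            # cap strata per individual for desk-scale runtime
            capped = []
            for ind, s_ind in sub.groupby("individual_id"):
                if len(s_ind) > cfg.max_strata_per_individual:
                    idx = rng.choice(
                        len(s_ind), cfg.max_strata_per_individual, replace=False
                    )
                    s_ind = s_ind.iloc[np.sort(idx)]
                capped.append(s_ind)
            sub_c = pd.concat(capped)
            strata = ssa.build_strata(
                sub_c, dists, self.habitat, self.temperature,
                n_available=cfg.n_available,
                seed=int(np.random.SeedSequence([cfg.seed, 11]).generate_state(1)[0] % 2**31),
            )
            if strata.empty or strata["stratum_id"].nunique() < 2:
                results[key] = {"note": "insufficient strata"}
                continue
            fit = ssa.fit_issa(strata)
            self.issa_fits[key] = fit
            t = self._scalings[season]
            zq = {
                q: (np.quantile(t["t_max"], q) - t["mean"]) / t["sd"]
                for q in (0.2, 0.5, 0.8)
            }
            rss_rows = []
            for habn in ssa.HABITAT_NAMES:
                for qname, q in (("cool", 0.2), ("median", 0.5), ("warm", 0.8)):
                    for lag in ("z_lag0", "z_lag1"):
                        kw = {"z_lag0": 0.0, "z_lag1": 0.0}
                        kw[lag] = zq[q]
                        r = ssa.relative_selection(fit, habn, **kw)
                        rss_rows.append(
                            dict(r, temperature=qname, lag=lag,
                                 species=species, season=season)
                        )
            results[key] = {
                "step_distributions": asdict(dists),
                "n_strata": fit.n_strata,
                "coefficients": fit.summary().round(4).to_dict(orient="index"),
                "rss": rss_rows,
            }
        self.report["issa"] = results
        rss_flat = [
            row for r in results.values() for row in r.get("rss", [])
        ]
        if rss_flat:
            _write_csv(pd.DataFrame(rss_flat), self.out / "rss.csv")

    # -- stage: activity ------------------------------------------------------
    def activity(self) -> None:
        cfg = self.cfg
        tbl = self.activity_table.copy()
        tbl["suntime"] = act.to_sun_time(tbl["hour"], self.sun)
        tbl["date"] = pd.to_datetime(tbl["hour"]).dt.date
        tcols = self.temperature.set_index("date")[
            ["season", "z_lag0", "z_lag1", "day_of_year"]
        ]
        tbl = tbl.join(tcols, on="date").dropna(subset=["z_lag0", "z_lag1"])
        meta = self.hourly.groupby("individual_id")[["species", "role"]].first()
        tbl = tbl.join(meta, on="individual_id")
        self.activity_joined = tbl
        fits: dict = {}
        summaries: dict = {}
        for (species, season), sub in tbl.groupby(["species", "season"]):
            key = f"{species}|{season}"
            try:
                fit = gamm.fit_activity_model(
                    sub,
                    k_sun=cfg.activity_k_sun,
                    k_tensor=tuple(cfg.activity_k_tensor),
                    maxfev=cfg.activity_maxfev,
                    scaling=self._scalings[season],
                )
                fits[key] = fit
                summaries[key] = fit.summary()
            except (gamm.NoContrastError, ValueError) as e:
                summaries[key] = {"note": str(e)}
        self.activity_fits = fits

        roles = tbl.groupby("species")["role"].first()
        dom_species = roles[roles == "dominant"].index.tolist()
        overlaps: dict = {}
        for season in self.seasons:
            for species, role in roles.items():
                if role == "dominant":
                    continue
                for dom in dom_species:
                    ka, kb = f"{species}|{season}", f"{dom}|{season}"
                    if ka not in fits or kb not in fits:
                        continue
                    for lag in ("z_lag0", "z_lag1"):
                        est = act.compare_overlap(
                            fits[ka], fits[kb], lag=lag,
                            n_draws=cfg.overlap_draws,
                            seed=int(
                                np.random.SeedSequence(
                                    [cfg.seed, 13, hash(f"{ka}{kb}{lag}") % 2**31]
                                ).generate_state(1)[0] % 2**31
                            ),
                            species_pair=f"{species}-{dom}",
                            season=season,
                        )
                        overlaps[f"{species}-{dom}|{season}|{lag}"] = {
                            "delta": est.delta,
                            "ci": {str(k): list(v) for k, v in est.ci.items()},
                            "significant_change": est.significant_change,
                        }
        self.report["activity_models"] = summaries
        self.report["activity_overlap"] = overlaps

    # -- stage: report ---------------------------------------------------------
    def write_report(self) -> dict:
        path = self.out / "report.json"
        with open(path, "w") as fh:
            json.dump(self.report, fh, indent=2, default=_json_default)
        fold_rows = []
        for section in ("encounters", "spatial_overlap"):
            for key, entry in self.report.get(section, {}).items():
                for fc in entry.get("fold_changes", []):
                    fold_rows.append(dict(fc, model=section, stratum=key))
        if fold_rows:
            _write_csv(pd.DataFrame(fold_rows), self.out / "fold_changes.csv")
        return self.report


def _fold_change_table(fit: gamm.AdditiveModelFit) -> list[dict]:
    rows = []
    pvals = fit.smooth_p_values()
    for lag in ("z_lag0", "z_lag1"):
        for q in (0.8, 0.9):
            fc = gamm.predict_fold_change(fit, lag=lag, quantile_cmp=q)
            rows.append(
                {
                    "lag": lag,
                    "quantile": q,
                    "ratio": fc.ratio,
                    "ci_low": fc.ci_low,
                    "ci_high": fc.ci_high,
                    "p_smooth": pvals.get(f"s({lag})"),
                }
            )
    return rows


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if hasattr(o, "isoformat"):
        return o.isoformat()
    return str(o)


STAGES = ("simulate", "preprocess", "encounters", "homerange", "issa",
          "activity", "report")


def run_pipeline(config: PipelineConfig, until: str = "report") -> dict:
    """Run stages in order up to ``until`` (inclusive); return the report."""
    if until not in STAGES:
        raise ValueError(f"unknown stage {until!r}; choose from {STAGES}")
    pipe = Pipeline(config)
    methods = {
        "simulate": pipe.simulate,
        "preprocess": pipe.preprocess,
        "encounters": pipe.encounters,
        "homerange": pipe.homerange,
        "issa": pipe.issa,
        "activity": pipe.activity,
        "report": pipe.write_report,
    }
    for stage in STAGES:
        try:
            methods[stage]()
        except StageError:
            raise
        except Exception as e:  # annotate with stage context
            counts = pipe.report.get("row_counts", {})
            raise StageError(stage, f"{e} (row counts so far: {counts})") from e
        if stage == until:
            break
    if until != "report":
        pipe.write_report()
    report = dict(pipe.report)
    report["_pipeline"] = pipe  # handle for callers needing fitted objects
    return report
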