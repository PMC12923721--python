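"""End-to-end orchestration: tables in, report bundle out.

Runs every analysis stage on a study (simulated or read from disk):
nest daily survival, egg mass loss, hatching statistics, hatchling
models, growth-curve selection and growth models, Kaplan-Meier and Cox
survival, and the reproductive-value chain.  Stages degrade
independently — a failure in one is recorded and the rest still run —
and a fixed (config, seed) pair reproduces the bundle byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import growth, io, nest_survival, rv, survival
from . import eggs as eggmod
from .config import StudyConfig
from .simulate import StudyData, simulate_study
from .types import ByGroup, HATCHED, TRAITS

__all__ = ["PipelineConfig", "run_pipeline", "save_bundle"]

log = logging.getLogger("clutchkit")


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs."""

    mode: str = "simulate"  # "simulate" or "files"
    study: StudyConfig = field(default_factory=StudyConfig)
    input_dir: str | None = None
    # laying-period durations enter the nesting period from the
    # literature, not from these data
    lay_days: ByGroup = field(default_factory=lambda: ByGroup(6.5, 8.7))
    hatchling_max_age: float = growth.HATCHLING_MAX_AGE
    growth_max_age: float = growth.GROWTH_MAX_AGE
    survival_window: float = survival.ANALYSIS_WINDOW
    egg_mass_max_age: float = eggmod.MASS_LOSS_MAX_AGE
    yates: bool = False
    diff_baseline: str = "enlarged"
    seed: int | None = None
    out_dir: str | None = None
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.mode not in ("simulate", "files"):
            raise ValueError(f"mode: unknown mode {self.mode!r}")
        if self.mode == "files" and not self.input_dir:
            raise ValueError("input_dir: required in files mode")
        for f in ("hatchling_max_age", "growth_max_age", "survival_window",
                  "egg_mass_max_age"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f}: must be positive")


def _group_maps(data: StudyData):
    groups = {n.nest_id: n.group for n in data.nests}
    lays = {n.nest_id: n.laying_day for n in data.nests}
    return groups, lays


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns a bundle of DataFrames/dicts keyed by stage.

    Keys: data (the study), dsr_models, dsr_by_group, mass_loss,
    hatch_summary, hatch_tests, hatchling_models, growth_selection,
    growth_models, km_curves, cox, s10, rv_table, partial_products,
    row_counts, errors.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    bundle: dict = {"errors": {}}

    if config.mode == "simulate":
        seed = config.seed if config.seed is not None else config.study.seed
        log.info("simulating study with seed %d", seed)
        data = simulate_study(config.study, seed=seed)
    else:
        log.info("loading study from %s", config.input_dir)
        data = io.load_study(config.input_dir)
    bundle["data"] = data
    groups, lays = _group_maps(data)
    bundle["row_counts"] = {
        "nests": len(data.nests), "eggs": len(data.eggs),
        "chick_captures": len(data.chicks), "fates": len(data.fates),
    }

    def stage(name, fn):
        try:
            bundle[name] = fn()
        except Exception as exc:  # stages degrade independently
            log.warning("stage %s failed: %s", name, exc)
            bundle["errors"][name] = str(exc)
            bundle[name] = None

    # --- nest survival -----------------------------------------------
    stage("dsr_models", lambda: nest_survival.dsr_model_table(data.nests))

    def _dsr_by_group():
        out = {}
        for g in ("control", "enlarged"):
            sub = [n for n in data.nests if n.group == g]
            fit = nest_survival.fit_dsr_mle(sub)
            out[g] = {"dsr": fit.dsr, "se": fit.dsr_se,
                      "exposure_days": fit.n_exposure,
                      "boundary": fit.boundary}
        return pd.DataFrame(out).T.rename_axis("group").reset_index()

    stage("dsr_by_group", _dsr_by_group)

    # --- eggs ---------------------------------------------------------
    stage("mass_loss", lambda: eggmod.fit_mass_loss(
        data.eggs, groups, lays, max_age=config.egg_mass_max_age).report())

    def _hatch():
        summaries, tests = eggmod.hatch_summaries(
            data.nests, data.hatch_times, data.eggs, yates=config.yates)
        sm = pd.DataFrame({g: vars(s) for g, s in summaries.items()}).T
        sm["failure_rate"] = [summaries[g].failure_rate for g in sm.index]
        tst = pd.DataFrame(
            [{"test": k, "statistic": t.statistic, "df": t.df,
              "p_value": t.p_value, "method": t.method}
             for k, t in tests.items()]
        )
        return sm.rename_axis("group").reset_index(), tst

    stage("hatch", _hatch)
    if bundle.get("hatch"):
        bundle["hatch_summary"], bundle["hatch_tests"] = bundle.pop("hatch")

    # --- hatchlings and growth ---------------------------------------
    mean_vol = {}
    for n in data.nests:
        vols = [eggmod.egg_volume(e.length_cm, e.breadth_cm)
                for e in data.eggs if e.nest_id == n.nest_id]
        if vols:
            mean_vol[n.nest_id] = float(np.mean(vols))

    def _hatchlings():
        models = growth.fit_hatchling_models(
            data.chicks, mean_vol, lays, max_age=config.hatchling_max_age)
        return {tr: m.report() for tr, m in models.items()}, \
               {tr: m.table for tr, m in models.items()}

    stage("hatchling", _hatchlings)
    if bundle.get("hatchling"):
        bundle["hatchling_models"], bundle["hatchling_selection"] = \
            bundle.pop("hatchling")

    def _growth():
        frame = growth.observations_frame(data.chicks, lays)
        curves, tables = {}, {}
        for tr in TRAITS:
            obs = frame.dropna(subset=[tr])[["age", tr]].to_numpy()
            if len(obs) < 8:
                continue
            curve, table = growth.select_growth_family(obs)
            curves[tr] = curve
            table.insert(0, "trait", tr)
            tables[tr] = table
        models = growth.fit_growth_models(
            data.chicks, curves, lays, max_age=config.growth_max_age)
        selection = pd.concat(tables.values(), ignore_index=True) \
            if tables else pd.DataFrame()
        return selection, {tr: m.report() for tr, m in models.items()}, curves

    stage("growthstage", _growth)
    if bundle.get("growthstage"):
        (bundle["growth_selection"], bundle["growth_models"],
         bundle["growth_curves"]) = bundle.pop("growthstage")

    # --- chick survival ----------------------------------------------
    fates10 = survival.truncate_fates(data.fates, config.survival_window)

    stage("km_curves", lambda: survival.kaplan_meier(fates10))

    def _cox():
        fit = survival.fit_cox(fates10)
        lo, hi = fit.ci95
        return pd.DataFrame([{
            "beta": fit.beta, "se": fit.se, "hr": fit.hr,
            "ci95_lower": lo, "ci95_upper": hi, "p_value": fit.p_value,
            "n": fit.n, "n_events": fit.n_events, "ties": fit.ties_method,
            "boundary": fit.boundary,
        }])

    stage("cox", _cox)
    stage("s10", lambda: pd.DataFrame(
        survival.s10(fates10, config.survival_window)
    ).T.rename_axis("group").reset_index())

    # --- reproductive value ------------------------------------------
    def _rv():
        hs = bundle.get("hatch_summary")
        dsr_df = bundle.get("dsr_by_group")
        s10_df = bundle.get("s10")
        if hs is None or dsr_df is None:
            raise ValueError("needs hatch_summary and dsr_by_group stages")
        hs = hs.set_index("group")
        dsr_df = dsr_df.set_index("group")
        inputs = {}
        for g, C in (("control", 4), ("enlarged", 5)):
            # partial clutch survival over all eggs (incl. the artificial
            # fifth) in surviving nests
            hatched_nests = [n for n in data.nests
                             if n.group == g and n.fate == HATCHED]
            total_eggs = sum(n.n_eggs for n in hatched_nests)
            lost = sum(1 for e in data.eggs
                       if e.lost and groups[e.nest_id] == g)
            P = 1.0 - lost / total_eggs if total_eggs else np.nan
            s10_row = None
            if s10_df is not None:
                row = s10_df.set_index("group").loc[g]
                if row["known"] > 0:
                    s10_row = (int(row["survivors"]), int(row["known"]))
            inputs[g] = rv.RVInputs(
                C=C, lay_days=config.lay_days[g],
                inc_days=float(hs.loc[g, "incubation_mean"]),
                dsr=float(dsr_df.loc[g, "dsr"]), P=P,
                H=1.0 - float(hs.loc[g, "failure_rate"]),
                s10=s10_row,
            )
        table = rv.rv_table(inputs["control"], inputs["enlarged"],
                            baseline=config.diff_baseline)
        chain = rv.partial_products_table(inputs["control"], inputs["enlarged"])
        return table, chain

    stage("rvstage", _rv)
    if bundle.get("rvstage"):
        bundle["rv_table"], bundle["partial_products"] = bundle.pop("rvstage")

    if config.out_dir:
        save_bundle(bundle, config.out_dir)
    return bundle


def save_bundle(bundle: dict, out_dir: str | Path) -> Path:
    """Write every tabular report as CSV plus a JSON index."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    index = {"reports": [], "errors": bundle.get("errors", {})}
    for key, val in bundle.items():
        if key in ("data", "errors", "growth_curves"):
            continue
        if isinstance(val, pd.DataFrame):
            val.to_csv(out / f"{key}.csv", index=False)
            index["reports"].append(f"{key}.csv")
        elif isinstance(val, dict) and val and \
                all(isinstance(v, pd.DataFrame) for v in val.values()):
            for sub, df in val.items():
                df.to_csv(out / f"{key}_{sub}.csv")
                index["reports"].append(f"{key}_{sub}.csv")
    if "growth_curves" in bundle and bundle["growth_curves"]:
        curves = {tr: {"family": c.family, **c.params}
                  for tr, c in bundle["growth_curves"].items()}
        (out / "growth_curves.json").write_text(json.dumps(curves, indent=2))
        index["reports"].append("growth_curves.json")
    index["reports"].sort()
    (out / "index.json").write_text(json.dumps(index, indent=2, sort_keys=True))
    return out / "index.json"
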