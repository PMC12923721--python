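"""Delimited-text serialization of a study and schema validation.

A study round-trips through four UTF-8 CSV tables — ``nests.csv``,
``eggs.csv``, ``chicks.csv``, ``fates.csv`` — plus a ``config.json``
sidecar holding the generating configuration.  Repeated measurements
(nest visit intervals, egg masses, chick hatch times) are packed into
single columns as ``;``-separated ``:``-joined records so each entity
stays one row.  Missing values are empty fields.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

from .config import (
    GrowthResidualCoeffs,
    HatchlingCoeffs,
    LogisticCurve,
    MassLossCoeffs,
    StudyConfig,
)
from .simulate import StudyData
from .types import ByGroup, ChickFate, ChickObservation, EggSeries, NestHistory, TRAITS

__all__ = ["save_study", "load_study", "validate_tables", "config_from_dict"]

NEST_COLS = ["nest_id", "group", "laying_day", "first_found_day", "n_eggs",
             "hatch_day", "intervals", "hatch_times"]
EGG_COLS = ["egg_id", "nest_id", "length_cm", "breadth_cm", "hatched", "lost",
            "measurements"]
CHICK_COLS = ["chick_id", "brood_id", "group", "age", "mass", "tarsus", "bill",
              "head_bill", "habitat"]
FATE_COLS = ["chick_id", "brood_id", "group", "entry_day", "exit_day", "event"]


def _pack(records, fmt) -> str:
    return ";".join(fmt(r) for r in records)


def save_study(data: StudyData, outdir: str | Path) -> dict[str, Path]:
    """Write the four study tables and the config sidecar; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nests = pd.DataFrame(
        [
            {
                "nest_id": n.nest_id, "group": n.group,
                "laying_day": n.laying_day, "first_found_day": n.first_found_day,
                "n_eggs": n.n_eggs,
                "hatch_day": n.hatch_day if n.hatch_day is not None else "",
                "intervals": _pack(n.intervals,
                                   lambda r: f"{r[0]!r}:{r[1]!r}:{r[2]}"),
                "hatch_times": _pack(data.hatch_times.get(n.nest_id, []),
                                     lambda t: f"{t!r}"),
            }
            for n in data.nests
        ],
        columns=NEST_COLS,
    )
    eggs = pd.DataFrame(
        [
            {
                "egg_id": e.egg_id, "nest_id": e.nest_id,
                "length_cm": e.length_cm, "breadth_cm": e.breadth_cm,
                "hatched": "" if e.hatched is None else str(e.hatched).lower(),
                "lost": str(e.lost).lower(),
                "measurements": _pack(e.measurements,
                                      lambda m: f"{m[0]!r}:{m[1]!r}"),
            }
            for e in data.eggs
        ],
        columns=EGG_COLS,
    )
    chicks = pd.DataFrame(
        [
            {
                "chick_id": c.chick_id, "brood_id": c.brood_id, "group": c.group,
                "age": c.age,
                **{tr: getattr(c, tr) for tr in TRAITS},
                "habitat": c.habitat or "",
            }
            for c in data.chicks
        ],
        columns=CHICK_COLS,
    )
    fates = pd.DataFrame(
        [
            {
                "chick_id": f.chick_id, "brood_id": f.brood_id, "group": f.group,
                "entry_day": f.entry_day, "exit_day": f.exit_day,
                "event": str(f.event).lower(),
            }
            for f in data.fates
        ],
        columns=FATE_COLS,
    )
    paths = {}
    for name, df in [("nests", nests), ("eggs", eggs), ("chicks", chicks),
                     ("fates", fates)]:
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    cfg_path = outdir / "config.json"
    cfg_path.write_text(data.truth.to_json())
    paths["config"] = cfg_path
    return paths


def _unpack_byg(d) -> ByGroup:
    return ByGroup(**d) if isinstance(d, dict) else d


def config_from_dict(d: dict) -> StudyConfig:
    """Rebuild a StudyConfig from its JSON dictionary form."""
    d = dict(d)
    for f in ("incubation_mean", "incubation_sd", "asynchrony_mean",
              "asynchrony_sd", "dsr", "egg_fail_prob", "partial_loss_prob"):
        if f in d:
            d[f] = _unpack_byg(d[f])
    if isinstance(d.get("mass_loss"), dict):
        d["mass_loss"] = MassLossCoeffs(**d["mass_loss"])
    if isinstance(d.get("hatchling"), dict):
        d["hatchling"] = {k: HatchlingCoeffs(**v) if isinstance(v, dict) else v
                          for k, v in d["hatchling"].items()}
    if isinstance(d.get("growth_truth"), dict):
        d["growth_truth"] = {k: LogisticCurve(**v) if isinstance(v, dict) else v
                             for k, v in d["growth_truth"].items()}
    if isinstance(d.get("growth_residual"), dict):
        d["growth_residual"] = {
            k: GrowthResidualCoeffs(**v) if isinstance(v, dict) else v
            for k, v in d["growth_residual"].items()
        }
    for f in ("visit_gap", "egg_length_cm", "egg_breadth_cm"):
        if f in d and isinstance(d[f], list):
            d[f] = tuple(d[f])
    valid = {fl.name for fl in dataclasses.fields(StudyConfig)}
    return StudyConfig(**{k: v for k, v in d.items() if k in valid})


def load_study(indir: str | Path) -> StudyData:
    """Read a study written by :func:`save_study`."""
    indir = Path(indir)
    nests_df = pd.read_csv(indir / "nests.csv", keep_default_na=False)
    eggs_df = pd.read_csv(indir / "eggs.csv", keep_default_na=False)
    chicks_df = pd.read_csv(indir / "chicks.csv")
    fates_df = pd.read_csv(indir / "fates.csv", keep_default_na=False)
    cfg = config_from_dict(json.loads((indir / "config.json").read_text()))

    nests, hatch_times = [], {}
    for _, r in nests_df.iterrows():
        intervals = []
        if r["intervals"]:
            for rec in str(r["intervals"]).split(";"):
                a, b, status = rec.split(":")
                intervals.append((float(a), float(b), status))
        nests.append(NestHistory(
            nest_id=r["nest_id"], group=r["group"],
            laying_day=float(r["laying_day"]),
            first_found_day=float(r["first_found_day"]),
            intervals=intervals,
            hatch_day=float(r["hatch_day"]) if str(r["hatch_day"]) != "" else None,
            n_eggs=int(r["n_eggs"]),
        ))
        if str(r["hatch_times"]):
            hatch_times[r["nest_id"]] = [float(t)
                                         for t in str(r["hatch_times"]).split(";")]
    eggs = []
    for _, r in eggs_df.iterrows():
        meas = []
        if r["measurements"]:
            for rec in str(r["measurements"]).split(";"):
                age, mass = rec.split(":")
                meas.append((float(age), float(mass)))
        eggs.append(EggSeries(
            egg_id=r["egg_id"], nest_id=r["nest_id"],
            length_cm=float(r["length_cm"]), breadth_cm=float(r["breadth_cm"]),
            measurements=meas,
            hatched=None if str(r["hatched"]) == "" else str(r["hatched"]).lower() == "true",
            lost=str(r["lost"]).lower() == "true",
        ))
    chicks = []
    for _, r in chicks_df.iterrows():
        chicks.append(ChickObservation(
            chick_id=r["chick_id"], brood_id=r["brood_id"], group=r["group"],
            age=float(r["age"]),
            **{tr: (None if pd.isna(r[tr]) else float(r[tr])) for tr in TRAITS},
            habitat=None if (pd.isna(r["habitat"]) or r["habitat"] == "")
            else r["habitat"],
        ))
    fates = [
        ChickFate(
            chick_id=r["chick_id"], brood_id=r["brood_id"], group=r["group"],
            entry_day=float(r["entry_day"]), exit_day=float(r["exit_day"]),
            event=str(r["event"]).lower() == "true",
        )
        for _, r in fates_df.iterrows()
    ]
    return StudyData(nests=nests, eggs=eggs, chicks=chicks, fates=fates,
                     truth=cfg, hatch_times=hatch_times)


def validate_tables(indir: str | Path) -> list[dict[str, str]]:
    """Schema check of the four study tables.

    Verifies column presence, value ranges and referential integrity;
    returns one record per violation (file, row, column, message) and an
    empty list for a valid study.  Never raises on content problems.
    """
    indir = Path(indir)
    violations: list[dict[str, str]] = []

    def bad(file, row, column, message):
        violations.append({"file": file, "row": str(row), "column": column,
                           "message": message})

    frames = {}
    expected = {"nests.csv": NEST_COLS, "eggs.csv": EGG_COLS,
                "chicks.csv": CHICK_COLS, "fates.csv": FATE_COLS}
    for fname, cols in expected.items():
        path = indir / fname
        if not path.exists():
            bad(fname, "-", "-", "file missing")
            continue
        df = pd.read_csv(path, keep_default_na=False)
        frames[fname] = df
        for c in cols:
            if c not in df.columns:
                bad(fname, "-", c, "column missing")

    nest_ids = set()
    if "nests.csv" in frames and "nest_id" in frames["nests.csv"]:
        ndf = frames["nests.csv"]
        nest_ids = set(ndf["nest_id"])
        for i, r in ndf.iterrows():
            if r.get("group") not in ("control", "enlarged"):
                bad("nests.csv", i, "group", f"unknown group {r.get('group')!r}")
    if "eggs.csv" in frames:
        for i, r in frames["eggs.csv"].iterrows():
            if nest_ids and r.get("nest_id") not in nest_ids:
                bad("eggs.csv", i, "nest_id",
                    f"egg references unknown nest {r.get('nest_id')!r}")
            try:
                L, B = float(r["length_cm"]), float(r["breadth_cm"])
                if not (L >= B > 0):
                    bad("eggs.csv", i, "length_cm",
                        f"need length >= breadth > 0, got {L}, {B}")
            except (ValueError, KeyError):
                bad("eggs.csv", i, "length_cm", "non-numeric dimensions")
            for rec in str(r.get("measurements", "")).split(";"):
                if not rec:
                    continue
                age, mass = (float(v) for v in rec.split(":"))
                if mass <= 0:
                    bad("eggs.csv", i, "measurements", f"nonpositive mass {mass}")
                if age < 0:
                    bad("eggs.csv", i, "measurements", f"negative age {age}")
    if "chicks.csv" in frames:
        for i, r in frames["chicks.csv"].iterrows():
            if nest_ids and r.get("brood_id") not in nest_ids:
                bad("chicks.csv", i, "brood_id",
                    f"chick references unknown nest {r.get('brood_id')!r}")
            try:
                if float(r["age"]) < 0:
                    bad("chicks.csv", i, "age", f"negative age {r['age']}")
            except (ValueError, KeyError, TypeError):
                bad("chicks.csv", i, "age", "non-numeric age")
    if "fates.csv" in frames:
        for i, r in frames["fates.csv"].iterrows():
            try:
                entry, exit_ = float(r["entry_day"]), float(r["exit_day"])
                if not 0 <= entry < exit_:
                    bad("fates.csv", i, "exit_day",
                        f"need 0 <= entry < exit, got ({entry}, {exit_})")
            except (ValueError, KeyError):
                bad("fates.csv", i, "entry_day", "non-numeric times")
            if nest_ids and r.get("brood_id") not in nest_ids:
                bad("fates.csv", i, "brood_id",
                    f"fate references unknown nest {r.get('brood_id')!r}")
    return violations
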