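"""End-to-end orchestration of the analysis stages.

``run_all`` executes simulate -> ethogram -> vms -> trips -> interact ->
stats on a synthetic dataset and writes every artefact (tables, events,
profile, breakpoint fit, model reports, figures) plus a manifest into one
output directory.  Each stage failure aborts with the stage name.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd

from . import behaviour, groupstats, interaction, trips as trips_mod, vms
from .geo import Colony, to_local_time
from .simulate import SimConfig, SimDataset


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name):
    def deco(fn):
        def wrapped(*a, **k):
            try:
                return fn(*a, **k)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(f"stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


@_stage("ethogram")
def ethogram_stage(sim: SimDataset):
    """Per-bird ethogram labels, VeDBA series and daily summaries."""
    labels_by_bird = {}
    daily = []
    for bid in sorted(sim.bird_truth):
        acc = sim.accel_for(bid)
        gps_b = sim.fixes[sim.fixes["bird_id"] == bid]
        n_sec = int(acc.duration_s)
        speed = behaviour.ground_speed_per_second(gps_b, acc.t0, n_sec)
        labels, vedba = behaviour.build_ethogram(acc, speed)
        labels_by_bird[bid] = (acc.t0, labels)
        daily.append(behaviour.daily_summaries(labels, vedba))
    return labels_by_bird, pd.concat(daily, ignore_index=True)


@_stage("vms")
def vms_stage(native: pd.DataFrame):
    grid = vms.interpolate_pings(native)
    return vms.classify_activity(grid)


@_stage("trips")
def trips_stage(fixes: pd.DataFrame, colony: Colony, events=None):
    seg = trips_mod.segment_trips(fixes, colony)
    return seg, trips_mod.trip_table(seg, colony, events)


@_stage("interact")
def interact_stage(fixes, vessel_grid, labels_by_bird, profile_max_km=5.0,
                   n_boot=1000, seed=None):
    """Approach detection, distance profile and interaction validation.

    Approaches are detected on all grid pings (the rule needs the full
    distance series).  The distance profile feeding the breakpoint fit is
    restricted to the trustworthy subset of pairs: fishing-classified
    pings (steaming interpolation carries multi-km displacement),
    simultaneous fix/grid instants (a ping up to 5 min stale displaces a
    moving vessel by several hundred metres -- on the scale of the
    interaction distance itself), and each fix's nearest vessel (the
    vessel the bird's behaviour is a response to; pairs with farther
    vessels carry the attended vessel's sitting signal and corrupt the
    baseline).  Validation likewise requires the minimum-distance fix to
    sit on a fishing ping.
    """
    pairs = interaction.match_pairs(fixes, vessel_grid)
    pairs = interaction.attach_sit_fraction(pairs, labels_by_bird)
    pp = interaction.select_profile_pairs(pairs)
    profile = interaction.build_distance_profile(pp, max_km=profile_max_km)
    fit = interaction.fit_breakpoint(profile, n_boot=n_boot, seed=seed)
    approaches = interaction.detect_approaches(pairs)
    events = interaction.validate_interactions(approaches, fit,
                                               require_fishing_min=True)
    return pairs, profile, fit, approaches, events


def build_trip_day_records(trip_tbl: pd.DataFrame, daily: pd.DataFrame,
                           sexes: dict) -> pd.DataFrame:
    """One record per short-trip day joining daily activity metrics with
    the trip's interaction status and movement metrics."""
    rows = []
    for _, tr in trip_tbl.iterrows():
        if tr["category"] != "short":
            continue
        d0 = to_local_time(tr["start"]).normalize()
        d1 = to_local_time(tr["end"]).normalize()
        sel = daily[(daily["bird_id"] == tr["bird_id"])
                    & (daily["date"] >= d0) & (daily["date"] <= d1)]
        for _, day in sel.iterrows():
            rows.append({
                "bird_id": tr["bird_id"], "trip_id": tr["trip_id"],
                "date": day["date"], "sex": sexes.get(tr["bird_id"], "M"),
                "int_flag": tr["int_flag"],
                "daily_vedba_sum": day["daily_vedba_sum"],
                "daily_flight_time_h": day["daily_flight_time_h"],
                "trip_length_km": tr["trip_length_km"],
                "max_colony_distance_km": tr["max_colony_distance_km"],
            })
    return pd.DataFrame(rows)


@_stage("stats")
def stats_stage(trip_tbl, daily, sexes, events, fleet_by_gear):
    out = {}
    records = build_trip_day_records(trip_tbl, daily, sexes)
    out["records"] = records
    if len(records) >= 3 and records["daily_vedba_sum"].std() > 0:
        out["flight_vs_vedba"] = groupstats.regress_flight_on_vedba(records)
    models = {}
    short = trip_tbl[trip_tbl["category"] == "short"].copy()
    short["sex"] = short["bird_id"].map(sexes).fillna("M")
    for resp, frame in (("daily_vedba_sum", records),
                        ("daily_flight_time_h", records),
                        ("trip_length_km", short),
                        ("max_colony_distance_km", short)):
        try:
            models[resp] = groupstats.fit_lmm(frame, resp)
        except Exception:
            models[resp] = None
    out["models"] = models
    out["foraging_table"] = groupstats.foraging_table(records)
    out["gear_table"] = groupstats.gear_table(fleet_by_gear)
    by_gear = {}
    for ev in events:
        by_gear[ev.gear] = by_gear.get(ev.gear, 0) + 1
    out["interactions_by_gear"] = by_gear
    if len(by_gear) >= 1 and len([g for g in fleet_by_gear.values() if g]) >= 2:
        try:
            out["gear_preference"] = groupstats.gear_preference_test(
                by_gear, fleet_by_gear)
        except Exception:
            out["gear_preference"] = None
    birds = short.groupby("bird_id").agg(
        sex=("sex", "first"),
        any_int=("int_flag", lambda s: "INT_YES" if (s == "INT_YES").any()
                 else "INT_NO")).reset_index().rename(columns={"any_int": "int_flag"})
    try:
        out["sex_test"] = groupstats.sex_interaction_test(birds)
    except Exception:
        out["sex_test"] = None
    out["birds"] = birds
    return out


def _figures(outdir, profile, fit, records, diel):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    x = np.linspace(profile.centers_km.min(), profile.centers_km.max(), 200)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(profile.centers_km, profile.mean_sit_pct, "ko", ms=4)
    ax.plot(x, fit.predict(x), "r-")
    ax.axvline(fit.breakpoint_km, ls="--", c="grey")
    ax.set_xlabel("distance from vessel (km)")
    ax.set_ylabel("sitting on the water (%)")
    ax.set_title(f"interaction distance {fit.breakpoint_km:.2f} km "
                 f"(95% CI {fit.ci95[0]:.2f}-{fit.ci95[1]:.2f})")
    fig.tight_layout()
    fig.savefig(os.path.join(outdir, "fig_profile.png"), dpi=120)
    plt.close(fig)
    if len(records):
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(records["daily_vedba_sum"], records["daily_flight_time_h"],
                "k.", alpha=0.6)
        ax.set_xlabel("daily sum of VeDBA")
        ax.set_ylabel("daily flight time (h)")
        fig.tight_layout()
        fig.savefig(os.path.join(outdir, "fig_flight_vedba.png"), dpi=120)
        plt.close(fig)
    fig, ax = plt.subplots(figsize=(7, 3.5))
    colors = ["0.4" if n else "0.85" for n in diel["is_night"]]
    ax.bar(diel["hour_local"], diel["n_events"], color=colors)
    ax.set_xlabel("hour of day (GMT+2)")
    ax.set_ylabel("interaction events")
    fig.tight_layout()
    fig.savefig(os.path.join(outdir, "fig_diel.png"), dpi=120)
    plt.close(fig)


def run_all(outdir, cfg: SimConfig | None = None, profile_max_km: float = 5.0,
            n_boot: int = 1000, seed: int | None = None,
            make_figures: bool = True) -> dict:
    """Run the full synthetic study end-to-end; returns the result bundle.

    Stages: simulate -> ethogram -> vms -> trips -> interact -> stats.
    Every artefact is written under ``outdir`` with a manifest of the
    parameters used.
    """
    os.makedirs(outdir, exist_ok=True)
    if cfg is None:
        cfg = SimConfig(seed=0 if seed is None else seed)
    try:
        sim = SimDataset(cfg)
    except Exception as exc:
        raise StageError(f"stage 'simulate' failed: {exc}") from exc
    labels_by_bird, daily = ethogram_stage(sim)
    vessel_grid = vms_stage(sim.native_pings)
    pairs, profile, fit, approaches, events = interact_stage(
        sim.fixes, vessel_grid, labels_by_bird,
        profile_max_km=profile_max_km, n_boot=n_boot, seed=cfg.seed)
    # attach gear for the downstream gear tests
    gear_of = {v: sim.vessel_truth[v]["gear"] for v in sim.vessel_truth}
    for ev in approaches + events:
        ev.gear = gear_of.get(ev.vessel_id)
    seg, trip_tbl = trips_stage(sim.fixes, Colony(cfg.colony), events)
    fleet_by_gear = {}
    for v in sim.vessel_truth.values():
        fleet_by_gear[v["gear"]] = fleet_by_gear.get(v["gear"], 0) + 1
    stats = stats_stage(trip_tbl, daily, sim.truth.sexes, events, fleet_by_gear)
    diel = interaction.diel_interaction_counts(events)

    # ---- artefacts -------------------------------------------------------
    profile.to_frame().to_csv(os.path.join(outdir, "distance_profile.csv"),
                              index=False)
    interaction.write_events(approaches + [e for e in events],
                             os.path.join(outdir, "events.csv"))
    trips_mod.write_trip_table(trip_tbl, os.path.join(outdir, "trips.csv"))
    daily.to_csv(os.path.join(outdir, "daily_metrics.csv"), index=False)
    diel.to_csv(os.path.join(outdir, "diel_counts.csv"), index=False)
    stats["gear_table"].to_csv(os.path.join(outdir, "gear_table.csv"), index=False)
    stats["foraging_table"].to_csv(os.path.join(outdir, "foraging_table.csv"),
                                   index=False)
    report = {
        "breakpoint_km": fit.breakpoint_km,
        "ci95": list(fit.ci95),
        "slopes_pct_per_km": list(fit.slopes),
        "n_approaches": len(approaches),
        "n_interaction_events": len(events),
        "n_trips": int(len(trip_tbl)),
        "n_pairs": int(len(pairs)),
        "true_interaction_km": sim.truth.true_interaction_km,
        "n_planted_interactions": len(sim.truth.interactions),
    }
    models_out = {}
    for resp, mr in stats["models"].items():
        if mr is None:
            continue
        models_out[resp] = {
            "transform": mr.transform, "method": mr.method,
            "random_variance": mr.random_variance,
            "effects": mr.effects.to_dict(orient="records"),
        }
    report["models"] = models_out
    if "flight_vs_vedba" in stats:
        s, i, F, d1, d2, p = stats["flight_vs_vedba"]
        report["flight_vs_vedba"] = {"slope": s, "intercept": i, "F": F,
                                     "df": [d1, d2], "p": p}
    for key in ("gear_preference", "sex_test"):
        if stats.get(key) is not None:
            report[key] = list(stats[key])
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1)
    manifest = {"config": cfg.to_dict(), "profile_max_km": profile_max_km,
                "n_boot": n_boot, "seed": cfg.seed}
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    if make_figures:
        _figures(outdir, profile, fit, stats["records"], diel)
    return {
        "sim": sim, "labels_by_bird": labels_by_bird, "daily": daily,
        "vessel_grid": vessel_grid, "pairs": pairs, "profile": profile,
        "fit": fit, "approaches": approaches, "events": events,
        "trip_table": trip_tbl, "stats": stats, "diel": diel,
        "report": report,
    }
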