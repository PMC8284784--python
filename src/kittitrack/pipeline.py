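"""End-to-end pipeline driver: filter -> trajectories -> space use ->
dispersal -> activity -> group statistics.

Each stage writes its outputs before the next begins, so a failure leaves the
completed stages' files on disk with a stage-tagged error. A run manifest
(config hash, seed, versions, record counts) is written for every run; a
rerun with the same inputs, config and seed reproduces every output
byte-identically.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .activity import activity_table, assign_phases, bird_compositions, summarize_activity
from .config import PipelineConfig
from .dispersal import dispersal_series
from .group_stats import breeding_success, james_bootstrap_p, subcomposition
from .space_use import ba_bootstrap, colony_ud_pair, isopleth
from .trajectories import daily_midpoints, filter_complete, summarize_trajectories

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


def _stage_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Execute the full analysis and write all outputs under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
        "inputs": {},
    }
    t_start = time.time()

    def finish_stage(name, **counts):
        manifest["stages"][name] = {"elapsed_s": round(time.time() - t_start, 2), **counts}
        io.write_json(manifest, out / "manifest.json")
        logger.info("stage %s done %s", name, counts)

    # ---- inputs ----------------------------------------------------------
    if config.tracks_path is None:
        raise StageError("inputs", ValueError("tracks_path is required"))
    try:
        tracks = io.read_tracks(config.tracks_path)
        manifest["inputs"]["tracks_rows"] = len(tracks)
        immersion = None
        if config.immersion_path is not None:
            immersion = io.read_immersion(config.immersion_path)
            manifest["inputs"]["immersion_rows"] = len(immersion)
        else:
            logger.info("no immersion path configured; activity and composition stages will be skipped")
        nests = None
        if config.nests_path is not None:
            nests = io.read_nests(config.nests_path)
            manifest["inputs"]["nests_rows"] = len(nests)
    except Exception as exc:  # noqa: BLE001 - stage-tagged rethrow
        raise StageError("inputs", exc) from exc

    # ---- filter + trajectories ------------------------------------------
    try:
        window = config.window("non_breeding")
        retained = filter_complete(
            tracks, window, mode="locations", tolerance=config.completeness_tolerance
        )
        tracks_full = tracks[tracks["bird_id"].isin(retained)]
        summary = summarize_trajectories(tracks_full, config.colony_positions, window)
        summary.to_csv(out / "trajectory_summary.csv", index=False)
        daily = daily_midpoints(tracks)
        daily.to_csv(out / "daily_positions.csv", index=False)
    except Exception as exc:
        raise StageError("trajectories", exc) from exc
    finish_stage("trajectories", birds_retained=len(retained), daily_positions=len(daily))

    daily_full = daily[daily["bird_id"].isin(retained)]
    colonies = sorted(daily_full["colony"].unique())

    # ---- space use -------------------------------------------------------
    try:
        periods = {
            "early_winter": config.window("early_winter"),
            "late_winter": config.window("late_winter"),
        }
        overlap_rows = []
        for period, (w0, w1) in periods.items():
            sub = daily_full[(daily_full["date"] >= w0) & (daily_full["date"] <= w1)]
            pos_a = sub[sub["colony"] == colonies[0]]
            pos_b = sub[sub["colony"] == colonies[1]]
            ud_a, ud_b = colony_ud_pair(
                pos_a, pos_b, config.ud_cell_size_km, config.ud_bandwidth_km
            )
            isopleths = []
            for level in config.ud_levels:
                res = ba_bootstrap(
                    pos_a,
                    pos_b,
                    level,
                    n_boot=config.ud_n_boot,
                    seed=_stage_seed(config.seed, 1),
                    cell_size_km=config.ud_cell_size_km,
                    bandwidth_km=config.ud_bandwidth_km,
                )
                overlap_rows.append(
                    {
                        "period": period,
                        "level": level,
                        "ba": res.ba,
                        "ba_se": res.ba_se,
                        "n_boot": res.n_boot,
                        f"n_birds_{colonies[0]}": pos_a["bird_id"].nunique(),
                        f"n_birds_{colonies[1]}": pos_b["bird_id"].nunique(),
                    }
                )
                for colony, ud in ((colonies[0], ud_a), (colonies[1], ud_b)):
                    isopleths.append((isopleth(ud, level), {"colony": colony, "period": period}))
            io.write_isopleth_geojson(isopleths, out / f"isopleths_{period}.geojson")
        pd.DataFrame(overlap_rows).to_csv(out / "ud_overlap.csv", index=False)
    except Exception as exc:
        raise StageError("space_use", exc) from exc
    finish_stage("space_use", overlap_rows=len(overlap_rows))

    # ---- dispersal -------------------------------------------------------
    try:
        daily_disp = dispersal_series(
            daily,
            n_boot=config.dispersal_n_boot,
            seed=_stage_seed(config.seed, 2),
            scope="daily",
        )
        daily_disp.to_csv(out / "dispersal_daily.csv", index=False)
        monthly_disp = dispersal_series(
            daily,
            n_boot=config.dispersal_n_boot,
            seed=_stage_seed(config.seed, 2),
            scope="monthly",
        )
        monthly_disp.to_csv(out / "dispersal_monthly.csv", index=False)
    except Exception as exc:
        raise StageError("dispersal", exc) from exc
    finish_stage("dispersal", days=len(daily_disp), months=len(monthly_disp))

    # ---- activity + composition tests -----------------------------------
    if immersion is not None:
        try:
            act_window = config.window("activity")
            retained_act = filter_complete(
                immersion, act_window, mode="immersion", tolerance=config.completeness_tolerance
            )
            w0, w1 = act_window
            ts = pd.to_datetime(immersion["block_start"])
            inside = (ts.dt.date >= w0) & (ts.dt.date <= w1)
            blocks = immersion[inside & immersion["bird_id"].isin(retained_act)]
            colony_of = dict(zip(tracks["bird_id"], tracks["colony"]))
            records = assign_phases(
                blocks,
                daily,
                half_width_min=config.phase_half_width_min,
                window_mode=config.phase_window_mode,
            )
            records["colony"] = records["bird_id"].map(colony_of)
            summarize_activity(records, by=["colony"]).to_csv(out / "activity_colony.csv", index=False)
            summarize_activity(records, by=["colony", "month", "phase"]).to_csv(
                out / "activity_colony_month_phase.csv", index=False
            )
            activity_table(records, ["colony", "phase"]).to_csv(
                out / "activity_table_phase.csv", index=False
            )
            comp = bird_compositions(records, ["colony"])
            comp.to_csv(out / "bird_compositions.csv", index=False)
        except Exception as exc:
            raise StageError("activity", exc) from exc
        finish_stage("activity", blocks=len(records), birds=len(retained_act))

        try:
            james_rows = []
            ew0, ew1 = config.window("early_winter")
            lw0, lw1 = config.window("late_winter")
            rec_dates = pd.to_datetime(records["block_start"]).dt.date
            spans = {
                "oct_mar": records,
                "oct_dec": records[(rec_dates >= ew0) & (rec_dates <= ew1)],
                "jan_mar": records[(rec_dates >= lw0) & (rec_dates <= lw1)],
            }
            for span, rec in spans.items():
                comps = bird_compositions(rec, ["colony"])
                grp_a = comps[comps["colony"] == colonies[0]]
                grp_b = comps[comps["colony"] == colonies[1]]
                if len(grp_a) < 3 or len(grp_b) < 3:
                    logger.warning("skipping James test for %s: too few birds", span)
                    continue
                cols = ["p_water", "p_flight", "p_forage"]
                res = james_bootstrap_p(
                    subcomposition(grp_a[cols].to_numpy()),
                    subcomposition(grp_b[cols].to_numpy()),
                    n_boot=config.james_n_boot,
                    seed=_stage_seed(config.seed, 3),
                )
                james_rows.append(
                    {
                        "comparison": f"{colonies[0]}_vs_{colonies[1]}",
                        "span": span,
                        "statistic": res.statistic,
                        "p_boot": res.p_boot,
                        "n_boot": res.n_boot,
                        "n_a": len(grp_a),
                        "n_b": len(grp_b),
                    }
                )
            pd.DataFrame(james_rows).to_csv(out / "james_results.csv", index=False)
        except Exception as exc:
            raise StageError("group_stats", exc) from exc
        finish_stage("group_stats", tests=len(james_rows))
    else:
        logger.info("activity and group_stats stages skipped (no immersion data)")

    # ---- breeding success ------------------------------------------------
    if nests is not None:
        try:
            rows = []
            for r in nests.itertuples():
                bs = breeding_success(r.n_nests, r.n_with_eggs, r.n_hatched, r.n_fledged)
                rows.append(
                    {
                        "colony": r.colony,
                        "year": r.year,
                        "n_nests": r.n_nests,
                        "laying": round(bs.laying, 4),
                        "hatching": round(bs.hatching, 4),
                        "fledging": round(bs.fledging, 4),
                        "overall": round(bs.overall, 4),
                    }
                )
            pd.DataFrame(rows).to_csv(out / "breeding_success.csv", index=False)
        except Exception as exc:
            raise StageError("breeding", exc) from exc
        finish_stage("breeding", colony_years=len(rows))

    finish_stage("all")
    return out
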