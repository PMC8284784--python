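"""Run the full pipeline end to end on simulated inputs.

Writes tracks and immersion CSVs, then executes
filter -> trajectories -> space use -> dispersal -> activity -> group stats,
leaving every table, the isopleth GeoJSONs and a run manifest in ./pipeline_out.
The same can be done from the shell:

    kittitrack simulate --seed 1 --out data
    kittitrack run-all --tracks data/tracks.csv --immersion data/immersion.csv --seed 1 --out pipeline_out
"""

from pathlib import Path

import pandas as pd

import kittitrack as kt
from kittitrack import io
from kittitrack.config import PipelineConfig
from kittitrack.pipeline import run_pipeline

data = Path("pipeline_data")
data.mkdir(exist_ok=True)
schedules = kt.default_schedules(2016)
tracks, _ = kt.simulate_tracks(schedules, kt.MovementConfig(n_birds=3, noise_sd_km=100.0, seed=7))
io.write_tracks(tracks, data / "tracks.csv")
blocks, _ = kt.simulate_immersion(tracks, kt.ImmersionSimConfig(seed=8))
io.write_immersion(blocks, data / "immersion.csv")

cfg = PipelineConfig(
    tracks_path=str(data / "tracks.csv"),
    immersion_path=str(data / "immersion.csv"),
    ud_n_boot=20, dispersal_n_boot=200, james_n_boot=500, seed=7,
)
out = run_pipeline(cfg, "pipeline_out")
print("outputs:", ", ".join(sorted(p.name for p in out.iterdir())))
print()
print(pd.read_csv(out / "ud_overlap.csv").round(3).to_string(index=False))
# ud_overlap.csv mirrors the headline result: near-zero core overlap in early
# winter, strong overlap in late winter, with bootstrap SEs per level.
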