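"""Plain-text (CSV) readers and writers for the pipeline tables.

File schemas:
  events.csv   session_id, behavior, onset_s, offset_s
  zones.csv    session_id, time_s, zone
  cells.csv    cell_id, animal_id, cell_type
  traces.csv   cell_id, then one column per sample (s0, s1, ...)
  truth.csv    planted per-cell ground truth
  regions.csv  region_id, name, parent_id, level, volume_mm3
  counts.csv   subject_id, group, region_id, count
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import RegionTable
from .types import BehaviorEvent, Ethogram, TraceMatrix, ZoneTrack


def write_ethogram(etho: Ethogram, path: str | Path) -> None:
    pd.DataFrame(
        [
            {"session_id": etho.session_id, "behavior": e.behavior,
             "onset_s": e.onset_s, "offset_s": e.offset_s}
            for e in etho.events
        ]
    ).to_csv(path, index=False)


def read_ethogram(
    path: str | Path, duration_s: float | None = None, male_entry_s: float = 0.0
) -> Ethogram:
    df = pd.read_csv(path)
    events = [
        BehaviorEvent(r.behavior, float(r.onset_s), float(r.offset_s))
        for r in df.itertuples()
    ]
    session_id = str(df["session_id"].iloc[0]) if len(df) else "session"
    if duration_s is None:
        duration_s = max((e.offset_s for e in events), default=0.0)
    return Ethogram(session_id=session_id, duration_s=duration_s, events=events,
                    male_entry_s=male_entry_s)


def write_zone_track(track: ZoneTrack, path: str | Path) -> None:
    pd.DataFrame(
        {"session_id": track.session_id, "time_s": track.times(), "zone": track.zones}
    ).to_csv(path, index=False)


def read_zone_track(
    path: str | Path, male_entry_s: float = 0.0, ejaculation_s: float | None = None
) -> ZoneTrack:
    df = pd.read_csv(path)
    times = df["time_s"].to_numpy()
    frame_rate = 1.0 / np.median(np.diff(times)) if len(times) > 1 else 1.0
    return ZoneTrack(
        session_id=str(df["session_id"].iloc[0]) if len(df) else "session",
        frame_rate=float(round(frame_rate, 6)),
        zones=df["zone"].to_numpy(),
        male_entry_s=male_entry_s,
        ejaculation_s=ejaculation_s,
    )


def write_traces(traces: TraceMatrix, cells_path: str | Path, traces_path: str | Path) -> None:
    pd.DataFrame(
        {"cell_id": traces.cell_ids, "animal_id": traces.animal_ids,
         "cell_type": traces.cell_types}
    ).to_csv(cells_path, index=False)
    tdf = pd.DataFrame(
        traces.values, columns=[f"s{i}" for i in range(traces.n_samples)]
    )
    tdf.insert(0, "cell_id", traces.cell_ids)
    tdf.to_csv(traces_path, index=False, float_format="%.6g")


def read_traces(
    cells_path: str | Path,
    traces_path: str | Path,
    frame_rate: float = 10.0,
    background_window: tuple[float, float] = (0.0, 60.0),
    zscored: bool = False,
) -> TraceMatrix:
    cells = pd.read_csv(cells_path).set_index("cell_id")
    tdf = pd.read_csv(traces_path)
    cell_ids = tdf["cell_id"].astype(str).tolist()
    values = tdf.drop(columns=["cell_id"]).to_numpy(dtype=float)
    meta = cells.loc[cell_ids]
    return TraceMatrix(
        cell_ids=cell_ids,
        cell_types=meta["cell_type"].tolist(),
        animal_ids=meta["animal_id"].astype(str).tolist(),
        values=values,
        frame_rate=frame_rate,
        background_window=background_window,
        zscored=zscored,
    )


def write_region_table(table: RegionTable, regions_path: str | Path,
                       counts_path: str | Path) -> None:
    table.regions.to_csv(regions_path, index=False)
    table.counts.to_csv(counts_path, index=False)


def read_region_table(regions_path: str | Path, counts_path: str | Path) -> RegionTable:
    regions = pd.read_csv(regions_path, keep_default_na=False)
    regions["parent_id"] = regions["parent_id"].astype(str)
    counts = pd.read_csv(counts_path)
    return RegionTable(regions=regions, counts=counts)
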