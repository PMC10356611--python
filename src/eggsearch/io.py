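"""CSV schemas shared by the simulator and the analysis modules.

All on-disk formats are plain CSV:

- trajectory:   ``t_s,x_mm,y_mm``
- events:       ``egg_id,ovulation_start_s,search_start_s,bend_complete_s,deposition_s,substrate``
- fluorescence: ``volume_t_s,F_cell,F_background``
- stimulation:  ``stim_onset_s,duration_s,intensity_level``
- synapses:     ``pre_id,post_id,pre_class,post_class,pre_side,post_side,n_synapses``
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import EggLayingSequence, Trajectory
from .calcium import FluorescenceRecording

NEUPRINT_COLUMN_MAP = {
    # documented mapping for neuPrint-style connectivity exports
    "bodyId_pre": "pre_id",
    "bodyId_post": "post_id",
    "type_pre": "pre_class",
    "type_post": "post_class",
    "somaSide_pre": "pre_side",
    "somaSide_post": "post_side",
    "weight": "n_synapses",
}


def write_trajectory(path, traj: Trajectory) -> None:
    pd.DataFrame({"t_s": traj.t, "x_mm": traj.x, "y_mm": traj.y}).to_csv(
        path, index=False
    )


def read_trajectory(path) -> Trajectory:
    df = pd.read_csv(path)
    return Trajectory(df["t_s"].to_numpy(), df["x_mm"].to_numpy(), df["y_mm"].to_numpy())


def write_events(path, eggs: list[EggLayingSequence]) -> None:
    pd.DataFrame(
        [
            {
                "egg_id": i,
                "ovulation_start_s": e.ovulation_start_s,
                "search_start_s": e.search_start_s,
                "bend_complete_s": e.bend_complete_s,
                "deposition_s": e.deposition_s,
                "substrate": e.substrate_at_deposition,
            }
            for i, e in enumerate(eggs)
        ],
        columns=[
            "egg_id",
            "ovulation_start_s",
            "search_start_s",
            "bend_complete_s",
            "deposition_s",
            "substrate",
        ],
    ).to_csv(path, index=False)


def read_events(path) -> list[EggLayingSequence]:
    df = pd.read_csv(path)
    return [
        EggLayingSequence(
            row.ovulation_start_s,
            row.search_start_s,
            row.bend_complete_s,
            row.deposition_s,
            str(row.substrate),
        )
        for row in df.itertuples()
    ]


def write_fluorescence(path, rec: FluorescenceRecording) -> None:
    pd.DataFrame(
        {
            "volume_t_s": rec.volume_t,
            "F_cell": rec.F_cell,
            "F_background": rec.F_background,
        }
    ).to_csv(path, index=False)


def read_fluorescence(path) -> FluorescenceRecording:
    df = pd.read_csv(path)
    return FluorescenceRecording(
        df["volume_t_s"].to_numpy(),
        df["F_cell"].to_numpy(),
        df["F_background"].to_numpy(),
    )


def write_stimulations(path, onsets, duration_s=5.0, intensity_level=1) -> None:
    onsets = np.asarray(onsets, float)
    pd.DataFrame(
        {
            "stim_onset_s": onsets,
            "duration_s": np.full(len(onsets), duration_s),
            "intensity_level": np.full(len(onsets), intensity_level),
        }
    ).to_csv(path, index=False)


def read_stimulations(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_synapses(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_synapses(path, column_map: dict | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    elif set(NEUPRINT_COLUMN_MAP) <= set(df.columns):
        df = df.rename(columns=NEUPRINT_COLUMN_MAP)
    return df
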