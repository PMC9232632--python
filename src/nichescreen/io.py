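"""Plain-text readers/writers for the pipeline's tables.

Event tables are CSV with one row per acquired event and one column per
panel channel (an optional ``label`` column carries generator ground truth
and is ignored by gating).  Layouts, counts and readouts are tidy CSV keyed
by well id; thresholds and ground truth are JSON sidecars.
"""

from __future__ import annotations

import os

import pandas as pd


def write_events(events_by_well: dict, directory, layout: pd.DataFrame = None,
                 truth=None) -> None:
    """Write one ``<well>.csv`` per well, plus layout and truth sidecars."""
    os.makedirs(directory, exist_ok=True)
    for well, table in events_by_well.items():
        table.to_csv(os.path.join(directory, f"{well}.csv"), index=False)
    if layout is not None:
        layout.to_csv(os.path.join(directory, "layout.csv"), index=False)
    if truth is not None:
        from .synth import save_truth
        save_truth(truth, os.path.join(directory, "ground_truth.json"))


def read_events(directory) -> dict:
    """Read every per-well event CSV in a directory (layout.csv excluded)."""
    out = {}
    for name in sorted(os.listdir(directory)):
        if not name.endswith(".csv") or name == "layout.csv":
            continue
        out[name[:-4]] = pd.read_csv(os.path.join(directory, name))
    if not out:
        raise FileNotFoundError(f"no event tables found under {directory}")
    return out


def read_layout(path) -> pd.DataFrame:
    layout = pd.read_csv(path, keep_default_na=False)
    required = {"well", "sample", "role", "replicate"}
    missing = required - set(layout.columns)
    if missing:
        raise ValueError(f"layout missing columns: {sorted(missing)}")
    return layout


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path)
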