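"""Delimited-text readers and writers for joint response/time data.

Two layouts are supported:

* long format -- one row per person-item pair with columns
  ``person_id, group, item_id, score, time`` (time in minutes);
* wide format -- a persons x items score matrix, a persons x items time
  matrix and a person/group table.

Missing values are written as the token ``NA`` and read back as NaN.
Seconds can be converted on input; only the time column is rescaled (the
log-scale intensities then shift by log 60).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import MISSING_TOKEN, Dataset

__all__ = ["read_long", "write_long", "read_wide", "write_wide"]


def write_long(data: Dataset, path) -> None:
    """Write a dataset in long format (one row per person-item pair)."""
    P, I = data.responses.shape
    df = pd.DataFrame({
        "person_id": np.repeat(data.person_id, I),
        "group": np.repeat(data.group, I),
        "item_id": np.tile(data.item_id, P),
        "score": data.responses.ravel(),
        "time": data.times.ravel(),
    })
    df.to_csv(path, index=False, na_rep=MISSING_TOKEN)


def read_long(path, time_unit: str = "minutes") -> Dataset:
    """Read a long-format file into a Dataset.

    ``time_unit`` may be ``"minutes"`` (default) or ``"seconds"``; seconds
    are converted to minutes on input.
    """
    df = pd.read_csv(path, na_values=[MISSING_TOKEN], keep_default_na=True)
    required = {"person_id", "group", "item_id", "score", "time"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"long-format file lacks columns: {sorted(missing)}")
    persons = df["person_id"].drop_duplicates().to_numpy()
    items = df["item_id"].drop_duplicates().to_numpy()
    p_idx = {p: i for i, p in enumerate(persons)}
    i_idx = {it: j for j, it in enumerate(items)}
    X = np.full((len(persons), len(items)), np.nan)
    T = np.full((len(persons), len(items)), np.nan)
    rows = df["person_id"].map(p_idx).to_numpy()
    cols = df["item_id"].map(i_idx).to_numpy()
    X[rows, cols] = df["score"].to_numpy(dtype=float)
    T[rows, cols] = df["time"].to_numpy(dtype=float)
    if time_unit == "seconds":
        T = T / 60.0
    elif time_unit != "minutes":
        raise ValueError("time_unit must be 'minutes' or 'seconds'")
    groups = df.drop_duplicates("person_id").set_index("person_id")["group"]
    return Dataset(X, T, groups.loc[persons].to_numpy(),
                   person_id=persons, item_id=items)


def write_wide(data: Dataset, scores_path, times_path, groups_path) -> None:
    """Write the two matrices and the person/group table."""
    idx = pd.Index(data.person_id, name="person_id")
    pd.DataFrame(data.responses, index=idx, columns=data.item_id).to_csv(
        scores_path, na_rep=MISSING_TOKEN)
    pd.DataFrame(data.times, index=idx, columns=data.item_id).to_csv(
        times_path, na_rep=MISSING_TOKEN)
    pd.DataFrame({"person_id": data.person_id, "group": data.group}).to_csv(
        groups_path, index=False)


def read_wide(scores_path, times_path, groups_path, time_unit: str = "minutes") -> Dataset:
    """Read the wide layout written by :func:`write_wide`."""
    sc = pd.read_csv(scores_path, index_col=0, na_values=[MISSING_TOKEN])
    tm = pd.read_csv(times_path, index_col=0, na_values=[MISSING_TOKEN])
    gr = pd.read_csv(groups_path)
    if not sc.index.equals(tm.index) or list(sc.columns) != list(tm.columns):
        raise ValueError("score and time matrices must share persons and items")
    T = tm.to_numpy(dtype=float)
    if time_unit == "seconds":
        T = T / 60.0
    elif time_unit != "minutes":
        raise ValueError("time_unit must be 'minutes' or 'seconds'")
    groups = gr.set_index("person_id")["group"].loc[sc.index].to_numpy()
    return Dataset(sc.to_numpy(dtype=float), T, groups,
                   person_id=sc.index.to_numpy(), item_id=sc.columns.to_numpy())
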