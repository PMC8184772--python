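"""Plain-text persistence: event-table CSV + JSON sidecar, result tables."""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd

from .simulate import EventTable, SampleMeta


def sample_basename(meta: SampleMeta) -> str:
    grav = "1G" if meta.gravity == "1G" else "suG"
    stim = "unstim" if meta.stimulation == "unstim" else "stim"
    tp = f"{meta.timepoint_h:g}h"
    return f"{meta.donor_id}_{grav}_{stim}_{tp}"


def write_event_table(table: EventTable, directory: str) -> str:
    """One CSV per sample (header = channel names, one row per cell) plus a
    JSON metadata sidecar. Returns the CSV path."""
    os.makedirs(directory, exist_ok=True)
    base = sample_basename(table.meta)
    csv_path = os.path.join(directory, base + ".csv")
    pd.DataFrame(table.values, columns=table.channel_names).to_csv(
        csv_path, index=False, float_format="%.6g"
    )
    meta = {
        "donor_id": table.meta.donor_id,
        "gravity": table.meta.gravity,
        "stimulation": table.meta.stimulation,
        "timepoint_h": table.meta.timepoint_h,
        "barcode_key_index": table.meta.barcode_key_index,
        "cofactor": table.cofactor,
    }
    with open(os.path.join(directory, base + ".json"), "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1, ensure_ascii=False)
    return csv_path


def read_event_table(csv_path: str) -> EventTable:
    sidecar = os.path.splitext(csv_path)[0] + ".json"
    with open(sidecar, encoding="utf-8") as fh:
        meta = json.load(fh)
    df = pd.read_csv(csv_path)
    return EventTable(
        meta=SampleMeta(
            donor_id=meta["donor_id"],
            gravity=meta["gravity"],
            stimulation=meta["stimulation"],
            timepoint_h=float(meta["timepoint_h"]),
            barcode_key_index=meta.get("barcode_key_index"),
        ),
        values=df.to_numpy(dtype=float),
        channel_names=list(df.columns),
        cofactor=float(meta.get("cofactor", 5.0)),
    )


def write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_labels(labels: np.ndarray, path: str) -> None:
    pd.DataFrame({"label": labels}).to_csv(path, index=False)


def read_labels(path: str) -> np.ndarray:
    return pd.read_csv(path)["label"].to_numpy(dtype=object)
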