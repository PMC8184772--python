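"""Immune-feature derivation from gated event tables.

Three feature modes are supported, all keyed by (subset, marker):

* ``response`` — the asinh ratio: difference of arcsinh-scale median
  functional-marker intensities between the 4 h stimulated and the 0 h
  unstimulated sample of the same (donor, gravity) unit. The default
  panel and 18-leaf tree give 18 x 14 = 252 response features.
* ``basal`` — arcsinh-scale medians of the unstimulated samples.
* ``abundance`` — gated leaf frequencies of the unstimulated samples.

Features from subsets with fewer than ``min_cells`` events are flagged
missing (NaN), never silently zero; a median imputation helper produces
the complete matrix the elastic net needs, together with the list of
imputed columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gating import UNASSIGNED, GatingHierarchy
from .panel import PanelConfig
from .simulate import GRAVITY_SUG, STIM_CONA, STIM_NONE, EventTable

MODE_RESPONSE = "response"
MODE_BASAL = "basal"
MODE_ABUNDANCE = "abundance"

DEFAULT_MIN_CELLS = 20


class PairingError(ValueError):
    """A (donor, gravity) unit lacks a required stim/unstim sample."""


def arcsinh_transform(x, cofactor: float):
    """Variance-stabilizing cytometry transform asinh(x / cofactor)."""
    if not cofactor > 0:
        raise ValueError(f"cofactor must be positive, got {cofactor}")
    return np.arcsinh(np.asarray(x, dtype=float) / cofactor)


def median_intensity(
    events: EventTable,
    labels: np.ndarray,
    subset: str,
    marker: str,
    cofactor: float | None = None,
    min_cells: int = DEFAULT_MIN_CELLS,
) -> float:
    """Median arcsinh-transformed intensity of ``marker`` over ``subset``.

    Returns NaN (missing flag) when the subset holds fewer than
    ``min_cells`` events.
    """
    cofactor = cofactor if cofactor is not None else events.cofactor
    mask = np.asarray(labels, dtype=object) == subset
    if int(mask.sum()) < min_cells:
        return float("nan")
    return float(np.median(arcsinh_transform(events.channel(marker)[mask], cofactor)))


def response_feature(median_stim: float, median_unstim: float) -> float:
    """Asinh ratio: stimulated minus unstimulated arcsinh median."""
    if np.isnan(median_stim) or np.isnan(median_unstim):
        return float("nan")
    return float(median_stim - median_unstim)


@dataclass
class FeatureMatrix:
    """Samples x (subset, marker, mode) feature matrix.

    Rows are indexed by (donor, gravity); columns by a 3-level
    (subset, marker, mode) MultiIndex in deterministic order.
    """

    data: pd.DataFrame
    mode: str
    imputed_columns: list[tuple] = field(default_factory=list)

    @property
    def X(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def donors(self) -> np.ndarray:
        return self.data.index.get_level_values("donor").to_numpy()

    def y(self) -> np.ndarray:
        """Gravity outcome encoded sµG = +1, 1G = -1."""
        grav = self.data.index.get_level_values("gravity")
        return np.where(grav == GRAVITY_SUG, 1.0, -1.0)

    def impute(self) -> "FeatureMatrix":
        """Per-column median imputation of missing features (flagged)."""
        df = self.data.copy()
        imputed = [col for col in df.columns if df[col].isna().any()]
        medians = df.median(axis=0)
        df = df.fillna(medians)
        df = df.fillna(0.0)  # all-missing columns have no median
        return FeatureMatrix(df, self.mode, imputed_columns=list(imputed))

    def to_csv(self, path: str) -> None:
        self.data.to_csv(path, float_format="%.10g")

    @classmethod
    def read_csv(cls, path: str, mode: str) -> "FeatureMatrix":
        df = pd.read_csv(path, header=[0, 1, 2], index_col=[0, 1])
        df.index.names = ["donor", "gravity"]
        df.columns.names = ["subset", "marker", "mode"]
        return cls(df, mode)


def _median_table(
    events: EventTable,
    labels: np.ndarray,
    leaves: list[str],
    markers: list[str],
    min_cells: int,
) -> pd.DataFrame:
    """Per-(subset, marker) arcsinh medians in one pass (NaN below floor)."""
    z = arcsinh_transform(
        events.values[:, [events.channel_names.index(m) for m in markers]], events.cofactor
    )
    df = pd.DataFrame(z, columns=markers)
    df["__label"] = np.asarray(labels, dtype=object)
    grouped = df[df["__label"] != UNASSIGNED].groupby("__label", sort=False)
    med = grouped.median()
    counts = grouped.size()
    med = med.reindex(leaves)
    small = counts.reindex(leaves).fillna(0) < min_cells
    med.loc[small.to_numpy(), :] = np.nan
    return med  # leaves x markers


def _unit_key(meta) -> tuple[str, str]:
    return (meta.donor_id, meta.gravity)


def build_feature_matrix(
    samples: list[tuple[EventTable, np.ndarray]],
    hierarchy: GatingHierarchy,
    panel: PanelConfig,
    mode: str = MODE_RESPONSE,
    min_cells: int = DEFAULT_MIN_CELLS,
    stim_timepoint_h: float = 4.0,
) -> FeatureMatrix:
    """Assemble the feature matrix for one experiment.

    ``samples`` pairs each event table with its per-event gating labels.
    Response mode requires, for every (donor, gravity) unit, a matched
    unstimulated (0 h) and stimulated (``stim_timepoint_h``) table.
    """
    if mode not in (MODE_RESPONSE, MODE_BASAL, MODE_ABUNDANCE):
        raise ValueError(f"unknown feature mode {mode!r}")
    leaves = hierarchy.leaves
    markers = panel.functional_markers

    units: dict[tuple[str, str], dict[str, tuple[EventTable, np.ndarray]]] = {}
    for table, labels in samples:
        key = _unit_key(table.meta)
        slot = None
        if table.meta.stimulation == STIM_NONE and table.meta.timepoint_h == 0:
            slot = "unstim"
        elif table.meta.stimulation == STIM_CONA and table.meta.timepoint_h == stim_timepoint_h:
            slot = "stim"
        if slot is not None:
            units.setdefault(key, {})[slot] = (table, labels)

    unit_keys = sorted(units)
    rows, index = [], []
    for key in unit_keys:
        slots = units[key]
        if "unstim" not in slots:
            raise PairingError(f"unit {key} lacks an unstimulated 0 h sample")
        if mode == MODE_RESPONSE and "stim" not in slots:
            raise PairingError(f"unit {key} lacks a stimulated {stim_timepoint_h} h sample")

        if mode == MODE_ABUNDANCE:
            from .gating import compute_frequencies

            table, labels = slots["unstim"]
            freqs = compute_frequencies(labels, leaves)
            rows.append(freqs[leaves].to_numpy())
        elif mode == MODE_BASAL:
            table, labels = slots["unstim"]
            med = _median_table(table, labels, leaves, markers, min_cells)
            rows.append(med.to_numpy().ravel())
        else:
            t_u, l_u = slots["unstim"]
            t_s, l_s = slots["stim"]
            med_u = _median_table(t_u, l_u, leaves, markers, min_cells)
            med_s = _median_table(t_s, l_s, leaves, markers, min_cells)
            rows.append((med_s.to_numpy() - med_u.to_numpy()).ravel())
        index.append(key)

    if mode == MODE_ABUNDANCE:
        columns = pd.MultiIndex.from_tuples(
            [(leaf, "frequency", mode) for leaf in leaves], names=["subset", "marker", "mode"]
        )
    else:
        columns = pd.MultiIndex.from_tuples(
            [(leaf, m, mode) for leaf in leaves for m in markers],
            names=["subset", "marker", "mode"],
        )
    data = pd.DataFrame(
        np.vstack(rows),
        index=pd.MultiIndex.from_tuples(index, names=["donor", "gravity"]),
        columns=columns,
    )
    return FeatureMatrix(data, mode)
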