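"""Combinatorial palladium sample barcoding and debarcoding.

Samples are labeled with unique k-of-n combinations of Pd isotopes (3-of-6
in the default scheme, giving C(6,3) = 20 keys) so that pooled samples can
be computationally deconvolved: an event is assigned to the key whose
positive-isotope set equals the event's k brightest barcode channels,
provided those k channels are separated from the rest by a margin on the
arcsinh scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .panel import PanelConfig, default_panel
from .simulate import EventTable, SampleMeta

UNASSIGNED_KEY = -1


@dataclass(frozen=True)
class BarcodeScheme:
    n_isotopes: int
    k_positive: int
    keys: tuple[tuple[int, ...], ...]

    @property
    def n_keys(self) -> int:
        return len(self.keys)

    def positive_sets(self) -> list[frozenset[int]]:
        return [frozenset(np.flatnonzero(np.array(key)).tolist()) for key in self.keys]


def make_barcode_scheme(n_isotopes: int, k_positive: int) -> BarcodeScheme:
    """All C(n, k) exactly-k-of-n binary keys in lexicographic order."""
    if not (1 <= k_positive <= n_isotopes <= 16):
        raise ValueError(
            f"require 1 <= k_positive <= n_isotopes <= 16, got k={k_positive}, n={n_isotopes}"
        )
    keys = []
    for combo in combinations(range(n_isotopes), k_positive):
        mask = [0] * n_isotopes
        for i in combo:
            mask[i] = 1
        keys.append(tuple(mask))
    return BarcodeScheme(n_isotopes=n_isotopes, k_positive=k_positive, keys=tuple(keys))


def pool_samples(
    tables: list[EventTable],
    scheme: BarcodeScheme,
    panel: PanelConfig | None = None,
    separation: float = 3.0,
    negative_mean: float = 0.5,
    band_sd: float = 0.3,
    seed: int = 0,
) -> EventTable:
    """Barcode each sample with the next free key and pool all events.

    Barcode channel intensities are drawn as two Gaussian bands on the
    arcsinh scale (negative at ``negative_mean``, positive at
    ``negative_mean + separation``) and inverse-transformed to raw counts.
    The pooled table records the generating sample index per event in
    ``true_sample_idx`` as debarcoding ground truth.
    """
    panel = panel if panel is not None else default_panel()
    barcode_channels = panel.barcode_markers
    if len(barcode_channels) != scheme.n_isotopes:
        raise ValueError(
            f"panel has {len(barcode_channels)} barcode channels, scheme expects {scheme.n_isotopes}"
        )
    if len(tables) > scheme.n_keys:
        raise ValueError(f"scheme supports at most {scheme.n_keys} samples, got {len(tables)}")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    blocks, labels, idx = [], [], []
    base_channels = tables[0].channel_names
    for i, table in enumerate(tables):
        if table.channel_names != base_channels:
            raise ValueError("all pooled tables must share identical channel names")
        key = np.array(scheme.keys[i], dtype=float)
        means = negative_mean + separation * key
        z = means + rng.normal(0.0, band_sd, size=(table.n_cells, scheme.n_isotopes))
        raw_bc = np.maximum(np.sinh(z) * table.cofactor, 0.0)
        blocks.append(np.hstack([table.values, raw_bc]))
        labels.append(np.full(table.n_cells, i))
        idx.append(table)

    pooled_meta = SampleMeta("pooled", tables[0].meta.gravity, tables[0].meta.stimulation,
                             tables[0].meta.timepoint_h)
    return EventTable(
        meta=pooled_meta,
        values=np.vstack(blocks),
        channel_names=base_channels + barcode_channels,
        cofactor=tables[0].cofactor,
        true_sample_idx=np.concatenate(labels),
    )


def pool_and_debarcode(
    pooled: EventTable,
    scheme: BarcodeScheme,
    barcode_channels: list[str] | None = None,
    margin: float = 1.0,
    cofactor: float | None = None,
) -> np.ndarray:
    """Assign each pooled event to a barcode key (or ``-1`` if unassigned).

    An event is assigned to key j iff the set of its ``k_positive``
    brightest barcode channels equals key j's positive set and the gap
    between the dimmest positive and brightest negative channel exceeds
    ``margin`` on the arcsinh scale. Ties at the k-th channel never exceed
    a positive margin, so ambiguous events stay unassigned.
    """
    if barcode_channels is None:
        barcode_channels = default_panel().barcode_markers
    missing = [c for c in barcode_channels if c not in pooled.channel_names]
    if missing:
        raise KeyError(f"pooled table is missing barcode channels: {missing}")
    if len(barcode_channels) != scheme.n_isotopes:
        raise ValueError("barcode channel list must match scheme.n_isotopes")

    cofactor = cofactor if cofactor is not None else pooled.cofactor
    cols = [pooled.channel_names.index(c) for c in barcode_channels]
    z = np.arcsinh(pooled.values[:, cols] / cofactor)
    k = scheme.k_positive

    order = np.argsort(z, axis=1)  # ascending
    top_k = order[:, -k:]
    kth = z[np.arange(z.shape[0]), order[:, -k]]
    if k < scheme.n_isotopes:
        next_highest = z[np.arange(z.shape[0]), order[:, -k - 1]]
        ok = (kth - next_highest) > margin
    else:
        ok = np.ones(z.shape[0], dtype=bool)

    key_lookup = {fs: j for j, fs in enumerate(scheme.positive_sets())}
    assignments = np.full(z.shape[0], UNASSIGNED_KEY, dtype=int)
    top_sorted = np.sort(top_k, axis=1)
    for i in np.flatnonzero(ok):
        j = key_lookup.get(frozenset(top_sorted[i].tolist()))
        if j is not None:
            assignments[i] = j
    return assignments
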