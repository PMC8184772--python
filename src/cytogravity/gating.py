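"""Hierarchical threshold gating of single-cell event tables.

Every event descends a tree of 1-D marker-threshold rules evaluated on
arcsinh-transformed intensities; the label is the deepest *leaf* reached.
Events that stop at an internal node (no child's rule set satisfied) are
left unassigned. The default tree partitions PBMC-like data into 18 leaf
subsets spanning the major innate and adaptive compartments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .panel import PanelConfig

POSITIVE = "positive"
NEGATIVE = "negative"
UNASSIGNED = "unassigned"


class GatingError(ValueError):
    """Configuration or schema problem in a gating hierarchy."""


@dataclass(frozen=True)
class GateRule:
    """A single 1-D gate: events pass if marker > threshold (positive)
    or marker <= threshold (negative), on the arcsinh scale."""

    marker: str
    polarity: str
    threshold: float

    def __post_init__(self) -> None:
        if self.polarity not in (POSITIVE, NEGATIVE):
            raise GatingError(f"polarity must be positive/negative, got {self.polarity!r}")

    def passes(self, values: np.ndarray) -> np.ndarray:
        if self.polarity == POSITIVE:
            return values > self.threshold
        return values <= self.threshold


@dataclass
class GateNode:
    name: str
    rules: list[GateRule] = field(default_factory=list)
    children: list["GateNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class GatingHierarchy:
    """Threshold-rule tree whose leaves are the immune subsets."""

    root: GateNode

    @property
    def leaves(self) -> list[str]:
        out: list[str] = []

        def walk(node: GateNode) -> None:
            if node.is_leaf:
                out.append(node.name)
            for child in node.children:
                walk(child)

        walk(self.root)
        return out

    def rule_markers(self) -> set[str]:
        markers: set[str] = set()

        def walk(node: GateNode) -> None:
            markers.update(r.marker for r in node.rules)
            for child in node.children:
                walk(child)

        walk(self.root)
        return markers

    def validate_against_panel(self, panel: PanelConfig) -> None:
        surface = set(panel.surface_markers)
        missing = self.rule_markers() - surface
        if missing:
            raise GatingError(
                f"gating rules reference markers absent from the panel's surface class: {sorted(missing)}"
            )

    def leaf_phenotypes(self) -> dict[str, dict[str, bool]]:
        """Marker positivity implied by each leaf's root-to-leaf rule chain.

        Used by the synthetic generator: markers not mentioned on the path
        are treated as negative.
        """
        out: dict[str, dict[str, bool]] = {}

        def walk(node: GateNode, acc: dict[str, bool]) -> None:
            acc = dict(acc)
            for r in node.rules:
                acc[r.marker] = r.polarity == POSITIVE
            if node.is_leaf:
                out[node.name] = acc
            for child in node.children:
                walk(child, acc)

        walk(self.root, {})
        return out

    # --- serialization -----------------------------------------------------

    def _node_payload(self, node: GateNode) -> dict:
        return {
            "name": node.name,
            "rules": [
                {"marker": r.marker, "polarity": r.polarity, "threshold": float(r.threshold)}
                for r in node.rules
            ],
            "children": [self._node_payload(c) for c in node.children],
        }

    def to_yaml(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self._node_payload(self.root), fh, sort_keys=False, allow_unicode=True)

    @classmethod
    def from_yaml(cls, path: str) -> "GatingHierarchy":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)

        def build(p: dict) -> GateNode:
            rules = [GateRule(r["marker"], r["polarity"], float(r["threshold"])) for r in p.get("rules", [])]
            children = [build(c) for c in p.get("children", [])]
            return GateNode(p["name"], rules, children)

        return cls(root=build(payload))


def _pos(marker: str, t: float) -> GateRule:
    return GateRule(marker, POSITIVE, t)


def _neg(marker: str, t: float) -> GateRule:
    return GateRule(marker, NEGATIVE, t)


def build_default_hierarchy(panel: PanelConfig, threshold: float = 2.05) -> GatingHierarchy:
    """The default 18-leaf PBMC hierarchy.

    Leaves: cMC, intermediate MC, ncMC, mDC, pDC, B naive, B memory,
    NK CD56dim CD16+, NK CD56bright CD16-, NKT, gdT, CD4/CD8 T naive and
    memory, Treg naive/memory and a Lin- remainder. A single global
    threshold on the arcsinh scale separates the generator's negative and
    positive population bands; it is configurable (real data would use
    per-marker thresholds via a custom tree).
    """
    t = threshold

    cd8_branch = GateNode("CD8 T", [_pos("CD8a", t)], [
        GateNode("CD8 T naive", [_pos("CD45RA", t)]),
        GateNode("CD8 T memory", [_neg("CD45RA", t)]),
    ])
    treg_branch = GateNode("Treg", [_pos("FoxP3", t)], [
        GateNode("Treg naive", [_pos("CD45RA", t)]),
        GateNode("Treg memory", [_neg("CD45RA", t)]),
    ])
    cd4_conv = GateNode("CD4 Tconv", [_neg("FoxP3", t)], [
        GateNode("CD4 T naive", [_pos("CD45RA", t)]),
        GateNode("CD4 T memory", [_neg("CD45RA", t)]),
    ])
    cd4_branch = GateNode("CD4 T", [_pos("CD4", t)], [treg_branch, cd4_conv])

    ab_t = GateNode("abT non-NKT", [_neg("CD56", t)], [
        cd8_branch,
        GateNode("CD8- T", [_neg("CD8a", t)], [cd4_branch]),
    ])
    t_branch = GateNode("T cells", [_pos("CD3", t)], [
        GateNode("gdT", [_pos("TCRgd", t)]),
        GateNode("abT", [_neg("TCRgd", t)], [
            GateNode("NKT", [_pos("CD56", t)]),
            ab_t,
        ]),
    ])

    b_branch = GateNode("B cells", [_pos("CD19", t)], [
        GateNode("B memory", [_pos("CD27", t)]),
        GateNode("B naive", [_neg("CD27", t)]),
    ])
    nk_branch = GateNode("NK cells", [_pos("CD56", t)], [
        GateNode("NK CD56dim CD16+", [_pos("CD16", t)]),
        GateNode("NK CD56bright CD16-", [_neg("CD16", t)]),
    ])
    mono_pos = GateNode("CD14+ MC", [_pos("CD14", t)], [
        GateNode("intermediate MC", [_pos("CD16", t)]),
        GateNode("cMC", [_neg("CD16", t)]),
    ])
    cd14_neg = GateNode("CD14- myeloid", [_neg("CD14", t)], [
        GateNode("ncMC", [_pos("CD16", t)]),
        GateNode("DC/other", [_neg("CD16", t)], [
            GateNode("pDC", [_pos("CD123", t)]),
            GateNode("CD123-", [_neg("CD123", t)], [
                GateNode("mDC", [_pos("CD11c", t)]),
                GateNode("Lin- remainder", [_neg("CD11c", t)]),
            ]),
        ]),
    ])
    non_t = GateNode("non-T", [_neg("CD3", t)], [
        b_branch,
        GateNode("CD19-", [_neg("CD19", t)], [
            nk_branch,
            GateNode("CD56-", [_neg("CD56", t)], [mono_pos, cd14_neg]),
        ]),
    ])

    root = GateNode("CD45+", [_pos("CD45", t)], [t_branch, non_t])
    hierarchy = GatingHierarchy(root=root)
    hierarchy.validate_against_panel(panel)
    if len(hierarchy.leaves) != 18:
        raise GatingError(f"default hierarchy must have 18 leaves, got {len(hierarchy.leaves)}")
    return hierarchy


def apply_gating(events, hierarchy: GatingHierarchy, cofactor: float | None = None) -> np.ndarray:
    """Label each event with its leaf subset (or ``'unassigned'``).

    ``events`` is an :class:`~cytogravity.simulate.EventTable`; gating is
    evaluated on arcsinh-transformed intensities. Children are evaluated in
    tree order and an event follows the first child whose rules it
    satisfies (the default tree's siblings are mutually exclusive, so order
    never matters there).
    """
    cofactor = events_cofactor(events, cofactor)
    missing = hierarchy.rule_markers() - set(events.channel_names)
    if missing:
        raise GatingError(f"event table lacks channels required by gating rules: {sorted(missing)}")

    col = {name: i for i, name in enumerate(events.channel_names)}
    z = np.arcsinh(events.values / cofactor)
    n = z.shape[0]
    labels = np.full(n, UNASSIGNED, dtype=object)

    def rules_mask(rules: list[GateRule], idx: np.ndarray) -> np.ndarray:
        mask = np.ones(idx.shape[0], dtype=bool)
        for r in rules:
            mask &= r.passes(z[idx, col[r.marker]])
        return mask

    def descend(node: GateNode, idx: np.ndarray) -> None:
        if node.is_leaf:
            labels[idx] = node.name
            return
        remaining = idx
        for child in node.children:
            if remaining.size == 0:
                break
            mask = rules_mask(child.rules, remaining)
            descend(child, remaining[mask])
            remaining = remaining[~mask]

    root_idx = np.arange(n)
    mask = rules_mask(hierarchy.root.rules, root_idx)
    descend_root = root_idx[mask]
    if hierarchy.root.is_leaf:
        labels[descend_root] = hierarchy.root.name
    else:
        descend(hierarchy.root, descend_root)
    return labels


def events_cofactor(events, cofactor: float | None) -> float:
    if cofactor is not None:
        return cofactor
    cf = getattr(events, "cofactor", None)
    if cf is None:
        raise GatingError("no arcsinh cofactor available; pass one explicitly")
    return cf


def compute_frequencies(labels: np.ndarray, leaves: list[str]) -> pd.Series:
    """Per-leaf fraction of events plus the unassigned remainder.

    The returned Series is indexed by the leaf names followed by
    ``'unassigned'`` and sums to 1.
    """
    labels = np.asarray(labels, dtype=object)
    if labels.size == 0:
        raise ValueError("cannot compute frequencies over zero events")
    n = labels.size
    counts = pd.Series(labels).value_counts()
    freqs = pd.Series(
        [counts.get(leaf, 0) / n for leaf in leaves] + [counts.get(UNASSIGNED, 0) / n],
        index=list(leaves) + [UNASSIGNED],
        dtype=float,
    )
    return freqs
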