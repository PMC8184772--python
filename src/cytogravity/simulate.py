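"""Synthetic CyTOF experiment generation with ground truth.

The generator emulates the study design this package analyzes: PBMCs from
``n_donors`` healthy donors are exposed for 18 h to normal gravity (1G) or
rotating-wall-vessel simulated microgravity (sµG), then analyzed
unstimulated (0 h) and after ConA/anti-CD28 stimulation (4 h; an optional
1.5 h timepoint is supported). Each sample is a cells x channels table of
nonnegative ion-count-like intensities.

Generative model (per cell):

* subset membership is multinomial over the 18 gating-tree leaves;
* each surface marker is Gaussian on the arcsinh scale around a high band
  (subset positive for the marker per the gating tree's phenotype) or a low
  band (negative);
* each functional marker is Gaussian on the arcsinh scale around
  ``base + donor intercept + stim response + configured condition shifts``,
  where the stimulation response carries a per-(donor, marker) random
  slope — donors differ in overall pathway responsiveness — which makes
  same-marker response features correlated across subsets, emulating the
  strong inter-correlation of real signaling features;
* arcsinh-scale draws are inverse-transformed (``sinh(z) * cofactor``) and
  floored at 0 to produce raw intensities.

Condition shifts come from an :class:`EffectSpec` whose entries act on the
stimulation axis, the gravity axis (basal sµG effect, present in stim and
unstim samples alike), or their interaction (sµG effect on the stimulation
response only). The spec is returned alongside the samples and serves as
recovery ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .gating import GatingHierarchy, build_default_hierarchy
from .panel import PanelConfig, default_panel

GRAVITY_1G = "1G"
GRAVITY_SUG = "sµG"
STIM_NONE = "unstim"
STIM_CONA = "ConA/anti-CD28"

AXIS_STIM = "stimulation"
AXIS_GRAVITY = "gravity"
AXIS_INTERACTION = "gravity_x_stimulation"
_AXES = (AXIS_STIM, AXIS_GRAVITY, AXIS_INTERACTION)


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SampleMeta:
    donor_id: str
    gravity: str
    stimulation: str
    timepoint_h: float
    barcode_key_index: int | None = None

    def __post_init__(self) -> None:
        if self.gravity not in (GRAVITY_1G, GRAVITY_SUG):
            raise SimConfigError(f"gravity must be {GRAVITY_1G!r} or {GRAVITY_SUG!r}")
        if self.stimulation not in (STIM_NONE, STIM_CONA):
            raise SimConfigError("unknown stimulation state")
        if self.timepoint_h == 0 and self.stimulation != STIM_NONE:
            raise SimConfigError("timepoint 0 h must be unstimulated")


@dataclass
class EventTable:
    """One sample's cells x channels nonnegative intensity matrix."""

    meta: SampleMeta
    values: np.ndarray
    channel_names: list[str]
    cofactor: float = 5.0
    true_labels: np.ndarray | None = None
    true_sample_idx: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (cells x channels)")
        if self.values.shape[0] < 1:
            raise ValueError("event table needs at least one cell")
        if self.values.shape[1] != len(self.channel_names):
            raise ValueError("channel_names must match the value matrix width")
        if not np.isfinite(self.values).all() or (self.values < 0).any():
            raise ValueError("intensities must be finite and nonnegative")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def channel(self, name: str) -> np.ndarray:
        return self.values[:, self.channel_names.index(name)]


@dataclass(frozen=True)
class EffectEntry:
    subset: str
    marker: str
    axis: str
    shift: float

    def __post_init__(self) -> None:
        if self.axis not in _AXES:
            raise SimConfigError(f"axis must be one of {_AXES}, got {self.axis!r}")


@dataclass
class EffectSpec:
    """Ground-truth condition shifts on the arcsinh scale."""

    entries: list[EffectEntry] = field(default_factory=list)

    def validate(self, leaves: list[str], functional_markers: list[str]) -> None:
        for e in self.entries:
            if e.subset not in leaves:
                raise SimConfigError(f"effect subset {e.subset!r} is not a hierarchy leaf")
            if e.marker not in functional_markers:
                raise SimConfigError(f"effect marker {e.marker!r} is not a functional marker")

    def by_axis(self, axis: str) -> list[EffectEntry]:
        return [e for e in self.entries if e.axis == axis]


def default_effect_spec() -> EffectSpec:
    """Condition shifts emulating the reported sµG immune phenotype.

    On the stimulation response (gravity x stimulation axis): pSTAT5
    increased in Tregs; CD25 decreased in CD8 T subsets and CD56dim NK
    cells; CD69 decreased in CD4 and CD8 T subsets; pSTAT1 decreased in
    CD8 T subsets. On the basal (gravity) axis: lower Treg pSTAT5 and
    lower mDC MyD88-pathway tone after sµG. Magnitudes are 1.0 arcsinh
    unit for response effects and 0.5 for basal effects.
    """
    gx = AXIS_INTERACTION
    g = AXIS_GRAVITY
    entries = [
        EffectEntry("Treg naive", "pSTAT5", gx, +1.0),
        EffectEntry("Treg memory", "pSTAT5", gx, +1.0),
        EffectEntry("NK CD56dim CD16+", "CD25", gx, -1.0),
        EffectEntry("CD8 T naive", "CD25", gx, -1.0),
        EffectEntry("CD8 T memory", "CD25", gx, -1.0),
        EffectEntry("CD8 T naive", "CD69", gx, -1.0),
        EffectEntry("CD8 T memory", "CD69", gx, -1.0),
        EffectEntry("CD4 T naive", "CD69", gx, -1.0),
        EffectEntry("CD4 T memory", "CD69", gx, -1.0),
        EffectEntry("CD8 T naive", "pSTAT1", gx, -1.0),
        EffectEntry("CD8 T memory", "pSTAT1", gx, -1.0),
        EffectEntry("Treg naive", "pSTAT5", g, -0.5),
        EffectEntry("Treg memory", "pSTAT5", g, -0.5),
        EffectEntry("mDC", "pMAPKAPK2", g, -0.5),
        EffectEntry("mDC", "pP38", g, -0.5),
        EffectEntry("mDC", "pNFkB", g, -0.5),
        EffectEntry("mDC", "pERK1/2", g, -0.5),
    ]
    return EffectSpec(entries)


def default_subset_proportions() -> dict[str, float]:
    """PBMC-realistic leaf proportions (sum to 1)."""
    return {
        "gdT": 0.03,
        "NKT": 0.03,
        "CD8 T naive": 0.08,
        "CD8 T memory": 0.08,
        "Treg naive": 0.02,
        "Treg memory": 0.03,
        "CD4 T naive": 0.15,
        "CD4 T memory": 0.15,
        "B memory": 0.04,
        "B naive": 0.06,
        "NK CD56dim CD16+": 0.10,
        "NK CD56bright CD16-": 0.02,
        "intermediate MC": 0.03,
        "cMC": 0.12,
        "ncMC": 0.03,
        "pDC": 0.01,
        "mDC": 0.015,
        "Lin- remainder": 0.005,
    }


@dataclass
class SimConfig:
    """Full specification of a synthetic experiment.

    All means, SDs and shifts are on the arcsinh scale. Defaults follow
    the emulated study: 8 donors, 2 gravity conditions, unstimulated plus
    4 h stimulated samples.
    """

    n_donors: int = 8
    cells_per_sample: int = 5000
    subset_proportions: dict[str, float] = field(default_factory=default_subset_proportions)
    surface_lo: float = 0.6
    surface_hi: float = 3.5
    surface_sd: float = 0.35
    functional_base: float = 1.0
    functional_sd: float = 0.3
    stim_response: float = 0.8
    donor_sd: float = 0.2
    donor_response_sd: float = 0.15
    effect_spec: EffectSpec = field(default_factory=default_effect_spec)
    baseline_means: dict[tuple[str, str], float] = field(default_factory=dict)
    include_early_timepoint: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_donors < 2:
            raise SimConfigError("need at least 2 donors")
        if self.cells_per_sample < 1:
            raise SimConfigError("cells_per_sample must be positive")
        total = float(sum(self.subset_proportions.values()))
        if abs(total - 1.0) > 1e-9:
            raise SimConfigError(f"subset_proportions must sum to 1, got {total}")
        if any(p < 0 for p in self.subset_proportions.values()):
            raise SimConfigError("subset_proportions must be nonnegative")
        if self.donor_sd < 0 or self.donor_response_sd < 0:
            raise SimConfigError("donor effect SDs must be nonnegative")

    def null_copy(self) -> "SimConfig":
        """Same conditions with every gravity-linked effect removed."""
        spec = EffectSpec([e for e in self.effect_spec.entries if e.axis == AXIS_STIM])
        return replace(self, effect_spec=spec)


def simulate_experiment(
    config: SimConfig,
    panel: PanelConfig | None = None,
    hierarchy: GatingHierarchy | None = None,
) -> tuple[list[EventTable], EffectSpec]:
    """Generate one full synthetic experiment.

    Returns one :class:`EventTable` per (donor, gravity, timepoint) sample
    — unstimulated 0 h and stimulated 4 h by default — plus the effect
    spec as recovery ground truth. Identical config and seed give
    bit-identical output. Tables carry per-cell ground-truth subset labels
    in ``true_labels``; barcode channels are added separately by
    :func:`cytogravity.barcode.pool_samples`.
    """
    panel = panel if panel is not None else default_panel()
    hierarchy = hierarchy if hierarchy is not None else build_default_hierarchy(panel)
    leaves = hierarchy.leaves
    missing = set(config.subset_proportions) - set(leaves)
    if missing:
        raise SimConfigError(f"proportions given for unknown subsets: {sorted(missing)}")
    if set(leaves) - set(config.subset_proportions):
        raise SimConfigError("subset_proportions must cover every hierarchy leaf")
    config.effect_spec.validate(leaves, panel.functional_markers)

    surface = panel.surface_markers
    functional = panel.functional_markers
    n_s, n_f, n_leaves = len(surface), len(functional), len(leaves)

    pheno = hierarchy.leaf_phenotypes()
    surface_means = np.full((n_leaves, n_s), config.surface_lo)
    for i, leaf in enumerate(leaves):
        for j, m in enumerate(surface):
            if pheno[leaf].get(m, False):
                surface_means[i, j] = config.surface_hi

    base_means = np.full((n_leaves, n_f), config.functional_base)
    for (subset, marker), mean in config.baseline_means.items():
        base_means[leaves.index(subset), functional.index(marker)] = mean

    shift = {ax: np.zeros((n_leaves, n_f)) for ax in _AXES}
    for e in config.effect_spec.entries:
        shift[e.axis][leaves.index(e.subset), functional.index(e.marker)] += e.shift

    props = np.array([config.subset_proportions[leaf] for leaf in leaves])
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    donor_intercepts = rng.normal(0.0, config.donor_sd, size=(config.n_donors, n_f))
    donor_response = rng.normal(0.0, config.donor_response_sd, size=(config.n_donors, n_f))

    timepoints: list[tuple[float, str]] = [(0.0, STIM_NONE)]
    if config.include_early_timepoint:
        timepoints.append((1.5, STIM_CONA))
    timepoints.append((4.0, STIM_CONA))

    channel_names = surface + functional
    tables: list[EventTable] = []
    for d in range(config.n_donors):
        donor_id = f"D{d + 1:02d}"
        for gravity in (GRAVITY_1G, GRAVITY_SUG):
            g = 1.0 if gravity == GRAVITY_SUG else 0.0
            for timepoint, stim_state in timepoints:
                s = 1.0 if stim_state == STIM_CONA else 0.0
                n = config.cells_per_sample
                subset_idx = rng.choice(n_leaves, size=n, p=props)

                z_surface = surface_means[subset_idx] + rng.normal(0.0, config.surface_sd, size=(n, n_s))
                f_means = (
                    base_means[subset_idx]
                    + donor_intercepts[d]
                    + s * (config.stim_response + donor_response[d] + shift[AXIS_STIM][subset_idx])
                    + g * shift[AXIS_GRAVITY][subset_idx]
                    + s * g * shift[AXIS_INTERACTION][subset_idx]
                )
                z_functional = f_means + rng.normal(0.0, config.functional_sd, size=(n, n_f))

                z = np.hstack([z_surface, z_functional])
                raw = np.maximum(np.sinh(z) * panel.cofactor, 0.0)
                meta = SampleMeta(donor_id, gravity, stim_state, timepoint)
                tables.append(
                    EventTable(
                        meta=meta,
                        values=raw,
                        channel_names=list(channel_names),
                        cofactor=panel.cofactor,
                        true_labels=np.array([leaves[i] for i in subset_idx], dtype=object),
                    )
                )
    return tables, config.effect_spec
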