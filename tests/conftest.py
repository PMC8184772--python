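import numpy as np
import pytest

import cytogravity as cg


@pytest.fixture(scope="session")
def panel():
    return cg.default_panel()


@pytest.fixture(scope="session")
def hierarchy(panel):
    return cg.build_default_hierarchy(panel)


@pytest.fixture(scope="session")
def small_experiment(panel, hierarchy):
    """4 donors x 1200 cells/sample with the default injected effects."""
    config = cg.SimConfig(n_donors=4, cells_per_sample=1200, seed=11)
    tables, effect_spec = cg.simulate_experiment(config, panel, hierarchy)
    return config, tables, effect_spec


@pytest.fixture(scope="session")
def small_gated(small_experiment, hierarchy):
    _, tables, _ = small_experiment
    return [(t, cg.apply_gating(t, hierarchy)) for t in tables]


@pytest.fixture(scope="session")
def response_matrix(small_gated, hierarchy, panel):
    return cg.build_feature_matrix(small_gated, hierarchy, panel, "response")


def make_event_table(panel, marker_levels, n_cells=1, gravity="1G",
                     stimulation="unstim", timepoint=0.0, donor="D01"):
    """Event table with arcsinh-scale levels per marker (default low band)."""
    channels = panel.surface_markers + panel.functional_markers
    z = np.full((n_cells, len(channels)), 0.5)
    for marker, level in marker_levels.items():
        z[:, channels.index(marker)] = level
    raw = np.maximum(np.sinh(z) * panel.cofactor, 0.0)
    meta = cg.SampleMeta(donor, gravity, stimulation, timepoint)
    return cg.EventTable(meta=meta, values=raw, channel_names=channels,
                         cofactor=panel.cofactor)
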