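"""End-to-end orchestration: simulate → gate → features → screens → EN → network.

One :func:`run_pipeline` call executes the full analysis under a single
seed and writes every artifact as plain text (CSV/TSV/GraphML/JSON) into
the output directory. Each randomized stage derives its seed from the
global seed plus a fixed per-stage offset, so stages can be re-run in
isolation and reproduce the full-run results exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .en import (
    CVResult,
    ModelSignificance,
    component_report,
    cv_lambda_path,
    nested_model_significance,
)
from .features import (
    MODE_ABUNDANCE,
    MODE_BASAL,
    MODE_RESPONSE,
    FeatureMatrix,
    build_feature_matrix,
)
from .gating import GatingHierarchy, apply_gating, build_default_hierarchy
from .panel import PanelConfig, default_panel
from .simulate import AXIS_GRAVITY, AXIS_INTERACTION, EventTable, SimConfig, simulate_experiment
from .stats import UndefinedTestError, bky_two_stage_fdr, wilcoxon_signed_rank_exact

logger = logging.getLogger("cytogravity")

STAGE_SEED_OFFSETS = {"simulate": 0, "en": 1, "layout": 2, "communities": 3}


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    seed: int = 0
    outdir: str = "cytogravity_run"
    sim: SimConfig = field(default_factory=SimConfig)
    events_dir: str | None = None  # real-data entry point: per-sample CSVs
    hierarchy_path: str | None = None
    panel_path: str | None = None
    fdr_q: float = 0.01
    en_mixing: float = 0.5
    en_n_lambda: int = 50
    en_decades: float = 4.0
    en_report_lambda: str = "1se"
    min_cells: int = 20
    write_events: bool = False

    def to_yaml(self, path: str) -> None:
        payload = dataclasses.asdict(self)
        payload["sim"]["effect_spec"] = [
            dataclasses.asdict(e) for e in self.sim.effect_spec.entries
        ]
        payload["sim"]["baseline_means"] = {
            f"{s}|{m}": v for (s, m), v in self.sim.baseline_means.items()
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False, allow_unicode=True)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        from .simulate import EffectEntry, EffectSpec

        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        sim_payload = payload.pop("sim", {})
        entries = [EffectEntry(**e) for e in sim_payload.pop("effect_spec", [])]
        baseline = {
            tuple(k.split("|", 1)): float(v)
            for k, v in sim_payload.pop("baseline_means", {}).items()
        }
        sim = SimConfig(effect_spec=EffectSpec(entries), baseline_means=baseline, **sim_payload)
        return cls(sim=sim, **payload)


@dataclass
class RunReport:
    config_fingerprint: str
    paths: dict[str, str]
    summary: dict

    def to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "config_fingerprint": self.config_fingerprint,
                    "paths": self.paths,
                    "summary": self.summary,
                },
                fh,
                indent=1,
                sort_keys=True,
                ensure_ascii=False,
            )


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def validate_inputs(
    config: RunConfig,
    panel: PanelConfig | None = None,
    hierarchy: GatingHierarchy | None = None,
    tables: list[EventTable] | None = None,
) -> list[str]:
    """Consistency diagnostics (actionable messages; never raises)."""
    diags: list[str] = []
    try:
        panel = panel or _load_panel(config)
        hierarchy = hierarchy or _load_hierarchy(config, panel)
    except Exception as exc:  # noqa: BLE001
        diags.append(f"schema: {exc}")
        return diags
    missing = hierarchy.rule_markers() - set(panel.surface_markers)
    if missing:
        diags.append(f"schema: gating rules reference non-surface markers {sorted(missing)}")
    leaves = set(hierarchy.leaves)
    extra = set(config.sim.subset_proportions) - leaves
    if extra:
        diags.append(f"config: proportions for unknown subsets {sorted(extra)}")
    if tables is not None:
        units: dict[tuple[str, str], set[str]] = {}
        for t in tables:
            slot = "unstim" if t.meta.stimulation == "unstim" else "stim"
            units.setdefault((t.meta.donor_id, t.meta.gravity), set()).add(slot)
        for key, slots in sorted(units.items()):
            for need in ("unstim", "stim"):
                if need not in slots:
                    diags.append(f"pairing: unit {key} is missing its {need} sample")
        donors = {k[0] for k in units}
        for d in sorted(donors):
            gravities = {k[1] for k in units if k[0] == d}
            if len(gravities) != 2:
                diags.append(f"pairing: donor {d} lacks one gravity condition")
    return diags


def _load_panel(config: RunConfig) -> PanelConfig:
    if config.panel_path:
        return PanelConfig.from_yaml(config.panel_path)
    return default_panel()


def _load_hierarchy(config: RunConfig, panel: PanelConfig) -> GatingHierarchy:
    if config.hierarchy_path:
        h = GatingHierarchy.from_yaml(config.hierarchy_path)
        h.validate_against_panel(panel)
        return h
    return build_default_hierarchy(panel)


def _fingerprint(config: RunConfig) -> str:
    payload = dataclasses.asdict(config)
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _paired_screen(fm: FeatureMatrix, q: float) -> pd.DataFrame:
    """Per-feature paired Wilcoxon (sµG - 1G per donor) + two-stage FDR."""
    df = fm.data
    donors = sorted(set(df.index.get_level_values("donor")))
    diffs = np.empty((len(donors), df.shape[1]))
    for i, d in enumerate(donors):
        sug = df.loc[(d, "sµG")].to_numpy(dtype=float)
        one = df.loc[(d, "1G")].to_numpy(dtype=float)
        diffs[i] = sug - one
    rows = []
    for j, col in enumerate(df.columns):
        dj = diffs[:, j]
        dj = dj[~np.isnan(dj)]
        try:
            res = wilcoxon_signed_rank_exact(dj)
            rows.append((res.statistic, res.p_two_sided, res.n_effective, False))
        except (UndefinedTestError, ValueError):
            rows.append((np.nan, 1.0, 0, True))
    out = pd.DataFrame(rows, columns=["W", "p", "n_effective", "degenerate"])
    out.insert(0, "feature", ["|".join(map(str, c)) for c in df.columns])
    fdr = bky_two_stage_fdr(out["p"].to_numpy(), q)
    out["q_level"] = q
    out["discovery"] = fdr.discoveries
    return out


def _en_stage(fm: FeatureMatrix, config: RunConfig) -> tuple[CVResult, ModelSignificance | None, FeatureMatrix]:
    imputed = fm.impute()
    cv = cv_lambda_path(
        imputed.X,
        imputed.y(),
        imputed.donors,
        mixing=config.en_mixing,
        n_lambda=config.en_n_lambda,
        decades=config.en_decades,
        seed=config.seed + STAGE_SEED_OFFSETS["en"],
    )
    try:
        sig = nested_model_significance(
            imputed.X,
            imputed.y(),
            imputed.donors,
            which=config.en_report_lambda,
            mixing=config.en_mixing,
            n_lambda=config.en_n_lambda,
            decades=config.en_decades,
            seed=config.seed + STAGE_SEED_OFFSETS["en"],
        )
    except UndefinedTestError:
        sig = None
    return cv, sig, imputed


def _cv_payload(cv: CVResult, sig: ModelSignificance | None, feature_ids: list) -> dict:
    fit = cv.fit_1se
    return {
        "lambda_grid": cv.lambda_grid.tolist(),
        "cv_error_mean": cv.cv_error_mean.tolist(),
        "cv_error_sd": cv.cv_error_sd.tolist(),
        "lambda_min": cv.lambda_min,
        "lambda_1se": cv.lambda_1se,
        "mixing": cv.mixing,
        "degenerate": cv.degenerate,
        "notes": cv.notes,
        "fold_donors": cv.fold_donors,
        "beta_1se": {
            "|".join(map(str, fid)): float(b)
            for fid, b in zip(feature_ids, fit.beta)
            if b != 0
        },
        "beta_min": {
            "|".join(map(str, fid)): float(b)
            for fid, b in zip(feature_ids, cv.fit_min.beta)
            if b != 0
        },
        "n_nonzero_1se": fit.n_nonzero,
        "n_nonzero_min": cv.fit_min.n_nonzero,
        "objective_1se": fit.objective,
        "model_significance": None
        if sig is None
        else {
            "p": sig.test.p_two_sided,
            "W": sig.test.statistic,
            "n": sig.test.n_effective,
            "method": sig.test.method,
            "differences": sig.differences.tolist(),
        },
    }


def _recovery_summary(cv: CVResult, feature_ids: list, effect_entries, axis: str, which: str) -> dict:
    truth: dict[tuple[str, str], float] = {}
    for e in effect_entries:
        if e.axis == axis:
            truth[(e.subset, e.marker)] = truth.get((e.subset, e.marker), 0.0) + e.shift
    fit = cv.fit(which)
    beta_by_sm = {(fid[0], fid[1]): b for fid, b in zip(feature_ids, fit.beta)}
    n_truth = len(truth)
    recovered = sum(
        1
        for sm, shift in truth.items()
        if np.sign(beta_by_sm.get(sm, 0.0)) == np.sign(shift) and beta_by_sm.get(sm, 0.0) != 0
    )
    return {
        "n_injected": n_truth,
        "n_recovered_correct_sign": recovered,
        "recovery_fraction": recovered / n_truth if n_truth else float("nan"),
    }


def run_pipeline(
    config: RunConfig,
    tables: list[EventTable] | None = None,
) -> RunReport:
    """Execute the full analysis and write all artifacts to ``config.outdir``.

    With ``tables=None`` a synthetic experiment is generated from
    ``config.sim`` (stage seed = global seed); passing real event tables
    skips simulation (and ground-truth recovery). Identical config + seed
    reproduce byte-identical output files.
    """
    os.makedirs(config.outdir, exist_ok=True)
    paths: dict[str, str] = {}
    summary: dict = {}
    t0 = time.time()

    def stage(name):
        logger.info("stage %-10s t=%.1fs", name, time.time() - t0)

    try:
        stage("setup")
        panel = _load_panel(config)
        hierarchy = _load_hierarchy(config, panel)
        effect_spec = None
        synthetic = tables is None
        if synthetic:
            stage("simulate")
            sim = dataclasses.replace(config.sim, seed=config.seed + STAGE_SEED_OFFSETS["simulate"])
            tables, effect_spec = simulate_experiment(sim, panel, hierarchy)
            if config.write_events:
                events_dir = os.path.join(config.outdir, "events")
                for t in tables:
                    cio.write_event_table(t, events_dir)
                paths["events"] = events_dir
    except Exception as exc:  # noqa: BLE001
        raise StageError("simulate", exc) from exc

    try:
        stage("gate")
        gated = [(t, apply_gating(t, hierarchy)) for t in tables]
    except Exception as exc:  # noqa: BLE001
        raise StageError("gate", exc) from exc

    try:
        stage("features")
        fm_resp = build_feature_matrix(gated, hierarchy, panel, MODE_RESPONSE, config.min_cells)
        fm_basal = build_feature_matrix(gated, hierarchy, panel, MODE_BASAL, config.min_cells)
        fm_abund = build_feature_matrix(gated, hierarchy, panel, MODE_ABUNDANCE, config.min_cells)
        for name, fm in (("response", fm_resp), ("basal", fm_basal), ("abundance", fm_abund)):
            p = os.path.join(config.outdir, f"features_{name}.csv")
            fm.to_csv(p)
            paths[f"features_{name}"] = p
        summary["n_response_features"] = int(fm_resp.data.shape[1])
        summary["n_samples"] = int(fm_resp.data.shape[0])
    except Exception as exc:  # noqa: BLE001
        raise StageError("features", exc) from exc

    try:
        stage("screen")
        univariate = _paired_screen(fm_resp.impute(), config.fdr_q)
        abund_tests = _paired_screen(fm_abund, config.fdr_q)
        p = os.path.join(config.outdir, "univariate_response.tsv")
        cio.write_tsv(univariate, p)
        paths["univariate_response"] = p
        p = os.path.join(config.outdir, "abundance_tests.tsv")
        cio.write_tsv(abund_tests, p)
        paths["abundance_tests"] = p
        summary["n_response_discoveries"] = int(univariate["discovery"].sum())
        summary["n_abundance_discoveries"] = int(abund_tests["discovery"].sum())
    except Exception as exc:  # noqa: BLE001
        raise StageError("screen", exc) from exc

    try:
        stage("fit-en")
        feature_ids = list(fm_resp.data.columns)
        cv_resp, sig_resp, _ = _en_stage(fm_resp, config)
        payload = _cv_payload(cv_resp, sig_resp, feature_ids)
        basal_ids = list(fm_basal.data.columns)
        cv_basal, sig_basal, _ = _en_stage(fm_basal, config)
        basal_payload = _cv_payload(cv_basal, sig_basal, basal_ids)
        for name, pl in (("en_response", payload), ("en_basal", basal_payload)):
            p = os.path.join(config.outdir, f"{name}.json")
            with open(p, "w", encoding="utf-8") as fh:
                json.dump(pl, fh, indent=1, sort_keys=True, ensure_ascii=False)
            paths[name] = p
        summary["model_significance_p_response"] = (
            None if sig_resp is None else sig_resp.test.p_two_sided
        )
        summary["model_significance_p_basal"] = (
            None if sig_basal is None else sig_basal.test.p_two_sided
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("fit-en", exc) from exc

    try:
        stage("network")
        from .network import annotate_communities, build_network, detect_communities, layout_2d

        net = build_network(fm_resp.impute())
        communities = detect_communities(net, seed=config.seed + STAGE_SEED_OFFSETS["communities"])
        annotations = annotate_communities(communities)
        layout_2d(net, seed=config.seed + STAGE_SEED_OFFSETS["layout"])
        p = os.path.join(config.outdir, "network.graphml")
        nx.write_graphml(net.to_graph(), p)
        paths["network_graphml"] = p
        p = os.path.join(config.outdir, "network_edges.tsv")
        cio.write_tsv(net.edge_table(), p)
        paths["network_edges"] = p
        nodes_df = pd.DataFrame(
            {
                "node": ["|".join(map(str, n)) for n in net.nodes],
                "community": [communities[n] for n in net.nodes],
                "x": [net.layout[n][0] for n in net.nodes],
                "y": [net.layout[n][1] for n in net.nodes],
            }
        )
        p = os.path.join(config.outdir, "network_nodes.tsv")
        cio.write_tsv(nodes_df, p)
        paths["network_nodes"] = p
        summary["n_network_nodes"] = net.n_nodes
        summary["n_network_edges"] = net.n_edges
        summary["n_communities"] = len(set(communities.values()))
        summary["community_annotations"] = {
            str(k): v["attribute"] for k, v in sorted(annotations.items())
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("network", exc) from exc

    try:
        stage("report")
        pmap = {tuple(f.split("|")): p for f, p in zip(univariate["feature"], univariate["p"])}
        qmap = {tuple(f.split("|")): d for f, d in zip(univariate["feature"], univariate["discovery"])}
        comm_by_id = {n: c for n, c in communities.items()}
        report_df = component_report(
            cv_resp.fit(config.en_report_lambda),
            feature_ids,
            p_values=[pmap.get(tuple(map(str, fid)), np.nan) for fid in feature_ids],
            q_flags=[bool(qmap.get(tuple(map(str, fid)), False)) for fid in feature_ids],
            communities=comm_by_id,
        )
        p = os.path.join(config.outdir, "component_report.tsv")
        cio.write_tsv(report_df, p)
        paths["component_report"] = p

        if synthetic and effect_spec is not None:
            summary["recovery_response"] = _recovery_summary(
                cv_resp, feature_ids, effect_spec.entries, AXIS_INTERACTION, config.en_report_lambda
            )
            summary["recovery_basal"] = _recovery_summary(
                cv_basal, basal_ids, effect_spec.entries, AXIS_GRAVITY, config.en_report_lambda
            )
        summary["seed"] = config.seed
        report = RunReport(_fingerprint(config), paths, summary)
        rp = os.path.join(config.outdir, "report.json")
        report.to_json(rp)
        report.paths["report"] = rp
        return report
    except Exception as exc:  # noqa: BLE001
        raise StageError("report", exc) from exc
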