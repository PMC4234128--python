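"""End-to-end, config-driven pipeline.

Stages: read/validate inputs → control model + fold-changes → kinetic
clustering → dose-sensitivity classes → pathway scale + bias records →
correlation panel → per-line and per-subtype graphs → summary table and run
manifest.  Identical config and inputs produce identical outputs; any stage
failure aborts with the stage name.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bias import bias_records, correlate_panel, fit_pathway_scale
from .classify import assign_kinetics, assign_sensitivity
from .config import RunConfig
from .constants import TARGETS
from .errors import GFResponseError, PipelineError
from .io import (ResponseCube, read_basal_table, read_ligand_receptor_map,
                 read_response_table, read_subtype_table, write_summary_table)
from .metrics import assemble_summary, compute_fold_changes, fit_control_model
from .network import build_graph, build_subtype_graph, compute_panel_norms, export_graph
from .synthetic import PanelBundle


@dataclass
class PipelineResult:
    responses: pd.DataFrame
    kinetics: pd.DataFrame
    sensitivity: pd.DataFrame
    summary: pd.DataFrame
    alpha: float
    bias: pd.DataFrame
    correlations: pd.DataFrame
    norms: dict
    manifest: dict


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except GFResponseError as exc:
                if isinstance(exc, PipelineError):
                    raise
                raise PipelineError(name, str(exc)) from exc
        return wrapped
    return deco


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, inputs: PanelBundle | None = None,
                 write: bool = True) -> PipelineResult:
    """Run every stage.

    ``inputs`` supplies an in-memory panel (e.g. from the synthetic
    generator) instead of reading ``config``'s input paths.
    """
    cfg = config
    checksums = {}

    # -- load ---------------------------------------------------------------
    load = _stage("load")(_load_inputs)
    cube, basal, lrmap, subtypes, checksums = load(cfg, inputs)

    # -- fold changes -------------------------------------------------------
    @_stage("fold_changes")
    def _fold():
        model = fit_control_model(cube)
        return compute_fold_changes(cube, model, cfg.sd_multiplier)
    responses = _fold()

    # -- kinetics -----------------------------------------------------------
    @_stage("kinetics")
    def _kin():
        return assign_kinetics(responses, k=cfg.kinetics_k, seed=cfg.seed,
                               restarts=cfg.kinetics_restarts,
                               normalize=cfg.normalize_trajectories,
                               sd_multiplier=cfg.sd_multiplier)
    kinetics, clf = _kin()

    # -- sensitivity --------------------------------------------------------
    @_stage("sensitivity")
    def _sens():
        return assign_sensitivity(responses, cfg.sensitivity_ratio, cfg.sensitivity_mode)
    sensitivity = _sens()

    # -- pathway scale + bias ----------------------------------------------
    @_stage("bias")
    def _bias():
        if cfg.fixed_alpha is not None:
            alpha = float(cfg.fixed_alpha)
        else:
            high = responses[responses["dose"] == cfg.bias_dose]
            if cfg.scale_significant_only:
                high = high[high["significant"]]
            perk = 10.0 ** high.loc[high["target"] == "pERK", "max_fold_change"].to_numpy()
            pakt = 10.0 ** high.loc[high["target"] == "pAKT", "max_fold_change"].to_numpy()
            grid = np.geomspace(cfg.scale_grid_min, cfg.scale_grid_max, cfg.scale_grid_size)
            alpha = fit_pathway_scale(pakt, perk, grid=grid)
        rec = bias_records(responses, alpha, dose=cfg.bias_dose, bias_scale=cfg.bias_scale)
        return alpha, rec
    alpha, bias = _bias()

    # -- correlations -------------------------------------------------------
    @_stage("correlate")
    def _corr():
        if basal is None:
            return pd.DataFrame()
        return correlate_panel(responses, basal, method=cfg.corr_method,
                               dose=cfg.bias_dose, adjust=cfg.corr_adjust)
    correlations = _corr()

    # -- summary ------------------------------------------------------------
    @_stage("summary")
    def _summary():
        return assemble_summary(responses, kinetics, sensitivity)
    summary = _summary()

    # -- graphs -------------------------------------------------------------
    norms: dict = {}
    graphs = {}
    subtype_graphs = {}
    if basal is not None and lrmap is not None:
        @_stage("graphs")
        def _graphs():
            ns = compute_panel_norms(basal, responses)
            per_line = {c: build_graph(c, basal, responses, lrmap, ns)
                        for c in cube.cell_lines}
            per_subtype = {}
            if subtypes is not None:
                for s in sorted(subtypes["subtype"].unique()):
                    per_subtype[s] = build_subtype_graph(s, subtypes, basal,
                                                         responses, lrmap, ns)
            else:
                warnings.warn("no subtype table; skipping subtype-average graphs")
            return ns, per_line, per_subtype
        norms, graphs, subtype_graphs = _graphs()

    manifest = {
        "package": "gfresponse",
        "version": __version__,
        "seed": cfg.seed,
        "alpha": alpha,
        "config": _jsonable(cfg.to_dict()),
        "input_checksums": checksums,
        "n_measurements": len(cube),
        "n_cell_lines": len(cube.cell_lines),
        "n_ligands": len(cube.ligands),
    }

    if write:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        responses.to_csv(out / "responses.csv", index=False)
        kinetics.to_csv(out / "kinetics.csv", index=False)
        np.savetxt(out / "kinetic_centroids.csv", clf.cluster_centers_,
                   delimiter=",", header=",".join(map(str, clf.cluster_names_)),
                   comments="")
        sensitivity.to_csv(out / "sensitivity.csv", index=False)
        write_summary_table(summary, out / "summary.csv")
        bias.to_csv(out / "bias.csv", index=False)
        if len(correlations):
            correlations.to_csv(out / "correlations.csv", index=False)
        gdir = out / "graphs"
        gdir.mkdir(exist_ok=True)
        for name, g in graphs.items():
            export_graph(g, gdir / f"{name}.graphml")
            export_graph(g, gdir / f"{name}.json")
        for name, g in subtype_graphs.items():
            export_graph(g, gdir / f"subtype_{name}.graphml")
            export_graph(g, gdir / f"subtype_{name}.json")
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)

    return PipelineResult(responses=responses, kinetics=kinetics,
                          sensitivity=sensitivity, summary=summary, alpha=alpha,
                          bias=bias, correlations=correlations, norms=norms,
                          manifest=manifest)


def _load_inputs(cfg: RunConfig, inputs: PanelBundle | None):
    checksums = {}
    if inputs is not None:
        return inputs.cube, inputs.basal, inputs.lrmap, inputs.subtypes, checksums
    if cfg.response_path is None:
        raise PipelineError("load", "no response table configured")
    cube = read_response_table(cfg.response_path, cfg.dialect)
    checksums["response"] = _sha256(cfg.response_path)
    basal = lrmap = subtypes = None
    if cfg.basal_path:
        basal = read_basal_table(cfg.basal_path, cfg.detection_thresholds)
        checksums["basal"] = _sha256(cfg.basal_path)
    if cfg.lrmap_path:
        lrmap = read_ligand_receptor_map(cfg.lrmap_path)
        checksums["lrmap"] = _sha256(cfg.lrmap_path)
    if cfg.subtype_path:
        subtypes = read_subtype_table(cfg.subtype_path)
        checksums["subtypes"] = _sha256(cfg.subtype_path)
    elif basal is not None:
        warnings.warn("no subtype table configured; subtype aggregation will be skipped")
    return cube, basal, lrmap, subtypes, checksums


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
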