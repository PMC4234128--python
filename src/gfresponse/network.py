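"""Node-edge signaling graphs.

For one cell line the graph holds three node roles — ligands, receptors, and
the downstream targets pERK/pAKT — and two edge kinds: ligand→receptor
binding edges (unweighted) and ligand→target response edges weighted by the
maximum induction across all times and doses, min–max normalised per target
across the whole panel.  Receptor/target node size encodes log10 expression
and shading log10 phosphorylation, each min–max normalised across the panel
within its attribute class (all expression values together, all
phosphorylation values together).  Below-detection basal values sit at the
panel minimum by construction (they are floored to the detection threshold)
and carry a flag; analytes with no measurement at all (e.g. unmeasured
receptor phosphorylation) are marked unmeasured, which is distinct from
below-detection.

Subtype-average graphs aggregate the raw (pre-normalisation) log10 values
across the subtype's lines with the interquartile mean, then normalise with
the same panel-wide extrema, so aggregation and normalisation commute with
the panel norms held fixed.
"""

from __future__ import annotations

import json
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .constants import TARGETS
from .errors import ValidationError
from .metrics import overall_max_fold

#: Basal analyte backing each downstream target node.
TARGET_ANALYTES = {"pERK": "ERK", "pAKT": "AKT"}


def interquartile_mean(values) -> float:
    """Mean of the values lying within [25th, 75th] percentile, inclusive.

    Percentiles follow the linear-interpolation ("type 7") convention.
    Robust: for n >= 5 any single value outside the interquartile range can
    be moved arbitrarily without changing the result (with quartiles fixed).
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValidationError("interquartile_mean of an empty collection")
    q25, q75 = np.percentile(arr, [25, 75])
    inside = arr[(arr >= q25) & (arr <= q75)]
    if inside.size == 0:
        # only possible at n = 2, where both quartiles fall strictly between
        # the two points; fall back to the plain mean
        return float(arr.mean())
    return float(inside.mean())


def normalize01(value, lo: float, hi: float):
    """Min–max normalisation onto [0, 1]; degenerate ranges map to 0.5."""
    value = np.asarray(value, dtype=float)
    if hi <= lo:
        out = np.full_like(value, 0.5)
    else:
        out = np.clip((value - lo) / (hi - lo), 0.0, 1.0)
    if out.ndim == 0:
        return float(out)
    return out


def compute_panel_norms(basal: pd.DataFrame, responses: pd.DataFrame) -> dict:
    """Panel-wide min/max per attribute class.

    Keys: ``"expression"``, ``"phosphorylation"`` (pooled basal log10 values)
    and ``("response", target)`` (overall max log10 fold per target across
    all cell lines and ligands).
    """
    norms: dict = {}
    for kind in ("expression", "phosphorylation"):
        vals = basal.loc[basal["kind"] == kind, "value"]
        if len(vals):
            norms[kind] = (float(vals.min()), float(vals.max()))
    agg = overall_max_fold(responses)
    for target in TARGETS:
        vals = agg.loc[agg["target"] == target, "max_fold"]
        if len(vals):
            norms[("response", target)] = (float(vals.min()), float(vals.max()))
    return norms


def _graph_from_values(name: str, kind: str, basal_one: pd.DataFrame,
                       edges_one: pd.DataFrame, lrmap: Mapping[str, set],
                       norms: dict) -> nx.DiGraph:
    """Assemble a graph from one line's (or one aggregate's) raw values."""
    G = nx.DiGraph(name=name, graph_kind=kind)
    by_analyte = {(a, k): (v, bd) for a, k, v, bd in
                  basal_one[["analyte", "kind", "value", "below_detection"]]
                  .itertuples(index=False)}
    receptors = sorted({r for recs in lrmap.values() for r in recs})
    extra = sorted(set(basal_one["analyte"].unique())
                   - set(receptors) - set(TARGET_ANALYTES.values()))

    def _add_measured_node(node, role, analyte):
        expr = by_analyte.get((analyte, "expression"))
        phos = by_analyte.get((analyte, "phosphorylation"))
        attrs = {"role": role, "measured": expr is not None or phos is not None}
        if expr is not None:
            lo, hi = norms["expression"]
            attrs["size01"] = normalize01(expr[0], lo, hi)
            attrs["below_detection"] = bool(expr[1])
        if phos is not None:
            lo, hi = norms["phosphorylation"]
            attrs["shade01"] = normalize01(phos[0], lo, hi)
            attrs["phospho_below_detection"] = bool(phos[1])
        G.add_node(node, **attrs)

    for rec in receptors + extra:
        _add_measured_node(rec, "receptor", rec)
    for target, analyte in TARGET_ANALYTES.items():
        _add_measured_node(target, "target", analyte)
    for ligand in sorted(lrmap):
        G.add_node(ligand, role="ligand")
        for rec in sorted(lrmap[ligand]):
            G.add_edge(ligand, rec, kind="binding")

    for row in edges_one.itertuples(index=False):
        key = ("response", row.target)
        if key not in norms:
            continue
        lo, hi = norms[key]
        G.add_edge(row.ligand, row.target, kind="response", target=row.target,
                   weight01=normalize01(row.max_fold, lo, hi),
                   significant=bool(row.significant))
    return G


def build_graph(cell_line: str, basal: pd.DataFrame, responses: pd.DataFrame,
                lrmap: Mapping[str, set], norms: dict) -> nx.DiGraph:
    """Signaling graph of a single cell line (panel-wide ``norms`` required)."""
    basal_one = basal[basal["cell_line"] == cell_line]
    agg = overall_max_fold(responses)
    edges_one = agg[agg["cell_line"] == cell_line]
    if basal_one.empty and edges_one.empty:
        raise ValidationError(f"cell line {cell_line!r} absent from inputs")
    return _graph_from_values(cell_line, "cell_line", basal_one, edges_one, lrmap, norms)


def build_subtype_graph(subtype: str, subtypes: pd.DataFrame, basal: pd.DataFrame,
                        responses: pd.DataFrame, lrmap: Mapping[str, set],
                        norms: dict) -> nx.DiGraph:
    """Subtype-average graph: interquartile means of the raw per-line values.

    An edge of the aggregate is flagged significant when at least half of the
    subtype's lines respond significantly; a node is flagged below detection
    when every line is below detection.
    """
    members = subtypes.loc[subtypes["subtype"] == subtype, "cell_line"]
    if members.empty:
        raise ValidationError(f"no cell lines with subtype {subtype!r}")
    basal_sub = basal[basal["cell_line"].isin(members)]
    basal_agg = (basal_sub.groupby(["analyte", "kind"])
                 .agg(value=("value", interquartile_mean),
                      below_detection=("below_detection", "all"))
                 .reset_index())
    basal_agg.insert(0, "cell_line", subtype)

    agg = overall_max_fold(responses)
    edges_sub = agg[agg["cell_line"].isin(members)]
    edges_agg = (edges_sub.groupby(["ligand", "target"])
                 .agg(max_fold=("max_fold", interquartile_mean),
                      significant=("significant", lambda s: s.mean() >= 0.5))
                 .reset_index())
    return _graph_from_values(subtype, "subtype", basal_agg, edges_agg, lrmap, norms)


# -- export / import --------------------------------------------------------

def export_graph(graph: nx.DiGraph, path, fmt: str | None = None) -> None:
    """Write a graph as GraphML or JSON node-link; attribute round-trip is lossless."""
    fmt = _resolve_format(path, fmt)
    if fmt == "graphml":
        nx.write_graphml(graph, path)
    else:
        # endpoint keys renamed so the "target" edge attribute survives
        data = nx.node_link_data(graph, edges="edges", source="from", target="to")
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)


def load_graph(path, fmt: str | None = None) -> nx.DiGraph:
    fmt = _resolve_format(path, fmt)
    if fmt == "graphml":
        g = nx.read_graphml(path, node_type=str)
        g.graph.pop("node_default", None)
        g.graph.pop("edge_default", None)
        return g
    with open(path) as fh:
        data = json.load(fh)
    return nx.node_link_graph(data, edges="edges", source="from", target="to")


def _resolve_format(path, fmt: str | None) -> str:
    if fmt is None:
        s = str(path).lower()
        if s.endswith(".graphml"):
            fmt = "graphml"
        elif s.endswith(".json"):
            fmt = "json"
        else:
            raise ValidationError(f"cannot infer graph format from {path!r}")
    if fmt not in ("graphml", "json"):
        raise ValidationError(f"unsupported graph format {fmt!r}")
    return fmt


def graphs_equal(a: nx.Graph, b: nx.Graph, atol: float = 1e-9) -> bool:
    """Structural and attribute equality up to float tolerance."""
    if set(a.nodes) != set(b.nodes) or set(a.edges) != set(b.edges):
        return False

    def _attrs_equal(da, db):
        if set(da) != set(db):
            return False
        for k, va in da.items():
            vb = db[k]
            if isinstance(va, float) or isinstance(vb, float):
                if not np.isclose(float(va), float(vb), rtol=0, atol=atol):
                    return False
            elif va != vb:
                return False
        return True

    if not _attrs_equal(a.graph, b.graph):
        return False
    for n in a.nodes:
        if not _attrs_equal(a.nodes[n], b.nodes[n]):
            return False
    for e in a.edges:
        if not _attrs_equal(a.edges[e], b.edges[e]):
            return False
    return True
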