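import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gfresponse as gf
from gfresponse.errors import ValidationError
from gfresponse.network import TARGET_ANALYTES


def iqm_bruteforce(values):
    """Oracle under the documented convention: linear-interpolation quartiles,
    inclusive membership, plain mean when the window is empty."""
    v = sorted(values)
    n = len(v)

    def pct(q):
        pos = q * (n - 1)
        lo, hi = math.floor(pos), math.ceil(pos)
        return v[lo] + (pos - lo) * (v[hi] - v[lo])

    q25, q75 = pct(0.25), pct(0.75)
    inside = [x for x in v if q25 <= x <= q75]
    return sum(inside) / len(inside) if inside else sum(v) / len(v)


class TestInterquartileMean:
    @pytest.mark.parametrize("values,expected", [
        ([5, 5, 5, 5], 5.0),
        ([1, 2, 3, 4, 100], 3.0),   # q25=2, q75=4 -> mean of {2,3,4}
        ([7.5], 7.5),
    ])
    def test_examples(self, values, expected):
        assert gf.interquartile_mean(values) == pytest.approx(expected)

    def test_robust_to_outlier_magnitude(self):
        # quartiles of both inputs coincide, so the extreme value is ignored
        assert gf.interquartile_mean([1, 2, 3, 4, 100]) == \
            gf.interquartile_mean([1, 2, 3, 4, 10_000])

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            gf.interquartile_mean([])

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=30))
    def test_within_bounds_and_matches_oracle(self, values):
        m = gf.interquartile_mean(values)
        assert min(values) - 1e-9 <= m <= max(values) + 1e-9
        assert m == pytest.approx(iqm_bruteforce(values), abs=1e-9)


@pytest.fixture(scope="module")
def graph_inputs():
    panel = gf.generate_panel(6, 4, seed=23)
    responses = gf.compute_fold_changes(panel.cube)
    norms = gf.compute_panel_norms(panel.basal, responses)
    return panel, responses, norms


class TestBuildGraph:
    def test_attributes_in_unit_interval(self, graph_inputs):
        panel, responses, norms = graph_inputs
        for cell in panel.cube.cell_lines:
            g = gf.build_graph(cell, panel.basal, responses, panel.lrmap, norms)
            for _, d in g.nodes(data=True):
                for key in ("size01", "shade01"):
                    if key in d:
                        assert 0.0 <= d[key] <= 1.0
            for _, _, d in g.edges(data=True):
                if d["kind"] == "response":
                    assert 0.0 <= d["weight01"] <= 1.0

    def test_panel_extrema_map_to_unit(self, graph_inputs):
        panel, responses, norms = graph_inputs
        b = panel.basal[panel.basal["kind"] == "expression"]
        top = b.loc[b["value"].idxmax()]
        g = gf.build_graph(top["cell_line"], panel.basal, responses, panel.lrmap, norms)
        node = top["analyte"]
        if node in TARGET_ANALYTES.values():
            node = {v: k for k, v in TARGET_ANALYTES.items()}[node]
        assert g.nodes[node]["size01"] == pytest.approx(1.0)

    def test_nonsignificant_edges_flagged(self, graph_inputs):
        panel, responses, norms = graph_inputs
        agg = gf.overall_max_fold(responses)
        row = agg[~agg["significant"]].iloc[0]
        g = gf.build_graph(row["cell_line"], panel.basal, responses,
                           panel.lrmap, norms)
        assert g.edges[row["ligand"], row["target"]]["significant"] is False

    def test_below_detection_minimal_size(self):
        panel = gf.generate_panel(6, 4, seed=23,
                                  detection_threshold=2.5)  # aggressive censoring
        responses = gf.compute_fold_changes(panel.cube)
        norms = gf.compute_panel_norms(panel.basal, responses)
        flagged = panel.basal[(panel.basal["below_detection"])
                              & (panel.basal["kind"] == "expression")]
        assert len(flagged), "censoring should trigger at this threshold"
        row = flagged.iloc[0]
        g = gf.build_graph(row["cell_line"], panel.basal, responses,
                           panel.lrmap, norms)
        node = row["analyte"]
        if node in TARGET_ANALYTES.values():
            node = {v: k for k, v in TARGET_ANALYTES.items()}[node]
        assert g.nodes[node]["below_detection"] is True
        assert g.nodes[node]["size01"] == pytest.approx(0.0)  # floored = panel min

    def test_unknown_cell_line_rejected(self, graph_inputs):
        panel, responses, norms = graph_inputs
        with pytest.raises(ValidationError, match="absent"):
            gf.build_graph("NOPE", panel.basal, responses, panel.lrmap, norms)


class TestSubtypeGraph:
    def test_singleton_subtype_equals_line_graph(self, graph_inputs):
        panel, responses, norms = graph_inputs
        cell = panel.subtypes["cell_line"].iloc[0]
        one = panel.subtypes.iloc[[0]].assign(subtype="HRpos")
        gs = gf.build_subtype_graph("HRpos", one, panel.basal, responses,
                                    panel.lrmap, norms)
        gl = gf.build_graph(cell, panel.basal, responses, panel.lrmap, norms)
        gs.graph = gl.graph = {}
        assert gf.graphs_equal(gs, gl)

    def test_identical_lines_identical_aggregate(self, graph_inputs):
        panel, responses, norms = graph_inputs
        cell = panel.subtypes["cell_line"].iloc[0]
        # duplicate the same line under two names
        clone = "CLONE"
        basal2 = pd.concat([panel.basal,
                            panel.basal[panel.basal["cell_line"] == cell]
                            .assign(cell_line=clone)])
        resp2 = pd.concat([responses,
                           responses[responses["cell_line"] == cell]
                           .assign(cell_line=clone)])
        resp2.attrs = responses.attrs
        sub = pd.DataFrame({"cell_line": [cell, clone], "subtype": "TNBC"})
        gs = gf.build_subtype_graph("TNBC", sub, basal2, resp2, panel.lrmap, norms)
        gl = gf.build_graph(cell, panel.basal, responses, panel.lrmap, norms)
        gs.graph = gl.graph = {}
        assert gf.graphs_equal(gs, gl)

    def test_aggregation_before_normalization(self, graph_inputs):
        """Aggregate node value = IQM of raw log10 values, then normalised."""
        panel, responses, norms = graph_inputs
        sub = panel.subtypes
        subtype = sub["subtype"].mode().iloc[0]
        members = sub.loc[sub["subtype"] == subtype, "cell_line"]
        g = gf.build_subtype_graph(subtype, sub, panel.basal, responses,
                                   panel.lrmap, norms)
        b = panel.basal
        vals = b[(b["cell_line"].isin(members)) & (b["analyte"] == "EGFR")
                 & (b["kind"] == "expression")]["value"]
        lo, hi = norms["expression"]
        expected = (gf.interquartile_mean(vals) - lo) / (hi - lo)
        assert g.nodes["EGFR"]["size01"] == pytest.approx(expected)

    def test_empty_subtype_rejected(self, graph_inputs):
        panel, responses, norms = graph_inputs
        with pytest.raises(ValidationError, match="subtype"):
            gf.build_subtype_graph("HRpos", panel.subtypes.iloc[:0],
                                   panel.basal, responses, panel.lrmap, norms)


class TestExportImport:
    @pytest.mark.parametrize("fmt,ext", [("graphml", "graphml"), ("json", "json")])
    def test_lossless_round_trip(self, graph_inputs, tmp_path, fmt, ext):
        panel, responses, norms = graph_inputs
        cell = panel.cube.cell_lines[0]
        g = gf.build_graph(cell, panel.basal, responses, panel.lrmap, norms)
        p = tmp_path / f"g.{ext}"
        gf.export_graph(g, p, fmt)
        assert gf.graphs_equal(g, gf.load_graph(p, fmt))

    def test_json_parses_with_standard_parser(self, graph_inputs, tmp_path):
        import json
        panel, responses, norms = graph_inputs
        g = gf.build_graph(panel.cube.cell_lines[0], panel.basal, responses,
                           panel.lrmap, norms)
        p = tmp_path / "g.json"
        gf.export_graph(g, p)
        data = json.loads(p.read_text())
        assert {n["id"] for n in data["nodes"]} == set(g.nodes)

    def test_edgeless_graph_exports(self, tmp_path):
        import networkx as nx
        g = nx.DiGraph()
        g.add_node("EGFR", role="receptor", measured=False)
        p = tmp_path / "g.graphml"
        gf.export_graph(g, p)
        assert gf.graphs_equal(g, gf.load_graph(p))

    def test_unsupported_format_rejected(self, tmp_path):
        import networkx as nx
        with pytest.raises(ValidationError, match="format"):
            gf.export_graph(nx.DiGraph(), tmp_path / "g.xml", "dot")
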