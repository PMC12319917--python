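"""Flowchart format, plug-in API, interpreter, jobs and citations."""

import json

import numpy as np
import pytest

from atomflow import flowchart as fcm
from atomflow.errors import FlowchartError
from atomflow.flowchart import (
    Citation, Flowchart, PluginRegistry, StepSpec, collect_citations,
    default_registry, parse_flowchart, rebuild_index, run_job,
    serialize_flowchart, simple_plugin, substitute,
)
from atomflow.properties import PropertyStore


def example_flowchart_text(density=0.3, target_atoms=60):
    """Forcefield -> packing -> dynamics: the liquid-density workflow shape."""
    return json.dumps({
        "format_version": 1,
        "variables": {"smiles": "CCO"},
        "start": "n1",
        "nodes": {
            "n1": {"module_id": "atomflow.steps", "class_id": "ForceField",
                   "version": "1.0.0",
                   "parameters": {"text": "[types]\nX [*] 0 0\n"}},
            "n2": {"module_id": "atomflow.steps", "class_id": "Packing",
                   "version": "1.0.0",
                   "parameters": {"smiles": "${smiles}", "density": density,
                                  "target_atoms": target_atoms, "pack": True}},
            "n3": {"module_id": "atomflow.steps", "class_id": "Dynamics",
                   "version": "1.0.0",
                   "parameters": {"n_frames": 1200, "density": 0.803}},
        },
        "edges": [["n1", "next", "n2"], ["n2", "next", "n3"]],
    })


class TestParseSerialize:
    def test_three_step_chain(self):
        fc = parse_flowchart(example_flowchart_text())
        assert len(fc.nodes) == 3
        assert fc.successor("n1") == "n2"
        assert fc.successor("n2") == "n3"

    def test_shebang_line_permitted(self):
        fc = parse_flowchart(fcm.SHEBANG + "\n" + example_flowchart_text())
        assert len(fc.nodes) == 3

    def test_parse_serialize_parse_fixed_point(self):
        s1 = serialize_flowchart(parse_flowchart(example_flowchart_text()))
        s2 = serialize_flowchart(parse_flowchart(s1))
        assert s1 == s2

    def test_start_only_flowchart_valid_noop(self, tmp_path):
        reg = PluginRegistry()
        reg.register(simple_plugin("m", "Start", "1.0.0", lambda c, p: None))
        fc = Flowchart(nodes={"s": StepSpec("m", "Start", "1.0.0")}, start="s")
        rec = run_job(fc, datastore_root=tmp_path, registry=reg)
        assert rec.state == "finished"

    def test_unknown_plugin_parameters_opaque(self):
        text = json.dumps({
            "format_version": 1, "start": "a",
            "nodes": {"a": {"module_id": "future.mod", "class_id": "X",
                            "version": "9.9.9",
                            "parameters": {"weird": [1, {"deep": "stuff"}],
                                           "tensor": [[1, 2], [3, 4]]}}},
            "edges": [],
        })
        fc = parse_flowchart(text)
        round_tripped = parse_flowchart(serialize_flowchart(fc))
        assert round_tripped.nodes["a"].parameters == fc.nodes["a"].parameters
        assert round_tripped.nodes["a"].version == "9.9.9"

    def test_missing_identifiers_listed(self):
        text = json.dumps({
            "format_version": 1, "start": "a",
            "nodes": {"a": {"module_id": "m", "class_id": "", "version": "1"}},
            "edges": []})
        with pytest.raises(FlowchartError, match="a"):
            parse_flowchart(text)

    def test_dangling_edge_rejected(self):
        text = json.dumps({
            "format_version": 1, "start": "a",
            "nodes": {"a": {"module_id": "m", "class_id": "C", "version": "1"}},
            "edges": [["a", "next", "ghost"]]})
        with pytest.raises(FlowchartError, match="dangling"):
            parse_flowchart(text)

    def test_unreachable_node_rejected(self):
        text = json.dumps({
            "format_version": 1, "start": "a",
            "nodes": {"a": {"module_id": "m", "class_id": "C", "version": "1"},
                      "b": {"module_id": "m", "class_id": "C", "version": "1"}},
            "edges": []})
        with pytest.raises(FlowchartError, match="unreachable"):
            parse_flowchart(text)


class TestRegistry:
    def test_duplicate_same_version_idempotent(self):
        reg = PluginRegistry()
        p = simple_plugin("m", "C", "1.0.0", lambda c, prm: None)
        reg.register(p)
        reg.register(p)
        assert reg.resolve("m", "C") is p

    def test_conflicting_versions_rejected(self):
        reg = PluginRegistry()
        reg.register(simple_plugin("m", "C", "1.0.0", lambda c, prm: None))
        with pytest.raises(FlowchartError, match="conflicting"):
            reg.register(simple_plugin("m", "C", "2.0.0", lambda c, prm: None))

    def test_unregistered_step_names_pair(self, tmp_path):
        fc = Flowchart(nodes={"a": StepSpec("nowhere", "Nothing", "1.0.0")},
                       start="a")
        with pytest.raises(FlowchartError, match=r"nowhere.*Nothing"):
            run_job(fc, datastore_root=tmp_path, registry=PluginRegistry())

    def test_version_mismatch_warns_but_runs(self, tmp_path):
        reg = PluginRegistry()
        reg.register(simple_plugin("m", "C", "1.0.0", lambda c, prm: None))
        fc = Flowchart(nodes={"a": StepSpec("m", "C", "2.0.0")}, start="a")
        rec = run_job(fc, datastore_root=tmp_path, registry=reg)
        assert rec.state == "finished"
        meta = json.loads(
            (tmp_path / f"job_{rec.job_id:06d}" / "job_data.json").read_text())
        assert any("2.0.0" in line for line in meta["log"])


class TestExecution:
    def test_example_run_creates_step_dirs_and_metadata(self, tmp_path):
        rec = run_job(example_flowchart_text(), datastore_root=tmp_path, seed=3)
        assert rec.state == "finished"
        job_dir = tmp_path / f"job_{rec.job_id:06d}"
        names = {p.name for p in job_dir.iterdir()}
        assert {"step_1_ForceField", "step_2_Packing", "step_3_Dynamics",
                "job_data.json", "citations.bib"} <= names

    def test_variable_equals_literal_result(self, tmp_path):
        literal = example_flowchart_text().replace("${smiles}", "CCO")
        r1 = run_job(example_flowchart_text(), datastore_root=tmp_path / "a",
                     seed=5)
        r2 = run_job(literal, datastore_root=tmp_path / "b", seed=5)
        d1 = PropertyStore(tmp_path / "a" / f"job_{r1.job_id:06d}" / "store.db").dump()
        d2 = PropertyStore(tmp_path / "b" / f"job_{r2.job_id:06d}" / "store.db").dump()
        assert d1 == d2

    def test_identical_reruns_identical_stores(self, tmp_path):
        r1 = run_job(example_flowchart_text(), datastore_root=tmp_path, seed=7)
        r2 = run_job(example_flowchart_text(), datastore_root=tmp_path, seed=7)
        d1 = PropertyStore(tmp_path / f"job_{r1.job_id:06d}" / "store.db").dump()
        d2 = PropertyStore(tmp_path / f"job_{r2.job_id:06d}" / "store.db").dump()
        assert d1 == d2 and len(d1) > 0

    def test_step_failure_retains_prior_outputs(self, tmp_path):
        reg = PluginRegistry()
        reg.register(simple_plugin("m", "Ok", "1.0.0",
                                   lambda c, p: (c.step_dir / "out.txt").write_text("x")))

        def boom(ctx, params):
            raise RuntimeError("deliberate failure")

        reg.register(simple_plugin("m", "Boom", "1.0.0", boom))
        fc = Flowchart(
            nodes={"a": StepSpec("m", "Ok", "1.0.0"),
                   "b": StepSpec("m", "Boom", "1.0.0")},
            edges=[("a", "next", "b")], start="a")
        rec = run_job(fc, datastore_root=tmp_path, registry=reg)
        assert rec.state == "error"
        assert "b" in rec.error_message and "deliberate" in rec.error_message
        assert (tmp_path / f"job_{rec.job_id:06d}" / "step_1_Ok" / "out.txt").exists()

    def test_loop_creates_iteration_directories(self, tmp_path):
        body = {"format_version": 1, "start": "s",
                "nodes": {"s": {"module_id": "atomflow.steps",
                                "class_id": "Structure", "version": "1.0.0",
                                "parameters": {"smiles": "${item}",
                                               "name": "mol_${item}"}}},
                "edges": []}
        fc = parse_flowchart(json.dumps({
            "format_version": 1, "start": "L",
            "nodes": {"L": {"module_id": "atomflow.steps", "class_id": "Loop",
                            "version": "1.0.0",
                            "parameters": {"items": ["C", "CC", "CCO"],
                                           "variable": "item", "body": body}}},
            "edges": []}))
        rec = run_job(fc, datastore_root=tmp_path, seed=1)
        assert rec.state == "finished"
        loop_dir = tmp_path / f"job_{rec.job_id:06d}" / "step_1_Loop"
        assert sorted(p.name for p in loop_dir.iterdir()) == \
            ["iter_1", "iter_2", "iter_3"]
        assert [c.name for c in run_job.last_job.system.configurations] == \
            ["mol_C", "mol_CC", "mol_CCO"]


class TestSubflowchart:
    def make_sub(self, names):
        nodes = {f"s{i}": StepSpec("m", name, "1.0.0")
                 for i, name in enumerate(names)}
        edges = [(f"s{i}", "next", f"s{i+1}") for i in range(len(names) - 1)]
        return Flowchart(nodes=nodes, edges=edges, start="s0")

    def registry_with(self, *names, actions=None):
        reg = PluginRegistry()
        for name in names:
            fn = (actions or {}).get(name, lambda c, p: None)
            reg.register(simple_plugin("m", name, "1.0.0", fn))
        return reg

    def test_nested_sub_steps_under_parent_directory(self, tmp_path):
        sub = self.make_sub(["Initialization", "Velocities", "NPT"])

        def dynamics(ctx, params):
            ctx.run_subflowchart(sub)

        reg = self.registry_with("Initialization", "Velocities", "NPT",
                                 "Dynamics", actions={"Dynamics": dynamics})
        fc = Flowchart(nodes={"d": StepSpec("m", "Dynamics", "1.0.0")}, start="d")
        rec = run_job(fc, datastore_root=tmp_path, registry=reg)
        assert rec.state == "finished"
        parent = tmp_path / f"job_{rec.job_id:06d}" / "step_1_Dynamics"
        names = sorted(p.name for p in parent.iterdir())
        assert names == ["step_1_Initialization", "step_2_Velocities",
                         "step_3_NPT"]

    def test_empty_subflowchart_is_noop(self, tmp_path):
        def host(ctx, params):
            reg2 = PluginRegistry()
            reg2.register(simple_plugin("m", "S", "1.0.0", lambda c, p: None))
            sub = Flowchart(nodes={"s": StepSpec("m", "S", "1.0.0")}, start="s")

        reg = self.registry_with("Host", actions={"Host": host})
        fc = Flowchart(nodes={"h": StepSpec("m", "Host", "1.0.0")}, start="h")
        assert run_job(fc, datastore_root=tmp_path, registry=reg).state == "finished"

    def test_sub_step_property_visible_to_later_top_level_step(self, tmp_path):
        seen = {}

        def writer(ctx, params):
            ctx.properties.store("shared", "volume", 123.0)

        def host(ctx, params):
            sub = Flowchart(nodes={"w": StepSpec("m", "Writer", "1.0.0")},
                            start="w")
            ctx.run_subflowchart(sub)

        def reader(ctx, params):
            seen["records"] = ctx.properties.query(name="volume")

        reg = self.registry_with("Writer", "Host", "Reader",
                                 actions={"Writer": writer, "Host": host,
                                          "Reader": reader})
        fc = Flowchart(nodes={"h": StepSpec("m", "Host", "1.0.0"),
                              "r": StepSpec("m", "Reader", "1.0.0")},
                       edges=[("h", "next", "r")], start="h")
        rec = run_job(fc, datastore_root=tmp_path, registry=reg)
        assert rec.state == "finished"
        assert seen["records"][0].value == pytest.approx(123.0)


class TestCitations:
    def test_deduplicated_in_first_use_order(self, tmp_path):
        bib = "@article{ff2001, title={A force field}}"

        def citer(key):
            return lambda ctx, p: ctx.cite(key, bib)

        reg = PluginRegistry()
        reg.register(simple_plugin("m", "A", "1.0.0", citer("ff2001")))
        reg.register(simple_plugin("m", "B", "1.0.0", citer("ff2001")))
        fc = Flowchart(nodes={"a": StepSpec("m", "A", "1.0.0"),
                              "b": StepSpec("m", "B", "1.0.0")},
                       edges=[("a", "next", "b")], start="a")
        run_job(fc, datastore_root=tmp_path, registry=reg)
        cits, bibtex = collect_citations(run_job.last_job)
        assert [c.key for c in cits] == ["ff2001"]
        assert bibtex.count("@article") == 1

    def test_example_run_cites_all_components(self, tmp_path):
        run_job(example_flowchart_text(), datastore_root=tmp_path, seed=1)
        keys = [c.key for c in run_job.last_job.citations]
        for expected in ("forcefield", "packing", "dynamics",
                         "timeseries-stats"):
            assert expected in keys

    def test_no_citations_empty_list(self, tmp_path):
        reg = PluginRegistry()
        reg.register(simple_plugin("m", "Quiet", "1.0.0", lambda c, p: None))
        fc = Flowchart(nodes={"q": StepSpec("m", "Quiet", "1.0.0")}, start="q")
        run_job(fc, datastore_root=tmp_path, registry=reg)
        cits, bibtex = collect_citations(run_job.last_job)
        assert cits == [] and bibtex == ""

    def test_malformed_bibtex_kept_verbatim_with_warning(self, tmp_path):
        reg = PluginRegistry()
        reg.register(simple_plugin(
            "m", "Bad", "1.0.0",
            lambda ctx, p: ctx.cite("oops", "not bibtex at all")))
        fc = Flowchart(nodes={"b": StepSpec("m", "Bad", "1.0.0")}, start="b")
        run_job(fc, datastore_root=tmp_path, registry=reg)
        cits, bibtex = collect_citations(run_job.last_job)
        assert "not bibtex at all" in bibtex
        assert any("oops" in line for line in run_job.last_job.log)


class TestJobIndex:
    def submit_n(self, tmp_path, n):
        reg = PluginRegistry()
        reg.register(simple_plugin("m", "S", "1.0.0", lambda c, p: None))
        fc = Flowchart(nodes={"s": StepSpec("m", "S", "1.0.0")}, start="s")
        return [run_job(fc, datastore_root=tmp_path, registry=reg)
                for _ in range(n)]

    def test_rebuild_matches_incremental(self, tmp_path):
        submitted = self.submit_n(tmp_path, 5)
        rebuilt, problems = rebuild_index(tmp_path)
        assert problems == []
        assert [(r.job_id, r.state, r.directory) for r in rebuilt] == \
            [(r.job_id, r.state, r.directory) for r in submitted]

    def test_empty_root_empty_index(self, tmp_path):
        records, problems = rebuild_index(tmp_path)
        assert records == [] and problems == []

    def test_corrupted_metadata_skipped_and_reported(self, tmp_path):
        self.submit_n(tmp_path, 3)
        (tmp_path / "job_000002" / "job_data.json").write_text("{broken")
        records, problems = rebuild_index(tmp_path)
        assert [r.job_id for r in records] == [1, 3]
        assert len(problems) == 1 and "job_000002" in problems[0]

    def test_ids_continue_after_rebuild(self, tmp_path):
        self.submit_n(tmp_path, 2)
        more = self.submit_n(tmp_path, 1)
        assert more[0].job_id == 3


class TestSubstitution:
    def test_type_preserving_whole_match(self):
        assert substitute("${x}", {"x": [1, 2]}) == [1, 2]

    def test_interpolation_in_text(self):
        assert substitute("mol_${name}.xyz", {"name": "eth"}) == "mol_eth.xyz"

    def test_unknown_placeholder_left_verbatim(self):
        assert substitute("${later}", {}) == "${later}"

    def test_recursion_through_containers(self):
        value = {"a": ["${x}", {"b": "${x}"}]}
        assert substitute(value, {"x": 7}) == {"a": [7, {"b": 7}]}
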