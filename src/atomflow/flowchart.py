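"""Flowchart format, plug-in registry, interpreter and job datastore.

A flowchart is a JSON text file (optionally starting with a shebang line)
describing a directed graph of versioned steps:

.. code-block:: json

    {
      "format_version": 1,
      "variables": {"smiles": "CCO"},
      "start": "n1",
      "nodes": {
        "n1": {"module_id": "atomflow.steps", "class_id": "Structure",
               "version": "1.0.0", "parameters": {"smiles": "${smiles}"}}
      },
      "edges": [["n1", "next", "n2"]]
    }

Step parameters are *opaque*: the engine round-trips them byte-for-byte
and never interprets them beyond ``${name}`` variable substitution in
string values at step start.  Plug-ins communicate only through the shared
system/property stores in the execution context; each step runs in its own
working subdirectory and may raise citations, which the job aggregates,
de-duplicated, in order of first use.

Jobs are directories under a datastore root.  Each job writes a
``job_data.json`` metadata file sufficient to rebuild the whole index, so
``rebuild_index`` recovers exactly what incremental submission produced.
"""

from __future__ import annotations

import datetime
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Iterable, Optional

from .datamodel import System
from .errors import FlowchartError
from .properties import PropertyStore

FORMAT_VERSION = 1
SHEBANG = "#!/usr/bin/env atomflow"


# ---------------------------------------------------------------------------
# flowchart data model
# ---------------------------------------------------------------------------

@dataclass
class StepSpec:
    module_id: str
    class_id: str
    version: str
    parameters: dict = field(default_factory=dict)

    def validate(self, node_id: str) -> None:
        if not (self.module_id and self.class_id and self.version):
            raise FlowchartError(
                f"node {node_id!r}: module_id, class_id and version are required"
            )


@dataclass
class Flowchart:
    nodes: dict[str, StepSpec] = field(default_factory=dict)
    edges: list[tuple[str, str, str]] = field(default_factory=list)  # from, port, to
    start: str | None = None
    variables: dict[str, Any] = field(default_factory=dict)

    def validate(self) -> None:
        if self.start is None or self.start not in self.nodes:
            raise FlowchartError("flowchart needs a start node present in nodes")
        bad = [nid for nid, spec in self.nodes.items()
               if not (spec.module_id and spec.class_id and spec.version)]
        if bad:
            raise FlowchartError(
                f"nodes missing module/class/version: {sorted(bad)}"
            )
        for (src, port, dst) in self.edges:
            if src not in self.nodes or dst not in self.nodes:
                raise FlowchartError(f"dangling edge ({src!r}, {port!r}, {dst!r})")
        # reachability from start
        seen = {self.start}
        frontier = [self.start]
        while frontier:
            cur = frontier.pop()
            for (src, _, dst) in self.edges:
                if src == cur and dst not in seen:
                    seen.add(dst)
                    frontier.append(dst)
        unreachable = set(self.nodes) - seen
        if unreachable:
            raise FlowchartError(f"unreachable nodes: {sorted(unreachable)}")

    def successor(self, node_id: str, port: str = "next") -> str | None:
        for (src, p, dst) in self.edges:
            if src == node_id and p == port:
                return dst
        return None


def parse_flowchart(text: str) -> Flowchart:
    """Parse flowchart JSON; a leading shebang line is permitted."""
    body = text
    if body.startswith("#!"):
        body = body.split("\n", 1)[1] if "\n" in body else ""
    try:
        data = json.loads(body)
    except json.JSONDecodeError as exc:
        raise FlowchartError(f"flowchart is not valid JSON: {exc}") from exc
    nodes = {}
    for nid, nd in data.get("nodes", {}).items():
        nodes[nid] = StepSpec(
            module_id=nd.get("module_id", ""),
            class_id=nd.get("class_id", ""),
            version=nd.get("version", ""),
            parameters=nd.get("parameters", {}),
        )
    fc = Flowchart(
        nodes=nodes,
        edges=[tuple(e) for e in data.get("edges", [])],
        start=data.get("start"),
        variables=data.get("variables", {}),
    )
    fc.validate()
    return fc


def serialize_flowchart(fc: Flowchart, shebang: bool = True) -> str:
    """Canonical JSON serialization; parameters preserved exactly."""
    fc.validate()
    data = {
        "format_version": FORMAT_VERSION,
        "variables": fc.variables,
        "start": fc.start,
        "nodes": {
            nid: {
                "module_id": spec.module_id,
                "class_id": spec.class_id,
                "version": spec.version,
                "parameters": spec.parameters,
            }
            for nid, spec in sorted(fc.nodes.items())
        },
        "edges": [list(e) for e in fc.edges],
    }
    text = json.dumps(data, indent=1, sort_keys=True)
    return (SHEBANG + "\n" + text + "\n") if shebang else text + "\n"


# ---------------------------------------------------------------------------
# plug-in registry and API
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Citation:
    key: str
    bibtex: str
    raised_by: str = ""


class StepContext:
    """Everything a plug-in's run() may touch.

    The only connection between plug-ins is the underlying data model:
    ``system`` (configurations) and ``properties`` (results), plus the
    flowchart variables.  ``step_dir`` is the step's private working
    directory; ``seed`` is a per-step deterministic substream seed.
    """

    def __init__(self, system: System, properties: PropertyStore,
                 variables: dict, step_dir: Path, seed: int, job: "Job",
                 node_id: str, registry: "PluginRegistry"):
        self.system = system
        self.properties = properties
        self.variables = variables
        self.step_dir = step_dir
        self.seed = seed
        self.job = job
        self.node_id = node_id
        self.registry = registry

    def cite(self, key: str, bibtex: str) -> None:
        self.job.add_citation(Citation(key, bibtex, raised_by=self.node_id))

    @property
    def configuration(self):
        """The current (most recently added) configuration, or None."""
        return self.system.configurations[-1] if self.system.configurations else None

    def run_subflowchart(self, subflowchart: Flowchart,
                         variables: dict | None = None) -> None:
        """Execute a nested flowchart in this step's context.

        Sub-steps share the parent's system and property store and write
        their outputs under the parent step directory.  Nesting depth is
        unlimited.
        """
        merged = dict(self.variables)
        if variables:
            merged.update(variables)
        _execute(subflowchart, merged, self.step_dir, self.system,
                 self.properties, self.job, self.registry, self.seed)


class PluginFactory:
    """Factory creating compute objects for one (module_id, class_id).

    ``create(parameters)`` returns an object with ``run(ctx)``;
    ``parameter_schema`` describes the accepted parameters (the stand-in
    for a graphical edit surface).  Subclass or use :func:`simple_plugin`.
    """

    module_id: str = ""
    class_id: str = ""
    version: str = "1.0.0"
    citations: tuple = ()

    def parameter_schema(self) -> dict:
        return {}

    def create(self, parameters: dict):
        raise NotImplementedError


def simple_plugin(module_id: str, class_id: str, version: str,
                  run_fn: Callable[[StepContext, dict], None],
                  schema: dict | None = None,
                  citations: Iterable[tuple[str, str]] = ()) -> PluginFactory:
    """Build a PluginFactory from a plain run function."""

    class _Step:
        def __init__(self, parameters):
            self.parameters = parameters

        def run(self, ctx: StepContext):
            for key, bib in citations:
                ctx.cite(key, bib)
            return run_fn(ctx, self.parameters)

    class _Factory(PluginFactory):
        pass

    f = _Factory()
    f.module_id, f.class_id, f.version = module_id, class_id, version
    f.citations = tuple(citations)
    f.parameter_schema = lambda: dict(schema or {})
    f.create = lambda parameters: _Step(parameters)
    return f


class PluginRegistry:
    def __init__(self):
        self._factories: dict[tuple[str, str], PluginFactory] = {}

    def register(self, factory: PluginFactory) -> None:
        key = (factory.module_id, factory.class_id)
        if key in self._factories:
            if self._factories[key].version == factory.version:
                return  # idempotent duplicate
            raise FlowchartError(
                f"conflicting registration for {key}: versions "
                f"{self._factories[key].version} vs {factory.version}"
            )
        self._factories[key] = factory

    def resolve(self, module_id: str, class_id: str) -> PluginFactory:
        key = (module_id, class_id)
        if key not in self._factories:
            raise FlowchartError(f"no registered plug-in for {key}")
        return self._factories[key]


# ---------------------------------------------------------------------------
# variable substitution
# ---------------------------------------------------------------------------

_VAR_RE = re.compile(r"\$\{([A-Za-z_][A-Za-z0-9_]*)\}")


def substitute(value: Any, variables: dict) -> Any:
    """Resolve ${name} in strings, recursively through lists and dicts.

    A string that is exactly one ``${name}`` is replaced by the variable's
    value with its type preserved; otherwise matches are interpolated as
    text.  Placeholders naming variables not yet defined are left verbatim
    (loop bodies reference their iteration variable before it exists).
    """
    if isinstance(value, str):
        whole = _VAR_RE.fullmatch(value)
        if whole:
            name = whole.group(1)
            return variables[name] if name in variables else value

        def repl(m):
            name = m.group(1)
            return str(variables[name]) if name in variables else m.group(0)

        return _VAR_RE.sub(repl, value)
    if isinstance(value, list):
        return [substitute(v, variables) for v in value]
    if isinstance(value, dict):
        return {k: substitute(v, variables) for k, v in value.items()}
    return value


# ---------------------------------------------------------------------------
# jobs
# ---------------------------------------------------------------------------

@dataclass
class JobRecord:
    job_id: int
    state: str  # queued | running | finished | error
    directory: str
    flowchart_text: str
    submitted: str = ""
    finished: str = ""
    error_message: str = ""

    def to_dict(self) -> dict:
        return {
            "job_id": self.job_id, "state": self.state,
            "directory": self.directory, "flowchart": self.flowchart_text,
            "submitted": self.submitted, "finished": self.finished,
            "error_message": self.error_message,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "JobRecord":
        return cls(d["job_id"], d["state"], d["directory"], d["flowchart"],
                   d.get("submitted", ""), d.get("finished", ""),
                   d.get("error_message", ""))


class Job:
    """A running job: its record, stores and citation accumulator."""

    def __init__(self, record: JobRecord, system: System,
                 properties: PropertyStore):
        self.record = record
        self.system = system
        self.properties = properties
        self._citations: list[Citation] = []
        self.log: list[str] = []

    def add_citation(self, citation: Citation) -> None:
        if all(c.key != citation.key for c in self._citations):
            self._citations.append(citation)

    @property
    def citations(self) -> list[Citation]:
        return list(self._citations)


def collect_citations(job: Job) -> tuple[list[Citation], str]:
    """De-duplicated citations in order of first use, plus BibTeX text.

    A citation whose BibTeX does not look like a single entry is kept
    verbatim with a warning in the job log.
    """
    bib_chunks = []
    for c in job.citations:
        if not re.match(r"\s*@\w+\s*\{", c.bibtex):
            job.log.append(f"warning: citation {c.key!r} has malformed BibTeX")
        bib_chunks.append(c.bibtex.strip())
    return job.citations, "\n\n".join(bib_chunks) + ("\n" if bib_chunks else "")


def _execute(fc: Flowchart, variables: dict, parent_dir: Path, system: System,
             properties: PropertyStore, job: Job, registry: PluginRegistry,
             seed: int) -> None:
    """Run a (sub)flowchart sequentially from its start node."""
    node_id = fc.start
    step_no = 0
    while node_id is not None:
        spec = fc.nodes[node_id]
        step_no += 1
        factory = registry.resolve(spec.module_id, spec.class_id)
        if factory.version != spec.version:
            job.log.append(
                f"warning: node {node_id!r} requests {spec.class_id} "
                f"{spec.version}, registry provides {factory.version}"
            )
        step_dir = parent_dir / f"step_{step_no}_{spec.class_id}"
        step_dir.mkdir(parents=True, exist_ok=True)
        params = substitute(spec.parameters, variables)
        step_seed = (seed * 1_000_003 + step_no * 7919) % (2**31)
        ctx = StepContext(system, properties, variables, step_dir, step_seed,
                          job, node_id, registry)
        step = factory.create(params)
        try:
            step.run(ctx)
        except Exception as exc:
            raise _StepFailure(node_id, spec.class_id, exc) from exc
        node_id = fc.successor(node_id, "next")


class _StepFailure(Exception):
    def __init__(self, node_id: str, class_id: str, cause: Exception):
        super().__init__(f"step {node_id!r} ({class_id}) failed: {cause}")
        self.node_id = node_id
        self.cause = cause


def _now() -> str:
    return datetime.datetime.now(datetime.timezone.utc).isoformat()


def run_job(
    flowchart: Flowchart | str,
    variables: dict | None = None,
    datastore_root: str | Path = "datastore",
    registry: PluginRegistry | None = None,
    seed: int = 0,
) -> JobRecord:
    """Execute a flowchart as a job under the datastore root.

    Steps run sequentially from the start node, each in its own
    subdirectory, sharing one system and one property store.  On success
    the job directory holds ``job_data.json``, the flowchart snapshot,
    the shared store and ``citations.bib``; on a step failure prior step
    outputs are retained and the job ends in state ``error``.
    """
    if isinstance(flowchart, str):
        flowchart = parse_flowchart(flowchart)
    flowchart.validate()
    if registry is None:
        registry = default_registry()
    root = Path(datastore_root)
    root.mkdir(parents=True, exist_ok=True)
    existing = _scan_job_dirs(root)
    job_id = max(existing, default=0) + 1
    job_dir = root / f"job_{job_id:06d}"
    job_dir.mkdir()
    fc_text = serialize_flowchart(flowchart)
    record = JobRecord(job_id=job_id, state="running", directory=str(job_dir),
                       flowchart_text=fc_text, submitted=_now())
    merged_vars = dict(flowchart.variables)
    if variables:
        merged_vars.update(variables)
    system = System(name=f"job_{job_id}")
    properties = PropertyStore(job_dir / "store.db")
    job = Job(record, system, properties)
    (job_dir / "flowchart.flow").write_text(fc_text)
    try:
        _execute(flowchart, merged_vars, job_dir, system, properties, job,
                 registry, seed)
        record.state = "finished"
    except _StepFailure as exc:
        record.state = "error"
        record.error_message = str(exc)
        job.log.append(str(exc))
    record.finished = _now()
    _, bibtex = collect_citations(job)
    (job_dir / "citations.bib").write_text(bibtex)
    meta = record.to_dict()
    meta["log"] = job.log
    meta["citations"] = [{"key": c.key, "raised_by": c.raised_by}
                         for c in job.citations]
    (job_dir / "job_data.json").write_text(json.dumps(meta, indent=1))
    properties.close()
    job.record = record
    run_job.last_job = job  # inspection hook for callers/tests
    return record


def _scan_job_dirs(root: Path) -> dict[int, Path]:
    out = {}
    if root.exists():
        for p in sorted(root.glob("job_*")):
            if p.is_dir():
                try:
                    out[int(p.name.split("_")[1])] = p
                except (IndexError, ValueError):
                    continue
    return out


def rebuild_index(datastore_root: str | Path
                  ) -> tuple[list[JobRecord], list[str]]:
    """Recreate the job index from per-job metadata files.

    Returns (records sorted by id, problems).  A job directory whose
    metadata file is missing or unreadable is skipped and reported.
    """
    root = Path(datastore_root)
    records, problems = [], []
    for job_id, p in sorted(_scan_job_dirs(root).items()):
        meta = p / "job_data.json"
        try:
            records.append(JobRecord.from_dict(json.loads(meta.read_text())))
        except (OSError, json.JSONDecodeError, KeyError) as exc:
            problems.append(f"{p.name}: {exc}")
    return records, problems


def job_index(datastore_root: str | Path) -> list[JobRecord]:
    records, _ = rebuild_index(datastore_root)
    return records


# ---------------------------------------------------------------------------
# built-in steps
# ---------------------------------------------------------------------------

def _structure_run(ctx: StepContext, params: dict) -> None:
    from .builder import structure_from_smiles
    from .datamodel import new_configuration

    config = structure_from_smiles(params["smiles"], seed=ctx.seed)
    new_configuration(ctx.system, config.atom_set, config.bond_set,
                      config.coordinates, charge=config.charge,
                      name=params.get("name", params["smiles"]))


def _forcefield_run(ctx: StepContext, params: dict) -> None:
    from .forcefield import load_forcefield, parse_forcefield

    if "file" in params:
        ff = load_forcefield(params["file"])
    else:
        ff = parse_forcefield(params.get("text", ""))
    ctx.variables["_forcefield"] = ff


def _packing_run(ctx: StepContext, params: dict) -> None:
    from .builder import pack, plan_cell, structure_from_smiles, write_plan_summary
    from .datamodel import new_configuration

    mol = (ctx.configuration if "smiles" not in params
           else structure_from_smiles(params["smiles"], seed=ctx.seed))
    plan = plan_cell(
        [(mol, 1.0)], density_guess=float(params.get("density", 0.7)),
        target_atoms=int(params.get("target_atoms", 2000)),
        shape=params.get("shape", "cubic-periodic"),
    )
    write_plan_summary(plan, ctx.step_dir / "plan.json", seed=ctx.seed)
    from .properties import PropertyDefinition

    ctx.properties.define(PropertyDefinition("n_molecules", "integer", "count",
                                             "molecules in the packed cell"))
    if params.get("pack", True):
        packed = pack(plan, seed=ctx.seed)
        cfg = new_configuration(ctx.system, packed.atom_set, packed.bond_set,
                                packed.coordinates, cell=packed.cell,
                                name=f"packed_{ctx.node_id}")
        ctx.properties.store(cfg.name, "n_molecules",
                             sum(c for _, c in plan.components),
                             provenance=ctx.node_id)
        ctx.properties.store(cfg.name, "volume", packed.cell.volume,
                             provenance=ctx.node_id)


def _dynamics_run(ctx: StepContext, params: dict) -> None:
    """Stand-in equilibrium dynamics: emits a density time series with the
    statistics the analysis module expects (OU process about the target)."""
    from .analysis import steady_state_average
    from .synth import ou_series

    n = int(params.get("n_frames", 2000))
    density = float(params.get("density", 0.803))
    series = ou_series(density, float(params.get("variance", 1e-6)),
                       float(params.get("tau", 10.0)), 1.0, n, seed=ctx.seed)
    stats = steady_state_average(series)
    cfg = ctx.configuration.name if ctx.configuration else "none"
    ctx.properties.store(cfg, "density", stats.mean, provenance=ctx.node_id)
    (ctx.step_dir / "density.csv").write_text(
        "frame,density\n" + "\n".join(f"{i},{v}" for i, v in enumerate(series))
    )


def _loop_run(ctx: StepContext, params: dict) -> None:
    """Minimal for-each loop: runs a body subflowchart per item."""
    items = params.get("items", [])
    body = params.get("body")
    if body is None:
        return
    sub = parse_flowchart(json.dumps(body)) if isinstance(body, dict) else body
    for k, item in enumerate(items, 1):
        iter_dir = ctx.step_dir / f"iter_{k}"
        iter_dir.mkdir(exist_ok=True)
        sub_vars = dict(ctx.variables)
        sub_vars[params.get("variable", "item")] = item
        _execute(sub, sub_vars, iter_dir, ctx.system, ctx.properties,
                 ctx.job, ctx.registry, ctx.seed + k)


_BIB_RDKIT = ("rdkit", "@misc{rdkit, title={RDKit: Open-source cheminformatics}, "
              "howpublished={http://www.rdkit.org}}")
_BIB_PACK = ("packing", "@article{packing, title={Packing optimization for "
             "molecular simulation}, journal={J. Comput. Chem.}}")
_BIB_DYN = ("dynamics", "@article{dynamics, title={Equilibrium molecular "
            "dynamics engine}, journal={Comput. Phys. Commun.}}")
_BIB_FF = ("forcefield", "@article{forcefield, title={Transferable force "
           "field for organic liquids}, journal={J. Am. Chem. Soc.}}")
_BIB_STATS = ("timeseries-stats", "@article{timeseries, title={Statistical "
              "inefficiency and equilibration in molecular simulation}, "
              "journal={J. Chem. Theory Comput.}}")


def default_registry() -> PluginRegistry:
    """Registry with the built-in steps (structure, forcefield, packing,
    dynamics, loop)."""
    reg = PluginRegistry()
    reg.register(simple_plugin("atomflow.steps", "Structure", "1.0.0",
                               _structure_run, {"smiles": "str"},
                               citations=[_BIB_RDKIT]))
    reg.register(simple_plugin("atomflow.steps", "ForceField", "1.0.0",
                               _forcefield_run, {"file": "path", "text": "str"},
                               citations=[_BIB_FF]))
    reg.register(simple_plugin("atomflow.steps", "Packing", "1.0.0",
                               _packing_run,
                               {"smiles": "str", "density": "float",
                                "target_atoms": "int", "shape": "str",
                                "pack": "bool"},
                               citations=[_BIB_PACK]))
    reg.register(simple_plugin("atomflow.steps", "Dynamics", "1.0.0",
                               _dynamics_run,
                               {"n_frames": "int", "density": "float"},
                               citations=[_BIB_DYN, _BIB_STATS]))
    reg.register(simple_plugin("atomflow.steps", "Loop", "1.0.0", _loop_run,
                               {"items": "list", "variable": "str",
                                "body": "flowchart"}))
    return reg
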