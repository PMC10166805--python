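"""A minimal modular workflow engine with typed ports and provenance capture.

A *module* declares named, typed input and output ports and wraps a Python
callable. A *workflow* is an ordered list of module steps whose input ports
are bound in one of four ways:

* ``manual``  — a literal value written into the workflow definition,
* ``runtime`` — a prompt key whose value is supplied at execution time
  (this is what makes parameter sweeps possible without editing the
  workflow),
* ``pipe``    — an output of a *prior* step in the same workflow,
* ``hdf5``    — a dataset read from an HDF5 file (typically a stored
  execution record).

Steps run strictly serially in listed order. Every execution produces an
:class:`ExecutionRecord`: a self-contained snapshot of the workflow, every
resolved input value, every output, per-step status, and the seed used —
enough to re-execute the run bit-for-bit.

Validation is static and sound for the binding system: a workflow with no
validation issues resolves all bindings at execution time.
"""

from __future__ import annotations

import copy
import hashlib
import itertools
import json
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Callable, Mapping

import numpy as np
import pandas as pd

from .roi import InvalidInputError, ROISet

SEMANTIC_TYPES = frozenset(
    {"scalar_int", "scalar_float", "boolean", "text", "numeric_array", "roiset", "table", "path"}
)
CATEGORIES = frozenset(
    {"file_acquisition", "motion_correction", "cell_segmentation", "signal_extraction", "analysis"}
)
BINDING_KINDS = frozenset({"manual", "runtime", "pipe", "hdf5"})


def conforms(value: Any, semantic_type: str) -> bool:
    """Check a concrete value against a port's semantic type.

    Exact-type compatibility with one safe widening: an integer is accepted
    where a float is declared.
    """
    if semantic_type == "scalar_int":
        return isinstance(value, (int, np.integer)) and not isinstance(value, bool)
    if semantic_type == "scalar_float":
        return isinstance(value, (float, int, np.floating, np.integer)) and not isinstance(
            value, bool
        )
    if semantic_type == "boolean":
        return isinstance(value, (bool, np.bool_))
    if semantic_type == "text":
        return isinstance(value, str)
    if semantic_type == "numeric_array":
        if isinstance(value, np.ndarray):
            return np.issubdtype(value.dtype, np.number)
        return isinstance(value, (list, tuple)) and all(
            isinstance(v, (int, float, np.integer, np.floating)) for v in value
        )
    if semantic_type == "roiset":
        return isinstance(value, ROISet)
    if semantic_type == "table":
        return isinstance(value, pd.DataFrame)
    if semantic_type == "path":
        return isinstance(value, (str, Path))
    raise InvalidInputError(f"unknown semantic type {semantic_type!r}")


def _types_compatible(source: str, target: str) -> bool:
    return source == target or (source == "scalar_int" and target == "scalar_float")


@dataclass(frozen=True)
class Port:
    name: str
    semantic_type: str
    required: bool = True
    default: Any = None

    def __post_init__(self) -> None:
        if self.semantic_type not in SEMANTIC_TYPES:
            raise InvalidInputError(f"unknown semantic type {self.semantic_type!r}")
        if self.required and self.default is not None:
            raise InvalidInputError(f"required port {self.name!r} cannot have a default")
        if self.default is not None and not conforms(self.default, self.semantic_type):
            raise InvalidInputError(
                f"port {self.name!r}: default {self.default!r} does not conform "
                f"to {self.semantic_type}"
            )


@dataclass(frozen=True)
class ModuleSpec:
    """A registered computation with declared, typed input and output ports."""

    name: str
    category: str
    inputs: tuple[Port, ...]
    outputs: tuple[Port, ...]
    implementation: Callable[..., dict[str, Any]]

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise InvalidInputError(
                f"category {self.category!r} not one of {sorted(CATEGORIES)}"
            )
        for ports, direction in ((self.inputs, "input"), (self.outputs, "output")):
            names = [p.name for p in ports]
            if len(names) != len(set(names)):
                raise InvalidInputError(f"duplicate {direction} port names in {self.name!r}")

    def input_port(self, name: str) -> Port | None:
        return next((p for p in self.inputs if p.name == name), None)

    def output_port(self, name: str) -> Port | None:
        return next((p for p in self.outputs if p.name == name), None)


@dataclass(frozen=True)
class InputBinding:
    """How one input port receives its value; payload fields depend on kind."""

    kind: str
    value: Any = None          # manual
    prompt_key: str | None = None   # runtime
    source_step: int | None = None  # pipe
    source_output: str | None = None  # pipe
    file: str | None = None    # hdf5
    dataset: str | None = None  # hdf5

    def __post_init__(self) -> None:
        if self.kind not in BINDING_KINDS:
            raise InvalidInputError(f"unknown binding kind {self.kind!r}")
        if self.kind == "runtime" and not self.prompt_key:
            raise InvalidInputError("runtime binding requires a prompt key")
        if self.kind == "pipe" and (self.source_step is None or self.source_output is None):
            raise InvalidInputError("pipe binding requires source step index and output name")
        if self.kind == "hdf5" and (self.file is None or self.dataset is None):
            raise InvalidInputError("hdf5 binding requires file path and dataset path")


def manual(value: Any) -> InputBinding:
    return InputBinding("manual", value=value)


def runtime(prompt_key: str) -> InputBinding:
    return InputBinding("runtime", prompt_key=prompt_key)


def pipe(source_step: int, source_output: str) -> InputBinding:
    return InputBinding("pipe", source_step=source_step, source_output=source_output)


def hdf5(file: str, dataset: str) -> InputBinding:
    return InputBinding("hdf5", file=file, dataset=dataset)


@dataclass
class WorkflowStep:
    module: str
    bindings: dict[str, InputBinding] = field(default_factory=dict)


@dataclass
class WorkflowDef:
    name: str
    steps: list[WorkflowStep] = field(default_factory=list)
    seed: int | None = None


@dataclass
class ExecutionRecord:
    """Self-contained provenance snapshot of one workflow run."""

    workflow: WorkflowDef
    runtime_values: dict[str, Any]
    resolved_inputs: list[dict[str, Any]]
    outputs: list[dict[str, Any]]
    statuses: list[str]  # per step: "success" | "failed" | "skipped"
    errors: list[str | None]
    seed: int
    started: str
    finished: str
    figures: list[tuple[str, bytes]] = field(default_factory=list)
    derived: bool = False

    @property
    def status(self) -> str:
        return "success" if all(s == "success" for s in self.statuses) else "failed"


class ModuleRegistry:
    """Name -> ModuleSpec lookup for workflow construction and execution."""

    def __init__(self) -> None:
        self._modules: dict[str, ModuleSpec] = {}

    def register(self, spec: ModuleSpec) -> ModuleSpec:
        if spec.name in self._modules:
            raise InvalidInputError(f"module {spec.name!r} already registered")
        if not callable(spec.implementation):
            raise InvalidInputError(f"module {spec.name!r}: implementation is not callable")
        self._modules[spec.name] = spec
        return spec

    def get(self, name: str) -> ModuleSpec:
        if name not in self._modules:
            raise KeyError(f"no registered module named {name!r}")
        return self._modules[name]

    def __contains__(self, name: str) -> bool:
        return name in self._modules

    def names(self) -> list[str]:
        return sorted(self._modules)


def register_module(spec: ModuleSpec, registry: ModuleRegistry | None = None) -> ModuleSpec:
    """Register a module spec in ``registry`` (the default registry if omitted)."""
    return (registry or default_registry()).register(spec)


def validate_workflow(wf: WorkflowDef, registry: ModuleRegistry | None = None) -> list[str]:
    """Statically check a workflow; returns a list of issues (empty = valid)."""
    registry = registry or default_registry()
    issues: list[str] = []
    for i, step in enumerate(wf.steps):
        where = f"step {i} ({step.module})"
        if step.module not in registry:
            issues.append(f"{where}: unknown module")
            continue
        spec = registry.get(step.module)
        for port_name in step.bindings:
            if spec.input_port(port_name) is None:
                issues.append(f"{where}: binding for unknown port {port_name!r}")
        for port in spec.inputs:
            binding = step.bindings.get(port.name)
            if binding is None:
                if port.required:
                    issues.append(f"{where}: required port {port.name!r} unbound")
                continue
            if binding.kind == "manual":
                if not conforms(binding.value, port.semantic_type):
                    issues.append(
                        f"{where}: manual value for {port.name!r} does not conform "
                        f"to {port.semantic_type}"
                    )
            elif binding.kind == "pipe":
                src = binding.source_step
                if src is None or src >= i:
                    issues.append(
                        f"{where}: pipe for {port.name!r} references later or same module "
                        f"(source step {src})"
                    )
                elif src < 0 or wf.steps[src].module not in registry:
                    issues.append(f"{where}: pipe for {port.name!r} has invalid source step {src}")
                else:
                    src_spec = registry.get(wf.steps[src].module)
                    out = src_spec.output_port(binding.source_output)
                    if out is None:
                        issues.append(
                            f"{where}: pipe for {port.name!r}: source step {src} has no "
                            f"output {binding.source_output!r}"
                        )
                    elif not _types_compatible(out.semantic_type, port.semantic_type):
                        issues.append(
                            f"{where}: pipe type mismatch for {port.name!r}: "
                            f"{out.semantic_type} -> {port.semantic_type}"
                        )
            elif binding.kind == "hdf5":
                import h5py

                fpath = Path(binding.file)
                if not fpath.exists():
                    issues.append(f"{where}: hdf5 binding for {port.name!r}: missing file {fpath}")
                else:
                    with h5py.File(fpath, "r") as f:
                        if binding.dataset not in f:
                            issues.append(
                                f"{where}: hdf5 binding for {port.name!r}: no dataset "
                                f"{binding.dataset!r} in {fpath}"
                            )
    return issues


def _resolve_hdf5(binding: InputBinding, semantic_type: str) -> Any:
    import h5py

    from .records import read_value

    with h5py.File(binding.file, "r") as f:
        return read_value(f[binding.dataset], semantic_type)


def _now() -> str:
    return datetime.now(timezone.utc).isoformat()


def execute_workflow(
    wf: WorkflowDef,
    runtime_values: Mapping[str, Any] | None = None,
    registry: ModuleRegistry | None = None,
) -> ExecutionRecord:
    """Run a workflow serially and capture a complete execution record.

    Validation must pass and every runtime prompt key must be supplied
    before any step runs. On a step failure the remaining steps are marked
    ``skipped`` and the (failed) record is still returned.
    """
    registry = registry or default_registry()
    runtime_values = dict(runtime_values or {})
    issues = validate_workflow(wf, registry)
    if issues:
        raise InvalidInputError("invalid workflow: " + "; ".join(issues))
    needed = {
        b.prompt_key
        for step in wf.steps
        for b in step.bindings.values()
        if b.kind == "runtime"
    }
    missing = needed - set(runtime_values)
    if missing:
        raise InvalidInputError(f"missing runtime values for prompt keys: {sorted(missing)}")

    seed = wf.seed if wf.seed is not None else 0
    started = _now()
    resolved_all: list[dict[str, Any]] = []
    outputs_all: list[dict[str, Any]] = []
    statuses: list[str] = []
    errors: list[str | None] = []
    figures: list[tuple[str, bytes]] = []
    failed = False

    for i, step in enumerate(wf.steps):
        if failed:
            resolved_all.append({})
            outputs_all.append({})
            statuses.append("skipped")
            errors.append(None)
            continue
        spec = registry.get(step.module)
        inputs: dict[str, Any] = {}
        try:
            for port in spec.inputs:
                binding = step.bindings.get(port.name)
                if binding is None:
                    if port.name == "seed" and port.semantic_type == "scalar_int":
                        # independent per-step stream derived from the workflow seed
                        inputs[port.name] = seed + i
                    elif port.default is not None:
                        inputs[port.name] = port.default
                    continue
                if binding.kind == "manual":
                    value = binding.value
                elif binding.kind == "runtime":
                    value = runtime_values[binding.prompt_key]
                elif binding.kind == "pipe":
                    value = outputs_all[binding.source_step][binding.source_output]
                else:
                    value = _resolve_hdf5(binding, port.semantic_type)
                if not conforms(value, port.semantic_type):
                    raise InvalidInputError(
                        f"value for port {port.name!r} does not conform to "
                        f"{port.semantic_type}: {type(value).__name__}"
                    )
                inputs[port.name] = value
            result = spec.implementation(**inputs)
            for name, png in result.pop("__figures__", []):
                figures.append((f"{i:02d}_{step.module}_{name}", png))
            for port in spec.outputs:
                if port.name not in result:
                    raise InvalidInputError(
                        f"module {step.module!r} did not produce output {port.name!r}"
                    )
            resolved_all.append(inputs)
            outputs_all.append({p.name: result[p.name] for p in spec.outputs})
            statuses.append("success")
            errors.append(None)
        except Exception as exc:  # capture the failure in the record
            resolved_all.append(inputs)
            outputs_all.append({})
            statuses.append("failed")
            errors.append(f"{type(exc).__name__}: {exc}")
            failed = True

    return ExecutionRecord(
        workflow=copy.deepcopy(wf),
        runtime_values=runtime_values,
        resolved_inputs=resolved_all,
        outputs=outputs_all,
        statuses=statuses,
        errors=errors,
        seed=seed,
        started=started,
        finished=_now(),
        figures=figures,
    )


def run_queue(
    entries: list[tuple[WorkflowDef, Mapping[str, Any]]],
    registry: ModuleRegistry | None = None,
) -> list[ExecutionRecord]:
    """Execute workflows in submission order; one failure does not halt the rest."""
    records: list[ExecutionRecord] = []
    for wf, rv in entries:
        try:
            records.append(execute_workflow(wf, rv, registry))
        except Exception as exc:
            records.append(
                ExecutionRecord(
                    workflow=copy.deepcopy(wf),
                    runtime_values=dict(rv or {}),
                    resolved_inputs=[{} for _ in wf.steps],
                    outputs=[{} for _ in wf.steps],
                    statuses=["failed"] * max(len(wf.steps), 1),
                    errors=[f"{type(exc).__name__}: {exc}"] * max(len(wf.steps), 1),
                    seed=wf.seed if wf.seed is not None else 0,
                    started=_now(),
                    finished=_now(),
                )
            )
    return records


def expand_parameter_grid(
    template: WorkflowDef,
    grid: Mapping[str, list],
    base_runtime_values: Mapping[str, Any] | None = None,
) -> list[tuple[WorkflowDef, dict[str, Any]]]:
    """Cartesian-product expansion of runtime prompt keys into queue entries.

    Rows are generated row-major in grid-key declaration order, so the first
    key varies slowest. Every grid key must be a runtime-bound prompt key of
    the template.
    """
    prompt_keys = {
        b.prompt_key
        for step in template.steps
        for b in step.bindings.values()
        if b.kind == "runtime"
    }
    unknown = set(grid) - prompt_keys
    if unknown:
        raise InvalidInputError(
            f"grid keys not runtime-bound in template: {sorted(unknown)}"
        )
    keys = list(grid)
    entries = []
    for combo in itertools.product(*(grid[k] for k in keys)):
        rv = dict(base_runtime_values or {})
        rv.update(dict(zip(keys, combo)))
        entries.append((copy.deepcopy(template), rv))
    return entries


def value_digest(value: Any) -> str:
    """SHA-256 digest of a canonical serialization of a port value.

    Used for determinism checks between executions and between a stored
    record and its re-execution.
    """
    h = hashlib.sha256()

    def feed(v: Any) -> None:
        if isinstance(v, ROISet):
            h.update(b"roiset")
            h.update(str((v.field_width, v.field_height, v.source)).encode())
            feed(v.ids)
            feed(v.coords)
        elif isinstance(v, np.ndarray):
            arr = np.ascontiguousarray(v)
            h.update(b"array" + str(arr.dtype).encode() + str(arr.shape).encode())
            h.update(arr.tobytes())
        elif isinstance(v, pd.DataFrame):
            h.update(b"table")
            h.update(v.to_csv(index=False).encode())
        elif isinstance(v, (bool, np.bool_)):
            h.update(b"bool" + str(bool(v)).encode())
        elif isinstance(v, (int, np.integer)):
            h.update(b"int" + str(int(v)).encode())
        elif isinstance(v, (float, np.floating)):
            h.update(b"float" + float(v).hex().encode())
        elif isinstance(v, (str, Path)):
            h.update(b"text" + str(v).encode())
        elif isinstance(v, (list, tuple)):
            h.update(b"seq")
            for item in v:
                feed(item)
        elif v is None:
            h.update(b"none")
        else:
            h.update(b"repr" + repr(v).encode())

    feed(value)
    return h.hexdigest()


def record_output_digests(record: ExecutionRecord) -> list[dict[str, str]]:
    """Per-step, per-port digests of a record's outputs."""
    return [
        {port: value_digest(v) for port, v in step_outputs.items()}
        for step_outputs in record.outputs
    ]


# ---------------------------------------------------------------------------
# Built-in modules


def _builtin_specs() -> list[ModuleSpec]:
    from . import matching, metrics, roi, simulate

    def _load_roiset(path, field_width, field_height, source=""):
        return {"roiset": roi.load_roiset(path, field_width, field_height, source)}

    def _generate_ground_truth(n_cells, field_width, field_height, min_separation, seed):
        return {
            "ground_truth": simulate.generate_ground_truth(
                n_cells, field_width, field_height, min_separation, seed
            )
        }

    def _simulate_detector(
        ground_truth, detection_prob, jitter_sigma, n_false_positives, seed, fp_min_distance
    ):
        cfg = simulate.DetectorConfig(
            detection_prob=detection_prob,
            jitter_sigma=jitter_sigma,
            n_false_positives=n_false_positives,
            seed=seed,
            fp_min_distance=fp_min_distance,
        )
        return {"detected": simulate.simulate_detector(ground_truth, cfg)}

    def _match_rois(set_a, set_b, threshold):
        m = matching.match_rois(set_a, set_b, threshold)
        pairs = np.array(m.pairs, dtype=np.float64).reshape(-1, 3)
        return {
            "pairs": pairs,
            "unmatched_a": np.array(m.unmatched_a, dtype=np.int64),
            "unmatched_b": np.array(m.unmatched_b, dtype=np.int64),
            "consensus": m.consensus,
            "n_matched": m.n_matched,
        }

    def _consensus(set_a, set_b, threshold):
        return {"consensus": matching.match_rois(set_a, set_b, threshold).consensus}

    def _evaluate(detected, reference, threshold):
        rep = metrics.evaluate_detection(detected, reference, threshold)
        return {
            "n_detected": rep.n_detected,
            "n_reference": rep.n_reference,
            "n_matched": rep.n_matched,
            "tpr_percent": rep.tpr_percent,
            "precision_percent": rep.precision_percent,
        }

    t = matching.DEFAULT_THRESHOLD
    return [
        ModuleSpec(
            "load_roiset",
            "file_acquisition",
            inputs=(
                Port("path", "path"),
                Port("field_width", "scalar_int"),
                Port("field_height", "scalar_int"),
                Port("source", "text", required=False, default=""),
            ),
            outputs=(Port("roiset", "roiset"),),
            implementation=_load_roiset,
        ),
        ModuleSpec(
            "generate_ground_truth",
            "file_acquisition",
            inputs=(
                Port("n_cells", "scalar_int"),
                Port("field_width", "scalar_int"),
                Port("field_height", "scalar_int"),
                Port("min_separation", "scalar_float", required=False, default=15.0),
                Port("seed", "scalar_int", required=False, default=0),
            ),
            outputs=(Port("ground_truth", "roiset"),),
            implementation=_generate_ground_truth,
        ),
        ModuleSpec(
            "simulate_detector",
            "cell_segmentation",
            inputs=(
                Port("ground_truth", "roiset"),
                Port("detection_prob", "scalar_float", required=False, default=0.8),
                Port("jitter_sigma", "scalar_float", required=False, default=2.0),
                Port("n_false_positives", "scalar_int", required=False, default=50),
                Port("seed", "scalar_int", required=False, default=0),
                Port("fp_min_distance", "scalar_float", required=False, default=t),
            ),
            outputs=(Port("detected", "roiset"),),
            implementation=_simulate_detector,
        ),
        ModuleSpec(
            "match_rois",
            "analysis",
            inputs=(
                Port("set_a", "roiset"),
                Port("set_b", "roiset"),
                Port("threshold", "scalar_float", required=False, default=t),
            ),
            outputs=(
                Port("pairs", "numeric_array"),
                Port("unmatched_a", "numeric_array"),
                Port("unmatched_b", "numeric_array"),
                Port("consensus", "roiset"),
                Port("n_matched", "scalar_int"),
            ),
            implementation=_match_rois,
        ),
        ModuleSpec(
            "consensus_roiset",
            "analysis",
            inputs=(
                Port("set_a", "roiset"),
                Port("set_b", "roiset"),
                Port("threshold", "scalar_float", required=False, default=t),
            ),
            outputs=(Port("consensus", "roiset"),),
            implementation=_consensus,
        ),
        ModuleSpec(
            "evaluate",
            "analysis",
            inputs=(
                Port("detected", "roiset"),
                Port("reference", "roiset"),
                Port("threshold", "scalar_float", required=False, default=t),
            ),
            outputs=(
                Port("n_detected", "scalar_int"),
                Port("n_reference", "scalar_int"),
                Port("n_matched", "scalar_int"),
                Port("tpr_percent", "scalar_float"),
                Port("precision_percent", "scalar_float"),
            ),
            implementation=_evaluate,
        ),
    ]


_DEFAULT_REGISTRY: ModuleRegistry | None = None


def default_registry() -> ModuleRegistry:
    """The process-wide registry, with the built-in modules pre-registered."""
    global _DEFAULT_REGISTRY
    if _DEFAULT_REGISTRY is None:
        _DEFAULT_REGISTRY = ModuleRegistry()
        for spec in _builtin_specs():
            _DEFAULT_REGISTRY.register(spec)
    return _DEFAULT_REGISTRY


def fresh_registry(with_builtins: bool = True) -> ModuleRegistry:
    """An isolated registry (useful in tests)."""
    reg = ModuleRegistry()
    if with_builtins:
        for spec in _builtin_specs():
            reg.register(spec)
    return reg


# ---------------------------------------------------------------------------
# Workflow-definition (de)serialization for config files


def binding_to_dict(b: InputBinding) -> dict:
    d: dict[str, Any] = {"kind": b.kind}
    if b.kind == "manual":
        v = b.value
        if isinstance(v, (np.integer, np.floating, np.bool_)):
            v = v.item()
        d["value"] = v
    elif b.kind == "runtime":
        d["prompt_key"] = b.prompt_key
    elif b.kind == "pipe":
        d["source_step"] = b.source_step
        d["source_output"] = b.source_output
    else:
        d["file"] = b.file
        d["dataset"] = b.dataset
    return d


def binding_from_dict(d: Mapping[str, Any]) -> InputBinding:
    kind = d["kind"]
    if kind == "manual":
        return manual(d["value"])
    if kind == "runtime":
        return runtime(d["prompt_key"])
    if kind == "pipe":
        return pipe(d["source_step"], d["source_output"])
    if kind == "hdf5":
        return hdf5(d["file"], d["dataset"])
    raise InvalidInputError(f"unknown binding kind {kind!r}")


def workflow_to_dict(wf: WorkflowDef) -> dict:
    return {
        "name": wf.name,
        "seed": wf.seed,
        "steps": [
            {
                "module": s.module,
                "bindings": {p: binding_to_dict(b) for p, b in sorted(s.bindings.items())},
            }
            for s in wf.steps
        ],
    }


def workflow_from_dict(d: Mapping[str, Any]) -> WorkflowDef:
    steps = [
        WorkflowStep(
            module=s["module"],
            bindings={p: binding_from_dict(b) for p, b in s.get("bindings", {}).items()},
        )
        for s in d.get("steps", [])
    ]
    return WorkflowDef(name=d.get("name", "workflow"), steps=steps, seed=d.get("seed"))


def load_workflow(path: str | Path) -> WorkflowDef:
    """Read a workflow definition from a YAML or JSON config file."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) if str(path).endswith((".yaml", ".yml")) else json.load(fh)
    return workflow_from_dict(data)


def save_workflow(wf: WorkflowDef, path: str | Path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(workflow_to_dict(wf), fh, sort_keys=True)
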