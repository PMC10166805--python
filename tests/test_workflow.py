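import numpy as np
import pytest

from roiconsensus.roi import InvalidInputError
from roiconsensus.workflow import (
    ModuleSpec,
    Port,
    WorkflowDef,
    WorkflowStep,
    conforms,
    execute_workflow,
    expand_parameter_grid,
    fresh_registry,
    load_workflow,
    manual,
    pipe,
    record_output_digests,
    run_queue,
    runtime,
    save_workflow,
    validate_workflow,
)


def demo_workflow(seed=7, n_cells=40, field=256):
    """Ground truth -> two simulated detectors -> consensus -> evaluation."""
    return WorkflowDef(
        "consensus_demo",
        steps=[
            WorkflowStep(
                "generate_ground_truth",
                {
                    "n_cells": manual(n_cells),
                    "field_width": manual(field),
                    "field_height": manual(field),
                },
            ),
            WorkflowStep(
                "simulate_detector",
                {"ground_truth": pipe(0, "ground_truth"), "n_false_positives": manual(10)},
            ),
            WorkflowStep(
                "simulate_detector",
                {"ground_truth": pipe(0, "ground_truth"), "n_false_positives": manual(10)},
            ),
            WorkflowStep(
                "match_rois",
                {
                    "set_a": pipe(1, "detected"),
                    "set_b": pipe(2, "detected"),
                    "threshold": runtime("threshold"),
                },
            ),
            WorkflowStep(
                "evaluate",
                {
                    "detected": pipe(3, "consensus"),
                    "reference": pipe(0, "ground_truth"),
                    "threshold": runtime("threshold"),
                },
            ),
        ],
        seed=seed,
    )


class TestRegistry:
    def test_register_and_lookup(self):
        reg = fresh_registry(with_builtins=False)
        spec = ModuleSpec(
            "double", "analysis",
            inputs=(Port("x", "scalar_float"),),
            outputs=(Port("y", "scalar_float"),),
            implementation=lambda x: {"y": 2 * x},
        )
        reg.register(spec)
        assert "double" in reg
        assert reg.get("double") is spec

    def test_duplicate_name_rejected(self):
        reg = fresh_registry()
        spec = ModuleSpec(
            "match_rois", "analysis",
            inputs=(), outputs=(), implementation=lambda: {},
        )
        with pytest.raises(InvalidInputError, match="already registered"):
            reg.register(spec)

    def test_duplicate_port_names_rejected(self):
        with pytest.raises(InvalidInputError, match="duplicate"):
            ModuleSpec(
                "bad", "analysis",
                inputs=(Port("x", "scalar_int"), Port("x", "scalar_float")),
                outputs=(),
                implementation=lambda **kw: {},
            )

    def test_builtins_present(self):
        reg = fresh_registry()
        for name in (
            "load_roiset", "generate_ground_truth", "simulate_detector",
            "match_rois", "consensus_roiset", "evaluate",
        ):
            assert name in reg

    def test_required_port_cannot_default(self):
        with pytest.raises(InvalidInputError):
            Port("x", "scalar_int", required=True, default=3)


class TestTypeSystem:
    @pytest.mark.parametrize(
        "value, semantic_type, ok",
        [
            (3, "scalar_int", True),
            (True, "scalar_int", False),
            (3, "scalar_float", True),  # int widens to float
            (2.5, "scalar_int", False),
            ("hi", "text", True),
            (np.arange(3), "numeric_array", True),
            (np.array(["a"]), "numeric_array", False),
        ],
    )
    def test_conforms(self, value, semantic_type, ok):
        assert conforms(value, semantic_type) is ok


class TestValidation:
    def test_valid_workflow_has_no_issues(self):
        assert validate_workflow(demo_workflow()) == []

    def test_unbound_required_port(self):
        wf = WorkflowDef("w", [WorkflowStep("generate_ground_truth", {})])
        issues = validate_workflow(wf)
        assert any("required port" in i for i in issues)

    def test_pipe_to_later_step_flagged(self):
        wf = WorkflowDef(
            "w",
            [
                WorkflowStep(
                    "simulate_detector", {"ground_truth": pipe(1, "ground_truth")}
                ),
                WorkflowStep(
                    "generate_ground_truth",
                    {"n_cells": manual(5), "field_width": manual(64),
                     "field_height": manual(64)},
                ),
            ],
        )
        assert any("later or same" in i for i in validate_workflow(wf))

    def test_pipe_type_mismatch_flagged(self):
        wf = WorkflowDef(
            "w",
            [
                WorkflowStep(
                    "generate_ground_truth",
                    {"n_cells": manual(5), "field_width": manual(64),
                     "field_height": manual(64)},
                ),
                WorkflowStep(
                    "simulate_detector",
                    {"ground_truth": pipe(0, "ground_truth"),
                     # roiset piped into a float port
                     "jitter_sigma": pipe(0, "ground_truth")},
                ),
            ],
        )
        assert any("type mismatch" in i for i in validate_workflow(wf))

    def test_unknown_module_flagged(self):
        wf = WorkflowDef("w", [WorkflowStep("no_such_module", {})])
        assert any("unknown module" in i for i in validate_workflow(wf))

    def test_hdf5_binding_to_missing_file_flagged(self):
        from roiconsensus.workflow import hdf5

        wf = WorkflowDef(
            "w",
            [
                WorkflowStep(
                    "simulate_detector",
                    {"ground_truth": hdf5("/nonexistent/r.h5", "/steps/x")},
                )
            ],
        )
        assert any("missing file" in i for i in validate_workflow(wf))

    def test_manual_value_type_checked(self):
        wf = WorkflowDef(
            "w",
            [
                WorkflowStep(
                    "generate_ground_truth",
                    {"n_cells": manual("many"), "field_width": manual(64),
                     "field_height": manual(64)},
                )
            ],
        )
        assert any("does not conform" in i for i in validate_workflow(wf))


class TestExecution:
    def test_demo_pipeline_runs(self):
        rec = execute_workflow(demo_workflow(), {"threshold": 15.0})
        assert rec.statuses == ["success"] * 5
        assert rec.outputs[4]["n_reference"] == 40
        assert 0 <= rec.outputs[4]["tpr_percent"] <= 100

    def test_seed_determinism_end_to_end(self):
        r1 = execute_workflow(demo_workflow(seed=11), {"threshold": 15.0})
        r2 = execute_workflow(demo_workflow(seed=11), {"threshold": 15.0})
        assert record_output_digests(r1) == record_output_digests(r2)
        r3 = execute_workflow(demo_workflow(seed=12), {"threshold": 15.0})
        assert record_output_digests(r1) != record_output_digests(r3)

    def test_missing_runtime_value_fails_before_any_step(self):
        with pytest.raises(InvalidInputError, match="missing runtime values"):
            execute_workflow(demo_workflow(), {})

    def test_step_failure_skips_rest_but_returns_record(self):
        wf = demo_workflow()
        # a threshold of 0 makes the matcher fail at step 3
        rec = execute_workflow(wf, {"threshold": 0.0})
        assert rec.statuses == ["success", "success", "success", "failed", "skipped"]
        assert rec.status == "failed"
        assert "threshold" in rec.errors[3]

    def test_record_captures_every_declared_input(self):
        reg = fresh_registry()
        rec = execute_workflow(demo_workflow(), {"threshold": 15.0}, reg)
        for i, step in enumerate(rec.workflow.steps):
            spec = reg.get(step.module)
            for port in spec.inputs:
                assert port.name in rec.resolved_inputs[i]

    def test_unbound_seed_ports_get_per_step_streams(self):
        rec = execute_workflow(demo_workflow(seed=100), {"threshold": 15.0})
        assert rec.resolved_inputs[0]["seed"] == 100
        assert rec.resolved_inputs[1]["seed"] == 101
        assert rec.resolved_inputs[2]["seed"] == 102
        # the two detector outputs therefore differ
        a = rec.outputs[1]["detected"]
        b = rec.outputs[2]["detected"]
        assert not np.array_equal(a.coords, b.coords)

    def test_validation_soundness_on_random_workflows(self):
        # any randomly built workflow that passes validation must execute
        # without binding-resolution errors
        rng = np.random.default_rng(314)
        reg = fresh_registry()
        for trial in range(15):
            steps = [
                WorkflowStep(
                    "generate_ground_truth",
                    {"n_cells": manual(int(rng.integers(5, 20))),
                     "field_width": manual(128), "field_height": manual(128)},
                )
            ]
            roiset_outputs = [(0, "ground_truth")]
            for _ in range(int(rng.integers(1, 5))):
                i = len(steps)
                choice = rng.choice(["simulate_detector", "match_rois", "evaluate"])
                src = roiset_outputs[int(rng.integers(len(roiset_outputs)))]
                if choice == "simulate_detector":
                    steps.append(
                        WorkflowStep(choice, {"ground_truth": pipe(*src),
                                              "n_false_positives": manual(3)})
                    )
                    roiset_outputs.append((i, "detected"))
                elif choice == "match_rois":
                    src2 = roiset_outputs[int(rng.integers(len(roiset_outputs)))]
                    steps.append(
                        WorkflowStep(choice, {"set_a": pipe(*src), "set_b": pipe(*src2)})
                    )
                    roiset_outputs.append((i, "consensus"))
                else:
                    src2 = roiset_outputs[int(rng.integers(len(roiset_outputs)))]
                    steps.append(
                        WorkflowStep(choice, {"detected": pipe(*src),
                                              "reference": pipe(*src2)})
                    )
            wf = WorkflowDef(f"random_{trial}", steps, seed=trial)
            assert validate_workflow(wf, reg) == []
            rec = execute_workflow(wf, {}, reg)
            assert "skipped" not in rec.statuses


class TestQueueAndGrid:
    def test_queue_preserves_order(self):
        entries = [(demo_workflow(seed=s), {"threshold": 15.0}) for s in (1, 2, 3)]
        recs = run_queue(entries)
        assert [r.seed for r in recs] == [1, 2, 3]
        assert all(r.status == "success" for r in recs)

    def test_queue_failure_does_not_halt(self):
        entries = [
            (demo_workflow(seed=1), {"threshold": 15.0}),
            (demo_workflow(seed=2), {"threshold": 0.0}),  # fails at matching
            (demo_workflow(seed=3), {"threshold": 15.0}),
        ]
        recs = run_queue(entries)
        assert [r.status for r in recs] == ["success", "failed", "success"]

    def test_empty_queue(self):
        assert run_queue([]) == []

    def test_grid_cartesian_product_row_major(self):
        wf = demo_workflow()
        wf.steps[3].bindings["threshold"] = runtime("t")
        wf.steps[4].bindings["threshold"] = runtime("t")
        wf.steps[1].bindings["detection_prob"] = runtime("p")
        entries = expand_parameter_grid(wf, {"p": [0.5, 0.9], "t": [5.0, 10.0, 15.0]})
        assert len(entries) == 6
        assert [e[1]["p"] for e in entries] == [0.5, 0.5, 0.5, 0.9, 0.9, 0.9]
        assert [e[1]["t"] for e in entries[:3]] == [5.0, 10.0, 15.0]

    def test_printed_sweep_ranges(self):
        # threshold_scaling 0.7..3.4 step 0.1 -> 28 runs; max_overlap 0..1 step 0.1 -> 11
        wf = demo_workflow()
        wf.steps[3].bindings["threshold"] = runtime("threshold_scaling")
        wf.steps[4].bindings["threshold"] = runtime("max_overlap")
        ts = [round(0.7 + 0.1 * i, 1) for i in range(28)]
        assert ts[0] == 0.7 and ts[-1] == 3.4
        assert len(expand_parameter_grid(wf, {"threshold_scaling": ts})) == 28
        mo = [round(0.1 * i, 1) for i in range(11)]
        assert mo[0] == 0.0 and mo[-1] == 1.0
        assert len(expand_parameter_grid(wf, {"max_overlap": mo})) == 11

    def test_unknown_grid_key_rejected(self):
        with pytest.raises(InvalidInputError, match="grid keys"):
            expand_parameter_grid(demo_workflow(), {"nope": [1, 2]})


class TestWorkflowSerialization:
    def test_yaml_roundtrip(self, tmp_path):
        wf = demo_workflow(seed=5)
        path = tmp_path / "wf.yaml"
        save_workflow(wf, path)
        loaded = load_workflow(path)
        assert loaded.name == wf.name
        assert loaded.seed == 5
        assert [s.module for s in loaded.steps] == [s.module for s in wf.steps]
        r1 = execute_workflow(wf, {"threshold": 15.0})
        r2 = execute_workflow(loaded, {"threshold": 15.0})
        assert record_output_digests(r1) == record_output_digests(r2)
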