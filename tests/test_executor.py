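"""Executor: random invocations, simulation, container wrapping, launch."""

import copy
import os

import pytest

from clidesc import (ContainerImage, Descriptor, ExecutionEnvironmentError,
                     Input, InvalidInvocationError, OutputFile,
                     RandomInvocationError, UnsupportedContainerError,
                     generate_random_descriptor, invocation_is_valid, launch,
                     random_invocation, simulate, wrap_in_container)
from conftest import make_minimal


def echo_descriptor() -> Descriptor:
    """Self-contained smoke tool: expand a config file, write one output."""
    d = make_minimal()
    d.command_line = "cat [CONFIG] > /dev/null; echo ok > [OUT]"
    d.inputs = [Input(id="level", name="Level", type="Number",
                      value_key="[LEVEL]", optional=True,
                      default_value=2)]
    d.output_files = [
        OutputFile(id="result", name="Result", path_template="result.txt",
                   value_key="[OUT]"),
        OutputFile(id="config", name="Config", path_template="settings.cfg",
                   value_key="[CONFIG]",
                   file_template=["level = [LEVEL]"]),
    ]
    return d


class TestRandomInvocation:
    def test_required_bounded_number_within_range(self, minimal):
        minimal.command_line = "tool [N]"
        minimal.inputs = [Input(id="n", name="N", type="Number",
                                value_key="[N]", minimum=2, maximum=5)]
        for seed in range(20):
            inv = random_invocation(minimal, seed)
            assert set(inv) == {"n"}
            assert 2 <= inv["n"] <= 5

    def test_no_inputs_yields_empty_invocation(self, minimal):
        assert random_invocation(minimal, seed=0) == {}

    def test_deterministic_for_fixed_seed(self):
        d = generate_random_descriptor(3, n_inputs=5, n_outputs=2)
        assert random_invocation(d, 42) == random_invocation(d, 42)

    def test_one_is_required_mutex_group_gets_exactly_one_member(
            self, minimal):
        from clidesc import Group
        minimal.command_line = "tool [A] [B]"
        minimal.inputs = [
            Input(id="a", name="A", type="String", value_key="[A]",
                  optional=True),
            Input(id="b", name="B", type="String", value_key="[B]",
                  optional=True)]
        minimal.groups = [Group(id="g", name="G", members=["a", "b"],
                                mutually_exclusive=True,
                                one_is_required=True)]
        for seed in range(100):
            inv = random_invocation(minimal, seed)
            assert len(set(inv) & {"a", "b"}) == 1
            assert invocation_is_valid(minimal, inv)

    def test_over_constrained_descriptor_names_budget(self, minimal):
        # a required input that disables itself is never satisfiable
        minimal.command_line = "tool [A] [B]"
        minimal.inputs = [
            Input(id="a", name="A", type="String", value_key="[A]",
                  optional=True, requires_inputs=["b"],
                  disables_inputs=["b"])]
        # descriptor invalid (V9); bypass semantic checks with an
        # embedded all-rejecting schema on a valid descriptor instead
        minimal.inputs = [Input(id="a", name="A", type="String",
                                value_key="[A]", optional=True)]
        minimal.command_line = "tool [A]"
        minimal.invocation_schema = {"type": "object", "not": {}}
        with pytest.raises(RandomInvocationError):
            random_invocation(minimal, seed=0)

    def test_thousand_draws_all_validate(self):
        # corpus-wide robustness: every draw validates, no residual keys
        checked = 0
        for seed in range(100):
            d = generate_random_descriptor(seed, n_inputs=1 + seed % 5,
                                           n_outputs=seed % 3)
            for sub_seed in range(10):
                inv = random_invocation(d, seed=sub_seed)
                assert invocation_is_valid(d, inv)
                checked += 1
        assert checked == 1000


class TestSimulate:
    def test_minimal_without_invocation_equals_template(self, minimal):
        plan = simulate(minimal, seed=1)
        assert plan.command == minimal.command_line

    def test_fixed_seed_gives_identical_plan(self):
        d = generate_random_descriptor(5, n_inputs=4, n_outputs=2)
        assert simulate(d, seed=9) == simulate(d, seed=9)

    def test_invalid_supplied_invocation_refused_with_violations(
            self, worked_example):
        with pytest.raises(InvalidInvocationError) as exc:
            simulate(worked_example, {"str_input": 5, "file_input": "f"})
        assert exc.value.violations

    def test_simulation_writes_nothing(self, tmp_path, monkeypatch):
        monkeypatch.chdir(tmp_path)
        simulate(echo_descriptor(), {"level": 3})
        assert list(tmp_path.iterdir()) == []

    def test_no_residual_keys_across_corpus(self):
        for seed in range(50):
            d = generate_random_descriptor(seed, n_inputs=4, n_outputs=2)
            plan = simulate(d, seed=seed)
            for i in d.inputs:
                assert i.value_key not in plan.command


class TestWrapInContainer:
    def test_docker_form_is_byte_exact(self):
        c = ContainerImage(type="docker", image="img")
        text = wrap_in_container(c, "echo hi", "/work",
                                 [("/data", "/mnt/data")])
        assert text == ("docker run --rm -v /data:/mnt/data -w /work "
                        "img sh -c 'echo hi'")

    def test_singularity_form_is_byte_exact(self):
        c = ContainerImage(type="singularity", image="img.sif")
        text = wrap_in_container(c, "echo hi", "/work", [])
        assert text == "singularity exec --pwd /work img.sif sh -c 'echo hi'"

    def test_rootfs_cannot_be_launched(self):
        c = ContainerImage(type="rootfs", image="http://example.org/fs.tar")
        with pytest.raises(UnsupportedContainerError):
            wrap_in_container(c, "echo hi", "/work", [])

    def test_descriptor_working_directory_wins(self):
        c = ContainerImage(type="docker", image="img",
                           working_directory="/app")
        assert " -w /app " in wrap_in_container(c, "x", "/task", [])

    def test_entry_point_passes_command_as_arguments(self):
        c = ContainerImage(type="docker", image="img", entry_point=True)
        text = wrap_in_container(c, "--level 2", "/work", [])
        assert text == "docker run --rm -w /work img --level 2"

    def test_single_quotes_in_command_survive(self):
        c = ContainerImage(type="docker", image="img")
        text = wrap_in_container(c, "echo 'a b'", "/w", [])
        assert text.endswith("sh -c 'echo '\\''a b'\\'''")

    def test_registry_index_prefixes_image(self):
        c = ContainerImage(type="docker", image="img",
                           index="quay.io")
        assert " quay.io/img " in wrap_in_container(c, "x", "/w", [])


class TestLaunch:
    def test_smoke_run_finds_mandatory_outputs(self, tmp_path):
        d = echo_descriptor()
        record = launch(d, {"level": 3}, task_dir=str(tmp_path))
        assert record.exit_status == 0
        assert record.missing_mandatory_outputs == []
        found_ids = {i for i, _ in record.found_outputs}
        assert found_ids == {"result", "config"}
        assert (tmp_path / "settings.cfg").read_text() == "level = 3\n"
        assert (tmp_path / "result.txt").read_text() == "ok\n"
        assert record.success

    def test_missing_output_is_reported_not_raised(self, tmp_path):
        d = echo_descriptor()
        # drop the clause that creates the file; [OUT] stays in the template
        d.command_line = "cat [CONFIG] > /dev/null; true [OUT]"
        record = launch(d, {"level": 1}, task_dir=str(tmp_path))
        assert record.exit_status == 0
        assert record.missing_mandatory_outputs == ["result"]
        assert not record.success

    def test_optional_output_absence_is_not_failure(self, tmp_path):
        d = echo_descriptor()
        d.output_files[0].optional = True
        d.command_line = "cat [CONFIG] > /dev/null; true [OUT]"
        record = launch(d, {"level": 1}, task_dir=str(tmp_path))
        assert record.success

    def test_list_output_globbing(self, tmp_path):
        d = make_minimal()
        d.command_line = "touch part_1.txt part_2.txt"
        d.output_files = [OutputFile(id="parts", name="Parts", list=True,
                                     path_template="part_*.txt")]
        record = launch(d, {}, task_dir=str(tmp_path))
        [(out_id, paths)] = record.found_outputs
        assert out_id == "parts" and len(paths) == 2

    def test_empty_list_output_fails_when_mandatory(self, tmp_path):
        d = make_minimal()
        d.command_line = "true"
        d.output_files = [OutputFile(id="parts", name="Parts", list=True,
                                     path_template="part_*.txt")]
        record = launch(d, {}, task_dir=str(tmp_path))
        assert record.missing_mandatory_outputs == ["parts"]

    def test_nonzero_exit_status_recorded(self, tmp_path):
        d = make_minimal()
        d.command_line = "exit 3"
        record = launch(d, {}, task_dir=str(tmp_path))
        assert record.exit_status == 3 and not record.success

    def test_stdout_and_stderr_are_captured(self, tmp_path):
        d = make_minimal()
        d.command_line = "echo out; echo err >&2"
        record = launch(d, {}, task_dir=str(tmp_path))
        assert open(record.stdout_path).read() == "out\n"
        assert open(record.stderr_path).read() == "err\n"

    def test_dry_run_is_pure_and_matches_real_command(self, tmp_path):
        d = echo_descriptor()
        dry = launch(d, {"level": 3}, dry_run=True, task_dir=str(tmp_path))
        assert list(tmp_path.iterdir()) == []
        wet = launch(d, {"level": 3}, task_dir=str(tmp_path))
        assert dry.command == wet.command
        dry2 = launch(d, {"level": 3}, dry_run=True,
                      task_dir=str(tmp_path / "other"))
        assert not (tmp_path / "other").exists()
        assert dry2.command == dry.command

    def test_missing_runtime_errors_unless_forced(self, tmp_path,
                                                  monkeypatch):
        d = echo_descriptor()
        d.container = ContainerImage(type="docker", image="img")
        monkeypatch.setattr("shutil.which", lambda name: None)
        with pytest.raises(ExecutionEnvironmentError):
            launch(d, {"level": 1}, task_dir=str(tmp_path))
        with pytest.warns(UserWarning):
            record = launch(d, {"level": 1}, force_no_container=True,
                            task_dir=str(tmp_path))
        assert record.success

    def test_dry_run_reports_container_command(self, tmp_path):
        d = echo_descriptor()
        d.container = ContainerImage(type="docker", image="img",
                                     working_directory="/work")
        record = launch(d, {"level": 1}, dry_run=True,
                        task_dir=str(tmp_path))
        assert record.container_command is not None
        assert record.container_command.startswith("docker run --rm -v ")
        assert record.container_command.endswith(
            f"sh -c '{record.command}'")

    def test_rootfs_launch_unsupported(self, tmp_path):
        d = echo_descriptor()
        d.container = ContainerImage(type="rootfs",
                                     image="http://example.org/fs")
        with pytest.raises(UnsupportedContainerError):
            launch(d, {"level": 1}, task_dir=str(tmp_path))
        # but simulation is fully supported
        assert simulate(d, {"level": 1}).command

    def test_suggested_resources_are_advisory_metadata(self, tmp_path):
        from clidesc import SuggestedResources
        d = echo_descriptor()
        d.suggested_resources = SuggestedResources(cpu_cores=4, ram_gb=2.0)
        record = launch(d, {"level": 1}, task_dir=str(tmp_path))
        assert record.suggested_resources.cpu_cores == 4
        assert record.success
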