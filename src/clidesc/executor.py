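"""The executor: simulate command lines and launch them, optionally in a
container.

*simulate* builds a :class:`~clidesc.build.CommandLinePlan` from a supplied
or randomly drawn invocation without touching the filesystem; *launch*
writes the configuration files, runs the command through ``sh`` (wrapped in
the descriptor's container when a runtime is available), captures
stdout/stderr, and checks that every mandatory output exists afterwards.

Suggested resources are surfaced as advisory metadata only and never
enforced — actual requirements depend on the input data.
"""

from __future__ import annotations

import glob as _glob
import os
import random
import shutil
import string
import subprocess
import warnings
from dataclasses import dataclass, field, replace

from .build import CommandLinePlan, build_plan
from .errors import (ExecutionEnvironmentError, InvalidInvocationError,
                     RandomInvocationError, UnsupportedContainerError)
import jsonschema

from .invocation import (Invocation, generate_invocation_schema,
                         validate_invocation)
from .model import ContainerImage, Descriptor, Input, SuggestedResources
from .validation import assert_valid

STDOUT_NAME = ".task.stdout"
STDERR_NAME = ".task.stderr"

#: sampling range for Numbers with no declared bounds; one-sided bounds
#: extend 100 beyond the given bound.
UNBOUNDED_RANGE = 100.0

_ATTEMPT_BUDGET = 2000


def _sample_number(i: Input, rng: random.Random):
    lo, hi = i.minimum, i.maximum
    if lo is None and hi is None:
        lo, hi = -UNBOUNDED_RANGE, UNBOUNDED_RANGE
    elif lo is None:
        lo = hi - UNBOUNDED_RANGE
    elif hi is None:
        hi = lo + UNBOUNDED_RANGE
    if i.integer:
        ilo, ihi = int(-(-lo // 1)), int(hi // 1)
        if i.exclusive_minimum:
            ilo += 1
        if i.exclusive_maximum:
            ihi -= 1
        return rng.randint(ilo, ihi)
    val = rng.uniform(lo, hi)
    # nudge away from excluded endpoints
    if i.exclusive_minimum and val == lo:
        val = (lo + hi) / 2
    if i.exclusive_maximum and val == hi:
        val = (lo + hi) / 2
    return val


def _sample_scalar(i: Input, rng: random.Random):
    if i.value_choices:
        return rng.choice(i.value_choices)
    if i.type == "Number":
        return _sample_number(i, rng)
    if i.type == "Flag":
        return rng.random() < 0.5
    text = "".join(rng.choice(string.ascii_lowercase + string.digits)
                   for _ in range(rng.randint(1, 10)))
    if i.type == "File":
        return f"f_{text}.dat"
    return text


def _draw(d: Descriptor, rng: random.Random) -> Invocation:
    inv: Invocation = {}
    for i in d.inputs:
        if i.optional and rng.random() < 0.5:
            continue
        if i.list:
            inv[i.id] = [_sample_scalar(i, rng)
                         for _ in range(rng.randint(1, 3))]
        else:
            inv[i.id] = _sample_scalar(i, rng)
    return inv


def random_invocation(d: Descriptor, seed: int) -> Invocation:
    """Draw a valid invocation at random (generate-and-check).

    Deterministic for a fixed seed.  Required inputs are always assigned;
    optional inputs with probability one half; Numbers uniformly within
    their bounds; list lengths in 1..3.  Raises
    :class:`~clidesc.errors.RandomInvocationError` when no draw validates
    within the attempt budget (over-constrained descriptor).
    """
    assert_valid(d)
    schema = d.invocation_schema or generate_invocation_schema(d)
    validator = jsonschema.Draft4Validator(schema)
    rng = random.Random(seed)
    for _ in range(_ATTEMPT_BUDGET):
        inv = _draw(d, rng)
        if validator.is_valid(inv):
            return inv
    raise RandomInvocationError(_ATTEMPT_BUDGET)


def simulate(d: Descriptor, inv: Invocation | None = None,
             seed: int = 0) -> CommandLinePlan:
    """Build the plan that *would* be executed, without side effects.

    With ``inv`` absent a random invocation is drawn from ``seed``; a
    supplied invocation is validated first and refused with its violations.
    """
    if inv is None:
        inv = random_invocation(d, seed)
    else:
        violations = validate_invocation(d, inv)
        if violations:
            raise InvalidInvocationError(violations)
    return build_plan(d, inv)


def wrap_in_container(c: ContainerImage, command: str, workdir: str,
                      mounts=()) -> str:
    """Wrap a command in the container runtime's shell invocation.

    Forms are fixed for determinism: docker ->
    ``docker run --rm -v <host>:<cont> -w <workdir> <image> sh -c
    '<command>'``; singularity -> ``singularity exec -B <host>:<cont>
    --pwd <workdir> <image> sh -c '<command>'``.  With an entry point the
    command text is passed as arguments to the image instead of through an
    explicit ``sh`` invocation.  rootfs images cannot be launched.
    """
    if c.type == "rootfs":
        raise UnsupportedContainerError(
            "rootfs containers can be simulated but not launched")
    if c.type not in ("docker", "singularity"):
        raise UnsupportedContainerError(f"unknown container type {c.type!r}")
    image = f"{c.index.rstrip('/')}/{c.image}" if c.index else c.image
    wd = c.working_directory or workdir
    parts: list[str] = []
    if c.type == "docker":
        parts += ["docker", "run", "--rm"]
        for host, cont in mounts:
            parts += ["-v", f"{host}:{cont}"]
        parts += ["-w", wd, image]
    else:
        parts += ["singularity", "exec"]
        for host, cont in mounts:
            parts += ["-B", f"{host}:{cont}"]
        parts += ["--pwd", wd, image]
    if c.entry_point:
        return " ".join(parts) + " " + command
    escaped = command.replace("'", "'\\''")
    return " ".join(parts) + f" sh -c '{escaped}'"


@dataclass
class ExecutionRecord:
    """What happened (or would happen) in one launch."""

    command: str
    container_command: str | None
    exit_status: int
    found_outputs: list[tuple[str, list[str]]] = field(default_factory=list)
    missing_mandatory_outputs: list[str] = field(default_factory=list)
    stdout_path: str = ""
    stderr_path: str = ""
    suggested_resources: SuggestedResources | None = None

    @property
    def success(self) -> bool:
        return self.exit_status == 0 and not self.missing_mandatory_outputs


def write_config_files(plan: CommandLinePlan, task_dir: str) -> list[str]:
    """Materialize the plan's configuration files under ``task_dir``."""
    written = []
    for rel_path, content in plan.config_files:
        path = os.path.join(task_dir, rel_path)
        os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(content)
        written.append(path)
    return written


def _collect_outputs(plan: CommandLinePlan, task_dir: str):
    found: list[tuple[str, list[str]]] = []
    missing: list[str] = []
    for out in plan.expected_outputs:
        pattern = os.path.join(task_dir, out.path)
        if out.list:
            matches = sorted(_glob.glob(pattern))
        else:
            matches = [pattern] if os.path.exists(pattern) else []
        if matches:
            found.append((out.id, matches))
        elif not out.optional:
            missing.append(out.id)
    return found, missing


def _check_container_hash(c: ContainerImage, runtime: str) -> None:
    if not c.container_hash:
        return
    probe = {"docker": ["docker", "inspect", "--format",
                        "{{index .RepoDigests 0}}", c.image]}
    cmd = probe.get(runtime)
    if cmd is None:
        return
    try:
        res = subprocess.run(cmd, capture_output=True, text=True, timeout=30)
    except (OSError, subprocess.TimeoutExpired):  # pragma: no cover
        return
    digest = res.stdout.strip()
    if res.returncode == 0 and digest and c.container_hash not in digest:
        warnings.warn(
            f"container hash mismatch: descriptor says "
            f"{c.container_hash!r}, runtime reports {digest!r}",
            stacklevel=3)


def launch(d: Descriptor, inv: Invocation, *, dry_run: bool = False,
           force_no_container: bool = False,
           runtime_preference: str | None = None,
           task_dir: str = ".", mounts=()) -> ExecutionRecord:
    """Execute a descriptor for one invocation.

    Builds the plan, writes config files into ``task_dir``, wraps the
    command in the descriptor's container when a runtime is available,
    executes through ``sh`` capturing stdout/stderr, then checks expected
    outputs.  ``dry_run`` performs everything except execution and
    filesystem writes.  An execution failure is reported through
    ``exit_status``, not an exception.
    """
    plan = build_plan(d, inv)  # validates descriptor and invocation

    container_command = None
    exec_command = plan.command
    if d.container is not None and not force_no_container:
        runtime = runtime_preference or d.container.type
        if runtime == "rootfs":
            raise UnsupportedContainerError(
                "rootfs containers can be simulated but not launched")
        c = replace(d.container, type=runtime)
        host_dir = os.path.abspath(task_dir)
        workdir = c.working_directory or host_dir
        auto_mounts = list(mounts) + [(host_dir, workdir)]
        container_command = wrap_in_container(
            c, plan.command, workdir, auto_mounts)
        if shutil.which(runtime) is not None:
            _check_container_hash(c, runtime)
            exec_command = container_command
        elif force_no_container:  # pragma: no cover - unreachable guard
            pass
        elif dry_run:
            pass  # absence of the runtime is irrelevant to a dry run
        else:
            raise ExecutionEnvironmentError(
                f"container runtime {runtime!r} is not available; "
                "pass force_no_container=True to run bare")

    stdout_path = os.path.join(task_dir, STDOUT_NAME)
    stderr_path = os.path.join(task_dir, STDERR_NAME)

    if dry_run:
        return ExecutionRecord(
            command=plan.command, container_command=container_command,
            exit_status=0, found_outputs=[], missing_mandatory_outputs=[],
            stdout_path=stdout_path, stderr_path=stderr_path,
            suggested_resources=d.suggested_resources)

    if (d.container is not None and force_no_container
            and exec_command is plan.command):
        warnings.warn("descriptor declares a container but the command is "
                      "run bare (force_no_container)", stacklevel=2)

    os.makedirs(task_dir, exist_ok=True)
    write_config_files(plan, task_dir)
    with open(stdout_path, "w", encoding="utf-8") as out_fh, \
            open(stderr_path, "w", encoding="utf-8") as err_fh:
        result = subprocess.run(["sh", "-c", exec_command], cwd=task_dir,
                                stdout=out_fh, stderr=err_fh)
    found, missing = _collect_outputs(plan, task_dir)
    return ExecutionRecord(
        command=plan.command, container_command=container_command,
        exit_status=result.returncode, found_outputs=found,
        missing_mandatory_outputs=missing,
        stdout_path=stdout_path, stderr_path=stderr_path,
        suggested_resources=d.suggested_resources)
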