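"""Random descriptor generation for the test surface.

The generator draws descriptors spanning every input type, list-ness,
restrictions, groups, and dependencies — but only in combinations that are
valid by construction (the semantic validator returns no violations) and
satisfiable (a valid invocation exists), so that property suites can use
the corpus without per-case filtering.  Output is deterministic for fixed
arguments.
"""

from __future__ import annotations

import random

from .model import Descriptor, Group, Input, OutputFile


def _make_input(k: int, rng: random.Random) -> Input:
    kind = rng.choice(["String", "Number", "Flag", "File"])
    i = Input(id=f"in_{k}", name=f"Input {k}", type=kind,
              value_key=f"[IN_{k}]")
    if kind == "Flag":
        i.optional = True
        i.command_line_flag = f"--flag{k}"
        return i
    i.optional = rng.random() < 0.6
    i.list = rng.random() < 0.25
    if rng.random() < 0.5:
        i.command_line_flag = f"--opt{k}"
        if rng.random() < 0.3:
            i.command_line_flag_separator = "="
    if kind == "Number":
        i.integer = rng.random() < 0.5
        if rng.random() < 0.5:
            lo = rng.randint(-50, 0)
            i.minimum = lo
            i.maximum = lo + rng.randint(3, 50)
    if kind in ("String", "Number") and rng.random() < 0.3:
        if kind == "String":
            i.value_choices = [f"choice{k}_{j}"
                               for j in range(rng.randint(2, 4))]
        else:
            lo = i.minimum if i.minimum is not None else -50
            hi = i.maximum if i.maximum is not None else 50
            pool = sorted({rng.randint(int(lo), int(hi))
                           for _ in range(rng.randint(2, 4))})
            i.value_choices = [float(p) for p in pool] \
                if not i.integer else list(pool)
        if i.optional and rng.random() < 0.5:
            i.default_value = rng.choice(i.value_choices)
            if i.list:
                i.default_value = [i.default_value]
    return i


def _make_output(k: int, inputs: list[Input],
                 rng: random.Random) -> OutputFile:
    o = OutputFile(id=f"out_{k}", name=f"Output {k}",
                   path_template=f"result_{k}.txt")
    style = rng.random()
    substitutable = [i for i in inputs
                     if i.type in ("String", "File") and not i.list]
    if style < 0.25 and substitutable:
        ref = rng.choice(substitutable)
        o.path_template = f"result_{k}_{ref.value_key}.out"
        o.path_template_stripped_extensions = [".dat", ".txt", ".csv"]
    elif style < 0.45:
        o.list = True
        o.path_template = f"result_{k}_*.txt"
    elif style < 0.6:
        o.file_template = [f"# config {k}",
                           *(f"{i.id} = {i.value_key}"
                             for i in inputs[:2] if i.value_key)]
        o.path_template = f"config_{k}.cfg"
        o.value_key = f"[OUT_{k}]"
    elif style < 0.75:
        o.value_key = f"[OUT_{k}]"
    o.optional = rng.random() < 0.3
    return o


def generate_random_descriptor(seed: int, n_inputs: int = 4,
                               n_outputs: int = 2,
                               with_groups: bool = True) -> Descriptor:
    """Generate a deterministic, always-valid random descriptor.

    The command line contains every generated value key; groups and
    dependencies are drawn only in satisfiable combinations.
    """
    rng = random.Random(seed * 1_000_003 + n_inputs * 101
                        + n_outputs * 11 + int(with_groups))
    inputs = [_make_input(k, rng) for k in range(n_inputs)]
    outputs = [_make_output(k, inputs, rng) for k in range(n_outputs)]

    groups: list[Group] = []
    grouped: set[str] = set()
    optional_ids = [i.id for i in inputs if i.optional]
    if with_groups and len(optional_ids) >= 2 and rng.random() < 0.7:
        size = rng.randint(2, min(3, len(optional_ids)))
        members = rng.sample(optional_ids, size)
        grouped.update(members)
        kind = rng.choice(["mutex", "one_req", "all_or_none",
                           "mutex_one_req", "plain"])
        groups.append(Group(
            id="grp_0", name="Group 0", members=members,
            mutually_exclusive=kind in ("mutex", "mutex_one_req"),
            one_is_required=kind in ("one_req", "mutex_one_req"),
            all_or_none=kind == "all_or_none"))

    # at most one dependency edge, between optional ungrouped inputs
    free = [i for i in inputs if i.optional and i.id not in grouped]
    if len(free) >= 2 and rng.random() < 0.5:
        a, b = rng.sample(free, 2)
        if rng.random() < 0.5:
            a.requires_inputs = [b.id]
        else:
            a.disables_inputs = [b.id]

    keys = [i.value_key for i in inputs if i.value_key] + \
        [o.value_key for o in outputs if o.value_key]
    command_line = " ".join(["tool"] + keys) if keys else "tool"
    return Descriptor(
        name=f"random-tool-{seed}",
        description="Randomly generated descriptor for property testing.",
        tool_version="1.0.0",
        command_line=command_line,
        inputs=inputs,
        output_files=outputs,
        groups=groups,
    )
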