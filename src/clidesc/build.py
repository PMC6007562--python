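"""Command-line construction.

From a valid descriptor and a validated invocation this module renders input
tokens (value, flag, separator, quoting), resolves output path templates
(with suffix stripping), expands configuration-file templates, and produces
a :class:`CommandLinePlan`: the final sh command, the configuration files to
write, and the output paths expected after execution.

Construction is pure — nothing is written to disk here; the executor
materializes config files at launch time.

Substitution is a single simultaneous pass over all declared value keys,
which the validator's no-nested-keys rule (V5) makes equivalent to any
sequential order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import (InvalidInvocationError, UnresolvedValueKeyError)
from .model import Descriptor, Input, OutputFile
from .validation import assert_valid
from . import invocation as _inv

_UNSAFE = re.compile(r"[^A-Za-z0-9._/=+:,@-]")


def format_value(value) -> str:
    """Format a scalar value as command-line text.

    Integers (including integral floats) print without a decimal point;
    other numbers use the shortest round-trip decimal form; booleans print
    as ``true``/``false``; text passes through verbatim.
    """
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, int):
        return str(value)
    if isinstance(value, float):
        return str(int(value)) if value.is_integer() else repr(value)
    return str(value)


def quote(text: str) -> str:
    """Single-quote ``text`` for sh if it contains any unsafe character."""
    if text == "":
        return "''"
    if _UNSAFE.search(text):
        return "'" + text.replace("'", "'\\''") + "'"
    return text


def render_token(i: Input, value) -> str:
    """Render the command-line text an input contributes for ``value``.

    Flags render as their flag text when true and as empty text when false;
    valued inputs render as ``value`` or ``flag<separator>value``; list
    inputs join their rendered values with spaces, the flag (if any) emitted
    once before the list.
    """
    if i.type == "Flag":
        if not isinstance(value, bool):
            raise TypeError(
                f"Flag input {i.id!r} takes a boolean, got {value!r}")
        return i.command_line_flag if value else ""
    if i.list:
        text = " ".join(quote(format_value(v)) for v in value)
    else:
        text = quote(format_value(value))
    if i.command_line_flag is not None:
        return i.command_line_flag + i.command_line_flag_separator + text
    return text


def strip_suffix(value: str, suffixes) -> str:
    """Remove the first listed suffix that matches the end of ``value``,
    once; remaining entries are ignored (list order is author priority)."""
    for suffix in suffixes or []:
        if suffix and value.endswith(suffix):
            return value[:-len(suffix)]
    return value


def _path_value(i: Input, value, suffixes) -> str:
    if i.type == "Flag":
        return format_value(value)
    if i.list:
        return " ".join(strip_suffix(format_value(v), suffixes)
                        for v in value)
    return strip_suffix(format_value(value), suffixes)


def _substitute(text: str, mapping: dict[str, str]) -> str:
    """Simultaneous single-pass substitution of every key in ``mapping``."""
    if not mapping:
        return text
    pattern = re.compile("|".join(
        re.escape(k) for k in sorted(mapping, key=len, reverse=True)))
    return pattern.sub(lambda m: mapping[m.group(0)], text)


def resolve_output_path(o: OutputFile, inv: _inv.Invocation,
                        d: Descriptor) -> str:
    """Resolve an output's path template against an invocation.

    Each input value key in the template is replaced by the input's value
    after suffix stripping; a list output's wildcard ``*`` is preserved
    verbatim.  A referenced input with neither a value nor a default raises
    :class:`~clidesc.errors.UnresolvedValueKeyError`.
    """
    mapping: dict[str, str] = {}
    for i in d.inputs:
        if i.value_key is None or i.value_key not in o.path_template:
            continue
        if i.id in inv:
            value = inv[i.id]
        elif i.default_value is not None:
            value = i.default_value
        else:
            raise UnresolvedValueKeyError(i.value_key)
        mapping[i.value_key] = _path_value(
            i, value, o.path_template_stripped_extensions)
    return _substitute(o.path_template, mapping)


@dataclass(frozen=True)
class ExpectedOutput:
    """One output the platform should look for after execution."""

    id: str
    path: str            # resolved path, or glob pattern for list outputs
    optional: bool
    list: bool


@dataclass
class CommandLinePlan:
    """The fully substituted command, config files, and expected outputs."""

    command: str
    config_files: list[tuple[str, str]] = field(default_factory=list)
    expected_outputs: list[ExpectedOutput] = field(default_factory=list)


def _normalize_whitespace(command: str) -> str:
    """Collapse runs of spaces outside single-quoted spans; trim ends."""
    out: list[str] = []
    in_quote = False
    for ch in command:
        if ch == "'":
            in_quote = not in_quote
        if ch == " " and not in_quote and out and out[-1] == " ":
            continue
        out.append(ch)
    return "".join(out).strip(" ")


def build_plan(d: Descriptor, inv: _inv.Invocation) -> CommandLinePlan:
    """Construct the command line, config files, and expected outputs.

    Steps: apply defaults for unassigned optional inputs; render input
    tokens; resolve output paths; substitute everything into the command
    line and the file templates; normalize whitespace in the command.
    Unassigned optional inputs substitute as empty text.
    """
    assert_valid(d)
    violations = _inv.validate_invocation(d, inv)
    if violations:
        raise InvalidInvocationError(violations)

    effective = dict(inv)
    for i in d.inputs:
        if i.id not in effective and i.default_value is not None:
            effective[i.id] = i.default_value

    # command-line substitution map: rendered input tokens
    cmd_map: dict[str, str] = {}
    # config-file substitution map: plain value text (no flags, no quoting)
    cfg_map: dict[str, str] = {}
    for i in d.inputs:
        if i.value_key is None:
            continue
        if i.id in effective:
            cmd_map[i.value_key] = render_token(i, effective[i.id])
            cfg_map[i.value_key] = _path_value(i, effective[i.id], None)
        else:
            cmd_map[i.value_key] = ""
            cfg_map[i.value_key] = ""

    # resolved output paths (missing optional references resolve to empty)
    resolved: dict[str, str] = {}
    for o in d.output_files:
        path_map = {}
        for i in d.inputs:
            if i.value_key is None or i.value_key not in o.path_template:
                continue
            if i.id in effective:
                path_map[i.value_key] = _path_value(
                    i, effective[i.id], o.path_template_stripped_extensions)
            else:
                path_map[i.value_key] = ""
        resolved[o.id] = _substitute(o.path_template, path_map)

    for o in d.output_files:
        if o.value_key is None:
            continue
        path_text = quote(resolved[o.id])
        if o.command_line_flag is not None:
            token = (o.command_line_flag + o.command_line_flag_separator
                     + path_text)
        else:
            token = path_text
        cmd_map[o.value_key] = token
        cfg_map[o.value_key] = resolved[o.id]

    command = _normalize_whitespace(_substitute(d.command_line, cmd_map))

    declared_keys = [i.value_key for i in d.inputs if i.value_key] + \
        [o.value_key for o in d.output_files if o.value_key]
    for key in declared_keys:
        if key in command:
            raise UnresolvedValueKeyError(key)

    config_files: list[tuple[str, str]] = []
    for o in d.output_files:
        if o.file_template is None:
            continue
        content = "\n".join(_substitute(line, cfg_map)
                            for line in o.file_template) + "\n"
        config_files.append((resolved[o.id], content))

    expected = [ExpectedOutput(id=o.id, path=resolved[o.id],
                               optional=o.optional, list=o.list)
                for o in d.output_files]
    return CommandLinePlan(command=command, config_files=config_files,
                           expected_outputs=expected)
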