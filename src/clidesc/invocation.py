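"""Invocation schemas: generation from a descriptor and invocation validation.

An *invocation* is a plain JSON object mapping input identifiers to values
(String/File -> text, Number -> number, Flag -> boolean; list inputs map to
non-empty arrays of such values).  The *invocation schema* is an
application-specific JSON-schema document (draft-04 constructs only) that
accepts exactly the valid invocations of one descriptor: declared properties
with their types and restrictions, required inputs, and the group/dependency
constraints encoded with ``allOf``/``anyOf``/``not``.

A Flag assigned ``false`` contributes nothing to the command line, so for all
group and dependency semantics it is treated as absent.
"""

from __future__ import annotations

import json
from dataclasses import replace
from typing import Any

import jsonschema

from .errors import Violation
from .model import Descriptor, Input
from .validation import assert_valid

#: an invocation is a plain mapping from input id to value
Invocation = dict[str, Any]


def _base_type(i: Input) -> dict:
    if i.type == "Flag":
        return {"type": "boolean"}
    if i.type == "Number":
        t: dict[str, Any] = {"type": "integer" if i.integer else "number"}
        if i.minimum is not None:
            t["minimum"] = i.minimum
            if i.exclusive_minimum:
                t["exclusiveMinimum"] = True
        if i.maximum is not None:
            t["maximum"] = i.maximum
            if i.exclusive_maximum:
                t["exclusiveMaximum"] = True
    else:  # String, File
        t = {"type": "string"}
    if i.value_choices is not None:
        t["enum"] = list(i.value_choices)
    return t


def _property(i: Input) -> dict:
    if i.list:
        return {"type": "array", "items": _base_type(i), "minItems": 1}
    return _base_type(i)


def _contributes(i: Input) -> dict:
    """Schema satisfied iff the input is present and contributes a value
    (for Flags: present and true)."""
    if i.type == "Flag":
        return {"required": [i.id], "properties": {i.id: {"enum": [True]}}}
    return {"required": [i.id]}


def _absent(i: Input) -> dict:
    return {"not": _contributes(i)}


def generate_invocation_schema(d: Descriptor) -> dict:
    """Generate the invocation schema for a valid descriptor.

    Pure and deterministic: equal descriptors yield byte-identical schema
    text.  Raises :class:`~clidesc.errors.InvalidDescriptorError` if the
    descriptor fails semantic validation.
    """
    assert_valid(d)
    by_id = {i.id: i for i in d.inputs}
    schema: dict[str, Any] = {
        "$schema": "http://json-schema.org/draft-04/schema#",
        "title": f"{d.name}.invocation",
        "description": f"Invocation schema for {d.name}.",
        "type": "object",
        "additionalProperties": False,
        "properties": {i.id: _property(i) for i in d.inputs},
    }
    required = [i.id for i in d.inputs if not i.optional]
    if required:
        schema["required"] = required

    constraints: list[dict] = []
    for i in d.inputs:
        if i.requires_inputs:
            needed = [_contributes(by_id[r]) for r in i.requires_inputs]
            constraints.append(
                {"anyOf": [_absent(i), {"allOf": needed}]})
        if i.disables_inputs:
            blocked = [_absent(by_id[r]) for r in i.disables_inputs]
            constraints.append(
                {"anyOf": [_absent(i), {"allOf": blocked}]})
    for g in d.groups:
        members = [by_id[m] for m in g.members]
        if g.mutually_exclusive:
            for ai in range(len(members)):
                for bi in range(ai + 1, len(members)):
                    constraints.append(
                        {"not": {"allOf": [_contributes(members[ai]),
                                           _contributes(members[bi])]}})
        if g.one_is_required:
            constraints.append(
                {"anyOf": [_contributes(m) for m in members]})
        if g.all_or_none:
            constraints.append(
                {"anyOf": [{"allOf": [_contributes(m) for m in members]},
                           {"allOf": [_absent(m) for m in members]}]})
    if constraints:
        schema["allOf"] = constraints
    return schema


def invocation_schema_text(schema: dict) -> str:
    """Deterministic JSON text for an invocation schema."""
    return json.dumps(schema, indent=2) + "\n"


def _classify(err: jsonschema.exceptions.ValidationError,
              declared: set[str], inv: Invocation) -> Violation:
    path = "/" + "/".join(str(p) for p in err.absolute_path)
    if err.validator == "required" and not err.absolute_path:
        missing = [k for k in err.validator_value if k not in inv]
        return Violation("I1", err.message, tuple(missing) or (path,))
    if err.validator == "additionalProperties":
        extras = sorted(set(inv) - declared)
        return Violation("I3", "undeclared input(s): "
                         + ", ".join(map(repr, extras)), tuple(extras))
    if err.validator in ("anyOf", "allOf", "not", "oneOf"):
        return Violation("I4", "group or dependency constraint violated: "
                         + err.message, (path or "/",))
    return Violation("I2", err.message, (path or "/",))


def validate_invocation(d: Descriptor, inv: Invocation) -> list[Violation]:
    """Validate an invocation against the descriptor's invocation schema.

    Uses the schema embedded in the descriptor when present, otherwise
    generates one transparently.  Returns an empty list iff the invocation
    is acceptable.
    """
    schema = d.invocation_schema
    if schema is None:
        schema = generate_invocation_schema(d)
    validator = jsonschema.Draft4Validator(schema)
    declared = {i.id for i in d.inputs}
    out = [_classify(e, declared, inv)
           for e in validator.iter_errors(inv)]
    return sorted(out, key=lambda v: (v.rule_code, v.subjects))


def invocation_is_valid(d: Descriptor, inv: Invocation) -> bool:
    return not validate_invocation(d, inv)


def attach_invocation_schema(d: Descriptor) -> Descriptor:
    """Return a copy of ``d`` with its invocation schema embedded.

    Idempotent: attaching twice yields an identical descriptor.
    """
    schema = generate_invocation_schema(
        replace(d, invocation_schema=None))
    return replace(d, invocation_schema=schema)


def embedded_schema_is_current(d: Descriptor) -> bool:
    """True iff the embedded invocation schema (if any) matches what
    :func:`generate_invocation_schema` would produce now."""
    if d.invocation_schema is None:
        return True
    return d.invocation_schema == generate_invocation_schema(
        replace(d, invocation_schema=None))
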