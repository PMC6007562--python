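"""Descriptor data model and its canonical JSON dialect.

A *descriptor* is a JSON document that fully describes a command-line
application: an sh-syntax command template containing bracketed *value keys*,
the typed inputs and output files those keys stand for, optional group and
dependency constraints among inputs, and an optional container image plus
suggested resources.

The canonical dialect uses kebab-case property names (``command-line``,
``value-key``, ...).  Parsing fills defaults (``optional`` false, ``list``
false, flag separator a single space); serialization omits properties whose
value equals the default, so ``parse(serialize(d)) == d`` and serialization
is byte-deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

import jsonschema

from .errors import DescriptorParseError, SchemaError, SchemaViolation
from .schema import BASE_SCHEMA, SCHEMA_VERSION

DEFAULT_SEPARATOR = " "

#: value keys are bracketed tokens; any non-empty text is allowed inside.
VALUE_KEY_EXAMPLE = "[X]"


@dataclass
class Input:
    """One command-line parameter of type String, Number, Flag, or File."""

    id: str
    name: str
    type: str
    description: str | None = None
    value_key: str | None = None
    optional: bool = False
    list: bool = False
    command_line_flag: str | None = None
    command_line_flag_separator: str = DEFAULT_SEPARATOR
    default_value: Any = None
    value_choices: list | None = None
    minimum: float | None = None
    maximum: float | None = None
    exclusive_minimum: bool = False
    exclusive_maximum: bool = False
    integer: bool = False
    requires_inputs: list[str] | None = None
    disables_inputs: list[str] | None = None


@dataclass
class Group:
    """A named set of inputs carrying presentation and constraint semantics."""

    id: str
    name: str
    members: list[str]
    mutually_exclusive: bool = False
    one_is_required: bool = False
    all_or_none: bool = False


@dataclass
class OutputFile:
    """An output file/directory, or a configuration file when
    ``file_template`` is present."""

    id: str
    name: str
    path_template: str
    description: str | None = None
    path_template_stripped_extensions: list[str] | None = None
    optional: bool = False
    list: bool = False
    value_key: str | None = None
    command_line_flag: str | None = None
    command_line_flag_separator: str = DEFAULT_SEPARATOR
    file_template: list[str] | None = None

    @property
    def is_config_file(self) -> bool:
        return self.file_template is not None


@dataclass
class ContainerImage:
    """Container image reference: docker/singularity registry name or a
    rootfs URL."""

    type: str
    image: str
    index: str | None = None
    working_directory: str | None = None
    container_hash: str | None = None
    entry_point: bool = False


@dataclass
class SuggestedResources:
    """Advisory resource estimates; never enforced at execution time."""

    cpu_cores: int | None = None
    nodes: int | None = None
    ram_gb: float | None = None
    disk_gb: float | None = None
    walltime_estimate_s: float | None = None


@dataclass
class Descriptor:
    """A complete application description."""

    name: str
    description: str
    tool_version: str
    command_line: str
    schema_version: str = SCHEMA_VERSION
    inputs: list[Input] = field(default_factory=list)
    output_files: list[OutputFile] = field(default_factory=list)
    groups: list[Group] = field(default_factory=list)
    container: ContainerImage | None = None
    suggested_resources: SuggestedResources | None = None
    custom: dict | None = None
    invocation_schema: dict | None = None
    #: unknown top-level keys seen in lenient parsing; not part of identity
    warnings: list[str] = field(default_factory=list, compare=False)

    def input_by_id(self, input_id: str) -> Input:
        for i in self.inputs:
            if i.id == input_id:
                return i
        raise KeyError(input_id)

    def output_by_id(self, output_id: str) -> OutputFile:
        for o in self.output_files:
            if o.id == output_id:
                return o
        raise KeyError(output_id)


# ---------------------------------------------------------------------------
# serialization

def _input_to_json(i: Input) -> dict:
    d: dict[str, Any] = {"id": i.id, "name": i.name, "type": i.type}
    if i.description is not None:
        d["description"] = i.description
    if i.value_key is not None:
        d["value-key"] = i.value_key
    if i.optional:
        d["optional"] = True
    if i.list:
        d["list"] = True
    if i.command_line_flag is not None:
        d["command-line-flag"] = i.command_line_flag
    if i.command_line_flag_separator != DEFAULT_SEPARATOR:
        d["command-line-flag-separator"] = i.command_line_flag_separator
    if i.default_value is not None:
        d["default-value"] = i.default_value
    if i.value_choices is not None:
        d["value-choices"] = i.value_choices
    if i.minimum is not None:
        d["minimum"] = i.minimum
    if i.maximum is not None:
        d["maximum"] = i.maximum
    if i.exclusive_minimum:
        d["exclusive-minimum"] = True
    if i.exclusive_maximum:
        d["exclusive-maximum"] = True
    if i.integer:
        d["integer"] = True
    if i.requires_inputs is not None:
        d["requires-inputs"] = i.requires_inputs
    if i.disables_inputs is not None:
        d["disables-inputs"] = i.disables_inputs
    return d


def _output_to_json(o: OutputFile) -> dict:
    d: dict[str, Any] = {"id": o.id, "name": o.name,
                         "path-template": o.path_template}
    if o.description is not None:
        d["description"] = o.description
    if o.path_template_stripped_extensions is not None:
        d["path-template-stripped-extensions"] = \
            o.path_template_stripped_extensions
    if o.optional:
        d["optional"] = True
    if o.list:
        d["list"] = True
    if o.value_key is not None:
        d["value-key"] = o.value_key
    if o.command_line_flag is not None:
        d["command-line-flag"] = o.command_line_flag
    if o.command_line_flag_separator != DEFAULT_SEPARATOR:
        d["command-line-flag-separator"] = o.command_line_flag_separator
    if o.file_template is not None:
        d["file-template"] = o.file_template
    return d


def _group_to_json(g: Group) -> dict:
    d: dict[str, Any] = {"id": g.id, "name": g.name, "members": g.members}
    if g.mutually_exclusive:
        d["mutually-exclusive"] = True
    if g.one_is_required:
        d["one-is-required"] = True
    if g.all_or_none:
        d["all-or-none"] = True
    return d


def _container_to_json(c: ContainerImage) -> dict:
    d: dict[str, Any] = {"type": c.type, "image": c.image}
    if c.index is not None:
        d["index"] = c.index
    if c.working_directory is not None:
        d["working-directory"] = c.working_directory
    if c.container_hash is not None:
        d["container-hash"] = c.container_hash
    if c.entry_point:
        d["entry-point"] = True
    return d


def _resources_to_json(r: SuggestedResources) -> dict:
    d: dict[str, Any] = {}
    if r.cpu_cores is not None:
        d["cpu-cores"] = r.cpu_cores
    if r.nodes is not None:
        d["nodes"] = r.nodes
    if r.ram_gb is not None:
        d["ram-gb"] = r.ram_gb
    if r.disk_gb is not None:
        d["disk-gb"] = r.disk_gb
    if r.walltime_estimate_s is not None:
        d["walltime-estimate-s"] = r.walltime_estimate_s
    return d


def descriptor_to_json(d: Descriptor) -> dict:
    """The descriptor as a canonical-dialect JSON object (Python dict)."""
    doc: dict[str, Any] = {
        "name": d.name,
        "description": d.description,
        "tool-version": d.tool_version,
        "schema-version": d.schema_version,
        "command-line": d.command_line,
        "inputs": [_input_to_json(i) for i in d.inputs],
    }
    if d.output_files:
        doc["output-files"] = [_output_to_json(o) for o in d.output_files]
    if d.groups:
        doc["groups"] = [_group_to_json(g) for g in d.groups]
    if d.container is not None:
        doc["container-image"] = _container_to_json(d.container)
    if d.suggested_resources is not None:
        doc["suggested-resources"] = _resources_to_json(d.suggested_resources)
    if d.custom is not None:
        doc["custom"] = d.custom
    if d.invocation_schema is not None:
        doc["invocation-schema"] = d.invocation_schema
    return doc


def serialize_descriptor(d: Descriptor) -> str:
    """Serialize to deterministic canonical JSON text (stable key order,
    default-valued properties omitted, trailing newline)."""
    return json.dumps(descriptor_to_json(d), indent=2) + "\n"


# ---------------------------------------------------------------------------
# parsing

def _input_from_json(j: dict) -> Input:
    return Input(
        id=j["id"], name=j["name"], type=j["type"],
        description=j.get("description"),
        value_key=j.get("value-key"),
        optional=j.get("optional", False),
        list=j.get("list", False),
        command_line_flag=j.get("command-line-flag"),
        command_line_flag_separator=j.get("command-line-flag-separator",
                                          DEFAULT_SEPARATOR),
        default_value=j.get("default-value"),
        value_choices=j.get("value-choices"),
        minimum=j.get("minimum"),
        maximum=j.get("maximum"),
        exclusive_minimum=j.get("exclusive-minimum", False),
        exclusive_maximum=j.get("exclusive-maximum", False),
        integer=j.get("integer", False),
        requires_inputs=j.get("requires-inputs"),
        disables_inputs=j.get("disables-inputs"),
    )


def _output_from_json(j: dict) -> OutputFile:
    return OutputFile(
        id=j["id"], name=j["name"], path_template=j["path-template"],
        description=j.get("description"),
        path_template_stripped_extensions=j.get(
            "path-template-stripped-extensions"),
        optional=j.get("optional", False),
        list=j.get("list", False),
        value_key=j.get("value-key"),
        command_line_flag=j.get("command-line-flag"),
        command_line_flag_separator=j.get("command-line-flag-separator",
                                          DEFAULT_SEPARATOR),
        file_template=j.get("file-template"),
    )


def _group_from_json(j: dict) -> Group:
    return Group(
        id=j["id"], name=j["name"], members=j["members"],
        mutually_exclusive=j.get("mutually-exclusive", False),
        one_is_required=j.get("one-is-required", False),
        all_or_none=j.get("all-or-none", False),
    )


def _container_from_json(j: dict) -> ContainerImage:
    return ContainerImage(
        type=j["type"], image=j["image"],
        index=j.get("index"),
        working_directory=j.get("working-directory"),
        container_hash=j.get("container-hash"),
        entry_point=j.get("entry-point", False),
    )


def _resources_from_json(j: dict) -> SuggestedResources:
    return SuggestedResources(
        cpu_cores=j.get("cpu-cores"), nodes=j.get("nodes"),
        ram_gb=j.get("ram-gb"), disk_gb=j.get("disk-gb"),
        walltime_estimate_s=j.get("walltime-estimate-s"),
    )


def _loads(document: str):
    try:
        return json.loads(document)
    except json.JSONDecodeError as e:
        raise DescriptorParseError(
            f"malformed JSON at line {e.lineno}, column {e.colno}: {e.msg}",
            line=e.lineno, column=e.colno) from e


def _violations(obj) -> list[SchemaViolation]:
    validator = jsonschema.Draft4Validator(BASE_SCHEMA)
    out = []
    for err in sorted(validator.iter_errors(obj),
                      key=lambda e: (list(map(str, e.absolute_path)),
                                     e.message)):
        path = "/" + "/".join(str(p) for p in err.absolute_path)
        out.append(SchemaViolation(path=path, message=err.message))
    return out


def conforms_to_base_schema(document: str) -> list[SchemaViolation]:
    """Check a JSON text against the base descriptor schema.

    Returns an empty list iff the document conforms; violations are values,
    not exceptions, each locating the offending property by document path.
    """
    return _violations(_loads(document))


def parse_descriptor(document: str, strict: bool = True) -> Descriptor:
    """Parse canonical-dialect JSON text into a :class:`Descriptor`.

    Defaults are filled in (``optional`` false, ``list`` false, flag
    separator a single space).  In strict mode (default) any unknown
    top-level property outside ``custom`` is a schema error; with
    ``strict=False`` unknown top-level keys are dropped and reported on
    ``Descriptor.warnings``.
    """
    obj = _loads(document)
    warnings: list[str] = []
    if not strict and isinstance(obj, dict):
        known = set(BASE_SCHEMA["properties"])
        for key in [k for k in obj if k not in known]:
            warnings.append(f"unknown top-level property {key!r} ignored")
            obj.pop(key)
    violations = _violations(obj)
    if violations:
        raise SchemaError(violations)
    d = Descriptor(
        name=obj["name"],
        description=obj["description"],
        tool_version=obj["tool-version"],
        schema_version=obj["schema-version"],
        command_line=obj["command-line"],
        inputs=[_input_from_json(i) for i in obj["inputs"]],
        output_files=[_output_from_json(o)
                      for o in obj.get("output-files", [])],
        groups=[_group_from_json(g) for g in obj.get("groups", [])],
        container=(_container_from_json(obj["container-image"])
                   if "container-image" in obj else None),
        suggested_resources=(_resources_from_json(obj["suggested-resources"])
                             if "suggested-resources" in obj else None),
        custom=obj.get("custom"),
        invocation_schema=obj.get("invocation-schema"),
    )
    d.warnings = warnings
    return d


def load_descriptor(path, strict: bool = True) -> Descriptor:
    """Read and parse a descriptor file (UTF-8 JSON)."""
    with open(path, encoding="utf-8") as fh:
        return parse_descriptor(fh.read(), strict=strict)


def save_descriptor(d: Descriptor, path) -> None:
    """Write a descriptor to ``path`` in the canonical dialect."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(serialize_descriptor(d))
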