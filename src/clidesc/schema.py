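"""The base descriptor schema (JSON-schema draft-04).

The schema covers everything a generic JSON validator can express: property
types, required properties, enumerations, and the strict top level (unknown
keys are only allowed inside the free-form ``custom`` object).  Cross-field
rules — unique identifiers, value-key discipline, group consistency — live in
:mod:`clidesc.validation`.
"""

from __future__ import annotations

import copy
import json

IDENTIFIER_PATTERN = "^[0-9A-Za-z_]+$"

SCHEMA_VERSION = "0.5.5"

_INPUT_SCHEMA = {
    "type": "object",
    "properties": {
        "id": {"type": "string", "pattern": IDENTIFIER_PATTERN},
        "name": {"type": "string", "minLength": 1},
        "type": {"type": "string",
                 "enum": ["String", "Number", "Flag", "File"]},
        "description": {"type": "string"},
        "value-key": {"type": "string", "minLength": 1},
        "optional": {"type": "boolean"},
        "list": {"type": "boolean"},
        "command-line-flag": {"type": "string"},
        "command-line-flag-separator": {"type": "string"},
        "default-value": {},
        "value-choices": {"type": "array",
                          "items": {"type": ["string", "number"]}},
        "minimum": {"type": "number"},
        "maximum": {"type": "number"},
        "exclusive-minimum": {"type": "boolean"},
        "exclusive-maximum": {"type": "boolean"},
        "integer": {"type": "boolean"},
        "requires-inputs": {"type": "array",
                            "items": {"type": "string"}},
        "disables-inputs": {"type": "array",
                            "items": {"type": "string"}},
    },
    "required": ["id", "name", "type"],
    "additionalProperties": False,
}

_GROUP_SCHEMA = {
    "type": "object",
    "properties": {
        "id": {"type": "string", "pattern": IDENTIFIER_PATTERN},
        "name": {"type": "string", "minLength": 1},
        "members": {"type": "array", "minItems": 1,
                    "items": {"type": "string"}},
        "mutually-exclusive": {"type": "boolean"},
        "one-is-required": {"type": "boolean"},
        "all-or-none": {"type": "boolean"},
    },
    "required": ["id", "name", "members"],
    "additionalProperties": False,
}

_OUTPUT_SCHEMA = {
    "type": "object",
    "properties": {
        "id": {"type": "string", "pattern": IDENTIFIER_PATTERN},
        "name": {"type": "string", "minLength": 1},
        "description": {"type": "string"},
        "path-template": {"type": "string", "minLength": 1},
        "path-template-stripped-extensions": {
            "type": "array", "items": {"type": "string"}},
        "optional": {"type": "boolean"},
        "list": {"type": "boolean"},
        "value-key": {"type": "string", "minLength": 1},
        "command-line-flag": {"type": "string"},
        "command-line-flag-separator": {"type": "string"},
        "file-template": {"type": "array", "minItems": 1,
                          "items": {"type": "string"}},
    },
    "required": ["id", "name", "path-template"],
    "additionalProperties": False,
}

_CONTAINER_SCHEMA = {
    "type": "object",
    "properties": {
        "type": {"type": "string",
                 "enum": ["docker", "singularity", "rootfs"]},
        "image": {"type": "string", "minLength": 1},
        "index": {"type": "string"},
        "working-directory": {"type": "string"},
        "container-hash": {"type": "string"},
        "entry-point": {"type": "boolean"},
    },
    "required": ["type", "image"],
    "additionalProperties": False,
}

_RESOURCES_SCHEMA = {
    "type": "object",
    "properties": {
        "cpu-cores": {"type": "integer", "minimum": 1},
        "nodes": {"type": "integer", "minimum": 1},
        "ram-gb": {"type": "number", "exclusiveMinimum": True, "minimum": 0},
        "disk-gb": {"type": "number", "exclusiveMinimum": True, "minimum": 0},
        "walltime-estimate-s": {"type": "number",
                                "exclusiveMinimum": True, "minimum": 0},
    },
    "additionalProperties": False,
}

BASE_SCHEMA = {
    "$schema": "http://json-schema.org/draft-04/schema#",
    "title": "command-line tool descriptor",
    "type": "object",
    "properties": {
        "name": {"type": "string", "minLength": 1},
        "description": {"type": "string", "minLength": 1},
        "tool-version": {"type": "string", "minLength": 1},
        "schema-version": {"type": "string", "enum": [SCHEMA_VERSION]},
        "command-line": {"type": "string", "minLength": 1},
        "inputs": {"type": "array", "items": _INPUT_SCHEMA},
        "output-files": {"type": "array", "items": _OUTPUT_SCHEMA},
        "groups": {"type": "array", "items": _GROUP_SCHEMA},
        "container-image": _CONTAINER_SCHEMA,
        "suggested-resources": _RESOURCES_SCHEMA,
        "custom": {"type": "object"},
        "invocation-schema": {"type": "object"},
    },
    "required": ["name", "description", "tool-version", "schema-version",
                 "command-line", "inputs"],
    "additionalProperties": False,
}


def get_base_schema() -> dict:
    """Return a deep copy of the base descriptor schema."""
    return copy.deepcopy(BASE_SCHEMA)


def base_schema_text() -> str:
    """The base schema as deterministic, pretty-printed JSON text."""
    return json.dumps(BASE_SCHEMA, indent=2, sort_keys=False) + "\n"
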