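# Methods

This note records the precise semantics implemented by `clidesc`: the
descriptor dialect, the semantic rule catalogue, the encoding of
constraints into draft-04 JSON schema, the command-construction rules,
the execution model, and known limitations.

## Descriptor dialect

A descriptor is a JSON object with kebab-case keys. Mandatory
properties: `name`, `description`, `tool-version`, `schema-version`
(fixed at `"0.5.5"`), `command-line`, and `inputs`. Optional:
`output-files`, `groups`, `container-image`, `suggested-resources`,
`invocation-schema` (an embedded, pre-generated invocation schema),
`custom` (free-form), and `doi`/`url`-style metadata. The top level is
strict (`additionalProperties: false` in the base schema) except inside
`custom`, which passes through verbatim — including colon-namespaced
keys. `parse_descriptor(text, strict=False)` tolerates unknown top-level
keys by moving them into the parsed object's `warnings` instead of
raising.

Inputs carry: `id` (matching `^[0-9A-Za-z_]+$`), `name`, `type`
(`String` | `File` | `Number` | `Flag`), `value-key`, `optional`,
`list`, `command-line-flag`, `command-line-flag-separator` (default one
space), `default-value`, `value-choices`, numeric bounds (`minimum`,
`maximum`, `exclusive-minimum`, `exclusive-maximum`, `integer`), and
dependency lists `requires-inputs` / `disables-inputs`. Groups carry
`members` plus the three constraint booleans `mutually-exclusive`,
`one-is-required`, `all-or-none`. Output files carry `path-template`
with optional `path-template-stripped-extensions`, `list` (glob
patterns), `optional`, and — for generated configuration files —
`file-template` plus their own `value-key`. Container images are
`docker`, `singularity`, or `rootfs`, with optional `index`,
`working-directory`, and `entry-point`.

Serialization is deterministic: fixed key order, defaults omitted,
two-space indentation, trailing newline. `parse(serialize(d)) == d`
holds for every descriptor the generator can produce (verified over a
200-descriptor corpus).

## Semantic rule catalogue

Structural conformance is checked against the base JSON schema; the
following cross-reference rules are then enforced, each reported with a
stable code, a message, and the subject ids involved. Codes `V1`–`V18`
are reserved; `V17`/`V18` are currently unassigned.

| Code | Rule |
|------|------|
| V1   | Two inputs share a value key but have no group in common. |
| V2   | An input id collides with an output id (one shared namespace). |
| V3   | A value key appears on an input or output but occurs neither in the command line nor in any file template. (A configuration-file output's own value key is exempt: it is consumed when the file path is substituted.) |
| V4   | Two inputs share a value key and have a common group, but that group is not mutually exclusive. |
| V5   | One value key is a substring of another (nesting would make substitution order-dependent). |
| V6   | A group member id does not refer to a declared input. |
| V7a  | A mutually-exclusive group contains a non-optional member. |
| V7b  | A one-is-required group with all members impossible to supply, or an ill-formed constraint combination on the group. |
| V7c  | An all-or-none group containing a non-optional member. |
| V8   | A `Flag` input is non-optional (a flag that must be present is not a flag). |
| V9   | An input both requires and disables the same input. |
| V10  | A required input requires or is required by an impossible configuration (dependency cycle among non-optional semantics). |
| V11  | Duplicate ids among inputs, groups, or outputs. |
| V12  | A `Flag` input lacks a `command-line-flag`. |
| V13  | `value-choices` or `default-value` inconsistent with the declared type or bounds. |
| V14  | Numeric bounds are contradictory (e.g. minimum exceeds maximum). |
| V15  | A `requires-inputs`/`disables-inputs` entry names an unknown input. |
| V16  | A numeric restriction (`integer`, bounds) or choice list attached to a non-applicable type. |

The V1/V4 pair implements a deliberate reading: sharing a value key is
legal **iff** the sharers belong to a common mutually-exclusive group
(so at most one of them can ever bind the key). No common group at all
is V1; a common but non-exclusive group is V4. The two rules are
disjoint by construction, so each mis-authored descriptor in the test
fixture suite triggers exactly one code.

Violations are sorted by code then subjects, so validator output is
deterministic. Adding inputs to a broken descriptor never removes a
violation (checked by a monotonicity property test).

## Invocation schemas

An invocation is a JSON object mapping input ids to values. The
generated schema is plain draft-04:

- `properties` per input: `{"type": "string"}`, `{"type": "number"}` (or
  `"integer"`), `{"type": "boolean"}`, with `enum` for `value-choices`
  and `minimum`/`maximum`/`exclusiveMinimum`/`exclusiveMaximum` for
  bounds. List inputs become `{"type": "array", "items": ..., "minItems": 1}`.
- `required` lists the non-optional inputs; `additionalProperties` is
  `false`.
- Constraints go into `allOf`. With `contributes(i)` defined as
  `{"required": [id]}` — or, for a `Flag`, additionally
  `{"properties": {id: {"enum": [true]}}}` so a present-but-false flag
  counts as absent — and `absent(i) = {"not": contributes(i)}`:
  - `requires-inputs`: `anyOf[absent(A), allOf(contributes(deps)...)]`
  - `disables-inputs`: `anyOf[absent(A), allOf(absent(deps)...)]`
  - mutually-exclusive: pairwise `{"not": {"allOf": [contributes, contributes]}}`
  - one-is-required: `anyOf` over members' `contributes`
  - all-or-none: `anyOf` of all-present and all-absent.

Correctness is established against a brute-force oracle
(`tests/invocation_oracle.py`): an independent, direct interpreter of
the rules above, checked for agreement with the schema on every member
of a deterministic enumeration of candidate invocations — including
wrong types, out-of-range and non-choice values, empty lists, absent
required inputs, false flags, and an undeclared extra key. Agreement is
exact over >10⁴ enumerated cases across 50 random descriptors.

Descriptors may embed a pre-generated schema under `invocation-schema`;
validation then honors the embedded schema verbatim (so a descriptor is
self-contained for third-party validators), and
`embedded_schema_is_current` reports whether it matches what would be
regenerated.

## Command construction

`build_plan(descriptor, invocation)` validates both arguments, applies
default values, and renders one token per input:

- `Flag`: the flag text if true, the empty string if false/absent.
- Valued inputs: `flag + separator + value`; lists are space-joined with
  the flag emitted once in front.
- Values are formatted deterministically: integral numbers without a
  decimal point (`2.0` → `2`), other floats in shortest round-trip form
  (`repr`), booleans as `true`/`false`.
- A value is single-quoted iff it contains any character outside
  `[A-Za-z0-9._/=+:,@-]`, with embedded single quotes escaped as
  `'\''`; quoted tokens survive an `sh` round trip byte-exactly
  (property-tested via `printf`).

All value keys are replaced in a **single simultaneous pass** (one
regex alternation, longest key first). Because V5 forbids nested keys,
the result is independent of declaration order. After substitution,
runs of spaces outside single-quoted spans are collapsed — so inactive
optional inputs leave no double spaces — but configuration-file
contents are never re-whitespaced.

Output paths are resolved with the same substitution map except that
*plain* value text is used (no flags, no quoting): a configuration file
template line `n = [NUMBER_INPUT]` yields `n = 0.3`, not `n = -n=0.3`.
Extension stripping removes the first matching suffix in the
author-listed order, once.

## Execution

`launch` writes generated configuration files into the task directory,
runs the command via `sh -c` with stdout/stderr captured to
`.task.stdout`/`.task.stderr`, then resolves each declared output:
scalar paths by existence, list paths by glob. Missing non-optional
outputs are reported (not raised); `record.success` means exit status 0
and nothing mandatory missing. `dry_run` builds everything and touches
nothing.

Container wrapping is byte-stable:

```
docker run --rm -v H:C -w WD IMAGE sh -c 'CMD'
singularity exec -B H:C --pwd WD IMAGE sh -c 'CMD'
```

with one `-v`/`-B` pair per mount, the descriptor's
`working-directory` taking precedence over the task directory, the
`index` prefixed to the image name, and `entry-point: true` appending
the command as bare arguments instead of `sh -c`. `rootfs` images are
accepted as metadata but refused at launch with a dedicated error.
Launching a containerized descriptor without the runtime on `PATH`
raises an environment error unless `force_no_container` is passed
(which warns and runs bare).

`random_invocation` rejection-samples against the invocation schema
(budget 2000 attempts, schema and validator built once); unbounded
numbers are drawn from ±100. `generate_random_descriptor` produces
always-valid descriptors spanning all four types, lists, flags with
separators, bounds, choices, the three group constraints, dependencies,
and all output styles — realistic enough to exercise every construction
path, but it does not generate embedded invocation schemas, containers,
or multi-group overlap, and at most one dependency edge per descriptor.

## Limitations

- Only the current schema version is read; no migration of older
  dialects.
- `rootfs` containers and container-image hash enforcement (a mismatch
  only warns) are not executable.
- The BIDS importer covers the standard participant/group contract, not
  app-specific extra flags.
- Random-invocation sampling is rejection-based and can exhaust its
  budget on adversarially constrained (embedded-schema) descriptors;
  this is reported with a dedicated error rather than hanging.
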