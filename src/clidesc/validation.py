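"""Semantic validation of descriptors.

These are the cross-field rules a generic JSON validator cannot express.
Each rule has a stable code:

V1   value keys are unique among inputs (sharing with no common group)
V2   input and output identifiers are unique (one shared namespace)
V3   input/output value keys all appear in the command line or a file template
V4   inputs sharing a value key must sit in a mutually-exclusive group
V5   value keys must not be contained within each other
V6   output path templates are unique
V7a  Flag inputs must have a command-line flag
V7b  Flag inputs must be optional
V7c  Flag inputs must not be lists
V8   the default value of a restricted input must satisfy the restriction
V9   an input cannot both require and disable another input
V10  required (non-optional) inputs cannot require or disable others
V11  group members must exist and belong to at most one group
V12  mutually-exclusive group members must not require other members
V13  one-is-required groups must not contain required members
V14  all-or-none groups must not contain required members
V15  requires/disables lists must reference existing input ids
V16  restrictions must be consistent with the declared type

Sharing a value key is legal exactly when the sharing inputs belong to one
common group marked mutually-exclusive: V1 covers sharers with no common
group, V4 covers sharers whose common group is not exclusive.  Rules are
checked independently; one defect may trigger several rules.  A descriptor
is *valid* iff :func:`validate_semantics` returns an empty list.
"""

from __future__ import annotations

import re

from .errors import InvalidDescriptorError, Violation
from .model import Descriptor, Input

_CODE_RE = re.compile(r"^V(\d+)([a-z]?)$")


def _code_key(code: str):
    m = _CODE_RE.match(code)
    return (int(m.group(1)), m.group(2))


def _value_matches_type(value, inp: Input) -> bool:
    if inp.type == "Number":
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            return False
        return not (inp.integer and not isinstance(value, int))
    if inp.type == "Flag":
        return isinstance(value, bool)
    return isinstance(value, str)


def _within_bounds(value, inp: Input) -> bool:
    if not isinstance(value, (int, float)) or isinstance(value, bool):
        return True
    if inp.minimum is not None:
        if value < inp.minimum or (inp.exclusive_minimum
                                   and value == inp.minimum):
            return False
    if inp.maximum is not None:
        if value > inp.maximum or (inp.exclusive_maximum
                                   and value == inp.maximum):
            return False
    return True


def validate_semantics(d: Descriptor) -> list[Violation]:
    """Run the full semantic rule catalogue over a descriptor.

    Returns every violated rule with all offending subjects, deterministically
    ordered by rule code and then subjects.
    """
    v: list[Violation] = []
    inputs = d.inputs
    outputs = d.output_files
    groups = d.groups
    input_ids = [i.id for i in inputs]
    input_by_id = {i.id: i for i in inputs}

    # group membership index
    groups_of: dict[str, list] = {}
    for g in groups:
        for m in g.members:
            groups_of.setdefault(m, []).append(g)

    def common_groups(a: str, b: str):
        return [g for g in groups_of.get(a, []) if g in groups_of.get(b, [])]

    # --- V1 / V4: shared value keys among inputs ----------------------------
    by_key: dict[str, list[Input]] = {}
    for i in inputs:
        if i.value_key is not None:
            by_key.setdefault(i.value_key, []).append(i)
    for key, sharers in by_key.items():
        for ai in range(len(sharers)):
            for bi in range(ai + 1, len(sharers)):
                a, b = sharers[ai].id, sharers[bi].id
                common = common_groups(a, b)
                if not common:
                    v.append(Violation(
                        "V1", f"value key {key!r} is used by inputs "
                        f"{a!r} and {b!r}", (key, a, b)))
                elif not any(g.mutually_exclusive for g in common):
                    v.append(Violation(
                        "V4", f"inputs {a!r} and {b!r} share value key "
                        f"{key!r} without being mutually exclusive",
                        (key, a, b)))

    # --- V2: unique identifiers (inputs and outputs share one namespace) ----
    seen: dict[str, int] = {}
    for ident in input_ids + [o.id for o in outputs]:
        seen[ident] = seen.get(ident, 0) + 1
    for ident, n in seen.items():
        if n > 1:
            v.append(Violation(
                "V2", f"identifier {ident!r} is declared {n} times",
                (ident,)))

    # --- V3: value keys appear in the command line or a file template -------
    haystack = d.command_line
    for o in outputs:
        if o.file_template:
            haystack += "\n" + "\n".join(o.file_template)
    for i in inputs:
        if i.value_key is not None and i.value_key not in haystack:
            v.append(Violation(
                "V3", f"value key {i.value_key!r} of input {i.id!r} does "
                "not appear in the command line or any file template",
                (i.value_key, i.id)))
    for o in outputs:
        if o.is_config_file:
            continue  # config files may be read implicitly
        if o.value_key is not None and o.value_key not in haystack:
            v.append(Violation(
                "V3", f"value key {o.value_key!r} of output {o.id!r} does "
                "not appear in the command line or any file template",
                (o.value_key, o.id)))

    # --- V5: no value key contained in another ------------------------------
    keyed = [(i.value_key, i.id) for i in inputs if i.value_key is not None]
    keyed += [(o.value_key, o.id) for o in outputs if o.value_key is not None]
    for ka, ida in keyed:
        for kb, idb in keyed:
            if ka != kb and ka in kb:
                v.append(Violation(
                    "V5", f"value key {kb!r} ({idb!r}) contains value key "
                    f"{ka!r} ({ida!r})", (kb, ka)))

    # --- V6: unique output path templates -----------------------------------
    by_template: dict[str, list[str]] = {}
    for o in outputs:
        by_template.setdefault(o.path_template, []).append(o.id)
    for template, ids in by_template.items():
        if len(ids) > 1:
            v.append(Violation(
                "V6", f"outputs {', '.join(map(repr, ids))} share path "
                f"template {template!r}", tuple(ids)))

    # --- V7: Flag discipline -------------------------------------------------
    for i in inputs:
        if i.type != "Flag":
            continue
        if i.command_line_flag is None:
            v.append(Violation(
                "V7a", f"Flag input {i.id!r} has no command-line flag",
                (i.id,)))
        if not i.optional:
            v.append(Violation(
                "V7b", f"Flag input {i.id!r} must be optional", (i.id,)))
        if i.list:
            v.append(Violation(
                "V7c", f"Flag input {i.id!r} must not be a list", (i.id,)))

    # --- V8: defaults satisfy restrictions ----------------------------------
    for i in inputs:
        if i.default_value is None:
            continue
        values = i.default_value if isinstance(i.default_value, list) \
            else [i.default_value]
        if i.value_choices is not None:
            for val in values:
                if val not in i.value_choices:
                    v.append(Violation(
                        "V8", f"default value {val!r} of input {i.id!r} is "
                        "not among its value choices", (i.id,)))
        for val in values:
            if not _within_bounds(val, i):
                v.append(Violation(
                    "V8", f"default value {val!r} of input {i.id!r} is "
                    "outside its numeric range", (i.id,)))

    # --- V9 / V10 / V15: dependency discipline -------------------------------
    for i in inputs:
        reqs = i.requires_inputs or []
        disb = i.disables_inputs or []
        for both in sorted(set(reqs) & set(disb)):
            v.append(Violation(
                "V9", f"input {i.id!r} both requires and disables {both!r}",
                (i.id, both)))
        if not i.optional and (reqs or disb):
            v.append(Violation(
                "V10", f"required input {i.id!r} cannot require or disable "
                "other inputs", (i.id,)))
        for ref in reqs + disb:
            if ref not in input_by_id:
                v.append(Violation(
                    "V15", f"input {i.id!r} references unknown input "
                    f"{ref!r}", (i.id, ref)))

    # --- V11: group membership ------------------------------------------------
    membership_count: dict[str, int] = {}
    for g in groups:
        seen_members: set[str] = set()
        for m in g.members:
            if m not in input_by_id:
                v.append(Violation(
                    "V11", f"group {g.id!r} member {m!r} is not an input",
                    (g.id, m)))
                continue
            if m in seen_members:
                v.append(Violation(
                    "V11", f"group {g.id!r} lists member {m!r} twice",
                    (g.id, m)))
            seen_members.add(m)
            membership_count[m] = membership_count.get(m, 0) + 1
    for m, n in membership_count.items():
        if n > 1:
            v.append(Violation(
                "V11", f"input {m!r} appears in {n} groups", (m,)))

    # --- V12 / V13 / V14: group constraint discipline -------------------------
    for g in groups:
        members = [m for m in g.members if m in input_by_id]
        if g.mutually_exclusive:
            for m in members:
                reqs = input_by_id[m].requires_inputs or []
                for other in members:
                    if other != m and other in reqs:
                        v.append(Violation(
                            "V12", f"member {m!r} of mutually-exclusive "
                            f"group {g.id!r} requires member {other!r}",
                            (g.id, m, other)))
        if g.one_is_required:
            for m in members:
                if not input_by_id[m].optional:
                    v.append(Violation(
                        "V13", f"one-is-required group {g.id!r} has "
                        f"required member {m!r}", (g.id, m)))
        if g.all_or_none:
            for m in members:
                if not input_by_id[m].optional:
                    v.append(Violation(
                        "V14", f"all-or-none group {g.id!r} has required "
                        f"member {m!r}", (g.id, m)))

    # --- V16: restrictions consistent with type -------------------------------
    for i in inputs:
        if i.value_choices is not None:
            if i.type == "Flag":
                v.append(Violation(
                    "V16", f"Flag input {i.id!r} cannot have value choices",
                    (i.id,)))
            else:
                for choice in i.value_choices:
                    if not _value_matches_type(choice, i):
                        v.append(Violation(
                            "V16", f"value choice {choice!r} of input "
                            f"{i.id!r} does not match type {i.type}",
                            (i.id,)))
        if i.type != "Number" and (i.minimum is not None
                                   or i.maximum is not None):
            v.append(Violation(
                "V16", f"numeric bounds on non-Number input {i.id!r}",
                (i.id,)))
        if (i.minimum is not None and i.maximum is not None
                and i.minimum > i.maximum):
            v.append(Violation(
                "V16", f"input {i.id!r} has minimum > maximum", (i.id,)))

    return sorted(v, key=lambda x: (_code_key(x.rule_code), x.subjects))


def is_valid(d: Descriptor) -> bool:
    return not validate_semantics(d)


def assert_valid(d: Descriptor) -> None:
    """Raise :class:`InvalidDescriptorError` unless the descriptor is valid."""
    violations = validate_semantics(d)
    if violations:
        raise InvalidDescriptorError(violations)
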