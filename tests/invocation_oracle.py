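"""Independent brute-force interpreter of the invocation rules.

This oracle decides invocation validity directly from the descriptor's
declared types, restrictions, groups, and dependencies — it never looks at
a generated JSON schema — so it can cross-check schema-based decisions on
exhaustively enumerated small instances.

Semantics: an input "contributes a value" when it is assigned, except a
Flag assigned false, which contributes nothing.  List values must be
non-empty arrays of the element type.
"""

from __future__ import annotations

import itertools

#: sentinel meaning "input not assigned" in enumeration
ABSENT = object()


def _scalar_ok(i, v) -> bool:
    if i.type == "Flag":
        return isinstance(v, bool)
    if i.type == "Number":
        if isinstance(v, bool) or not isinstance(v, (int, float)):
            return False
        if i.integer and not isinstance(v, int):
            return False
        if i.minimum is not None and (
                v < i.minimum or (i.exclusive_minimum and v == i.minimum)):
            return False
        if i.maximum is not None and (
                v > i.maximum or (i.exclusive_maximum and v == i.maximum)):
            return False
    else:  # String, File
        if not isinstance(v, str):
            return False
    if i.value_choices is not None and v not in i.value_choices:
        return False
    return True


def _value_ok(i, v) -> bool:
    if i.list:
        return (isinstance(v, list) and len(v) > 0
                and all(_scalar_ok(i, x) for x in v))
    return _scalar_ok(i, v)


def _contributes(i, inv) -> bool:
    if i.id not in inv:
        return False
    if i.type == "Flag":
        return inv[i.id] is True
    return True


def oracle_accepts(d, inv: dict) -> bool:
    """Decide invocation validity by direct rule interpretation."""
    by_id = {i.id: i for i in d.inputs}
    if any(k not in by_id for k in inv):
        return False
    for i in d.inputs:
        if not i.optional and i.id not in inv:
            return False
    for k, v in inv.items():
        if not _value_ok(by_id[k], v):
            return False
    for i in d.inputs:
        if not _contributes(i, inv):
            continue
        for r in i.requires_inputs or []:
            if not _contributes(by_id[r], inv):
                return False
        for r in i.disables_inputs or []:
            if _contributes(by_id[r], inv):
                return False
    for g in d.groups:
        n = sum(_contributes(by_id[m], inv) for m in g.members)
        if g.mutually_exclusive and n > 1:
            return False
        if g.one_is_required and n == 0:
            return False
        if g.all_or_none and 0 < n < len(g.members):
            return False
    return True


def candidate_values(i) -> list:
    """Small deterministic value domain for one input, including absence
    and deliberately invalid values (wrong type, out of range, empty list)."""
    if i.type == "Flag":
        scalars = [True, False]
        bad_scalars = ["yes"]
    elif i.value_choices is not None:
        scalars = list(i.value_choices)[:2]
        bad_scalars = ["__not_a_choice__" if i.type != "Number" else -9999]
    elif i.type == "Number":
        lo = i.minimum if i.minimum is not None else -10
        hi = i.maximum if i.maximum is not None else 10
        mid = (lo + hi) / 2
        if i.integer:
            mid = int(mid)
        scalars = [mid]
        bad_scalars = ["not_a_number"]
        if i.minimum is not None:
            bad_scalars.append(lo - 1)
        if i.integer:
            bad_scalars.append(mid + 0.5)
    else:
        scalars = ["alpha.csv" if i.type == "String" else "f.dat"]
        bad_scalars = [7]
    values: list = [ABSENT]
    if i.list:
        values += [[s] for s in scalars[:2]]
        values.append(scalars[:1] + bad_scalars[:1])
        values.append([])
    else:
        values += scalars[:2] + bad_scalars[:2]
    return values


def enumerate_invocations(d, extra_key: bool = True):
    """Yield every combination of candidate values across the inputs.

    With ``extra_key`` one additional variant per combination carries an
    undeclared property (must always be rejected).
    """
    domains = [candidate_values(i) for i in d.inputs]
    ids = [i.id for i in d.inputs]
    for combo in itertools.product(*domains):
        inv = {k: v for k, v in zip(ids, combo) if v is not ABSENT}
        yield inv
        if extra_key:
            yield {**inv, "undeclared_extra": "x"}
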