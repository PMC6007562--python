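"""Per-rule validator fixture suite.

For every semantic rule code this module builds a minimal descriptor that
violates exactly that rule, together with the same descriptor with the
defect repaired.  Used by the validator tests and the acceptance checks.
"""

from __future__ import annotations

import copy

from clidesc import Descriptor, Group, Input, OutputFile

from conftest import make_minimal

# per-rule fixture suite: for every rule code, a minimal descriptor that
# violates exactly that rule, plus the same descriptor with the defect
# repaired.

def _base(**kw) -> Descriptor:
    d = make_minimal()
    for key, val in kw.items():
        setattr(d, key, val)
    return d


def _inp(id, key=None, **kw) -> Input:
    return Input(id=id, name=f"Input {id}", type=kw.pop("type", "String"),
                 value_key=key, **kw)


def _broken_and_repaired(code: str) -> tuple[Descriptor, Descriptor]:
    if code == "V1":
        broken = _base(command_line="tool [X]",
                       inputs=[_inp("a", "[X]", optional=True),
                               _inp("b", "[X]", optional=True)])
        repaired = copy.deepcopy(broken)
        repaired.inputs[1].value_key = "[Y]"
        repaired.command_line = "tool [X] [Y]"
    elif code == "V2":
        broken = _base(command_line="tool [X] [Y]",
                       inputs=[_inp("dup", "[X]"), _inp("dup", "[Y]")])
        repaired = copy.deepcopy(broken)
        repaired.inputs[1].id = "b"
    elif code == "V3":
        broken = _base(command_line="tool", inputs=[_inp("a", "[X]")])
        repaired = copy.deepcopy(broken)
        repaired.command_line = "tool [X]"
    elif code == "V4":
        broken = _base(
            command_line="tool [X]",
            inputs=[_inp("a", "[X]", optional=True),
                    _inp("b", "[X]", optional=True)],
            groups=[Group(id="g", name="G", members=["a", "b"])])
        repaired = copy.deepcopy(broken)
        repaired.groups[0].mutually_exclusive = True
    elif code == "V5":
        broken = _base(command_line="tool [A] [A]_TAIL",
                       inputs=[_inp("a", "[A]"), _inp("b", "[A]_TAIL")])
        repaired = copy.deepcopy(broken)
        repaired.inputs[1].value_key = "[B]"
        repaired.command_line = "tool [A] [B]"
    elif code == "V6":
        broken = _base(output_files=[
            OutputFile(id="o1", name="O1", path_template="out.txt"),
            OutputFile(id="o2", name="O2", path_template="out.txt")])
        repaired = copy.deepcopy(broken)
        repaired.output_files[1].path_template = "other.txt"
    elif code == "V7a":
        broken = _base(command_line="tool [F]",
                       inputs=[_inp("f", "[F]", type="Flag", optional=True)])
        repaired = copy.deepcopy(broken)
        repaired.inputs[0].command_line_flag = "-f"
    elif code == "V7b":
        broken = _base(command_line="tool [F]",
                       inputs=[_inp("f", "[F]", type="Flag",
                                    command_line_flag="-f", optional=False)])
        repaired = copy.deepcopy(broken)
        repaired.inputs[0].optional = True
    elif code == "V7c":
        broken = _base(command_line="tool [F]",
                       inputs=[_inp("f", "[F]", type="Flag",
                                    command_line_flag="-f", optional=True,
                                    list=True)])
        repaired = copy.deepcopy(broken)
        repaired.inputs[0].list = False
    elif code == "V8":
        broken = _base(command_line="tool [X]",
                       inputs=[_inp("a", "[X]", optional=True,
                                    value_choices=["u", "v"],
                                    default_value="w")])
        repaired = copy.deepcopy(broken)
        repaired.inputs[0].default_value = "u"
    elif code == "V9":
        broken = _base(command_line="tool [X] [Y]",
                       inputs=[_inp("a", "[X]", optional=True,
                                    requires_inputs=["b"],
                                    disables_inputs=["b"]),
                               _inp("b", "[Y]", optional=True)])
        repaired = copy.deepcopy(broken)
        repaired.inputs[0].disables_inputs = None
    elif code == "V10":
        broken = _base(command_line="tool [X] [Y]",
                       inputs=[_inp("a", "[X]", optional=False,
                                    requires_inputs=["b"]),
                               _inp("b", "[Y]", optional=True)])
        repaired = copy.deepcopy(broken)
        repaired.inputs[0].optional = True
    elif code == "V11":
        broken = _base(command_line="tool [X]",
                       inputs=[_inp("a", "[X]", optional=True)],
                       groups=[Group(id="g", name="G",
                                     members=["a", "ghost"])])
        repaired = copy.deepcopy(broken)
        repaired.groups[0].members = ["a"]
    elif code == "V12":
        broken = _base(
            command_line="tool [X] [Y]",
            inputs=[_inp("a", "[X]", optional=True, requires_inputs=["b"]),
                    _inp("b", "[Y]", optional=True)],
            groups=[Group(id="g", name="G", members=["a", "b"],
                          mutually_exclusive=True)])
        repaired = copy.deepcopy(broken)
        repaired.inputs[0].requires_inputs = None
    elif code == "V13":
        broken = _base(
            command_line="tool [X] [Y]",
            inputs=[_inp("a", "[X]", optional=False),
                    _inp("b", "[Y]", optional=True)],
            groups=[Group(id="g", name="G", members=["a", "b"],
                          one_is_required=True)])
        repaired = copy.deepcopy(broken)
        repaired.inputs[0].optional = True
    elif code == "V14":
        broken = _base(
            command_line="tool [X] [Y]",
            inputs=[_inp("a", "[X]", optional=True),
                    _inp("b", "[Y]", optional=False)],
            groups=[Group(id="g", name="G", members=["a", "b"],
                          all_or_none=True)])
        repaired = copy.deepcopy(broken)
        repaired.inputs[1].optional = True
    else:
        raise KeyError(code)
    return broken, repaired


RULE_CODES = ["V1", "V2", "V3", "V4", "V5", "V6", "V7a", "V7b", "V7c",
              "V8", "V9", "V10", "V11", "V12", "V13", "V14"]


def rule_fixture(code: str) -> tuple[Descriptor, Descriptor]:
    """(broken, repaired) pair for one rule code."""
    return _broken_and_repaired(code)


def descriptor_text(d: Descriptor) -> str:
    return serialize_descriptor(d)
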