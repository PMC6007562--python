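"""Shared fixtures: the minimal descriptor and the worked-example tool."""

from __future__ import annotations

import pytest

from clidesc import Descriptor, Input, OutputFile


def make_minimal() -> Descriptor:
    """A minimal descriptor: only the mandatory properties, no inputs."""
    return Descriptor(
        name="minimal",
        description="A tool that needs no parameters.",
        tool_version="1.0",
        command_line="echo hello",
    )


def make_worked_example() -> Descriptor:
    """The two-stage pipe template with a config file and a log output.

    The number input carries flag ``-n`` with separator ``=``; the log
    output's template strips ``.csv`` from the string input before
    substitution.
    """
    return Descriptor(
        name="example",
        description="Two chained tools writing a log.",
        tool_version="1.0",
        command_line=(
            "exampleTool_1 [CONFIG_FILE] [STRING_INPUT] [FILE_INPUT] | "
            "exampleTool_2 [FLAG_INPUT] [NUMBER_INPUT] >> [LOG].txt"),
        inputs=[
            Input(id="str_input", name="String input", type="String",
                  value_key="[STRING_INPUT]"),
            Input(id="file_input", name="File input", type="File",
                  value_key="[FILE_INPUT]"),
            Input(id="flag_input", name="Flag input", type="Flag",
                  value_key="[FLAG_INPUT]", command_line_flag="-f",
                  optional=True),
            Input(id="num_input", name="Number input", type="Number",
                  value_key="[NUMBER_INPUT]", command_line_flag="-n",
                  command_line_flag_separator="=", optional=True),
        ],
        output_files=[
            OutputFile(id="log", name="Log file",
                       path_template="log-[STRING_INPUT]",
                       path_template_stripped_extensions=[".csv"],
                       value_key="[LOG]"),
            OutputFile(id="config_file", name="Configuration file",
                       path_template="config.txt",
                       value_key="[CONFIG_FILE]",
                       file_template=["n = [NUMBER_INPUT]",
                                      "input = [FILE_INPUT]"]),
        ],
    )


@pytest.fixture
def minimal():
    return make_minimal()


@pytest.fixture
def worked_example():
    return make_worked_example()


@pytest.fixture
def worked_invocation():
    return {"str_input": "foo.csv", "file_input": "in.nii",
            "flag_input": True, "num_input": 0.3}
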