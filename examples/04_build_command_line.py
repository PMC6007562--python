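"""Turn a descriptor plus an invocation into a runnable shell command.

This two-stage pipeline exercises flags with separators, path templates
with stripped extensions, and a generated configuration file whose
content comes from the same substitution pass as the command line.
"""

from clidesc import Descriptor, Input, OutputFile, build_plan

descriptor = Descriptor(
    name="example",
    description="Two-stage pipeline writing an appended log.",
    tool_version="1.0",
    command_line=("exampleTool_1 [CONFIG_FILE] [STRING_INPUT] [FILE_INPUT] "
                  "| exampleTool_2 [FLAG_INPUT] [NUMBER_INPUT] "
                  ">> [LOG].txt"),
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
        OutputFile(id="log", name="Log", value_key="[LOG]",
                   path_template="log-[STRING_INPUT]",
                   path_template_stripped_extensions=[".csv"]),
        OutputFile(id="config_file", name="Config file",
                   value_key="[CONFIG_FILE]", path_template="config.txt",
                   file_template=["n = [NUMBER_INPUT]",
                                  "input = [FILE_INPUT]"]),
    ],
)

invocation = {"str_input": "foo.csv", "file_input": "in.nii",
              "flag_input": True, "num_input": 0.3}
plan = build_plan(descriptor, invocation)

print("command:", plan.command)
for path, content in plan.config_files:
    print(f"config file {path}:")
    print(content, end="")
for expected in plan.expected_outputs:
    print(f"expected output {expected.id}: {expected.path}")
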