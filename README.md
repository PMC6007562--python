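# clidesc

A JSON descriptor language for command-line scientific tools, with the
tool chain needed to put it to work: a structural and semantic
validator, an invocation-schema generator, a command-line builder, a
local/containerized executor, and an importer for BIDS apps.

## Why

Scientific data-processing tools are overwhelmingly command-line
programs, each with its own flags, positional arguments, configuration
files, and output conventions. Pipelines, web platforms, and test
harnesses that want to run such tools each end up re-describing the same
interfaces in incompatible, ad-hoc ways. `clidesc` factors that
description out into a single machine-readable JSON *descriptor*: a
command-line template whose placeholders (*value keys*) are bound to
typed, constrained input declarations, plus declared output files and an
optional container image. From one descriptor the library can

- **validate** the interface description itself (strict JSON-schema
  conformance plus sixteen semantic cross-reference rules, `V1`–`V16`,
  each with a stable code),
- **derive an invocation schema** — a standard draft-04 JSON schema that
  accepts exactly the runnable parameter assignments, so any JSON-schema
  validator can check inputs without knowing anything about this
  library,
- **construct the exact shell command** (and any generated configuration
  files) for a concrete invocation, with deterministic quoting and
  number formatting,
- **execute** the tool locally or wrapped in its Docker/Singularity
  image, capture stdout/stderr, and verify that declared outputs were
  produced,
- **fuzz** interfaces with seeded random invocations and random
  descriptors, and
- **import** any [BIDS app](https://bids-apps.neuroimaging.io/) into a
  full descriptor from just its image name.

## Worked example

A two-stage pipeline: stage one reads a generated configuration file and
two files; stage two takes a flag and a number and appends to a log
whose name is derived from an input with its `.csv` extension stripped.

```python
from clidesc import Descriptor, Input, OutputFile, build_plan

d = Descriptor(
    name="example",
    description="Two-stage pipeline writing an appended log.",
    tool_version="1.0",
    command_line=("exampleTool_1 [CONFIG_FILE] [STRING_INPUT] [FILE_INPUT] "
                  "| exampleTool_2 [FLAG_INPUT] [NUMBER_INPUT] >> [LOG].txt"),
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

plan = build_plan(d, {"str_input": "foo.csv", "file_input": "in.nii",
                      "flag_input": True, "num_input": 0.3})
print("command:", plan.command)
for path, content in plan.config_files:
    print(f"config file {path}:\n{content}", end="")
```

Running this prints:

```
command: exampleTool_1 config.txt foo.csv in.nii | exampleTool_2 -f -n=0.3 >> log-foo.txt
config file config.txt:
n = 0.3
input = in.nii
```

Note the details handled for you: the number `0.3` rendered as the
single token `-n=0.3` using the declared flag separator; the absent-able
flag `-f` present because `flag_input` is true; the log path `log-foo`
obtained by substituting `foo.csv` and stripping `.csv`; and the
configuration file receiving the *plain* value `0.3`, not the flagged
command-line form.

The `examples/` directory contains seven short runnable scripts covering
authoring, validation, invocation schemas, command construction,
simulation, local launch, and BIDS-app import. The same functionality is
exposed on the command line:

```
clidesc validate tool.json
clidesc invocation tool.json -i params.json
clidesc exec simulate tool.json
clidesc exec launch tool.json params.json
clidesc import bids/example
clidesc schema
```

## Design notes

See `docs/methods.md` for the descriptor dialect, the semantic rule
catalogue, the constraint-to-JSON-schema encoding, quoting and number
formatting rules, and known limitations.
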