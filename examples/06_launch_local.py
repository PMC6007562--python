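"""Execute a descriptor locally and check its declared outputs.

`launch` writes any generated configuration files into the task
directory, runs the command under `sh -c`, captures stdout/stderr to
files, and then resolves each declared output path to see what the tool
actually produced.
"""

import tempfile

from clidesc import Descriptor, Input, OutputFile, launch

descriptor = Descriptor(
    name="greeter",
    description="Write a greeting read from a config file.",
    tool_version="1.0",
    command_line="cat [CONFIG] > [GREETING]",
    inputs=[
        Input(id="name", name="Name", type="String", value_key="[NAME]"),
    ],
    output_files=[
        OutputFile(id="greeting", name="Greeting",
                   path_template="greeting-[NAME].txt",
                   value_key="[GREETING]"),
        OutputFile(id="config", name="Config", path_template="in.cfg",
                   value_key="[CONFIG]",
                   file_template=["hello, [NAME]"]),
    ],
)

with tempfile.TemporaryDirectory() as task_dir:
    record = launch(descriptor, {"name": "ada"}, task_dir=task_dir)
    print("command:     ", record.command)
    print("exit status: ", record.exit_status)
    print("success:     ", record.success)
    for out_id, paths in record.found_outputs:
        print(f"found output {out_id}: {paths}")
        if out_id == "greeting":
            print("  content:", open(paths[0]).read().strip())
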