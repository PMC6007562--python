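"""Author a minimal descriptor in Python and serialize it to JSON.

A descriptor pairs a command-line template with typed input declarations;
each input owns a value key (a placeholder string) that the builder later
replaces with a concrete, quoted value.
"""

from clidesc import Descriptor, Input, parse_descriptor, serialize_descriptor

descriptor = Descriptor(
    name="wordcount",
    description="Count lines in a text file.",
    tool_version="1.0",
    command_line="wc -l [INPUT_FILE]",
    inputs=[
        Input(id="input_file", name="Input file", type="File",
              description="File whose lines are counted.",
              value_key="[INPUT_FILE]"),
    ],
)

text = serialize_descriptor(descriptor)
print(text)

# Serialization is deterministic and parsing it back gives an equal object.
assert parse_descriptor(text) == descriptor
print("round trip: ok")
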