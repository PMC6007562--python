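"""Catch authoring mistakes with the semantic validator.

Structural conformance (key names, types) is checked against the base
JSON schema at parse time; the semantic validator then enforces the
cross-reference rules that a schema alone cannot express, reporting each
problem under a stable rule code.
"""

from clidesc import Descriptor, Input, validate_semantics

# Mistake 1: the value key [THRESHOLD] never appears in the command line.
# Mistake 2: input "mask" requires an input id that does not exist.
broken = Descriptor(
    name="segment",
    description="Segment an image.",
    tool_version="2.1",
    command_line="segment [IMAGE] [MASK]",
    inputs=[
        Input(id="image", name="Image", type="File", value_key="[IMAGE]"),
        Input(id="threshold", name="Threshold", type="Number",
              value_key="[THRESHOLD]", optional=True),
        Input(id="mask", name="Mask", type="File", value_key="[MASK]",
              optional=True, requires_inputs=["no_such_input"]),
    ],
)

for violation in validate_semantics(broken):
    print(f"{violation.rule_code}: {violation.message}")

# Fix both mistakes and the descriptor validates cleanly.
fixed = Descriptor(
    name="segment",
    description="Segment an image.",
    tool_version="2.1",
    command_line="segment [IMAGE] [MASK] [THRESHOLD]",
    inputs=[
        Input(id="image", name="Image", type="File", value_key="[IMAGE]"),
        Input(id="threshold", name="Threshold", type="Number",
              value_key="[THRESHOLD]", optional=True),
        Input(id="mask", name="Mask", type="File", value_key="[MASK]",
              optional=True, requires_inputs=["threshold"]),
    ],
)
print("fixed descriptor violations:", validate_semantics(fixed))
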