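"""Derive an invocation schema and use it to check concrete inputs.

An invocation is a JSON object mapping input ids to values.  The schema
generated from a descriptor encodes types, bounds, requiredness, group
constraints, and input dependencies, so any draft-04 JSON-schema
validator can decide whether an invocation is runnable.
"""

import json

from clidesc import (Descriptor, Group, Input, generate_invocation_schema,
                     validate_invocation)

descriptor = Descriptor(
    name="smooth",
    description="Smooth an image with exactly one kernel specification.",
    tool_version="0.9",
    command_line="smooth [IMAGE] [FWHM] [SIGMA]",
    inputs=[
        Input(id="image", name="Image", type="File", value_key="[IMAGE]"),
        Input(id="fwhm", name="FWHM", type="Number", value_key="[FWHM]",
              optional=True, minimum=0, command_line_flag="--fwhm"),
        Input(id="sigma", name="Sigma", type="Number", value_key="[SIGMA]",
              optional=True, minimum=0, command_line_flag="--sigma"),
    ],
    groups=[Group(id="kernel", name="Kernel", members=["fwhm", "sigma"],
                  mutually_exclusive=True, one_is_required=True)],
)

schema = generate_invocation_schema(descriptor)
print(json.dumps(schema["properties"]["fwhm"], indent=2))

candidates = [
    {"image": "t1.nii", "fwhm": 6},                # runnable
    {"image": "t1.nii"},                           # no kernel chosen
    {"image": "t1.nii", "fwhm": 6, "sigma": 2.5},  # both kernels chosen
    {"image": "t1.nii", "fwhm": -1},               # out of bounds
]
for invocation in candidates:
    violations = validate_invocation(descriptor, invocation)
    verdict = "ok" if not violations else violations[0].message
    print(f"{json.dumps(invocation)} -> {verdict}")
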