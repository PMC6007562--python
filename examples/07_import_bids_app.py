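"""Generate a complete descriptor for a BIDS app from just its image name.

BIDS apps share a fixed command-line contract (bids_dir, output_dir,
analysis_level, optional participant labels), so a full descriptor —
including the Docker container reference and a mandatory derivatives
output — can be produced automatically.
"""

from clidesc import (BidsAppRef, import_bids_app, serialize_descriptor,
                     simulate, validate_semantics)

descriptor = import_bids_app(BidsAppRef(image_name="bids/example",
                                        app_name="example"))
print(serialize_descriptor(descriptor))
assert validate_semantics(descriptor) == []

invocation = {"bids_dir": "/data/ds001", "output_dir": "/data/out",
              "analysis_level": "participant",
              "participant_label": ["01", "02"]}
print("command:", simulate(descriptor, invocation).command)
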