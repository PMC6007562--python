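"""Importer: construct descriptors for BIDS apps.

BIDS apps are containerized neuroimaging applications that all follow the
same calling convention: ``<app> <bids_dir> <output_dir> <analysis_level>
[--participant_label L ...]``, where the analysis level is ``participant``
(per-subject processing) or ``group`` (aggregate analysis).  Because the
interface is standardized, a complete descriptor can be emitted statically
from an image name without inspecting the image.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import ContainerImage, Descriptor, Input, OutputFile

#: standard analysis levels of the BIDS-app convention
ANALYSIS_LEVELS = ["participant", "group"]

#: historical spelling of the participant selection flag varies across apps;
#: this importer emits one fixed, documented spelling.
PARTICIPANT_LABEL_FLAG = "--participant_label"


@dataclass(frozen=True)
class BidsAppRef:
    """A reference to a BIDS-app container image."""

    image_name: str
    app_name: str


def import_bids_app(ref: BidsAppRef) -> Descriptor:
    """Build a valid descriptor for a BIDS app from its image reference.

    Purely constructive — the image is never pulled.  The result passes
    semantic validation and its invocation schema requires ``bids_dir``,
    ``output_dir``, and ``analysis_level``.
    """
    if not ref.image_name:
        raise ValueError("image_name must be non-empty")
    app = ref.app_name or ref.image_name
    inputs = [
        Input(id="bids_dir", name="BIDS dataset directory", type="File",
              description="Root directory of the BIDS-formatted dataset.",
              value_key="[BIDS_DIR]"),
        Input(id="output_dir", name="Output directory", type="File",
              description="Directory where derivatives are written.",
              value_key="[OUTPUT_DIR]"),
        Input(id="analysis_level", name="Analysis level", type="String",
              description="participant: per-subject analysis; "
                          "group: aggregate analysis.",
              value_key="[ANALYSIS_LEVEL]",
              value_choices=list(ANALYSIS_LEVELS)),
        Input(id="participant_label", name="Participant labels",
              type="String", optional=True, list=True,
              description="Subset of participants to process "
                          "(labels without the sub- prefix).",
              value_key="[PARTICIPANT_LABEL]",
              command_line_flag=PARTICIPANT_LABEL_FLAG),
    ]
    outputs = [
        OutputFile(id="derivatives", name="Derivatives",
                   description="The populated output directory.",
                   path_template="[OUTPUT_DIR]"),
    ]
    return Descriptor(
        name=app,
        description=f"BIDS app {app}, imported from its standardized "
                    "calling convention.",
        tool_version="unknown",
        command_line=f"{app} [BIDS_DIR] [OUTPUT_DIR] [ANALYSIS_LEVEL] "
                     "[PARTICIPANT_LABEL]",
        inputs=inputs,
        output_files=outputs,
        container=ContainerImage(type="docker", image=ref.image_name),
    )
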