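"""PatientProfile: one patient's molecular evidence bundle."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .variants import CopyNumberSegment, FusionCall, SomaticVariant

__all__ = ["PatientProfile"]


@dataclass
class PatientProfile:
    """Everything the pipeline knows about one tumor.

    ``expression`` is the tumor's per-gene vector on the declared matrix
    scale; ``methylation`` is a probe-level table (probe_id, gene, region,
    beta, qc_pass); ``catalog`` the 96-channel trinucleotide mutation
    counts; ``metadata`` carries clinical pass-through annotation (age, sex,
    stage, MYCN status, histology, DNA index, best response ...).
    """

    patient_id: str
    expression: pd.Series
    variants: list[SomaticVariant] = field(default_factory=list)
    segments: list[CopyNumberSegment] = field(default_factory=list)
    fusions: list[FusionCall] = field(default_factory=list)
    methylation: pd.DataFrame | None = None
    catalog: pd.Series | None = None
    metadata: dict = field(default_factory=dict)
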