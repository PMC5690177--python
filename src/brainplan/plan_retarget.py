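"""Retarget the best-matching database plan to a new patient.

The template's beam geometry, MLC sequences and monitor units are reused
verbatim — that is the value of retrieving a validated plan.  Only three
things change: the patient identity, fresh DICOM unique identifiers, and the
isocenter, which is mapped from the database frame back into the new
patient's frame by the inverse of the ICP translation (ICP aligned
patient -> database, so database geometry returns by subtracting the
translation).  Prescription dose is not stored in the plan and is entered
downstream in the treatment planning system.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pydicom.dataset import Dataset

from .dicom_io import PlanTemplate

__all__ = ["RetargetRequest", "retarget_plan", "plan_diff"]

# attributes legitimately touched by retargeting (plus file meta)
EDITABLE_TAGS = {
    "PatientName",
    "PatientID",
    "SOPInstanceUID",
    "SeriesInstanceUID",
    "StudyInstanceUID",
    "IsocenterPosition",
}


@dataclass
class RetargetRequest:
    template: PlanTemplate
    new_patient_name: str
    new_patient_id: str
    icp_translation_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.icp_translation_mm = np.asarray(self.icp_translation_mm, dtype=float)
        if self.icp_translation_mm.shape != (3,) or \
                not np.all(np.isfinite(self.icp_translation_mm)):
            raise ValueError("ICP translation must be 3 finite components")


def retarget_plan(req: RetargetRequest) -> PlanTemplate:
    """New plan = template with new identity, fresh UIDs, shifted isocenter."""
    template_iso = req.template.isocenter_mm  # raises if the template has none
    plan = req.template.copy()
    plan.set_patient(req.new_patient_name, req.new_patient_id)
    plan.set_isocenter(template_iso - req.icp_translation_mm)
    plan.refresh_identifiers()
    return plan


def _element_pairs(ds: Dataset, prefix: str = ""):
    for elem in ds:
        name = f"{prefix}{elem.keyword or elem.tag}"
        if elem.VR == "SQ":
            for i, item in enumerate(elem.value):
                yield from _element_pairs(item, prefix=f"{name}[{i}].")
        else:
            yield name, elem.value


def plan_diff(a: PlanTemplate, b: PlanTemplate) -> dict[str, tuple]:
    """Attribute-level diff of two plans: {path: (value_a, value_b)}.

    Used to verify that retargeting touched nothing beyond patient identity,
    identifiers and isocenter.
    """
    flat_a = dict(_element_pairs(a.dataset))
    flat_b = dict(_element_pairs(b.dataset))
    diffs: dict[str, tuple] = {}
    for key in sorted(set(flat_a) | set(flat_b)):
        va, vb = flat_a.get(key), flat_b.get(key)
        if va != vb:
            diffs[key] = (va, vb)
    return diffs
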