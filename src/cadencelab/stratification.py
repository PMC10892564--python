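"""Recovery-status stratification from Forgotten Joint Score change.

Patients are labelled ``MCID_plus`` when the 3-month FJS gain meets or exceeds
the surgery-specific minimal clinically important difference, ``MCID_minus``
when it falls short, and ``ineligible`` when no threshold applies (revision or
resurfacing procedures) or the 3-month score is missing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .stream_model import PatientMeta

__all__ = [
    "MCID_PLUS",
    "MCID_MINUS",
    "INELIGIBLE",
    "RecoveryLabel",
    "mcid_threshold",
    "label_recovery",
    "label_cohort",
    "labels_to_frame",
]

MCID_PLUS = "MCID_plus"
MCID_MINUS = "MCID_minus"
INELIGIBLE = "ineligible"

# thresholds on the 3-month FJS change, by (joint, surgery_type)
MCID_THRESHOLDS: dict[tuple[str, str], float] = {
    ("hip", "total"): 17.5,
    ("knee", "total"): 16.6,
    ("knee", "unicondylar"): 12.5,
}


@dataclass(frozen=True)
class RecoveryLabel:
    patient_id: str
    label: str
    fjs_delta: float | None
    threshold_used: float | None

    def __post_init__(self) -> None:
        if self.label not in (MCID_PLUS, MCID_MINUS, INELIGIBLE):
            raise ValueError(f"unknown label {self.label!r}")


def mcid_threshold(joint: str, surgery_type: str) -> float | None:
    """MCID threshold in FJS points, or None when the procedure has none."""
    return MCID_THRESHOLDS.get((joint, surgery_type))


def label_recovery(meta: PatientMeta) -> RecoveryLabel:
    """Label one patient from the FJS change at 3 months.

    Achieving the threshold at exact equality counts as MCID_plus (the
    minimal important difference is met when it is reached).
    """
    threshold = mcid_threshold(meta.joint, meta.surgery_type)
    if threshold is None or not meta.stratification_eligible:
        delta = (
            meta.fjs_3m - meta.fjs_pre
            if meta.stratification_eligible
            else None
        )
        return RecoveryLabel(meta.patient_id, INELIGIBLE, delta, None)
    delta = meta.fjs_3m - meta.fjs_pre
    label = MCID_PLUS if delta >= threshold else MCID_MINUS
    return RecoveryLabel(meta.patient_id, label, delta, threshold)


def label_cohort(metadata: Iterable[PatientMeta]) -> list[RecoveryLabel]:
    return [label_recovery(m) for m in metadata]


def labels_to_frame(labels: Iterable[RecoveryLabel]) -> pd.DataFrame:
    rows = [(l.patient_id, l.label, l.fjs_delta, l.threshold_used) for l in labels]
    return pd.DataFrame(rows, columns=["patient_id", "label", "fjs_delta", "threshold_used"])
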