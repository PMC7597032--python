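"""Clinical neuropathy scoring and patient grouping.

The composite NS-VPT variable sums four max-normalised contributions:
MNSI history questionnaire (max 15), MNSI physical assessment (max 10),
and the vibration perception thresholds at hallux and malleolus (max 40 V
each), giving a score in [0, 4].

Patients are assigned to the neuropathic group N when at least two of
three conditions hold (all strict inequalities): MNSI > 2, Michigan
Diabetes Neuropathy Score > 7, VPT > 25 V.  A LADA diagnosis overrides
the rule; every patient also belongs to the pooled ALL group.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import PedarchError

MNSI_HISTORY_MAX = 15.0
MNSI_PHYSICAL_MAX = 10.0
VPT_MAX = 40.0

MNSI_CUTOFF = 2.0
MDNS_CUTOFF = 7.0
VPT_CUTOFF = 25.0

GROUPS = ("N", "D", "LADA")


@dataclass
class ClinicalRecord:
    """Per-patient clinical record."""

    mnsi_history: float
    mnsi_physical: float
    mdns: float
    vpt_hallux: float
    vpt_malleolus: float
    age: float
    bmi: float
    yod: float
    diagnosis: str = "type1"  # or "LADA"

    def __post_init__(self) -> None:
        for name, value, hi in (
            ("mnsi_history", self.mnsi_history, MNSI_HISTORY_MAX),
            ("mnsi_physical", self.mnsi_physical, MNSI_PHYSICAL_MAX),
            ("vpt_hallux", self.vpt_hallux, VPT_MAX),
            ("vpt_malleolus", self.vpt_malleolus, VPT_MAX),
        ):
            if not 0.0 <= value <= hi:
                raise PedarchError(f"{name}={value} outside [0, {hi}]")
        if self.mdns < 0:
            raise PedarchError(f"mdns={self.mdns} must be non-negative")
        if self.diagnosis not in ("type1", "LADA"):
            raise PedarchError(f"unknown diagnosis {self.diagnosis!r}")


def ns_vpt(rec: ClinicalRecord) -> float:
    """Composite neuropathy score in [0, 4]: four contributions, each
    divided by its full-scale value."""
    return (
        rec.mnsi_history / MNSI_HISTORY_MAX
        + rec.mnsi_physical / MNSI_PHYSICAL_MAX
        + rec.vpt_hallux / VPT_MAX
        + rec.vpt_malleolus / VPT_MAX
    )


def classify_group(
    rec: ClinicalRecord,
    vpt: float | None = None,
    mnsi: str = "physical",
) -> str:
    """Assign a patient to N, D or LADA.

    ``vpt`` defaults to the hallux VPT; ``mnsi`` selects which MNSI
    sub-score the > 2 criterion uses ('physical', the clinical convention,
    or 'history').
    """
    if rec.diagnosis == "LADA":
        return "LADA"
    if vpt is None:
        vpt = rec.vpt_hallux
    if mnsi == "physical":
        mnsi_score = rec.mnsi_physical
    elif mnsi == "history":
        mnsi_score = rec.mnsi_history
    else:
        raise PedarchError(f"mnsi must be 'physical' or 'history', got {mnsi!r}")
    hits = (
        int(mnsi_score > MNSI_CUTOFF)
        + int(rec.mdns > MDNS_CUTOFF)
        + int(vpt > VPT_CUTOFF)
    )
    return "N" if hits >= 2 else "D"


def score_cohort(records: list[ClinicalRecord], **kwargs) -> pd.DataFrame:
    """NS-VPT and group label for a list of records, one row per patient."""
    rows = []
    for rec in records:
        rows.append(
            {
                "NS_VPT": ns_vpt(rec),
                "group": classify_group(rec, **kwargs),
                "AGE": rec.age,
                "BMI": rec.bmi,
                "YOD": rec.yod,
            }
        )
    return pd.DataFrame(rows)
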