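"""Clinical neuropathy scoring.

Implements the bedside rules used to label feet: the neuropathy symptom
score (NSS, 0-10) and its severity categories; the neuropathy disability
score (NDS, 0-10) built from vibration, temperature, pinprick and ankle
reflex testing; the per-foot definition of clinically evident peripheral
neuropathy (PNP: two or more positive findings among symptoms and signs on
that side); asymmetric PNP (at least one discordant finding between feet);
and the small-fiber / large-fiber / mixed phenotype partition.

NDS rubric convention: the published 0-10 scale is not restated in full in
the source protocol; here each of vibration, temperature and pinprick
contributes 1 point per abnormal side (0-6) and a reduced-or-absent ankle
reflex contributes 2 points per side (0-4), capped at 10.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import NeuroplayError

FEET = ("left", "right")

# a positive symptom finding = at least mild symptoms on the NSS
NSS_SYMPTOM_THRESHOLD = 3


@dataclass(frozen=True)
class FootSigns:
    """Sign items for one foot: 0 = normal, 1 = reduced/absent; the
    monofilament field counts insensate sites out of 3."""

    vibration: int
    temperature: int
    pinprick: int
    ankle_reflex: int
    monofilament_sites: int

    def __post_init__(self):
        for name in ("vibration", "temperature", "pinprick", "ankle_reflex"):
            v = getattr(self, name)
            if v not in (0, 1):
                raise NeuroplayError(f"{name} must be 0 or 1, got {v}")
        if not 0 <= self.monofilament_sites <= 3:
            raise NeuroplayError(
                f"monofilament_sites must be in 0..3, got {self.monofilament_sites}")

    @property
    def monofilament_positive(self) -> int:
        return int(self.monofilament_sites >= 1)


@dataclass(frozen=True)
class ClinicalExam:
    nss_total: int
    left: FootSigns
    right: FootSigns

    def __post_init__(self):
        if not 0 <= self.nss_total <= 10:
            raise NeuroplayError(f"NSS must be in 0..10, got {self.nss_total}")

    def foot(self, side: str) -> FootSigns:
        if side not in FEET:
            raise NeuroplayError(f"unknown foot {side!r}")
        return self.left if side == "left" else self.right


@dataclass(frozen=True)
class PnpStatus:
    pnp: dict  # foot -> bool
    phenotype: dict  # foot -> {'without','SFN','LFN','mixed'}
    any_pnp: bool
    asymmetric: bool


def nss_category(nss_total: int) -> str:
    """0-2 normal, 3-4 mild, 5-6 moderate, 7-10 severe."""
    if not 0 <= nss_total <= 10:
        raise NeuroplayError(f"NSS out of range 0..10: {nss_total}")
    if nss_total <= 2:
        return "normal"
    if nss_total <= 4:
        return "mild"
    if nss_total <= 6:
        return "moderate"
    return "severe"


def nds_total(exam: ClinicalExam) -> tuple[int, str]:
    """NDS on 0-10 across both feet and its category
    (0-2 normal, 3-5 mild, 6-8 moderate, 9-10 severe)."""
    total = 0
    for side in FEET:
        f = exam.foot(side)
        total += f.vibration + f.temperature + f.pinprick + 2 * f.ankle_reflex
    total = min(total, 10)
    if total <= 2:
        cat = "normal"
    elif total <= 5:
        cat = "mild"
    elif total <= 8:
        cat = "moderate"
    else:
        cat = "severe"
    return total, cat


def positive_findings(exam: ClinicalExam, foot: str) -> int:
    """Count of positive findings on one side: symptoms (NSS >= 3) plus the
    five sign items."""
    f = exam.foot(foot)
    return (
        int(exam.nss_total >= NSS_SYMPTOM_THRESHOLD)
        + f.vibration + f.temperature + f.pinprick + f.ankle_reflex
        + f.monofilament_positive
    )


def pnp_per_foot(exam: ClinicalExam, foot: str) -> bool:
    """Clinically evident PNP on one side: >= 2 positive findings."""
    return positive_findings(exam, foot) >= 2


def asymmetric_pnp(exam: ClinicalExam) -> bool:
    """At least one per-foot item discordant between sides (monofilament
    compared as positivity, not site count)."""
    l, r = exam.left, exam.right
    return (
        l.vibration != r.vibration
        or l.temperature != r.temperature
        or l.pinprick != r.pinprick
        or l.ankle_reflex != r.ankle_reflex
        or l.monofilament_positive != r.monofilament_positive
    )


def phenotype_classify(exam: ClinicalExam, foot: str) -> str:
    """Fiber-damage phenotype of one foot.

    Small-fiber score = temperature + pinprick (0-2); large-fiber score =
    ankle reflex + vibration + monofilament positivity (0-3).  'without'
    when both are 0, 'SFN'/'LFN' when only one class is affected, 'mixed'
    when both are.
    """
    f = exam.foot(foot)
    small = f.temperature + f.pinprick
    large = f.ankle_reflex + f.vibration + f.monofilament_positive
    if small == 0 and large == 0:
        return "without"
    if small >= 1 and large == 0:
        return "SFN"
    if large >= 1 and small == 0:
        return "LFN"
    return "mixed"


def pnp_status(exam: ClinicalExam) -> PnpStatus:
    pnp = {side: pnp_per_foot(exam, side) for side in FEET}
    return PnpStatus(
        pnp=pnp,
        phenotype={side: phenotype_classify(exam, side) for side in FEET},
        any_pnp=pnp["left"] or pnp["right"],
        asymmetric=asymmetric_pnp(exam),
    )


def cohort_summary(statuses: list[PnpStatus]) -> pd.DataFrame:
    """Prevalence table: counts and percentages (one decimal) of left-foot,
    right-foot, any and asymmetric PNP."""
    if not statuses:
        raise NeuroplayError("cohort_summary needs a non-empty status list")
    n = len(statuses)
    rows = {
        "left_foot_pnp": sum(s.pnp["left"] for s in statuses),
        "right_foot_pnp": sum(s.pnp["right"] for s in statuses),
        "any_pnp": sum(s.any_pnp for s in statuses),
        "asymmetric_pnp": sum(s.asymmetric for s in statuses),
    }
    return pd.DataFrame(
        {"count": list(rows.values()),
         "n": n,
         "percent": [round(100.0 * v / n, 1) for v in rows.values()]},
        index=list(rows.keys()),
    )
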