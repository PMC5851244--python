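"""Bedside and laboratory severity scores for ED sepsis screening.

Implements four scores on a single patient record:

* **qSOFA** (0-3): one point each for systolic blood pressure <= 100 mmHg,
  respiratory rate >= 22 /min, and altered mental status (any AVPU level
  other than Alert). Boundary values score a point.
* **qSOFA + lactate** (0-4): qSOFA plus one point when plasma lactate is at
  or above a threshold (default 2.0 mmol/L, inclusive).
* **SIRS** (0-4): temperature, heart rate, respiratory (rate or PaCO2) and
  white-cell criteria, strict inequalities per the consensus definition.
* **SOFA** (0-24): six organ subscores of 0-4 each; the CNS component maps
  the AVPU scale through conventional GCS anchors (A/V/P/U -> 15/13/8/3).

All scoring functions are pure: they take immutable value objects and
return integers (plus flags where inputs were imputed as normal). The
component cut-points live in versioned data files under ``sepscore/data``,
not in code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Optional

from .errors import IneligibleRecordError

__all__ = [
    "MentalStatus",
    "Vasopressor",
    "Outcome",
    "VitalSigns",
    "LabPanel",
    "PatientRecord",
    "ScorePanel",
    "SofaResult",
    "SirsResult",
    "qsofa",
    "lactate_point",
    "qsofa_lactate",
    "sirs",
    "avpu_to_cns_points",
    "sofa",
    "score_record",
    "LACTATE_THRESHOLD",
]

#: Default hyperlactatemia threshold in mmol/L. The boundary is inclusive:
#: a lactate of exactly 2.0 scores the extra point.
LACTATE_THRESHOLD = 2.0


class MentalStatus(Enum):
    """AVPU responsiveness scale: Alert / responds to Verbal / responds to
    Pain / Unresponsive. Anything other than ALERT counts as altered
    mental status for qSOFA."""

    ALERT = "ALERT"
    VERBAL = "VERBAL"
    PAIN = "PAIN"
    UNRESPONSIVE = "UNRESPONSIVE"


class Vasopressor(Enum):
    """Vasopressor dose class for the SOFA cardiovascular component.

    DOPA_LOW: dopamine <= 5 ug/kg/min; DOPA_MID_OR_ANY_NE_LOW: dopamine
    5-15 or any norepinephrine <= 0.1; DOPA_HIGH_OR_NE_HIGH: dopamine > 15
    or norepinephrine > 0.1.
    """

    NONE = "NONE"
    DOPA_LOW = "DOPA_LOW"
    DOPA_MID_OR_ANY_NE_LOW = "DOPA_MID_OR_ANY_NE_LOW"
    DOPA_HIGH_OR_NE_HIGH = "DOPA_HIGH_OR_NE_HIGH"


class Outcome(Enum):
    SURVIVED = "SURVIVED"
    DIED = "DIED"


def _check_range(name: str, value: Optional[float], lo: float, hi: float) -> None:
    if value is None:
        return
    if not (lo <= value <= hi):
        raise ValueError(f"{name}={value!r} outside physiologic range [{lo}, {hi}]")


@dataclass(frozen=True)
class VitalSigns:
    """One reduced set of vital signs per patient.

    sbp and rr are required for qSOFA; hr and temp only feed SIRS; map only
    feeds SOFA. Absent optional fields stay None, never zero.
    """

    sbp: Optional[float] = None  # systolic BP, mmHg
    rr: Optional[float] = None   # respiratory rate, breaths/min
    hr: Optional[float] = None   # heart rate, beats/min
    temp: Optional[float] = None # core temperature, degC
    map: Optional[float] = None  # mean arterial pressure, mmHg

    def __post_init__(self) -> None:
        _check_range("sbp", self.sbp, 30, 300)
        _check_range("rr", self.rr, 4, 80)
        _check_range("hr", self.hr, 10, 300)
        _check_range("temp", self.temp, 25, 45)
        _check_range("map", self.map, 20, 200)


@dataclass(frozen=True)
class LabPanel:
    """Laboratory values and vasopressor class. Lactate (mmol/L) is the
    only field the composite score requires; the rest feed SIRS and SOFA."""

    lactate: Optional[float] = None    # mmol/L
    wbc: Optional[float] = None        # 10^3/uL
    paco2: Optional[float] = None      # mmHg
    platelets: Optional[float] = None  # 10^3/uL
    bilirubin: Optional[float] = None  # mg/dL
    creatinine: Optional[float] = None # mg/dL
    pf_ratio: Optional[float] = None   # PaO2/FiO2, mmHg
    vasopressor: Optional[Vasopressor] = None

    def __post_init__(self) -> None:
        for name in ("lactate", "wbc", "paco2", "platelets", "bilirubin",
                     "creatinine", "pf_ratio"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name}={v!r} must be non-negative")


@dataclass(frozen=True)
class PatientRecord:
    """One ED patient after per-field reduction: identity, outcome, and the
    measurements the scores consume."""

    id: str
    outcome: Outcome
    vitals: VitalSigns
    labs: LabPanel
    mental: MentalStatus
    age: Optional[float] = None


@dataclass(frozen=True)
class SirsResult:
    score: int
    missing_components: tuple[str, ...] = ()


@dataclass(frozen=True)
class SofaResult:
    """Total SOFA with the six organ subscores. ``imputed_normal`` lists
    organ systems whose inputs were absent and therefore scored 0."""

    total: int
    respiration: int
    coagulation: int
    liver: int
    cardiovascular: int
    cns: int
    renal: int
    imputed_normal: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        subs = (self.respiration, self.coagulation, self.liver,
                self.cardiovascular, self.cns, self.renal)
        assert self.total == sum(subs)
        assert all(0 <= s <= 4 for s in subs)


@dataclass(frozen=True)
class ScorePanel:
    """All severity scores computed for one patient. SIRS and SOFA are None
    when their inputs are missing from the record."""

    qsofa: int
    qsofa_lactate: int
    lactate_point: int
    sirs: Optional[SirsResult] = None
    sofa: Optional[SofaResult] = None


def _load_data(name: str) -> dict:
    with resources.files("sepscore.data").joinpath(name).open() as fh:
        return json.load(fh)


_SOFA = _load_data("sofa_bands.json")
_SIRS = _load_data("sirs_criteria.json")


def qsofa(vitals: VitalSigns, mental: MentalStatus) -> int:
    """qSOFA score 0-3: SBP <= 100 mmHg, RR >= 22 /min, altered mentation.

    Both numeric boundaries are inclusive (100 mmHg and 22 /min each score
    a point). Raises :class:`IneligibleRecordError` naming the missing
    field when sbp or rr is absent.
    """
    if vitals.sbp is None:
        raise IneligibleRecordError("sbp")
    if vitals.rr is None:
        raise IneligibleRecordError("rr")
    score = 0
    if vitals.sbp <= 100:
        score += 1
    if vitals.rr >= 22:
        score += 1
    if mental is not MentalStatus.ALERT:
        score += 1
    return score


def lactate_point(lactate: Optional[float], threshold: float = LACTATE_THRESHOLD) -> int:
    """1 if plasma lactate >= threshold (default 2.0 mmol/L, inclusive), else 0."""
    if lactate is None:
        raise IneligibleRecordError("lactate")
    return 1 if lactate >= threshold else 0


def qsofa_lactate(
    vitals: VitalSigns,
    mental: MentalStatus,
    labs: LabPanel,
    threshold: float = LACTATE_THRESHOLD,
) -> int:
    """Composite qSOFA + lactate score, 0-4.

    Equals ``qsofa(vitals, mental) + lactate_point(labs.lactate)``; raises
    the component's ineligibility error if either part lacks its inputs.
    """
    return qsofa(vitals, mental) + lactate_point(labs.lactate, threshold)


def sirs(vitals: VitalSigns, labs: LabPanel) -> SirsResult:
    """SIRS criteria count 0-4 with strict consensus inequalities.

    Components: temp > 38 or < 36 degC; HR > 90; RR > 20 or PaCO2 < 32 mmHg;
    WBC > 12 or < 4 (10^3/uL). A component whose inputs are all missing
    contributes 0 and is listed in ``missing_components``. All four
    components missing raises an ineligibility error.
    """
    c = _SIRS
    score = 0
    missing: list[str] = []

    if vitals.temp is not None:
        t = c["temperature"]
        if vitals.temp > t["high"] or vitals.temp < t["low"]:
            score += 1
    else:
        missing.append("temperature")

    if vitals.hr is not None:
        if vitals.hr > c["heart_rate"]["high"]:
            score += 1
    else:
        missing.append("heart_rate")

    r = c["respiratory"]
    if vitals.rr is not None or labs.paco2 is not None:
        hit = (vitals.rr is not None and vitals.rr > r["rr_high"]) or (
            labs.paco2 is not None and labs.paco2 < r["paco2_low"])
        if hit:
            score += 1
    else:
        missing.append("respiratory")

    if labs.wbc is not None:
        w = c["white_cells"]
        if labs.wbc > w["high"] or labs.wbc < w["low"]:
            score += 1
    else:
        missing.append("white_cells")

    if len(missing) == 4:
        raise IneligibleRecordError("sirs_inputs", "all four SIRS components missing")
    return SirsResult(score=score, missing_components=tuple(missing))


def avpu_to_cns_points(mental: MentalStatus) -> int:
    """SOFA CNS points from the AVPU scale: A->0, V->1, P->3, U->4.

    The mapping pushes the conventional AVPU->GCS anchors (15/13/8/3)
    through the standard SOFA CNS bands (GCS 15->0, 13-14->1, 6-9->3, <6->4).
    """
    return int(_SOFA["cns"]["avpu_points"][mental.value])


def _band_points(value: float, bands: list, direction: str) -> int:
    # bands sorted most-severe first: [threshold, points]
    for threshold, points in bands:
        if direction == "lower_worse" and value < threshold:
            return int(points)
        if direction == "higher_worse" and value >= threshold:
            return int(points)
    return 0


def sofa(vitals: VitalSigns, labs: LabPanel, mental: MentalStatus) -> SofaResult:
    """Full SOFA score 0-24 from six organ subscores of 0-4 each.

    Missing organ inputs score 0 and are flagged in ``imputed_normal``
    (emergency-department records routinely lack PaO2/FiO2). Urine-output
    renal criteria are not implemented. Cut-points come from the shipped
    ``sofa_bands.json`` table.
    """
    imputed: list[str] = []

    def banded(system: str, value: Optional[float]) -> int:
        spec = _SOFA[system]
        if value is None:
            imputed.append(system)
            return 0
        return _band_points(value, spec["bands"], spec["direction"])

    resp = banded("respiration", labs.pf_ratio)
    coag = banded("coagulation", labs.platelets)
    liver = banded("liver", labs.bilirubin)
    renal = banded("renal", labs.creatinine)

    cv_spec = _SOFA["cardiovascular"]
    if labs.vasopressor is not None and labs.vasopressor is not Vasopressor.NONE:
        cardio = int(cv_spec["vasopressor_points"][labs.vasopressor.value])
    elif vitals.map is not None:
        cardio = 1 if vitals.map < cv_spec["map_hypotension_threshold"] else 0
    else:
        imputed.append("cardiovascular")
        cardio = 0

    cns = avpu_to_cns_points(mental)

    return SofaResult(
        total=resp + coag + liver + cardio + cns + renal,
        respiration=resp, coagulation=coag, liver=liver,
        cardiovascular=cardio, cns=cns, renal=renal,
        imputed_normal=tuple(imputed),
    )


def score_record(
    record: PatientRecord,
    lactate_threshold: float = LACTATE_THRESHOLD,
    require_sirs: bool = False,
    require_sofa: bool = False,
) -> ScorePanel:
    """Compute every available score for one patient record.

    SIRS is attempted only when at least one of its inputs is present;
    SOFA only when at least one organ input beyond mentation exists (the
    CNS input is always present). Set the ``require_*`` flags to raise
    instead of silently omitting.
    """
    q = qsofa(record.vitals, record.mental)
    lp = lactate_point(record.labs.lactate, lactate_threshold)

    sirs_result: Optional[SirsResult] = None
    have_sirs = any(v is not None for v in (
        record.vitals.temp, record.vitals.hr, record.vitals.rr, record.labs.wbc,
        record.labs.paco2))
    if have_sirs or require_sirs:
        sirs_result = sirs(record.vitals, record.labs)

    sofa_result: Optional[SofaResult] = None
    have_sofa = any(v is not None for v in (
        record.labs.pf_ratio, record.labs.platelets, record.labs.bilirubin,
        record.labs.creatinine, record.vitals.map, record.labs.vasopressor))
    if have_sofa or require_sofa:
        sofa_result = sofa(record.vitals, record.labs, record.mental)

    return ScorePanel(qsofa=q, qsofa_lactate=q + lp, lactate_point=lp,
                      sirs=sirs_result, sofa=sofa_result)
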