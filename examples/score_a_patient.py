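"""Score a single ED patient on qSOFA, qSOFA+lactate, SIRS and SOFA.

A hypotensive, tachypnoeic patient responding only to pain, with a
lactate of 3.1 mmol/L, scores the composite maximum of 4; the full SOFA
panel adds organ-level detail where labs are available.
"""

from sepscore import (LabPanel, MentalStatus, Outcome, PatientRecord,
                      VitalSigns, score_record)

patient = PatientRecord(
    id="example-001",
    outcome=Outcome.SURVIVED,
    vitals=VitalSigns(sbp=88, rr=26, hr=112, temp=38.6, map=62),
    labs=LabPanel(lactate=3.1, wbc=15.2, platelets=95, bilirubin=1.4,
                  creatinine=2.1, pf_ratio=210),
    mental=MentalStatus.PAIN,
)

panel = score_record(patient)
print(f"qSOFA            : {panel.qsofa}   (SBP<=100, RR>=22, AMS each score 1)")
print(f"lactate point    : {panel.lactate_point}   (lactate >= 2.0 mmol/L)")
print(f"qSOFA + lactate  : {panel.qsofa_lactate}   (range 0-4; >=2 flags high risk)")
print(f"SIRS             : {panel.sirs.score}")
print(f"SOFA             : {panel.sofa.total}  subscores "
      f"resp={panel.sofa.respiration} coag={panel.sofa.coagulation} "
      f"liver={panel.sofa.liver} cv={panel.sofa.cardiovascular} "
      f"cns={panel.sofa.cns} renal={panel.sofa.renal}")
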