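"""Score the five ATP III metabolic syndrome components for a subject.

Each component scores 1 when its criterion is met; a total of 3 or more
defines metabolic syndrome (MS).  The MSx score omits the waist
component for use alongside anthropometric risk, which already uses
waist circumference.
"""
from anthrorisk import ms_total

res = ms_total(
    waist_cm=103.0, sex="male",
    sbp_mmhg=128.0, dbp_mmhg=85.0, bp_meds=0,
    tg_mg_dl=150.0, hdl_mg_dl=40.0,
    glu_mg_dl=109.0, diabetes_pills=0,
)

print(f"components: waist={res.waist} bp={res.bp} tg={res.tg} "
      f"hdl={res.hdl} glu={res.glu}")
print(f"MS score = {res.ms_score} / 5  ->  MS = {res.ms}")
print(f"MSx score (waist excluded) = {res.msx_score} / 4")
print()
print("Waist (103 > 102 cm), diastolic BP (85 >= 85 mmHg) and fasting")
print("triglycerides (150 >= 150 mg/dL) each score a point; three points")
print("meet the metabolic syndrome definition.")
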