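"""Compute BMI, ABSI and hip index for a single subject.

ABSI normalizes waist circumference for height and weight, and HI does
the same for hip circumference, so each index carries information the
others do not.
"""
from anthrorisk import RawAnthro, compute_all

subject = RawAnthro(height_cm=166.0, weight_kg=73.0, waist_cm=90.0, hip_cm=100.0)
idx = compute_all(subject)

print(f"BMI  = {idx.bmi:.2f} kg/m^2")
print(f"ABSI = {idx.absi:.5f} m^(11/6) kg^(-2/3)")
print(f"HI   = {idx.hi:.2f} cm")
print()
print("This subject sits exactly at the reference height (166 cm) and")
print("weight (73 kg), so HI equals the raw hip circumference; an ABSI")
print("near 0.080 is typical for adults, with higher values indicating")
print("a larger waist than height and weight alone would predict.")
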