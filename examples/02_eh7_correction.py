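"""Correcting field Eh readings to pH 7 and normalizing oxygen units.

Redox potentials measured at different pH are not directly comparable; the
Nernst slope (-59.16 mV per pH unit at 25 degC) moves each reading along a
constant-slope line to pH 7 (Eh7).
"""

from redoxzc import eh_to_eh7, nernst_slope, o2_mg_per_L_to_uM, o2_percent_sat_to_uM

print(f"Nernst slope at 25 degC: {nernst_slope(25.0):.2f} mV/pH")
print(f"Nernst slope at 80 degC: {nernst_slope(80.0):.2f} mV/pH (hot springs)")

for eh, pH in [(0.0, 5.0), (-100.0, 9.0), (250.0, 7.0)]:
    print(f"Eh = {eh:+7.1f} mV at pH {pH}: Eh7 = {eh_to_eh7(eh, pH, 25.0):+8.2f} mV")
print("(an acidic sample reads higher than its pH-7 equivalent, an")
print(" alkaline one lower; at pH 7 the correction is the identity)")

print(f"\n8.0 mg/L dissolved O2 = {o2_mg_per_L_to_uM(8.0):.1f} uM")
print(f"100% air saturation at 25 degC = "
      f"{o2_percent_sat_to_uM(100.0, 25.0):.1f} uM")
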