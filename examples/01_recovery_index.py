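"""Recovery index and hepatosomatic index on hand-entered group values.

The recovery index anchors a recovered group's mean vasa deferentia dry
weight (VDW) between the depleted day-0 mean (0%) and the intact control
mean (100%). Values above 100% mean the males rebuilt more seminal material
than the control stock (overcompensation).
"""

from semrec import RecoveryIndexInput, compute_ri, hepatosomatic_index

# Baseline group means: control 84 mg, after electroejaculation 52 mg.
# A recovery group that reached 104.8 mg has regained (104.8-52)/(84-52).
inp = RecoveryIndexInput.from_groups(
    control_t0=[80.0, 88.0, 82.0, 86.0],      # mean 84 mg
    ee_t0=[50.0, 54.0, 48.0, 56.0],           # mean 52 mg
    ee_t1=[100.8, 108.8, 102.8, 106.8],       # mean 104.8 mg
)
res = compute_ri(inp)
print(f"increment A            = {res.A:.1f} mg")
print(f"amount to recover B    = {res.B:.1f} mg")
print(f"recovery index         = {res.ri:.1f} %   (> 100: overcompensation)")

# Hepatosomatic index: energy reserves as % of body dry weight.
hsi = hepatosomatic_index(hep_dry_weight=0.60, body_dry_weight=10.0)
print(f"hepatosomatic index    = {hsi:.1f} %   (0.60 g organ in a 10 g body)")
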