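"""Blood-pressure aggregation, MAP computation, and the three labeling rules.

Four repeated (SBP, DBP) readings are averaged into the resting pressure;
MAP = (1/3)·SBP + (2/3)·DBP is categorized into six clinical bands and
collapsed to a binary label (normal band vs everything above it; the
optimal band is excluded).
"""

from vasomap import bp_labels as bp

readings = [(126, 83), (123, 81), (125, 82), (122, 83)]
sbp, dbp = bp.resting_bp(readings)
map_value = bp.compute_map(sbp, dbp)

print(f"resting SBP/DBP : {sbp:.1f}/{dbp:.1f} mmHg")
print(f"MAP             : {map_value:.2f} mmHg")
print(f"MAP category    : {bp.map_category(map_value)}")
print(f"systolic rule   : {bp.label_systolic(sbp, dbp)}")
print(f"diastolic rule  : {bp.label_diastolic(sbp, dbp)}")
print(f"MAP rule        : {bp.label_map(sbp, dbp)}")
print()
print("A subject averaging 124/82 mmHg sits in the normal MAP band "
      "(93.33-99.00), is excluded by the systolic rule (120-130 gap), and "
      "is hypertensive by the diastolic rule (DBP > 80).")
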