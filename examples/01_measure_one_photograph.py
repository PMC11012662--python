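"""Measure the ten asymmetry parameters of one landmarked photograph.

Builds a symmetric trunk template for a 1000x1500 px back-view
photograph, applies a right-thoracic-like deformity (shoulders tilted
clockwise, trunk shifted toward the patient's right, left waist more
indented), and prints the resulting profile.
"""

from trunkmetrics import apply_deformity, hemitrunk_areas, make_template, measure_profile
from trunkmetrics.simulate import SubjectDeformity

template = make_template(height=1500, width=1000)
patient = apply_deformity(
    template,
    SubjectDeformity(
        shoulder_tilt_deg=4.0,       # patient's right shoulder lower
        axilla_tilt_deg=2.5,
        waist_tilt_deg=-1.5,
        trunk_shift_px=18.0,         # C7 plumbline toward patient-right
        waist_depth_left_px=15.0,    # deeper left waist crease
    ),
)

profile = measure_profile(patient)
areas = hemitrunk_areas(patient)

print("Angles (degrees, clockwise-positive viewed from the back):")
for name, value in list(profile.as_dict().items())[:6]:
    print(f"  {name}: {value:+.2f}")
print("Hemitrunk area ratios (left/right, 1.0 = symmetric):")
for name, value in list(profile.as_dict().items())[6:]:
    print(f"  {name}: {value:.3f}")
print(f"C7 plumbline at x = {areas.plumbline_x:.0f} px; "
      f"left hemitrunk {areas.left_total():.0f} px^2, "
      f"right {areas.right_total():.0f} px^2")
print()
print("Positive SHA/AHA mean the right side hangs lower; WAD < 0 means the")
print("right waistline is straighter than the left; ratios > 1 mean the left")
print("hemitrunk region is larger — together a right-convex asymmetry pattern.")
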