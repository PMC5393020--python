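"""Calibrate one functional spinal unit (FSU) and show what the surgical
release and the rib-cage weighting do to its stiffness.

The release (removal of the facet capsules and interspinous elements)
must reduce the unit's stiffness by the literature percentages — 17 %
axial rotation, 15 % flexion, 3.8 % coronal bending, 14 % axial
compression — and the rib cage stiffens thoracic units by 40/35/31 % in
flexion-extension / lateral bending / axial rotation.  Both behaviors are
calibration targets, so the printed numbers should hit them exactly.
"""
from spinesim import calibration as cal
from spinesim import model as md

params = cal.calibrate_release_partition(
    md.default_stiffness_params(), cal.default_fsu_targets())

intact = md.canonical_fsu_model("T6", params)
released = md.apply_surgical_release(intact, ["T6"])
print("T6-T7 FSU stiffness reduction after pedicle-screw-placement release:")
for mode in ("axial_rotation", "flexion", "lateral_bending",
             "axial_compression"):
    s_i = md.fsu_stiffness(intact, "T6", mode)
    s_r = md.fsu_stiffness(released, "T6", mode)
    print(f"  {mode:18s} {100 * (1 - s_r / s_i):5.2f} %")

targets = cal.default_fsu_targets()
with_rc = cal.calibrate_fsu(params, targets, "T6", ribcage=True)
without = cal.calibrate_fsu(params, targets, "T6", ribcage=False)
print("rib-cage stiffening of the thoracic unit:")
for mode in ("flexion", "lateral_bending", "axial_rotation"):
    a = md.fsu_stiffness(md.canonical_fsu_model("T6", with_rc), "T6", mode)
    b = md.fsu_stiffness(md.canonical_fsu_model("T6", without), "T6", mode)
    print(f"  {mode:18s} +{100 * (a / b - 1):5.1f} %")
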