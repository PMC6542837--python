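"""Captive-bubble contact angles by circular-arc fitting.

Renders circular-cap bubble silhouettes at the two initial-state angles
(bare polystyrene 103 deg, plasma-treated 126 deg, bubble-side convention)
and re-measures them from the pixels.
"""

from biofilmwet import BubblePhantomSpec, make_bubble_image, measure_contact_angle, water_side_angle

for label, angle in [("PS initial", 103.0), ("VGP-PS initial", 126.0)]:
    spec = BubblePhantomSpec(contact_angle_deg=angle, noise_sd=3.0, seed=11)
    image, truth = make_bubble_image(spec)
    res = measure_contact_angle(image, spec.baseline_row)
    print(
        f"{label:<15} truth {truth:6.1f} deg   measured {res.angle_deg:6.1f} deg"
        f"   (water side {water_side_angle(res.angle_deg):5.1f} deg,"
        f" fit residual {res.fit_residual:.2f} px)"
    )

print(
    "\nA smaller bubble-side angle means the bubble flattens onto the surface:"
    "\nthe bare polystyrene dish is the more hydrophobic of the two."
)
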