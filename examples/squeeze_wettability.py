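"""Liquid-squeezing wettability indexes for the four dish conditions.

Renders one synthetic air-jet squeeze video per condition (bare and
plasma-treated polystyrene, initial state and after biofilm-forming
incubation), measures the dry-area diameter on every frame, and prints the
two wettability indexes.
"""

from biofilmwet import make_squeeze_video, study_condition_spec
from biofilmwet.io import manifest_from_spec
from biofilmwet.squeeze import analyze_series, diameter_series

print(f"{'condition':<14} {'mean diameter':>14} {'residual':>10} {'oscillation':>12}")
for condition in ("PS_initial", "VGP_initial", "PS_14d", "VGP_14d"):
    spec = study_condition_spec(condition, seed=7, noise_sd=3.0)
    frames, truth = make_squeeze_video(spec)
    series = diameter_series(frames, manifest_from_spec(spec))
    idx = analyze_series(series)
    osc = f"{idx.oscillation_freq_hz:.1f} Hz" if idx.oscillation_freq_hz else "-"
    print(
        f"{condition:<14} {idx.mean_squeezed_diameter_mm:>11.2f} mm"
        f" {idx.residual_diameter_mm:>7.2f} mm {osc:>12}"
    )

print(
    "\nSmaller mean diameter = more wettable surface. Biofilm-covered dishes"
    "\n(14 d) squeeze to small diameters and recover fully (residual 0); the"
    "\nbare dish stays dry (residual = plateau) and the plasma-treated dish"
    "\noscillates near 6 Hz while partially recovering."
)
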