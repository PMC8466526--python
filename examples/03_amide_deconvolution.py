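"""Amide-I secondary-structure deconvolution on constructed profiles.

Builds noiseless five-Gaussian amide-I profiles whose alpha-helix /
beta-sheet area ratios are programmed to the four reference group compositions,
runs the full deconvolution procedure on each, and prints the recovered
ratio next to the programmed one.
"""

from cosanftirm import deconvolve_amide_i, reference_amide_profile

GROUPS = [("GIC7 control", 2.37), ("GIC7 200uM", 1.26),
          ("PG88 control", 10.62), ("PG88 200uM", 7.19)]

print(f"{'group':14s} {'programmed':>10s} {'recovered':>10s} {'SSE':>9s}")
for name, programmed in GROUPS:
    res = deconvolve_amide_i(reference_amide_profile(programmed))
    print(f"{name:14s} {programmed:10.2f} {res.ratio_alpha_beta:10.2f} "
          f"{res.sum_sq_error:9.2g}")
# the recovered ratio is the fitted area(alpha-helix)/area(beta-sheet);
# SSE is the squared misfit of the five-Gaussian model to the
# baseline-corrected, unit-normalized profile
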