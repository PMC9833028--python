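"""Full image-based quantification: calibration, standard curve, and LOD.

Generates a noisy synthetic dilution series, renders every replicate as a
developed droplet, reads the images back (inverse-blue intensity), converts
to OD through a render-derived calibration curve, fits the linear standard
curve, and estimates the limit of detection as 3.3*sd(blanks)/slope.
"""

import warnings

warnings.simplefilter("ignore")  # out-of-range clamp notices on deep blanks

from mdmsim.workflow import calibration_from_renders, standard_curve_experiment

calibration = calibration_from_renders()
print(f"calibration: {len(calibration.knots)} knots over inverse-blue "
      f"{calibration.valid_range[0]:.0f}-{calibration.valid_range[1]:.0f}")

res = standard_curve_experiment(seed=12, calibration=calibration)
lo, hi = res.curve.slope_ci()
print(f"fitted slope   : {res.curve.slope:.4f} OD per conc unit "
      f"(95% CI {lo:.4f}-{hi:.4f})")
print(f"true slope     : {res.truth['design_slope']:.4f}")
print(f"R^2            : {res.curve.r_squared:.4f}")
print(f"LOD            : {res.lod.lod:.3f} conc units "
      f"(analytic {res.truth['analytic_lod']:.3f})")
print(f"LOD provenance : method={res.lod.method}, blank sd={res.lod.blank_sd:.4f}, "
      f"n_blanks={res.lod.n_blanks}")
# the fitted slope CI covers the generating slope. A single seed's LOD
# scatters around the analytic value (the blank sd is estimated from 8
# replicates, so its relative sd is ~27%); averaged over 100 seeds the
# pipeline LOD lands within a few percent of 3.3*noise_sd/slope.
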