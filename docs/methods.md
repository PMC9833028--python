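# Methods

This note records the models behind `mdmsim`, the calibrated constants and
their provenance, what the synthetic data do and do not emulate, and the
design choices made where the design was genuinely open.

## Chip and motion model

A chip is a set of identical units, each a serpentine path of nine
microwells joined by eight microchannels, with a keypoint map tying the
magnet controller's nine x/y stations to well centers. Coordinates are in
mm, unit-local, origin at the unit's lower-left corner, y up; the built-in
chip places four 30×30 mm units on a 60×60 mm footprint. Wells 1–7 are
⌀ 6 mm / 30 µL, well 8 is ⌀ 7 mm / 50 µL (the uncoated observation window
used for optical readout), well 9 is ⌀ 4 mm / 10 µL.

Channel widths are not fully specified per well pair in the source
documentation of such chips; only two exemplar widths exist (1.3 mm
"wide", 0.6 mm "narrow"). The built-in layout assigns narrow to every
channel except 8–9, which is wide: the workflow must extract beads at
every forward transfer, while the small stop-solution droplet must be
dragged bodily back from well 9 to well 8. The assignment is data, not
code — a layout file can override it.

The magnet grid has four vertical layers (T/N/M/B). Lateral motion is free
in NEUTRAL (field too weak to disturb droplets), allowed in BOTTOM only
along a microchannel, and forbidden in TOP/MEZZANINE; layer changes happen
vertically at one keypoint. The validator enforces these rules statically;
a protocol that validates cleanly executes without transition errors.

The duration model sums incubation and hold times, keypoint-to-keypoint
travel at the commanded speed, and 18 s per standalone mixing cycle;
cycles embedded in an incubation are assumed to fit inside it. With these
rules the built-in protocol takes 2715 s ≈ 45 min, matching the platform's
advertised turnaround; the 18 s/cycle figure comes from the mixing anchor
(3 cycles ≈ 54 s) and therefore includes magnet travel overhead.

## Droplet engine

Droplet footprints use the spherical-cap identity
V = (πR³/3)(1 − cos θ)²(2 + cos θ) at a default contact angle of 150°
(superhydrophobic coating); for θ > 90° the planform width is the sphere
diameter 2R. This reproduces the two documented droplet sizes (10 µL →
2.68 mm, 30 µL → 3.87 mm, quoted as ~2.5 and ~3.7 mm).

A BOTTOM traversal classifies as droplet passage when
channel_width / droplet_diameter ≥ r_pass, bead extraction otherwise. The
default r_pass = 0.35 sits centrally in the band (≈0.24–0.52) consistent
with both documented operating points. Merging is additive in volume and
species; the merged droplet's homogeneity resets to 0 (a dye droplet
entering water is the canonical unmixed state) and its OD is the
volume-weighted mean of the parents — a choice the source leaves open; any
rule monotone in both parents would serve.

Bead extraction draws survivors from Binomial(n, p_retain). The default
p_retain = 0.78^(1/8) ≈ 0.96942 is *calibrated*: the built-in workflow
performs eight extractions (wells 1→2→…→8→9) and the platform reports
~78% overall retention at 1 mm/s. Each extraction also carries 0.5 µL of
liquid with the cluster (the true value is undocumented; it is logged
explicitly so volume conservation stays exactly auditable, and it is
user-overridable). Beads must be clustered — a TOP/BOTTOM hold of ≥ 1 s —
before a traversal can move them; the built-in protocol holds 20 s before
every extraction, the documented figure for the first one. Mixing
disperses the cluster.

One seeded `numpy` generator drives each run, with binomial draws in step
order, so identical (layout, protocol, seed) give identical states and
logs. Conservation is exact, not approximate: liquid never leaves the
chip, and beads lost at an extraction remain (implicitly) in the source
droplet and are logged.

## Mixing mathematics and kinetics

The mixing index M is the population standard deviation (divisor N, as the
definition prints) of blue-channel pixel intensities in the droplet ROI.
Homogeneity H = 1 − (M_c − M_f)/(M_i − M_f) is clamped to [0, 1] because
sensor noise can push M_c slightly past either reference. M_i is the
high-variability unmixed reference and M_f the fully-mixed one; the
normalization is affine-invariant in the three indices.

Dynamics use exponential residual decay, the simplest model consistent
with the normalization (any exponentially relaxing M_c maps to
H(t) = 1 − e^(−t/τ)). Two printed anchors fix the two constants:
H = 0.95 after 3 active cycles gives ρ = 0.05^(1/3) ≈ 0.3684 per cycle,
and 700 s to the same homogeneity passively gives τ = 700/ln 20 ≈ 233.7 s.
Both are exposed in `MixingParams`. Active inversion reports whole cycles
(ceiling, with a 1e-9 tolerance so the anchor lands on exactly 3) at
18 s/cycle.

## Synthetic assay and imaging

Binding is an equilibrium Langmuir isotherm (incubations are long relative
to typical immunoassay kinetics and no rate constants are documented);
development is linear in bound enzyme, time, and bead retention; replicate
noise is homoscedastic Gaussian on OD. Defaults (k_half = 500, capacity =
1, dev_rate = 12.8 OD/amount/min, dev_time = 5 min, noise_sd = 0.02 OD,
blank = 0.05 OD) put the default dilution series (0–8 concentration
units) in the gently-saturating regime with a low-concentration slope of
~0.1 OD per unit — a realistic colourimetric ELISA operating window whose
ODs stay inside the camera's calibrated range.

The renderer is an explicit stand-in for the platform camera, whose true
response is not documented: blue attenuation B = illumination·10^(−g·OD)
with illumination 235 and gain g = 1, red/green held at the illumination
level (developed droplets look yellow), whitish coating at 248, seeded
Gaussian sensor noise, 8-bit quantization, no gamma. The calibration stage
exists precisely to absorb whatever the response is, so none of the
quantification results depend on these constants — only on the response
being monotone.

Mixing image sequences draw ROI pixels as mean + M(t)·z with z
standardized exactly, so the pre-quantization index equals its target;
M(t) relaxes from 30 to 3 intensity units.

What the synthetic data do **not** emulate: real droplet photographs
(segmentation is out of scope; ROIs are given), non-uniform illumination,
heteroscedastic or drifting assay noise, bead-surface chemistry, and
instrument-specific concentration scales. Passing tests therefore
demonstrate that the pipeline is faithful to its own generating model —
parameter recovery — not that any particular clinical LOD is reproduced.
The platform's published per-analyte LODs depend on instrument dilution
series available only as figures, so they are out of reach of a desk
reproduction; the recovery properties stand in for them.

## Quantification

Calibration (inverse-blue → OD, one curve per unit to tolerate non-uniform
illumination) is fitted assumption-light: isotonic regression enforces
monotonicity, the resulting knots are joined piecewise-linearly, and
queries outside the fitted range clamp to the end knots. With a 0.05-OD
knot grid the piecewise-linear error against the logarithmic camera
response is far below 1%.

QC reads the documented exclusion rule literally: a reading is excluded
iff its inverse-blue value is strictly below 140 (139 is excluded, 140
kept).

Standard curves are ordinary least squares of OD on concentration
(residual sd with n − 2). The LOD rule is the ICH-style
3.3·sd(blanks)/slope with sample sd (ddof = 1), tagged
`"3.3sigma_slope"` in the estimate so alternative rules (3σ,
calibration-based) remain comparable. For recovery experiments the slope
estimand is the OLS slope of the *noiseless* ODs on the same design — the
right target for a linear pipeline over a slightly saturating binding
curve — and blanks get 8 replicates for a stable LOD denominator.

## Problem sizes and numerical choices

The retention study uses 1,000 seeded runs of the full protocol with
10,000 beads (standard error of the mean retention ≈ 1.4×10⁻⁴); recovery
experiments use 100 seeds with a shared noise-free calibration, rendering
single-unit crops at 5 px/mm (the camera response is position-independent,
so crops read identically to full-chip renders at a fraction of the
cost). Slope-CI coverage is asserted at ≥ 88/100, three binomial standard
deviations below the nominal 95%. Per-run seeds derive from one
`SeedSequence` and stay below 2³¹.

## Known limitations

- The engine tracks one representative unit; the four magnets are
  mechanically synchronous, so per-unit differences (the reason for
  per-unit calibration curves on the real instrument) arise only in the
  imaging/calibration layer, not in droplet handling.
- Bead-bound species (capture/analyte/enzyme amounts) are carried but the
  engine does not yet couple them to the assay model's development step;
  developed OD is stamped onto the final droplet when rendering a run.
- The substrate development time is undocumented; the built-in protocol
  defaults to 300 s, and the substrate volume defaults to 50 µL (its two
  documented mentions disagree, 40 vs 50 µL; both are overridable).
- No droplet splitting, evaporation, or pinning physics; no magnetic
  field computation (the documented field strengths are treated as
  constants).
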