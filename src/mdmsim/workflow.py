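"""Sample-in-answer-out pipelines binding the simulator to quantification.

These are the compositions a user of the platform actually runs:

* :func:`simulate_run` — validate, simulate a protocol, render the final
  chip photo, read every observation-window ROI, and quantify.
* :func:`calibration_from_renders` — build a unit's inverse-blue -> OD
  calibration curve by rendering droplets of known OD, exactly the way the
  physical instrument is calibrated with a spectrophotometer-verified
  dilution series.
* :func:`standard_curve_experiment` — full synthetic recovery experiment:
  generate a noisy dilution series, render each replicate droplet, read the
  images, calibrate intensities back to OD, fit the standard curve and LOD.
* :func:`mixing_recovery_experiment` — generate a mixing image sequence with
  a known time constant and re-estimate it through the image pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assay import (
    AssayParams,
    DEFAULT_ASSAY_PARAMS,
    dataset_manifest,
    generate_mixing_image_sequence,
    generate_standard_curve_dataset,
    linear_regime_slope,
)
from .chip import ChipLayout, builtin_elisa_layout, validate_layout
from .engine import (
    ChipState,
    DEFAULT_ENGINE_PARAMS,
    EngineParams,
    EventLog,
    run_protocol,
    retention_summary,
)
from .errors import MdmError
from .imaging import (
    ImageFrame,
    ROI,
    droplet_reading,
    fit_passive_tau,
    mixing_curve_from_images,
    render_chip,
    roi_for_well,
)
from .mixing import DEFAULT_TAU
from .protocol import Protocol, builtin_elisa_protocol, validate_protocol
from .quant import (
    CalibrationCurve,
    QCRule,
    apply_calibration,
    compute_lod,
    fit_calibration,
    fit_standard_curve,
)

DEFAULT_PX_PER_MM = 5.0


# ---------------------------------------------------------------------------
# simulate -> render -> read

@dataclass
class RunArtifacts:
    state: ChipState
    log: EventLog
    frame: ImageFrame
    readings: pd.DataFrame
    retention: float


def simulate_run(layout: ChipLayout | None = None, protocol: Protocol | None = None, *,
                 seed: int = 0, initial_beads: int = 10_000,
                 params: EngineParams = DEFAULT_ENGINE_PARAMS,
                 sample_od: float | None = None,
                 render_noise_sd: float = 1.0,
                 px_per_mm: float = DEFAULT_PX_PER_MM) -> RunArtifacts:
    """Validate and execute a protocol, then photograph and read the chip.

    ``sample_od`` optionally stamps a developed optical density on the final
    observation-well droplet before rendering (the engine tracks liquid
    handling, not enzyme kinetics, so the developed colour is an input
    here). Readings cover each unit's observation-window wells.
    """
    layout = layout or builtin_elisa_layout()
    protocol = protocol or builtin_elisa_protocol()
    issues = validate_layout(layout)
    if issues:
        raise MdmError("invalid layout: " + "; ".join(issues))
    issues = validate_protocol(protocol, layout)
    if issues:
        raise MdmError("invalid protocol: " + "; ".join(issues))

    state, log = run_protocol(layout, protocol, seed=seed,
                              initial_beads=initial_beads, params=params)
    if sample_od is not None and state.beads is not None:
        final_well = state.beads.location
        if final_well in state.droplets:
            state.droplets[final_well].od = sample_od
    frame = render_chip(state, layout, noise_sd=render_noise_sd,
                        seed=seed, px_per_mm=px_per_mm)
    rows = []
    for unit in layout.units:
        for well in unit.wells:
            if not well.observation_window:
                continue
            roi = roi_for_well(layout, unit.index, well.id, px_per_mm=px_per_mm)
            r = droplet_reading(frame, roi, unit=unit.index, well=well.id)
            rows.append({"unit": r.unit, "well": r.well, "mean_b": r.mean_b,
                         "inv_b": r.inv_b})
    return RunArtifacts(state=state, log=log, frame=frame,
                        readings=pd.DataFrame(rows),
                        retention=retention_summary(log))


# ---------------------------------------------------------------------------
# calibration by rendering known ODs

def _single_unit_view(layout: ChipLayout, unit_index: int) -> ChipLayout:
    """A one-unit crop of a layout (same geometry, origin reset to 0)."""
    from dataclasses import replace

    unit = replace(layout.unit(unit_index), origin=(0.0, 0.0))
    return ChipLayout(units=[unit], footprint=unit.size,
                      schema_version=layout.schema_version)


def _render_od_reading(od: float, layout: ChipLayout, *, unit_index: int = 1,
                       well_id: int = 8, noise_sd: float = 0.0,
                       seed: int | None = None,
                       px_per_mm: float = DEFAULT_PX_PER_MM) -> float:
    """Render one droplet of known OD in an observation well; return inv_b.

    Renders a single-unit crop of the layout: the camera response is
    position-independent, so the reading matches a full-chip render while
    costing a fraction of the pixels.
    """
    view = _single_unit_view(layout, unit_index)
    state = ChipState(unit_index=unit_index)
    state.new_droplet(well_id, 50.0, od=od)
    frame = render_chip(state, view, noise_sd=noise_sd, seed=seed,
                        px_per_mm=px_per_mm)
    roi = roi_for_well(view, unit_index, well_id, px_per_mm=px_per_mm)
    return droplet_reading(frame, roi, unit=unit_index, well=well_id).inv_b


def calibration_from_renders(od_grid=None, layout: ChipLayout | None = None, *,
                             unit_index: int = 1, noise_sd: float = 0.0,
                             seed: int | None = None,
                             px_per_mm: float = DEFAULT_PX_PER_MM) -> CalibrationCurve:
    """Build a unit's calibration curve from rendered droplets of known OD.

    The default OD grid spans 0-1.2 finely enough that piecewise-linear
    interpolation of the logarithmic camera response stays well under 1%.
    """
    layout = layout or builtin_elisa_layout()
    if od_grid is None:
        od_grid = np.round(np.arange(0.0, 1.21, 0.05), 3)
    pairs = []
    for od in od_grid:
        inv_b = _render_od_reading(float(od), layout, unit_index=unit_index,
                                   noise_sd=noise_sd, seed=seed, px_per_mm=px_per_mm)
        pairs.append((inv_b, float(od)))
    return fit_calibration(pairs, unit=unit_index)


# ---------------------------------------------------------------------------
# end-to-end standard-curve recovery

@dataclass
class StandardCurveResult:
    dataset: pd.DataFrame
    curve: "object"
    lod: "object"
    truth: dict
    readings: pd.DataFrame = field(default_factory=pd.DataFrame)


def standard_curve_experiment(*, seed: int = 0,
                              concentrations=(0.0, 0.5, 1.0, 2.0, 4.0, 8.0),
                              replicates: int = 3, blank_replicates: int = 8,
                              params: AssayParams = DEFAULT_ASSAY_PARAMS,
                              retention: float = 0.78,
                              calibration: CalibrationCurve | None = None,
                              layout: ChipLayout | None = None,
                              render_noise_sd: float = 0.0,
                              px_per_mm: float = DEFAULT_PX_PER_MM) -> StandardCurveResult:
    """Simulate a dilution series, push every replicate through the imaging
    path, and recover the standard curve and LOD.

    Each replicate's true noisy OD is rendered as a developed droplet in an
    observation well, read back as inverse-blue intensity, converted to OD
    through the calibration curve, and only then fitted — so the result
    carries the full render/read/calibrate error budget, not just the
    generator's noise. Blanks get extra replicates (``blank_replicates``)
    for a stable LOD denominator.
    """
    layout = layout or builtin_elisa_layout()
    if calibration is None:
        calibration = calibration_from_renders(layout=layout, px_per_mm=px_per_mm)

    dataset = generate_standard_curve_dataset(concentrations, replicates,
                                              params=params, seed=seed,
                                              retention=retention)
    # extra blank replicates beyond the dataset's own
    rng = np.random.default_rng([seed, 0xB1A2])  # stream disjoint from the dataset's
    blank_true = dataset.loc[dataset.concentration == 0.0, "od_true"].iloc[0]
    extra = max(0, blank_replicates - (dataset.concentration == 0.0).sum())
    extra_rows = [{
        "concentration": 0.0,
        "replicate": replicates + i + 1,
        "unit": (i % len(layout.units)) + 1,
        "od_true": blank_true,
        "od": blank_true + rng.normal(0.0, params.noise_sd),
    } for i in range(extra)]
    if extra_rows:
        dataset = pd.concat([dataset, pd.DataFrame(extra_rows)], ignore_index=True)

    recovered = []
    for i, row in dataset.iterrows():
        inv_b = _render_od_reading(float(row.od), layout,
                                   noise_sd=render_noise_sd,
                                   seed=None if render_noise_sd == 0 else seed * 100_003 + i,
                                   px_per_mm=px_per_mm)
        recovered.append(apply_calibration(calibration, inv_b))
    dataset = dataset.assign(inv_b=np.nan, od_recovered=recovered)

    curve = fit_standard_curve(dataset.concentration, dataset.od_recovered)
    blanks = dataset.loc[dataset.concentration == 0.0, "od_recovered"]
    lod = compute_lod(curve, blanks)
    truth = dataset_manifest(params, retention, seed)
    # the estimand of a *linear* pipeline over a slightly saturating binding
    # curve is the noiseless OLS slope on the same design, not the c->0 limit
    noiseless = fit_standard_curve(dataset.concentration, dataset.od_true)
    truth["design_slope"] = noiseless.slope
    truth["analytic_lod"] = 3.3 * params.noise_sd / noiseless.slope
    return StandardCurveResult(dataset=dataset, curve=curve, lod=lod, truth=truth)


# ---------------------------------------------------------------------------
# mixing-curve recovery

def mixing_recovery_experiment(tau: float = DEFAULT_TAU, *, seed: int = 0,
                               frame_times=None) -> dict:
    """Generate a seeded mixing image sequence and re-estimate tau from it."""
    if frame_times is None:
        frame_times = np.linspace(0.0, 2.5 * tau, 14)
    frames, mi_frame, mf_frame, roi, manifest = generate_mixing_image_sequence(
        tau, frame_times, seed=seed)
    curve = mixing_curve_from_images(frames, roi, mi_frame, mf_frame)
    tau_hat = fit_passive_tau(curve)
    return {"tau_true": tau, "tau_recovered": tau_hat,
            "relative_error": abs(tau_hat - tau) / tau,
            "curve": curve, "manifest": manifest}


# ---------------------------------------------------------------------------
# retention study (the headline stochastic figure)

def retention_study(n_runs: int = 1000, *, initial_beads: int = 10_000,
                    seed: int = 0, params: EngineParams = DEFAULT_ENGINE_PARAMS,
                    layout: ChipLayout | None = None,
                    protocol: Protocol | None = None) -> dict:
    """Mean bead retention of the built-in workflow over many seeded runs."""
    layout = layout or builtin_elisa_layout()
    protocol = protocol or builtin_elisa_protocol()
    seeds = np.random.SeedSequence(seed).generate_state(n_runs) % (2 ** 31)
    fractions = np.empty(n_runs)
    for i, s in enumerate(seeds):
        _, log = run_protocol(layout, protocol, seed=int(s),
                              initial_beads=initial_beads, params=params)
        fractions[i] = retention_summary(log)
    mean = float(fractions.mean())
    return {
        "n_runs": n_runs,
        "initial_beads": initial_beads,
        "mean_retention": mean,
        "sd_retention": float(fractions.std(ddof=1)),
        "se_mean": float(fractions.std(ddof=1) / np.sqrt(n_runs)),
        "expected_retention": params.p_retain ** 8,
    }
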