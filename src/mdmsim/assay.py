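"""Synthetic bead-ELISA signal model and fixture generators.

Everything downstream of the simulator (rendering, calibration, standard
curves, LOD) is exercised on data produced here, so no external dataset is
needed. The signal model is deliberately minimal:

* binding is an equilibrium Langmuir isotherm — the bound amount per bead
  population is ``capacity * c / (c + K_half)``;
* colour development is linear in bound enzyme, development time, and the
  fraction of beads that survived the workflow:
  ``OD = blank + dev_rate * dev_time * bound * retention``;
* replicate noise is additive Gaussian on OD.

The generators are fully seeded, and each dataset/image sequence ships a
manifest of its true parameters so tests can check parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .imaging import ImageFrame, ROI


@dataclass(frozen=True)
class AssayParams:
    """Signal-model constants.

    ``k_half``    half-saturation analyte concentration (concentration units).
    ``capacity``  maximum bound amount per bead population (arbitrary units).
    ``dev_rate``  OD produced per bound-enzyme amount per minute.
    ``dev_time``  development time in minutes.
    ``noise_sd``  per-replicate Gaussian OD noise.
    ``blank_od_mean``  OD of a blank (no-analyte) droplet.
    """

    k_half: float = 500.0
    capacity: float = 1.0
    dev_rate: float = 12.8
    dev_time: float = 5.0
    noise_sd: float = 0.02
    blank_od_mean: float = 0.05

    def __post_init__(self):
        if self.k_half <= 0:
            raise ValueError("k_half must be > 0")
        for name in ("capacity", "dev_rate", "dev_time", "noise_sd", "blank_od_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


DEFAULT_ASSAY_PARAMS = AssayParams()


def simulate_binding(conc: float, params: AssayParams = DEFAULT_ASSAY_PARAMS) -> float:
    """Equilibrium bound amount at analyte concentration ``conc`` (Langmuir)."""
    if conc < 0:
        raise ValueError("concentration must be >= 0")
    return params.capacity * conc / (conc + params.k_half)


def simulate_development(bound: float, retention: float,
                         params: AssayParams = DEFAULT_ASSAY_PARAMS) -> float:
    """Developed OD: blank plus a term linear in bound enzyme and bead retention."""
    if bound < 0 or retention < 0:
        raise ValueError("bound amount and retention must be >= 0")
    return params.blank_od_mean + params.dev_rate * params.dev_time * bound * retention


def linear_regime_slope(params: AssayParams = DEFAULT_ASSAY_PARAMS,
                        retention: float = 0.78) -> float:
    """d(OD)/d(conc) in the low-concentration limit (conc << k_half)."""
    return params.dev_rate * params.dev_time * params.capacity * retention / params.k_half


def generate_standard_curve_dataset(concentrations, replicates: int,
                                    params: AssayParams = DEFAULT_ASSAY_PARAMS,
                                    seed: int = 0, retention: float = 0.78,
                                    n_units: int = 4) -> pd.DataFrame:
    """Simulated serial-dilution dataset: one noisy OD per (concentration, replicate).

    Columns: concentration, replicate, unit, od_true, od. Concentration 0
    rows (blanks) are appended if absent so LOD estimation always has blank
    replicates. Identical seeds give identical tables.
    """
    concs = sorted(set(float(c) for c in concentrations))
    if len(concs) < 2:
        raise ValueError("need at least 2 distinct concentrations")
    if any(c < 0 for c in concs):
        raise ValueError("concentrations must be >= 0")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if 0.0 not in concs:
        concs = [0.0] + concs
    rng = np.random.default_rng(seed)
    rows = []
    for conc in concs:
        od_true = simulate_development(simulate_binding(conc, params), retention, params)
        for rep in range(1, replicates + 1):
            od = od_true + rng.normal(0.0, params.noise_sd)
            rows.append({
                "concentration": conc,
                "replicate": rep,
                "unit": ((rep - 1) % n_units) + 1,
                "od_true": od_true,
                "od": od,
            })
    return pd.DataFrame(rows)


def dataset_manifest(params: AssayParams, retention: float, seed: int) -> dict:
    """True generating parameters of a dataset (for tests and provenance)."""
    return {
        "params": asdict(params),
        "retention": retention,
        "seed": seed,
        "linear_slope": linear_regime_slope(params, retention),
        "analytic_lod": 3.3 * params.noise_sd / linear_regime_slope(params, retention),
    }


# ---------------------------------------------------------------------------
# mixing image sequences

def generate_mixing_image_sequence(tau: float, frame_times, *,
                                   seed: int = 0, size_px: int = 96,
                                   roi_radius_px: int = 36,
                                   m_initial: float = 30.0, m_final: float = 3.0,
                                   mean_blue: float = 128.0):
    """Synthetic droplet-ROI frame sequence whose blue-channel mixing index
    relaxes exponentially from ``m_initial`` toward ``m_final`` with time
    constant ``tau`` seconds.

    Pixel noise inside the ROI is rescaled to hit the target index exactly
    before 8-bit quantization, so the only recovery error downstream is the
    quantizer's. Returns ``(frames, mi_frame, mf_frame, roi, manifest)``.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    rng = np.random.default_rng(seed)
    c = size_px / 2.0
    roi = ROI(cx=c, cy=c, radius=roi_radius_px, label="droplet")

    def frame_with_index(m_target: float, t: float | None) -> ImageFrame:
        img = np.full((size_px, size_px, 3), 220.0)
        yy, xx = np.ogrid[:size_px, :size_px]
        mask = (xx - c) ** 2 + (yy - c) ** 2 <= roi_radius_px ** 2
        n = int(mask.sum())
        z = rng.normal(size=n)
        z = (z - z.mean()) / z.std()  # exact zero mean, unit population sd
        img[mask, 2] = mean_blue + m_target * z
        img[mask, 0] = mean_blue + 40.0
        img[mask, 1] = mean_blue + 30.0
        meta = {"target_M": m_target}
        if t is not None:
            meta["time_s"] = float(t)
        return ImageFrame(pixels=np.clip(np.rint(img), 0, 255).astype(np.uint8),
                          metadata=meta)

    mi_frame = frame_with_index(m_initial, None)
    mf_frame = frame_with_index(m_final, None)
    frames = []
    for t in frame_times:
        m_t = m_final + (m_initial - m_final) * np.exp(-float(t) / tau)
        frames.append(frame_with_index(m_t, t))
    manifest = {"tau_s": tau, "m_initial": m_initial, "m_final": m_final,
                "mean_blue": mean_blue, "seed": seed,
                "frame_times": [float(t) for t in frame_times]}
    return frames, mi_frame, mf_frame, roi, manifest
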