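"""Mixing index, homogeneity, and calibrated mixing dynamics.

The mixing state of a droplet is scored from an image: the *mixing index*
M is the population standard deviation of the blue-channel pixel
intensities inside the droplet ROI,

    M = sqrt( (1/N) * sum_b (I_b - Ibar)^2 ),

and *homogeneity* normalizes it between two reference states,

    H = 1 - (M_c - M_f) / (M_i - M_f),

where M_i is the index of the unmixed reference and M_f that of a fully
mixed droplet, so H runs from 0 (unmixed) to 1 (fully mixed). H is clamped
to [0, 1] because camera noise can push M_c slightly outside [M_f, M_i].

Dynamics are modelled as exponential residual decay, which Eq.-style
normalization maps onto H directly: active bead agitation multiplies the
residual (1 - H) by ``rho`` per mixing cycle; passive diffusion decays it
with time constant ``tau``. The defaults are calibrated to two observed
anchors — H > 0.95 after 3 active cycles (~54 s), and ~700 s to the same
homogeneity by diffusion alone — giving rho = 0.05^(1/3) and
tau = 700 / ln 20.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateReferenceError

#: Per-cycle residual factor: three cycles leave a residual of 0.05.
DEFAULT_RHO = 0.05 ** (1.0 / 3.0)
#: Passive relaxation time constant (s): 700 s to a residual of 0.05.
DEFAULT_TAU = 700.0 / math.log(20.0)
#: Seconds per active mixing cycle (travel included).
MIX_CYCLE_SECONDS = 18.0


@dataclass(frozen=True)
class MixingParams:
    rho: float = DEFAULT_RHO
    tau: float = DEFAULT_TAU

    def __post_init__(self):
        if not 0.0 < self.rho < 1.0:
            raise ValueError(f"rho must be in (0,1), got {self.rho}")
        if self.tau <= 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")


DEFAULT_PARAMS = MixingParams()


def mixing_index(intensities) -> float:
    """Population standard deviation (divisor N) of pixel intensities."""
    arr = np.asarray(intensities, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("mixing_index needs at least one pixel")
    return float(np.std(arr, ddof=0))


def homogeneity(m_c: float, m_i: float, m_f: float) -> float:
    """Normalized mixing progress between the two reference indices, clamped to [0,1]."""
    if m_i == m_f:
        raise DegenerateReferenceError(
            f"reference indices coincide (M_i = M_f = {m_i}); homogeneity undefined")
    h = 1.0 - (m_c - m_f) / (m_i - m_f)
    return min(1.0, max(0.0, h))


def advance_active(h: float, cycles: int, params: MixingParams = DEFAULT_PARAMS) -> float:
    """Homogeneity after ``cycles`` agitation cycles: residual shrinks by rho per cycle."""
    if cycles < 0:
        raise ValueError("cycles must be >= 0")
    if cycles == 0:
        return h
    return 1.0 - (1.0 - h) * params.rho ** cycles


def advance_passive(h: float, dt: float, params: MixingParams = DEFAULT_PARAMS) -> float:
    """Homogeneity after ``dt`` seconds of diffusion-only relaxation."""
    if dt < 0:
        raise ValueError("dt must be >= 0")
    if dt == 0.0:
        return h
    return 1.0 - (1.0 - h) * math.exp(-dt / params.tau)


def cycles_to_homogeneity(target: float, params: MixingParams = DEFAULT_PARAMS) -> int:
    """Smallest whole number of active cycles reaching homogeneity >= target."""
    if not 0.0 <= target < 1.0:
        raise ValueError(f"target homogeneity must be in [0,1), got {target}")
    if target == 0.0:
        return 0
    exact = math.log(1.0 - target) / math.log(params.rho)
    # tolerate float error when the anchor lands exactly on an integer
    return max(0, math.ceil(exact - 1e-9))


def time_to_homogeneity(target: float, mode: str,
                        params: MixingParams = DEFAULT_PARAMS,
                        cycle_seconds: float = MIX_CYCLE_SECONDS) -> float:
    """Seconds to reach homogeneity ``target`` from 0.

    ``mode`` is "active" (whole mixing cycles, ceiling, at ``cycle_seconds``
    each) or "passive" (continuous diffusion time). ``target`` must be < 1:
    exponential relaxation never quite arrives.
    """
    if target >= 1.0:
        raise ValueError("homogeneity 1.0 is unreachable under exponential relaxation")
    if not 0.0 <= target:
        raise ValueError(f"target must be in [0,1), got {target}")
    if mode == "active":
        return cycles_to_homogeneity(target, params) * cycle_seconds
    if mode == "passive":
        if target == 0.0:
            return 0.0
        return -params.tau * math.log(1.0 - target)
    raise ValueError(f"mode must be 'active' or 'passive', got {mode!r}")
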