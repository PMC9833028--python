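"""Calibration curves, QC filtering, standard curves, and LOD.

The camera's intensity response to optical density is nonlinear, so each
chip unit gets its own calibration curve mapping inverse-blue intensity
(255 - B) to OD, built from droplets of known OD. The curve is fitted
assumption-light: an isotonic regression enforces monotonicity, and the
resulting knots are joined piecewise-linearly; queries outside the fitted
range clamp to the end knots rather than extrapolate.

Sample quantification then follows plate-reader practice: readings whose
inverse-blue value falls strictly below the negative-control threshold
(default 140) are excluded, calibrated ODs are regressed linearly on
concentration, and the detection limit is the ICH-style
LOD = 3.3 * sd(blanks) / slope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.isotonic import IsotonicRegression

from .errors import QuantificationError
from .imaging import DropletReading


@dataclass
class CalibrationCurve:
    """Monotone piecewise-linear inverse-blue -> OD mapping for one unit."""

    unit: int
    knots: list[tuple[float, float]]  # (inv_b, od), strictly increasing inv_b

    @property
    def valid_range(self) -> tuple[float, float]:
        return (self.knots[0][0], self.knots[-1][0])

    def to_dict(self) -> dict:
        return {"unit": self.unit, "knots": [list(k) for k in self.knots]}

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        return cls(unit=d["unit"], knots=[tuple(k) for k in d["knots"]])


def fit_calibration(pairs, unit: int = 1) -> CalibrationCurve:
    """Fit a unit's calibration curve from (inv_b, OD) observations.

    Requires at least 3 pairs with distinct inv_b values. OD values are
    isotonic-regressed against inv_b (pool-adjacent-violators), which
    guarantees a monotone non-decreasing mapping; a warning is emitted when
    the monotonicity correction moves any OD by more than 1e-6.
    """
    pts = sorted((float(ib), float(od)) for ib, od in pairs)
    if len(pts) < 3:
        raise QuantificationError(f"need at least 3 calibration pairs, got {len(pts)}")
    inv_b = np.array([p[0] for p in pts])
    od = np.array([p[1] for p in pts])
    if len(np.unique(inv_b)) < 3:
        raise QuantificationError("need at least 3 distinct inv_b values")
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    od_fit = iso.fit_transform(inv_b, od)
    if np.max(np.abs(od_fit - od)) > 1e-6:
        warnings.warn("calibration data were not monotone; isotonic correction applied",
                      stacklevel=2)
    # collapse duplicate inv_b values (isotonic fit averages their ODs)
    knots: list[tuple[float, float]] = []
    for x, y in zip(inv_b, od_fit):
        if knots and knots[-1][0] == x:
            continue
        knots.append((float(x), float(y)))
    return CalibrationCurve(unit=unit, knots=knots)


def apply_calibration(curve: CalibrationCurve, inv_b: float) -> float:
    """Map an inverse-blue value to OD along the piecewise-linear curve.

    Values outside the fitted range clamp to the end knots (with a warning):
    the curve never extrapolates beyond its evidence.
    """
    lo, hi = curve.valid_range
    if inv_b < lo or inv_b > hi:
        warnings.warn(f"inv_b {inv_b:.2f} outside calibrated range [{lo:.2f}, {hi:.2f}]; clamped",
                      stacklevel=2)
    xs = np.array([k[0] for k in curve.knots])
    ys = np.array([k[1] for k in curve.knots])
    return float(np.interp(inv_b, xs, ys))


@dataclass(frozen=True)
class QCRule:
    """Exclude readings indistinguishable from the negative control.

    A reading is excluded iff its inverse-blue value is strictly below the
    threshold.
    """

    inv_b_threshold: float = 140.0

    def __post_init__(self):
        if not 0.0 <= self.inv_b_threshold <= 255.0:
            raise ValueError("threshold must be in [0, 255]")

    def keeps(self, reading: DropletReading) -> bool:
        return reading.inv_b >= self.inv_b_threshold


def qc_filter(readings, rule: QCRule = QCRule()) -> tuple[list, list]:
    """Partition readings into (kept, excluded), preserving input order."""
    kept, excluded = [], []
    for r in readings:
        (kept if rule.keeps(r) else excluded).append(r)
    return kept, excluded


@dataclass(frozen=True)
class StandardCurve:
    """OLS fit of OD against concentration."""

    slope: float
    intercept: float
    residual_sd: float  # sqrt(SSE / (n - 2))
    r_squared: float
    conc_range: tuple[float, float]
    n: int
    slope_stderr: float = float("nan")

    def predict(self, conc: float) -> float:
        return self.slope * conc + self.intercept

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Two-sided confidence interval for the slope (t distribution, n-2 df)."""
        tcrit = stats.t.ppf(0.5 + level / 2.0, self.n - 2)
        return (self.slope - tcrit * self.slope_stderr,
                self.slope + tcrit * self.slope_stderr)

    def to_dict(self) -> dict:
        return {"slope": self.slope, "intercept": self.intercept,
                "residual_sd": self.residual_sd, "r_squared": self.r_squared,
                "conc_range": list(self.conc_range), "n": self.n,
                "slope_stderr": self.slope_stderr}


def fit_standard_curve(concentrations, ods) -> StandardCurve:
    """Ordinary least-squares standard curve; needs >= 2 distinct concentrations."""
    conc = np.asarray(concentrations, dtype=float)
    od = np.asarray(ods, dtype=float)
    if conc.shape != od.shape or conc.ndim != 1:
        raise QuantificationError("concentrations and ODs must be equal-length 1-D")
    if len(np.unique(conc)) < 2:
        raise QuantificationError("need at least 2 distinct concentrations")
    res = stats.linregress(conc, od)
    n = len(conc)
    resid = od - (res.slope * conc + res.intercept)
    residual_sd = float(np.sqrt(np.sum(resid ** 2) / (n - 2))) if n > 2 else float("nan")
    return StandardCurve(slope=float(res.slope), intercept=float(res.intercept),
                         residual_sd=residual_sd, r_squared=float(res.rvalue ** 2),
                         conc_range=(float(conc.min()), float(conc.max())), n=n,
                         slope_stderr=float(res.stderr))


@dataclass(frozen=True)
class LodEstimate:
    """Limit of detection with the inputs that produced it."""

    lod: float
    method: str
    blank_mean: float
    blank_sd: float
    slope: float
    n_blanks: int

    def to_dict(self) -> dict:
        return {"lod": self.lod, "method": self.method, "blank_mean": self.blank_mean,
                "blank_sd": self.blank_sd, "slope": self.slope, "n_blanks": self.n_blanks}


def compute_lod(curve: StandardCurve, blank_ods) -> LodEstimate:
    """LOD = 3.3 * sd(blank ODs) / slope (sample sd, ddof=1)."""
    blanks = np.asarray(blank_ods, dtype=float)
    if blanks.size < 2:
        raise QuantificationError("need at least 2 blank replicates")
    if curve.slope <= 0:
        raise QuantificationError(f"standard-curve slope must be > 0, got {curve.slope}")
    sd = float(np.std(blanks, ddof=1))
    return LodEstimate(lod=3.3 * sd / curve.slope, method="3.3sigma_slope",
                       blank_mean=float(blanks.mean()), blank_sd=sd,
                       slope=curve.slope, n_blanks=int(blanks.size))
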