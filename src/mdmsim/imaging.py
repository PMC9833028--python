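"""Synthetic chip rendering and ROI-based intensity extraction.

The optical readout of the platform is a transilluminated colour photo of
the chip: developed droplets absorb blue light in proportion to their
optical density, so the mean blue-channel value of a droplet ROI falls as
the assay signal rises. This module renders 8-bit RGB frames of a simulated
chip state (a stand-in for the platform camera, with an explicit
Beer-Lambert-style response B = illumination * 10^(-g*OD)) and implements
the measurement side: per-channel ROI means, the inverse-blue statistic
255 - B, and mixing curves from frame sequences.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image

from .chip import ChipLayout
from .engine import ChipState, droplet_footprint_diameter
from .errors import DegenerateReferenceError
from .mixing import homogeneity as _homogeneity
from .mixing import mixing_index

#: Transillumination level reaching the camera through a clear, blank droplet.
DEFAULT_ILLUMINATION = 235.0
#: Whitish superhydrophobic coating as seen by the camera.
COATING_LEVEL = 248
#: Bare well floor (recessed, slightly darker than the coating).
WELL_LEVEL = 240


@dataclass
class ImageFrame:
    """An 8-bit RGB frame plus acquisition metadata (time, scale, ROIs)."""

    pixels: np.ndarray  # (h, w, 3) uint8
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an (h, w, 3) array")
        if self.pixels.dtype != np.uint8:
            raise ValueError("pixels must be uint8")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def save(self, path) -> None:
        Image.fromarray(self.pixels, mode="RGB").save(path)

    @classmethod
    def load(cls, path, **metadata) -> "ImageFrame":
        arr = np.asarray(Image.open(path).convert("RGB"), dtype=np.uint8)
        return cls(pixels=arr, metadata=metadata)


@dataclass
class ROI:
    """A circular region of interest (pixel coordinates), or an explicit mask."""

    cx: float = 0.0
    cy: float = 0.0
    radius: float = 0.0
    mask: np.ndarray | None = None
    label: str = ""

    def mask_for(self, frame: ImageFrame) -> np.ndarray:
        if self.mask is not None:
            if self.mask.shape != frame.pixels.shape[:2]:
                raise ValueError("explicit ROI mask does not match frame shape")
            return self.mask.astype(bool)
        yy, xx = np.ogrid[: frame.height, : frame.width]
        return (xx - self.cx) ** 2 + (yy - self.cy) ** 2 <= self.radius ** 2

    def pixel_values(self, frame: ImageFrame) -> np.ndarray:
        """(n, 3) array of RGB values inside the ROI."""
        m = self.mask_for(frame)
        if not m.any():
            raise ValueError(f"ROI {self.label or '(unnamed)'} selects no pixels")
        return frame.pixels[m].astype(float)

    def to_dict(self) -> dict:
        return {"cx": self.cx, "cy": self.cy, "radius": self.radius, "label": self.label}

    @classmethod
    def from_dict(cls, d: dict) -> "ROI":
        return cls(cx=d["cx"], cy=d["cy"], radius=d["radius"], label=d.get("label", ""))


def write_roi_registry(rois: list[ROI], path) -> None:
    with open(path, "w") as fh:
        json.dump([r.to_dict() for r in rois], fh, indent=1)


def read_roi_registry(path) -> list[ROI]:
    with open(path) as fh:
        return [ROI.from_dict(d) for d in json.load(fh)]


@dataclass(frozen=True)
class DropletReading:
    """Per-channel ROI means and the inverse-blue statistic of one droplet."""

    mean_r: float
    mean_g: float
    mean_b: float
    inv_b: float
    unit: int = 0
    well: int = 0
    label: str = ""


# ---------------------------------------------------------------------------
# rendering

def render_chip(state: ChipState, layout: ChipLayout, *,
                illumination: float = DEFAULT_ILLUMINATION,
                gain: float = 1.0, noise_sd: float = 0.0,
                seed: int | None = None, px_per_mm: float = 5.0) -> ImageFrame:
    """Render a simulated top-down photo of the chip under transillumination.

    Droplets are drawn at their wells with blue-channel attenuation
    ``B = illumination * 10^(-gain * OD)`` (red and green stay at the
    illumination level, so developed droplets look yellow). Coated regions
    are whitish; observation-window wells show the clear illumination level.
    Gaussian sensor noise of ``noise_sd`` counts is added per pixel and
    channel when requested; rendering is deterministic per seed.
    """
    w_px = int(round(layout.footprint[0] * px_per_mm))
    h_px = int(round(layout.footprint[1] * px_per_mm))
    img = np.full((h_px, w_px, 3), float(COATING_LEVEL))

    def disk(cx_mm, cy_mm, r_mm):
        cx, cy = cx_mm * px_per_mm, cy_mm * px_per_mm
        r = r_mm * px_per_mm
        yy, xx = np.ogrid[:h_px, :w_px]
        return (xx - cx) ** 2 + (yy - cy) ** 2 <= r ** 2

    for unit in layout.units:
        for well in unit.wells:
            gx = unit.origin[0] + well.center[0]
            gy = unit.origin[1] + well.center[1]
            level = illumination if well.observation_window else float(WELL_LEVEL)
            img[disk(gx, gy, well.diameter / 2.0)] = level

    # magnets are synchronous, so every unit shows the simulated unit's droplets
    for unit in layout.units:
        for well_id, droplet in state.droplets.items():
            try:
                well = unit.well(well_id)
            except KeyError:
                continue
            gx = unit.origin[0] + well.center[0]
            gy = unit.origin[1] + well.center[1]
            dia = droplet_footprint_diameter(droplet.volume) if droplet.volume > 0 else 0.0
            r_mm = min(dia, well.diameter) / 2.0
            if r_mm <= 0:
                continue
            m = disk(gx, gy, r_mm)
            blue = illumination * 10.0 ** (-gain * droplet.od)
            img[m, 0] = illumination
            img[m, 1] = illumination
            img[m, 2] = blue

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    out = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return ImageFrame(pixels=out, metadata={
        "px_per_mm": px_per_mm, "illumination": illumination, "gain": gain,
        "noise_sd": noise_sd, "seed": seed, "unit": state.unit_index,
    })


def roi_for_well(layout: ChipLayout, unit_index: int, well_id: int,
                 px_per_mm: float = 5.0, radius_fraction: float = 0.35) -> ROI:
    """Circular ROI centered on a well, sized as a fraction of the well diameter.

    The default fraction keeps the ROI well inside the smallest droplet a
    well plausibly holds, so readings do not straddle the droplet edge.
    """
    unit = layout.unit(unit_index)
    well = unit.well(well_id)
    gx = unit.origin[0] + well.center[0]
    gy = unit.origin[1] + well.center[1]
    return ROI(cx=gx * px_per_mm, cy=gy * px_per_mm,
               radius=well.diameter * radius_fraction * px_per_mm,
               label=f"unit{unit_index}/well{well_id}")


# ---------------------------------------------------------------------------
# measurement

def droplet_reading(frame: ImageFrame, roi: ROI, unit: int = 0, well: int = 0) -> DropletReading:
    """Mean R, G, B over the ROI and the inverse-blue statistic 255 - mean(B)."""
    px = roi.pixel_values(frame)
    mean_r, mean_g, mean_b = (float(px[:, c].mean()) for c in range(3))
    return DropletReading(mean_r=mean_r, mean_g=mean_g, mean_b=mean_b,
                          inv_b=255.0 - mean_b, unit=unit, well=well, label=roi.label)


def readings_to_dataframe(readings: list[DropletReading]) -> pd.DataFrame:
    return pd.DataFrame([{
        "unit": r.unit, "well": r.well, "label": r.label,
        "mean_r": r.mean_r, "mean_g": r.mean_g, "mean_b": r.mean_b,
        "inv_b": r.inv_b,
    } for r in readings])


def mixing_curve_from_images(frames: list[ImageFrame], roi: ROI,
                             mi_frame: ImageFrame, mf_frame: ImageFrame) -> pd.DataFrame:
    """Per-frame mixing index and homogeneity from a droplet image sequence.

    ``mi_frame``/``mf_frame`` are reference frames of the unmixed and
    fully-mixed droplet; their blue-channel mixing indices anchor the
    homogeneity normalization. Frame times are taken from each frame's
    ``metadata['time_s']`` (defaults to the frame's position).
    """
    if not frames:
        raise ValueError("need at least one frame")
    m_i = mixing_index(roi.pixel_values(mi_frame)[:, 2])
    m_f = mixing_index(roi.pixel_values(mf_frame)[:, 2])
    if m_i == m_f:
        raise DegenerateReferenceError("reference frames have equal mixing indices")
    rows = []
    for i, frame in enumerate(frames):
        m_c = mixing_index(roi.pixel_values(frame)[:, 2])
        rows.append({
            "time_s": float(frame.metadata.get("time_s", i)),
            "M_c": m_c,
            "H": _homogeneity(m_c, m_i, m_f),
        })
    return pd.DataFrame(rows)


def fit_passive_tau(curve: pd.DataFrame) -> float:
    """Estimate the passive relaxation time constant from a mixing curve.

    Fits ln(1 - H) against time by least squares over frames with H < 1
    (exponential-residual model); returns -1/slope in seconds.
    """
    usable = curve[(curve["H"] < 1.0) & (curve["H"] >= 0.0)]
    if len(usable) < 2:
        raise ValueError("need at least two frames with 0 <= H < 1 to fit tau")
    t = usable["time_s"].to_numpy()
    y = np.log(1.0 - usable["H"].to_numpy())
    slope = np.polyfit(t, y, 1)[0]
    if slope >= 0:
        raise ValueError("mixing curve is not relaxing; cannot fit tau")
    return -1.0 / slope
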