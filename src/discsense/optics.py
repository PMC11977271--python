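"""Forward optical model for an LDR array behind cone-shaped waveguide apertures.

A white LED illuminates a shallow fluidic channel from above; below the channel,
cone waveguides restrict each light-dependent resistor (LDR) to a sub-millimeter
aperture of diameter ``D1``. Colored fluid above an aperture attenuates the light
(decadic Beer-Lambert law over the channel depth), and a droplet or fluid column
casts a geometric shadow whose overlap with the aperture disc modulates the mix
of media seen by the sensor. The model composes, per sensor:

    LI_inst = baseline * tilt_efficiency * [(1 - f) * T_cont + f * T_disp]

where ``f`` is the aperture-area fraction occluded by the dispersed shadow and
``T`` are decadic transmittances at the channel depth, followed by a first-order
LDR lag (response time ~10 ms) and a dark-level floor. All light-intensity (LI)
values live on the min-max normalized [0, 1] scale of the instrument.

Units at the interface: mm, s, V. The axial coordinate is measured in mm from
the channel's inner (rotation-center-proximal) end, increasing outward; sensors
are indexed inner-to-outer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "WaveguideArray",
    "OpticalMedium",
    "LedSource",
    "LdrModel",
    "SensorTrace",
    "ChannelGeometry",
    "aperture_positions",
    "transmittance",
    "fit_attenuation",
    "occlusion_fraction",
    "li_signal",
    "normalize_li",
]


@dataclass(frozen=True)
class ChannelGeometry:
    """Straight radial fluidic channel, length x width x depth in mm."""

    length_d0_mm: float = 41.0
    width_mm: float = 1.0
    depth_mm: float = 2.0

    def __post_init__(self) -> None:
        if min(self.length_d0_mm, self.width_mm, self.depth_mm) <= 0:
            raise ValueError("channel dimensions must be positive")

    @property
    def volume_ul(self) -> float:
        """Full-channel capacity in microliters (1 mm^3 == 1 uL)."""
        return self.length_d0_mm * self.width_mm * self.depth_mm


@dataclass(frozen=True)
class WaveguideArray:
    """Linear array of cone waveguide apertures along the channel axis.

    ``aperture_diameter_D1`` is the narrow top opening restricting the LDR's
    field of view; ``base_diameter_D2`` matches the LDR face (5 mm commercial
    parts). ``tilt_efficiency`` is a static per-aperture transmission factor
    for oblique cones (center + two oblique cones by default).
    """

    n_apertures: int = 3
    aperture_diameter_D1: float = 1.0
    base_diameter_D2: float = 5.0
    gap: float = 0.3
    first_center: float = 0.0
    tilt_efficiency: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_apertures < 1:
            raise ValueError("n_apertures must be >= 1")
        if self.aperture_diameter_D1 <= 0:
            raise ValueError("aperture diameter D1 must be > 0")
        if self.aperture_diameter_D1 + self.gap <= 0:
            raise ValueError("pitch D1 + gap must be > 0")
        if self.tilt_efficiency is None:
            if self.n_apertures == 3:
                eff = (0.95, 1.0, 0.95)
            else:
                eff = tuple(1.0 for _ in range(self.n_apertures))
            object.__setattr__(self, "tilt_efficiency", eff)
        else:
            eff = tuple(float(e) for e in self.tilt_efficiency)
            if len(eff) != self.n_apertures:
                raise ValueError("tilt_efficiency length must equal n_apertures")
            if any(not (0 < e <= 1) for e in eff):
                raise ValueError("tilt_efficiency entries must lie in (0, 1]")
            object.__setattr__(self, "tilt_efficiency", eff)

    @property
    def pitch(self) -> float:
        """Center-to-center aperture spacing, D1 + gap (mm)."""
        return self.aperture_diameter_D1 + self.gap

    @property
    def positions(self) -> np.ndarray:
        return aperture_positions(self)


def aperture_positions(array: WaveguideArray) -> np.ndarray:
    """Axial aperture center positions in mm, inner-to-outer.

    positions[i] = first_center + i * (D1 + gap).
    """
    return array.first_center + array.pitch * np.arange(array.n_apertures)


@dataclass(frozen=True)
class OpticalMedium:
    """A fluid characterized by its decadic attenuation per mm of light path.

    ``transmittance(h) = 10**(-k h)`` so k = 0 is a perfectly transparent
    medium and larger k a darker dye at the working wavelength.
    """

    name: str
    decadic_attenuation_k: float = 0.0
    specific_gravity: float = 1.0

    def __post_init__(self) -> None:
        if self.decadic_attenuation_k < 0:
            raise ValueError("attenuation coefficient must be >= 0")
        if self.specific_gravity <= 0:
            raise ValueError("specific gravity must be > 0")

    def transmittance(self, depth_mm):
        return transmittance(self, depth_mm)


def transmittance(medium: OpticalMedium, depth_mm):
    """Decadic (Beer-Lambert) transmittance over ``depth_mm`` of the medium.

    Multiplicative in depth: T(a + b) == T(a) * T(b).

    Raises
    ------
    ValueError
        If any depth is negative.
    """
    depth = np.asarray(depth_mm, dtype=float)
    if np.any(depth < 0):
        raise ValueError("path depth must be >= 0")
    out = 10.0 ** (-medium.decadic_attenuation_k * depth)
    return float(out) if np.isscalar(depth_mm) else out


def fit_attenuation(
    observations: Sequence[tuple[float, float]], name: str = "fitted"
) -> tuple[OpticalMedium, float]:
    """Fit (k, baseline) of ``LI(h) = B * 10**(-k h)`` from two (depth, LI) points.

    Returns the fitted medium and the zero-depth baseline B. With the printed
    blue-dye measurements (0.74 at 0.08 mm, 0.60 at 0.80 mm) this yields
    k ~= 0.127 / mm and B ~= 0.757.
    """
    if len(observations) != 2:
        raise ValueError("exactly two (depth, LI) observations required")
    (h1, li1), (h2, li2) = observations
    if h1 == h2:
        raise ValueError("observation depths must differ")
    if li1 <= 0 or li2 <= 0:
        raise ValueError("LI observations must be positive")
    k = float(np.log10(li1 / li2) / (h2 - h1))
    if k < 0:
        raise ValueError("observations imply negative attenuation")
    baseline = float(li1 * 10.0 ** (k * h1))
    return OpticalMedium(name=name, decadic_attenuation_k=k), baseline


@dataclass(frozen=True)
class LedSource:
    """LED drive voltage mapped to baseline LI through a monotone calibration.

    The calibration is piecewise linear through anchor points; the instrument
    anchors are (0 V, 0.02) -- the LDR dark level -- and (3.5 V, 0.95), the
    brightest LI reached at full drive. ``dark_li`` doubles as the floor below
    which no sensor reading falls (residual leakage at full occlusion).
    """

    voltage: float = 3.5
    anchors: tuple[tuple[float, float], ...] = ((0.0, 0.02), (3.5, 0.95))

    def __post_init__(self) -> None:
        volts = [a[0] for a in self.anchors]
        lis = [a[1] for a in self.anchors]
        if sorted(volts) != list(volts) or len(set(volts)) != len(volts):
            raise ValueError("anchor voltages must be strictly increasing")
        if any(b < a for a, b in zip(lis, lis[1:])):
            raise ValueError("calibration must be non-decreasing in voltage")
        if any(not (0 <= li <= 1) for li in lis):
            raise ValueError("calibration LI anchors must lie in [0, 1]")
        if self.voltage < 0:
            raise ValueError("LED voltage must be >= 0")

    @property
    def dark_li(self) -> float:
        return self.anchors[0][1]

    @property
    def baseline_li(self) -> float:
        """Baseline LI at the configured drive voltage (clamped to anchor range)."""
        volts = np.array([a[0] for a in self.anchors])
        lis = np.array([a[1] for a in self.anchors])
        return float(np.interp(self.voltage, volts, lis))


@dataclass(frozen=True)
class LdrModel:
    """First-order LDR response: resistance bounds and a single time constant."""

    response_time_tau: float = 0.010  # s, midpoint of the 8-12 ms part band
    r_dark: float = 1.0e6
    r_bright: float = 1.0e3

    def __post_init__(self) -> None:
        if not (self.r_dark > self.r_bright > 0):
            raise ValueError("require r_dark > r_bright > 0")
        if self.response_time_tau <= 0:
            raise ValueError("response time must be > 0")


@dataclass
class SensorTrace:
    """Time-stamped normalized LI readings for every sensor of an array.

    ``li`` has one column per aperture, inner-to-outer. ``meta`` carries the
    scenario descriptor (rpm, geometry, seed, ...) for provenance.
    """

    time: np.ndarray
    li: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.li = np.atleast_2d(np.asarray(self.li, dtype=float))
        if self.li.shape[0] != self.time.shape[0]:
            raise ValueError("li rows must match time samples")
        if self.time.ndim != 1 or np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be a strictly increasing 1-D vector")
        if np.any(self.li < 0) or np.any(self.li > 1):
            raise ValueError("LI values must lie in [0, 1]")

    @property
    def n_sensors(self) -> int:
        return self.li.shape[1]

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def to_frame(self):
        import pandas as pd

        cols = {f"li_{i + 1}": self.li[:, i] for i in range(self.n_sensors)}
        return pd.DataFrame({"time_s": self.time, **cols})


def _overlap_area(r1, r2, d):
    """Intersection area of two discs with radii r1, r2 and center distance d."""
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    d = np.abs(np.asarray(d, dtype=float))
    r1, r2, d = np.broadcast_arrays(r1, r2, d)
    area = np.zeros(d.shape)
    small = np.minimum(r1, r2)
    contained = d <= np.abs(r1 - r2)
    area[contained] = np.pi * small[contained] ** 2
    partial = (~contained) & (d < r1 + r2)
    if np.any(partial):
        rr1, rr2, dd = r1[partial], r2[partial], d[partial]
        d1 = (dd**2 + rr1**2 - rr2**2) / (2 * dd)
        d2 = dd - d1
        # clip guards roundoff at tangency
        a1 = rr1**2 * np.arccos(np.clip(d1 / rr1, -1, 1))
        a2 = rr2**2 * np.arccos(np.clip(d2 / rr2, -1, 1))
        s1 = d1 * np.sqrt(np.maximum(rr1**2 - d1**2, 0.0))
        s2 = d2 * np.sqrt(np.maximum(rr2**2 - d2**2, 0.0))
        area[partial] = a1 - s1 + a2 - s2
    return area


def occlusion_fraction(shadow_center, shadow_diameter, aperture_center, aperture_diameter):
    """Fraction of the aperture disc covered by the projected shadow disc.

    Both discs are coaxial with the channel axis (1-D axial offsets only);
    the result is the circular-lens intersection area divided by the aperture
    area, in [0, 1]. Accepts scalars or broadcastable arrays.
    """
    shadow_diameter = np.asarray(shadow_diameter, dtype=float)
    aperture_diameter = np.asarray(aperture_diameter, dtype=float)
    if np.any(shadow_diameter <= 0) or np.any(aperture_diameter <= 0):
        raise ValueError("disc diameters must be > 0")
    sep = np.asarray(aperture_center, dtype=float) - np.asarray(shadow_center, dtype=float)
    area = _overlap_area(shadow_diameter / 2.0, aperture_diameter / 2.0, sep)
    frac = area / (np.pi * (aperture_diameter / 2.0) ** 2)
    out = np.clip(frac, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def _first_order_lag(x: np.ndarray, time: np.ndarray, tau: float) -> np.ndarray:
    """Apply y' = (x - y)/tau along axis 0; exact exponential update per step."""
    dt = np.diff(time)
    y = np.empty_like(x)
    y[0] = x[0]
    alphas = 1.0 - np.exp(-dt / tau)
    for i, a in enumerate(alphas, start=1):
        y[i] = y[i - 1] + a * (x[i] - y[i - 1])
    return y


def li_signal(
    time,
    shadow_position,
    shadow_diameter: float,
    shadow_medium: OpticalMedium,
    array: WaveguideArray,
    led: LedSource,
    ldr: LdrModel,
    continuous: OpticalMedium,
    channel_depth: float = 2.0,
    extra_shadows: Sequence[tuple[np.ndarray, float, OpticalMedium]] = (),
) -> SensorTrace:
    """Render the per-sensor LI trace for shadow(s) moving along the channel.

    Parameters
    ----------
    time : 1-D array, s, strictly increasing sample instants.
    shadow_position : 1-D array aligned with ``time``; axial center of the
        dispersed-phase shadow in mm (droplet center projected on the
        aperture plane).
    shadow_diameter, shadow_medium : geometry and optics of the shadow disc.
    extra_shadows : additional ``(positions, diameter, medium)`` shadows;
        simultaneous overlaps on one aperture are summed and clipped at full
        cover (adequate for well-separated droplets).

    The instantaneous LI is the area-weighted mix of continuous and dispersed
    transmittances scaled by LED baseline and per-cone tilt efficiency, then
    passed through the LDR's first-order lag and floored at the dark level.
    """
    time = np.asarray(time, dtype=float)
    if time.ndim != 1 or np.any(np.diff(time) <= 0):
        raise ValueError("time grid must be 1-D and strictly increasing")
    baseline = led.baseline_li
    t_cont = transmittance(continuous, channel_depth)
    positions = aperture_positions(array)
    shadows = [(np.asarray(shadow_position, dtype=float), shadow_diameter, shadow_medium)]
    shadows += [(np.asarray(p, dtype=float), d, m) for p, d, m in extra_shadows]

    inst = np.empty((time.size, array.n_apertures))
    for j, (center, eff) in enumerate(zip(positions, array.tilt_efficiency)):
        f_total = np.zeros(time.size)
        mix_disp = np.zeros(time.size)
        for pos, diam, medium in shadows:
            if pos.shape != time.shape:
                raise ValueError("shadow positions must align with the time grid")
            f = occlusion_fraction(pos, diam, center, array.aperture_diameter_D1)
            f_total += f
            mix_disp += f * transmittance(medium, channel_depth)
        over = f_total > 1.0
        if np.any(over):  # coincident shadows: renormalize to full cover
            mix_disp[over] *= 1.0 / f_total[over]
            f_total[over] = 1.0
        inst[:, j] = baseline * eff * ((1.0 - f_total) * t_cont + mix_disp)

    lagged = _first_order_lag(inst, time, ldr.response_time_tau)
    out = np.clip(np.maximum(lagged, led.dark_li), 0.0, 1.0)
    return SensorTrace(time=time, li=out, meta={"channel_depth_mm": channel_depth})


def normalize_li(raw_resistance, ldr: LdrModel):
    """Min-max normalize LDR resistance to the [0, 1] LI scale.

    LI = (r_dark - r) / (r_dark - r_bright); 0 at full darkness, 1 at the
    brightest calibration point. Out-of-range readings are clipped.
    """
    span = ldr.r_dark - ldr.r_bright
    if span <= 0:
        raise ValueError("degenerate calibration: r_dark must exceed r_bright")
    r = np.asarray(raw_resistance, dtype=float)
    li = np.clip((ldr.r_dark - r) / span, 0.0, 1.0)
    return float(li) if np.isscalar(raw_resistance) else li
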