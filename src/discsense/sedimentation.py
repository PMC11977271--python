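"""Two-front kinematic model of RBC-plasma separation under centrifugation.

A suspension of red blood cells at volume fraction phi0 fills a radial channel
of length d0. Under rotation the cells settle outward: a clear plasma zone
grows from the inner end (position c(t), the *clear front*) while a packed bed
of fraction phi_max grows from the outer end (the *bed front* b(t)). The clear
front advances at the hindered-settling (Richardson-Zaki) speed

    v = v_ref * (omega / omega_ref)^2 * (1 - phi0)^n

and cell conservation couples the fronts: (phi_max - phi0) * d(bed)/dt =
phi0 * dc/dt. The fronts merge when the suspension zone vanishes; afterwards
the state is constant with packed height d1_final = phi0 * d0 / phi_max.

The *sedimentation height* d1 reported to the sensors is the height of the
visible red column measured from the channel's outer end — suspension plus
bed, d1 = d0 - c(t) — matching what strobe photographs show. The
sedimentation index SI = (d0 - d1)/d0 then rises monotonically from 0 to its
mass-conservation ceiling 1 - phi0/phi_max. Deformability enters solely
through phi_max: deformable cells pack denser (higher phi_max, higher SI).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .dynamics import SpinProtocol
from .optics import ChannelGeometry

__all__ = [
    "SuspensionSpec",
    "SedimentationState",
    "SedimentationSeries",
    "SI_ENDPOINTS",
    "settle",
    "sedimentation_index",
    "virtual_sensor_occupancy",
    "fit_suspension",
]

#: Steady-state sedimentation indices measured photographically for the four
#: sample classes (normal, glutaraldehyde-stiffened at 0.01% / 0.02%, and
#: sickle-cell patient RBCs).
SI_ENDPOINTS = {"normal": 0.68, "GA_0.01": 0.64, "GA_0.02": 0.50, "patient": 0.63}

OMEGA_REF_RPM = 1600.0  # rotation speed of the sedimentation experiments


@dataclass(frozen=True)
class SuspensionSpec:
    """RBC suspension driving the two-front model.

    phi0
        Effective in-channel cell volume fraction. Configurable (default 0.30)
        because the nominal 40% V/V preparation is inconsistent with the
        measured SI endpoints (it would imply a packed fraction above 1).
    phi_max
        Deformability-dependent packing fraction of the sedimented bed.
    v_ref
        Single-cell settling speed scale (mm/s) at the reference rotation
        speed; sets the separation time scale (~40 min at 1600 rpm).
    rz_exponent_n
        Richardson-Zaki hindrance exponent (4.65, low-Re suspensions).
    """

    phi0: float = 0.30
    phi_max: float = 0.9375
    v_ref: float = 0.06
    rz_exponent_n: float = 4.65
    label: str = "normal"

    def __post_init__(self) -> None:
        if not (0 < self.phi0 < self.phi_max <= 1):
            raise ValueError("require 0 < phi0 < phi_max <= 1")
        if self.v_ref <= 0:
            raise ValueError("v_ref must be > 0")
        if self.rz_exponent_n < 0:
            raise ValueError("hindrance exponent must be >= 0")

    @classmethod
    def from_label(
        cls, label: str, phi0: float = 0.30, v_ref: float = 0.06, rz_exponent_n: float = 4.65
    ) -> "SuspensionSpec":
        """Calibrated spec whose steady-state SI matches the class endpoint."""
        if label not in SI_ENDPOINTS:
            raise KeyError(f"unknown sample label {label!r}; known: {sorted(SI_ENDPOINTS)}")
        si_inf = SI_ENDPOINTS[label]
        phi_max = phi0 / (1.0 - si_inf)
        if phi_max > 1:
            raise ValueError(
                f"phi0={phi0} with SI endpoint {si_inf} implies packing fraction "
                f"{phi_max:.3f} > 1; lower phi0"
            )
        return cls(phi0=phi0, phi_max=phi_max, v_ref=v_ref, rz_exponent_n=rz_exponent_n, label=label)

    @property
    def si_ceiling(self) -> float:
        """Mass-conservation bound on SI: 1 - phi0/phi_max."""
        return 1.0 - self.phi0 / self.phi_max

    def front_speed(self, rpm: float) -> float:
        """Clear-front speed in mm/s at the given rotation rate."""
        return (
            self.v_ref
            * (rpm / OMEGA_REF_RPM) ** 2
            * (1.0 - self.phi0) ** self.rz_exponent_n
        )


@dataclass(frozen=True)
class SedimentationState:
    """Snapshot of the separating column.

    Positions are mm from the channel's inner end; ``d1`` (mm) and ``si`` are
    the sedimentation height (from the outer end) and index at this instant.
    """

    time: float
    clear_front: float
    bed_front: float
    d1: float
    si: float


@dataclass
class SedimentationSeries:
    """Time series of the two fronts, d1(t) and SI(t)."""

    time: np.ndarray
    clear_front: np.ndarray
    bed_front: np.ndarray
    d1: np.ndarray
    si: np.ndarray

    def at(self, t: float) -> SedimentationState:
        i = int(np.argmin(np.abs(self.time - t)))
        return SedimentationState(
            time=float(self.time[i]),
            clear_front=float(self.clear_front[i]),
            bed_front=float(self.bed_front[i]),
            d1=float(self.d1[i]),
            si=float(self.si[i]),
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.time,
                "clear_front_mm": self.clear_front,
                "bed_front_mm": self.bed_front,
                "d1_mm": self.d1,
                "SI": self.si,
            }
        )


def settle(
    spec: SuspensionSpec,
    channel: ChannelGeometry,
    spin: SpinProtocol,
    t_span: tuple[float, float] = (0.0, 3600.0),
    dt: float = 5.0,
) -> SedimentationSeries:
    """Run the two-front kinematic model over ``t_span`` sampled every ``dt`` s.

    The model is piecewise linear and solved in closed form: the clear front
    advances at the hindered speed until it meets the receding bed front,
    after which the state is exactly constant.
    """
    d0 = channel.length_d0_mm
    t0, t1 = t_span
    if t1 <= t0 or dt <= 0:
        raise ValueError("t_span must be increasing and dt > 0")
    time = np.arange(t0, t1 + 0.5 * dt, dt)

    if np.isscalar(spin.rpm):
        c = spec.front_speed(float(spin.rpm)) * (time - t0)
    else:  # piecewise-constant rpm: integrate the front speed stepwise
        c = np.zeros_like(time)
        for i in range(1, time.size):
            c[i] = c[i - 1] + spec.front_speed(spin.rpm_at(time[i - 1])) * (
                time[i] - time[i - 1]
            )
    c_final = d0 * (1.0 - spec.phi0 / spec.phi_max)
    c = np.minimum(c, c_final)
    bed_height = spec.phi0 * c / (spec.phi_max - spec.phi0)  # packed zone height
    bed_front = d0 - bed_height
    d1 = d0 - c
    si = c / d0
    return SedimentationSeries(time=time, clear_front=c, bed_front=bed_front, d1=d1, si=si)


def sedimentation_index(d0: float, d1: float) -> float:
    """SI = (d0 - d1) / d0 for channel length d0 and sedimentation height d1 (mm)."""
    if d0 <= 0:
        raise ValueError("d0 must be > 0")
    if d1 < 0 or d1 > d0:
        raise ValueError("require 0 <= d1 <= d0")
    return (d0 - d1) / d0


def virtual_sensor_occupancy(state: SedimentationState | float, positions_from_outer) -> np.ndarray:
    """Which sensors the red column covers: True = covered, False = clear.

    ``positions_from_outer`` are aperture centers in mm measured from the
    channel's *outer* end (the sedimentation reference of d1). A sensor is
    covered when its center lies within the red column (position <= d1) and
    clear when it sits in the separated plasma/PBS zone.
    """
    d1 = state.d1 if isinstance(state, SedimentationState) else float(state)
    pos = np.asarray(positions_from_outer, dtype=float)
    if np.any(pos < 0):
        raise ValueError("positions must be >= 0 (measured from the outer end)")
    return pos <= d1


def fit_suspension(
    time,
    si,
    phi0: float = 0.30,
    rpm: float = OMEGA_REF_RPM,
    d0: float = 41.0,
    rz_exponent_n: float = 4.65,
) -> tuple[float, float]:
    """Recover (v_ref, phi_max) from a (possibly noisy) SI(t) curve.

    Fits the closed-form ramp-and-plateau SI(t) = min(v t, c_final)/d0 by
    nonlinear least squares; the ramp slope identifies v_ref and the plateau
    identifies phi_max.
    """
    time = np.asarray(time, dtype=float)
    si = np.asarray(si, dtype=float)
    hindrance = (1.0 - phi0) ** rz_exponent_n * (rpm / OMEGA_REF_RPM) ** 2

    def model(t, v_ref, phi_max):
        c = np.minimum(v_ref * hindrance * t, d0 * (1.0 - phi0 / phi_max))
        return c / d0

    si_plateau = float(np.clip(np.median(si[-max(3, si.size // 10):]), 1e-3, 0.999))
    p0 = (0.05, float(np.clip(phi0 / (1.0 - si_plateau), phi0 + 1e-3, 1.0)))
    popt, _ = curve_fit(
        model, time, si, p0=p0, bounds=([1e-6, phi0 + 1e-6], [10.0, 1.0]), maxfev=10000
    )
    return float(popt[0]), float(popt[1])
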