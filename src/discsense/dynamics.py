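"""Reduced-order droplet transport in a rotating radial microchannel.

A small droplet of a dispersed phase moves along a radial channel on a
spinning disc under the centrifugal body force, opposed by Stokes drag with
the Hadamard-Rybczynski mobility correction for a fluid sphere:

    m dv/dt = dRho * V * omega^2 * r(t)  -  18 mu V v / (d^2 H(kappa))

with H(kappa) = (1 + kappa) / (2/3 + kappa), kappa = mu_drop / mu_phase.
The quasi-steady balance gives the terminal velocity

    v_t = dRho * omega^2 * r * d^2 * H(kappa) / (18 mu)

which scales as omega^2 at fixed radius. Wall retardation and the unprinted
channel mounting radius are absorbed into a single effective radius ``r_eff``
calibrated from one observed (rpm, velocity) pair. Coriolis-driven lateral
deflection is summarized by the dimensionless stress ratio 2 rho omega w^2 / mu.

Units at the interface: mm, s, cP, rpm (SI internally). Velocities are signed:
positive = outward (denser droplet than the continuous phase).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .optics import OpticalMedium

__all__ = [
    "DropletSpec",
    "PhaseSpec",
    "SpinProtocol",
    "RotorFrame",
    "TrajectoryResult",
    "hadamard_rybczynski",
    "terminal_velocity",
    "fit_effective_radius",
    "droplet_trajectory",
    "coriolis_index",
]

RHO_WATER = 1000.0  # kg/m^3 per unit specific gravity
_CP = 1.0e-3  # Pa s per cP
_MM = 1.0e-3  # m per mm


@dataclass(frozen=True)
class DropletSpec:
    """Dispersed droplet: size, density and viscosity plus its optical medium."""

    diameter_d: float = 1.0  # mm
    specific_gravity: float = 1.0
    viscosity: float = 1.0  # cP
    medium: OpticalMedium = field(default_factory=lambda: OpticalMedium("water", 0.0))

    def __post_init__(self) -> None:
        if self.diameter_d <= 0 or self.specific_gravity <= 0 or self.viscosity <= 0:
            raise ValueError("droplet parameters must be positive")


@dataclass(frozen=True)
class PhaseSpec:
    """Continuous phase: viscosity, density and optical medium."""

    viscosity_mu: float = 75.0  # cP
    specific_gravity: float = 0.85
    medium: OpticalMedium = field(
        default_factory=lambda: OpticalMedium("mineral oil (blue)", 0.1265)
    )

    def __post_init__(self) -> None:
        if self.viscosity_mu <= 0 or self.specific_gravity <= 0:
            raise ValueError("phase parameters must be positive")


@dataclass(frozen=True)
class SpinProtocol:
    """Disc rotation: constant rpm or a piecewise-constant (t_start, rpm) schedule."""

    rpm: float | Sequence[tuple[float, float]] = 0.0
    direction: int = 1

    def __post_init__(self) -> None:
        if np.isscalar(self.rpm):
            if self.rpm < 0:
                raise ValueError("rpm must be >= 0")
        else:
            sched = tuple((float(t), float(r)) for t, r in self.rpm)
            if any(r < 0 for _, r in sched):
                raise ValueError("rpm must be >= 0")
            if any(b[0] <= a[0] for a, b in zip(sched, sched[1:])):
                raise ValueError("schedule times must be strictly increasing")
            object.__setattr__(self, "rpm", sched)

    def rpm_at(self, t: float) -> float:
        if np.isscalar(self.rpm):
            return float(self.rpm)
        out = self.rpm[0][1]
        for t0, r in self.rpm:
            if t >= t0:
                out = r
        return out

    def omega_at(self, t: float) -> float:
        """Angular speed in rad/s at time t."""
        return self.rpm_at(t) * 2.0 * np.pi / 60.0


@dataclass(frozen=True)
class RotorFrame:
    """Radial mounting of the channel: r0 is the radius of its inner end (mm)."""

    r0: float = 30.0

    def __post_init__(self) -> None:
        if self.r0 < 0:
            raise ValueError("r0 must be >= 0")


def hadamard_rybczynski(kappa: float) -> float:
    """Mobility factor (1 + kappa)/(2/3 + kappa) for viscosity ratio kappa.

    Approaches 1 in the rigid-sphere limit (kappa -> inf) and 3/2 for an
    inviscid bubble (kappa -> 0).
    """
    if kappa < 0:
        raise ValueError("viscosity ratio must be >= 0")
    return (1.0 + kappa) / (2.0 / 3.0 + kappa)


def _delta_rho(drop: DropletSpec, phase: PhaseSpec) -> float:
    return (drop.specific_gravity - phase.specific_gravity) * RHO_WATER


def _velocity_coefficient(drop: DropletSpec, phase: PhaseSpec) -> float:
    """Signed dv/d(omega^2 r) in SI: v_t = coef * omega^2 * r  [m/s per (rad/s)^2 m]."""
    kappa = drop.viscosity / phase.viscosity_mu
    h = hadamard_rybczynski(kappa)
    d = drop.diameter_d * _MM
    mu = phase.viscosity_mu * _CP
    return _delta_rho(drop, phase) * d**2 * h / (18.0 * mu)


def terminal_velocity(drop: DropletSpec, phase: PhaseSpec, omega: float, r: float) -> float:
    """Terminal (quasi-steady) droplet velocity in mm/s.

    Parameters: ``omega`` in rad/s, radius ``r`` in mm. Signed by the density
    contrast: positive moves outward.
    """
    if phase.viscosity_mu <= 0:
        raise ValueError("phase viscosity must be > 0")
    return _velocity_coefficient(drop, phase) * omega**2 * (r * _MM) / _MM


def fit_effective_radius(
    observed: tuple[float, float], drop: DropletSpec, phase: PhaseSpec
) -> float:
    """Invert the terminal-velocity closed form for the effective radius (mm).

    ``observed`` is one (rpm, velocity mm/s) calibration pair; the returned
    r_eff lumps the unprinted mounting radius together with wall retardation
    so that ``terminal_velocity(drop, phase, omega(rpm), r_eff)`` reproduces
    the observation exactly.
    """
    rpm, v_mm_s = observed
    if rpm <= 0:
        raise ValueError("calibration rpm must be > 0")
    if v_mm_s <= 0:
        raise ValueError("calibration velocity must be > 0")
    omega = rpm * 2.0 * np.pi / 60.0
    coef = _velocity_coefficient(drop, phase)
    if coef == 0:
        raise ValueError("neutrally buoyant droplet cannot be calibrated")
    r_m = (v_mm_s * _MM) / (coef * omega**2)
    return r_m / _MM


@dataclass
class TrajectoryResult:
    """Axial droplet trajectory: position x (mm from channel inner end), velocity."""

    time: np.ndarray
    x_mm: np.ndarray
    v_mm_s: np.ndarray

    def crossing_times(self, positions_mm) -> np.ndarray:
        """Times at which the droplet center crosses the given axial positions.

        Requires a monotone trajectory (nonzero density contrast); positions
        outside the travelled range come back as NaN.
        """
        x = self.x_mm
        if x[-1] < x[0]:
            x = -x
            positions_mm = -np.asarray(positions_mm, dtype=float)
        return np.interp(positions_mm, x, self.time, left=np.nan, right=np.nan)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time_s": self.time, "x_mm": self.x_mm, "v_mm_s": self.v_mm_s})


def droplet_trajectory(
    drop: DropletSpec,
    phase: PhaseSpec,
    spin: SpinProtocol,
    frame: RotorFrame,
    t_span: tuple[float, float],
    dt: float,
    x0: float = 0.0,
    v0: float = 0.0,
    channel_length: float | None = None,
    moving_r: bool = True,
    rtol: float = 1.0e-6,
) -> TrajectoryResult:
    """Integrate the droplet force balance along the channel.

    The centrifugal term uses r(t) = r0 + x(t) when ``moving_r`` (default) or
    the fixed inner radius r0 otherwise. Integration stops when the droplet
    reaches ``channel_length`` (mm from the inner end), holding the final
    state afterwards. LSODA with rtol 1e-6 handles the millisecond momentum
    relaxation stiffly and accurately.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    t0, t1 = t_span
    if not np.isfinite(t1 - t0) or t1 <= t0:
        raise ValueError("t_span must be finite with t1 > t0")

    rho_d = drop.specific_gravity * RHO_WATER
    drho = _delta_rho(drop, phase)
    kappa = drop.viscosity / phase.viscosity_mu
    h = hadamard_rybczynski(kappa)
    d = drop.diameter_d * _MM
    mu = phase.viscosity_mu * _CP
    drag = 18.0 * mu / (d**2 * h)  # Pa s / m^2 -> force per volume per velocity
    r0_m = frame.r0 * _MM

    def rhs(t, y):
        x, v = y
        r = r0_m + x if moving_r else r0_m
        omega = spin.omega_at(t)
        a = (drho * omega**2 * r - drag * v) / rho_d
        return (v, a)

    events = []
    if channel_length is not None:
        x_end = channel_length * _MM

        def hit_end(t, y):
            return y[0] - x_end

        hit_end.terminal = True
        hit_end.direction = 1
        events.append(hit_end)

    t_eval = np.arange(t0, t1 + 0.5 * dt, dt)
    t_eval = t_eval[t_eval <= t1]
    sol = solve_ivp(
        rhs,
        (t0, t1),
        (x0 * _MM, v0 * _MM),
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=(1.0e-10, 1.0e-10),
        events=events or None,
    )
    if not sol.success:
        raise RuntimeError(f"trajectory integration failed: {sol.message}")
    x = sol.y[0] / _MM
    v = sol.y[1] / _MM
    t = sol.t
    if t.size < t_eval.size:  # stopped at channel end: hold final state
        n_pad = t_eval.size - t.size
        t = t_eval
        x = np.concatenate([x, np.full(n_pad, x[-1])])
        v = np.concatenate([v, np.zeros(n_pad)])
    if not np.all(np.isfinite(x)):
        raise RuntimeError("non-finite trajectory state")
    return TrajectoryResult(time=t, x_mm=x, v_mm_s=v)


def coriolis_index(
    phase: PhaseSpec,
    omega: float,
    mean_velocity: float,
    channel_width: float,
    threshold: float = 1.0,
) -> tuple[float, bool]:
    """Coriolis-to-viscous stress ratio 2 rho omega w^2 / mu and a deflection flag.

    The mean streamwise velocity cancels between the Coriolis force density
    (2 rho omega U) and the viscous stress scale (mu U / w^2); it is accepted
    for interface symmetry and dimensional bookkeeping only. Low-viscosity
    phases score high and are flagged "deflecting" above ``threshold``.
    """
    if omega < 0 or channel_width <= 0 or mean_velocity < 0:
        raise ValueError("inputs must be positive")
    rho = phase.specific_gravity * RHO_WATER
    w = channel_width * _MM
    mu = phase.viscosity_mu * _CP
    index = 2.0 * rho * omega * w**2 / mu
    return index, bool(index > threshold)
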