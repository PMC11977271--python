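"""Seeded synthetic scenario generator: ground-truthed sensor traces.

Composes the forward models (droplet dynamics + optics, or sedimentation
kinematics + zone transmittances) into SensorTrace fixtures with known
ground truth, so every detector can be exercised without recorded data.
Noise is additive Gaussian on LI (default sigma = 0.005, about a tenth of
the instrument's reported 5% repeat deviation; 0.0125 is the stress tier),
clipped back to [0, 1]; all randomness flows from the explicit seed.
"""

from __future__ import annotations

from dataclasses import asdict

import numpy as np

from . import dynamics, optics, sedimentation
from .detection import PROTOCOLS
from .optics import ChannelGeometry, LdrModel, LedSource, OpticalMedium, SensorTrace, WaveguideArray

__all__ = [
    "RPM_PRESETS",
    "CALIBRATION_POINT",
    "default_array",
    "default_drop",
    "default_phase",
    "make_droplet_pass",
    "make_sedimentation",
]

#: Rotation-speed grid of the droplet velocimetry experiments (rpm).
RPM_PRESETS = (64, 95, 170, 240)

#: The (rpm, mm/s) observation used to calibrate the effective radius.
CALIBRATION_POINT = (64.0, 0.9)

DEFAULT_NOISE_SIGMA = 0.005


def default_array(first_center: float = 15.0) -> WaveguideArray:
    """Three 1 mm apertures with 0.3 mm gaps (pitch 1.3 mm)."""
    return WaveguideArray(n_apertures=3, aperture_diameter_D1=1.0, gap=0.3, first_center=first_center)


def default_drop() -> dynamics.DropletSpec:
    """1 mm transparent water droplet."""
    return dynamics.DropletSpec(
        diameter_d=1.0, specific_gravity=1.0, viscosity=1.0, medium=OpticalMedium("water", 0.0)
    )


def default_phase() -> dynamics.PhaseSpec:
    """Blue-dyed mineral oil, 75 cP, attenuation from the two-point depth fit."""
    return dynamics.PhaseSpec(
        viscosity_mu=75.0,
        specific_gravity=0.85,
        medium=OpticalMedium("mineral oil (blue)", 0.1265),
    )


def make_droplet_pass(
    rpm: float,
    drop: dynamics.DropletSpec | None = None,
    phase: dynamics.PhaseSpec | None = None,
    array: WaveguideArray | None = None,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    seed: int = 0,
    sample_rate: float = 100.0,
    channel: ChannelGeometry | None = None,
    channel_depth: float | None = None,
    lead_mm: float = 2.0,
    tail_mm: float = 2.0,
    led: LedSource | None = None,
    ldr: LdrModel | None = None,
) -> tuple[SensorTrace, dict]:
    """Simulate one droplet passing the aperture array at the given rpm.

    The rotor frame is placed so that the calibrated effective radius (from
    the printed 64 rpm observation) coincides with the first aperture, i.e.
    the droplet crosses the array at the speed the closed form predicts for
    that rpm. Returns the noisy trace and a ground-truth dict with aperture
    crossing times, per-pair and mean inter-aperture velocities, and the
    trajectory itself.
    """
    drop = drop or default_drop()
    phase = phase or default_phase()
    array = array or default_array()
    channel = channel or ChannelGeometry()
    depth = channel_depth if channel_depth is not None else channel.depth_mm
    led = led or LedSource(voltage=3.5)
    ldr = ldr or LdrModel()
    if rpm <= 0:
        raise ValueError("rpm must be > 0")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")

    r_eff = dynamics.fit_effective_radius(CALIBRATION_POINT, drop, phase)
    positions = optics.aperture_positions(array)
    x0 = positions[0] - lead_mm
    x_end = positions[-1] + tail_mm
    frame = dynamics.RotorFrame(r0=r_eff - positions[0])
    spin = dynamics.SpinProtocol(rpm=rpm)

    v_nominal = dynamics.terminal_velocity(drop, phase, spin.omega_at(0.0), r_eff)
    t_end = 1.5 * (x_end - x0) / v_nominal + 0.5
    traj = dynamics.droplet_trajectory(
        drop,
        phase,
        spin,
        frame,
        t_span=(0.0, t_end),
        dt=1.0 / sample_rate,
        x0=x0,
        channel_length=channel.length_d0_mm,
    )
    trace = optics.li_signal(
        traj.time,
        traj.x_mm,
        drop.diameter_d,
        drop.medium,
        array,
        led,
        ldr,
        phase.medium,
        channel_depth=depth,
    )
    rng = np.random.default_rng(seed)
    if noise_sigma > 0:
        trace.li = np.clip(trace.li + rng.normal(0.0, noise_sigma, trace.li.shape), 0.0, 1.0)

    crossing = traj.crossing_times(positions)
    dts = np.diff(crossing)
    pair_v = array.pitch / dts
    truth = {
        "kind": "droplet_pass",
        "rpm": float(rpm),
        "seed": int(seed),
        "noise_sigma": float(noise_sigma),
        "r_eff_mm": float(r_eff),
        "event_times_s": crossing.tolist(),
        "pair_velocities_mm_s": pair_v.tolist(),
        "mean_velocity_mm_s": float(np.mean(pair_v)),
        "terminal_velocity_at_r_eff_mm_s": float(v_nominal),
        "trajectory": traj,
    }
    trace.meta.update(
        {
            "kind": "droplet_pass",
            "rpm": float(rpm),
            "seed": int(seed),
            "noise_sigma": float(noise_sigma),
            "pitch_mm": array.pitch,
            "array": asdict(array),
            "sample_rate_hz": sample_rate,
        }
    )
    return trace, truth


def make_sedimentation(
    spec_label: str = "normal",
    channel: ChannelGeometry | None = None,
    array_positions_from_outer=None,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    seed: int = 0,
    rpm: float = sedimentation.OMEGA_REF_RPM,
    t_end: float = 3600.0,
    dt: float = 5.0,
    plasma_li: float = 0.90,
    rbc_li: float = 0.72,
    phi0: float = 0.30,
    v_ref: float = 0.06,
) -> tuple[SensorTrace, dict]:
    """Simulate the sedimentation assay for one calibrated RBC sample class.

    Each sensor reads the plasma LI level (0.9) once the clear front has
    passed it and the RBC-column level (0.72) while covered, per the
    two-front model; Gaussian noise is added on top. Ground truth carries
    d1(t), SI(t), the steady-state SI, and the enabled-sensor counts.
    """
    if spec_label not in sedimentation.SI_ENDPOINTS:
        raise KeyError(f"unknown sample label {spec_label!r}")
    channel = channel or ChannelGeometry(41.0, 1.0, 2.0)
    if array_positions_from_outer is None:
        array_positions_from_outer = PROTOCOLS["four_class"].positions_from_outer
    pos = np.asarray(array_positions_from_outer, dtype=float)
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")

    spec = sedimentation.SuspensionSpec.from_label(spec_label, phi0=phi0, v_ref=v_ref)
    spin = dynamics.SpinProtocol(rpm=rpm)
    series = sedimentation.settle(spec, channel, spin, t_span=(0.0, t_end), dt=dt)

    covered = pos[None, :] <= series.d1[:, None]  # (n_t, n_sensors)
    li = np.where(covered, rbc_li, plasma_li)
    rng = np.random.default_rng(seed)
    if noise_sigma > 0:
        li = np.clip(li + rng.normal(0.0, noise_sigma, li.shape), 0.0, 1.0)
    trace = SensorTrace(
        time=series.time,
        li=li,
        meta={
            "kind": "sedimentation",
            "label": spec_label,
            "rpm": float(rpm),
            "seed": int(seed),
            "noise_sigma": float(noise_sigma),
            "positions_from_outer_mm": pos.tolist(),
            "phi0": phi0,
            "v_ref_mm_s": v_ref,
            "d0_mm": channel.length_d0_mm,
        },
    )
    truth = {
        "kind": "sedimentation",
        "label": spec_label,
        "si_infinity": spec.si_ceiling,
        "phi_max": spec.phi_max,
        "d1_mm": series.d1.tolist(),
        "si": series.si.tolist(),
        "enabled_counts": (~covered).sum(axis=1).astype(int).tolist(),
        "series": series,
    }
    return trace, truth
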