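"""Two-wheel inverted-pendulum plant with configurable perturbations.

Standard wheeled-inverted-pendulum rigid-body equations in the coordinates
(phi: wheel angle, theta: body tilt from vertical).  The body is a set of
point masses hanging on the axle (the base body plus an optional load at a
signed longitudinal offset), so on-center loads perturb symmetrically and
off-center loads introduce a constant tilt torque.  A platform angle adds
the gravity component along the slope to the wheel coordinate.

Integration is RK4 at 1 ms inside each 10 ms control tick with the command
held constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "PlantParams",
    "Perturbation",
    "PlantState",
    "PlantBlowUpError",
    "make_perturbation",
    "plant_step",
    "reference_trajectory",
    "read_sensors",
    "mechanical_energy",
    "SensorNoise",
]

GRAVITY = 9.81


class PlantBlowUpError(RuntimeError):
    """Integration produced a non-finite state."""


@dataclass(frozen=True)
class PlantParams:
    """Physical constants of the simulated robot.

    The robot totals 600 g (body 540 g + wheels 60 g) so the standard 300 g
    load is 50% of its mass.
    """

    body_mass: float = 0.54  # kg
    wheel_mass: float = 0.06  # kg, both wheels + shaft lumped
    wheel_radius: float = 0.025  # m
    body_com_length: float = 0.07  # m, axle to body COM
    body_inertia: float = 8.8e-4  # kg m^2 about the body COM
    wheel_inertia: float = 1.9e-5  # kg m^2
    motor_torque_per_unit_command: float = 0.05  # N m per unit in [-1, 1]
    viscous_friction: float = 2e-4  # N m s on the wheel coordinate
    friction_asymmetry: float = 0.05  # fractional forward/backward difference
    body_friction: float = 1e-4  # N m s on the tilt coordinate
    #: N m s per m of load offset: an off-center load drags the wheel
    #: coordinate in the offset direction (contact-geometry shift), making
    #: motion toward the loaded side costlier.
    load_drag_coupling: float = 0.15
    gravity: float = GRAVITY
    fall_threshold: float = math.pi / 6  # rad

    def __post_init__(self) -> None:
        if min(self.body_mass, self.wheel_mass, self.wheel_radius,
               self.body_com_length) <= 0:
            raise ValueError("masses and lengths must be positive")


@dataclass(frozen=True)
class Perturbation:
    """External perturbation: a point load on the body and/or a slope."""

    kind: str = "none"
    load_mass: float = 0.0  # kg
    load_offset: float = 0.0  # m, signed along the body's forward axis
    load_height: float = 0.07  # m above the axle along the body axis
    platform_angle: float = 0.0  # rad, positive = uphill in +phi


def make_perturbation(kind: str, load_mass: float = 0.3,
                      load_offset: float = 0.005,
                      platform_angle: float = math.radians(10.0)) -> Perturbation:
    """Named presets used by the experimental scenarios.

    The 300 g load (50% of the robot's mass) sits at the top of the body for
    the symmetric case and slightly lower with a small longitudinal offset
    for the asymmetric cases.
    """
    if kind == "none":
        return Perturbation()
    if kind == "load_center":
        return Perturbation(kind, load_mass=load_mass, load_height=0.07)
    if kind == "load_front":
        return Perturbation(kind, load_mass=load_mass,
                            load_offset=abs(load_offset), load_height=0.05)
    if kind == "load_back":
        return Perturbation(kind, load_mass=load_mass,
                            load_offset=-abs(load_offset), load_height=0.05)
    if kind == "incline":
        return Perturbation(kind, platform_angle=abs(platform_angle))
    if kind == "decline":
        return Perturbation(kind, platform_angle=-abs(platform_angle))
    raise ValueError(f"unknown perturbation kind {kind!r}")


@dataclass
class PlantState:
    theta: float = 0.0  # rad, body tilt (+ = forward lean)
    theta_dot: float = 0.0
    phi: float = 0.0  # rad, wheel angle (+ = forward travel)
    phi_dot: float = 0.0
    fallen: bool = False

    def copy(self) -> "PlantState":
        return replace(self)


def _mass_terms(params: PlantParams, pert: Perturbation):
    """Point masses (m_i, l_i, delta_i) of the body, plus totals."""
    masses = [(params.body_mass, params.body_com_length, 0.0)]
    if pert.load_mass > 0.0:
        l_load = math.hypot(pert.load_offset, pert.load_height)
        delta = math.atan2(pert.load_offset, pert.load_height)
        masses.append((pert.load_mass, l_load, delta))
    m_total = params.wheel_mass + sum(m for m, _, _ in masses)
    return masses, m_total


def _derivatives(theta, theta_dot, phi_dot, tau, params: PlantParams,
                 masses, m_total, sin_slope, load_drag=0.0):
    """(theta_ddot, phi_ddot) of the coupled rigid-body equations.

    ``load_drag`` is the signed directional drag coefficient
    (load_drag_coupling * load_offset); it resists wheel motion toward the
    loaded side only.
    """
    r = params.wheel_radius
    g = params.gravity

    m11 = m_total * r * r + params.wheel_inertia
    m12 = 0.0
    m22 = params.body_inertia
    s = 0.0  # sum m_i l_i sin(theta + delta_i)
    for m, length, delta in masses:
        a = theta + delta
        m12 += m * r * length * math.cos(a)
        m22 += m * length * length
        s += m * length * math.sin(a)

    b = params.viscous_friction * (
        1.0 + params.friction_asymmetry * math.tanh(phi_dot / 0.5)
    )
    drag = 0.0
    if load_drag != 0.0:
        gate = 0.5 * (1.0 + math.tanh(math.copysign(1.0, load_drag) * phi_dot / 0.5))
        drag = abs(load_drag) * phi_dot * gate
    rhs_phi = (tau - b * phi_dot - drag - m_total * g * r * sin_slope
               + r * s * theta_dot * theta_dot)
    rhs_theta = -tau - params.body_friction * theta_dot + g * s

    det = m11 * m22 - m12 * m12
    phi_ddot = (m22 * rhs_phi - m12 * rhs_theta) / det
    theta_ddot = (m11 * rhs_theta - m12 * rhs_phi) / det
    return theta_ddot, phi_ddot


def plant_step(
    state: PlantState,
    u: float,
    params: PlantParams,
    pert: Perturbation | None = None,
    dt: float = 0.010,
    n_substeps: int = 10,
) -> PlantState:
    """Advance one control period with the command held, RK4 sub-stepped.

    Raises :class:`PlantBlowUpError` on non-finite state.  Once the fall
    threshold is crossed the ``fallen`` flag latches and the state freezes.
    """
    if pert is None:
        pert = Perturbation()
    if state.fallen:
        return state
    tau = params.motor_torque_per_unit_command * min(max(u, -1.0), 1.0)
    masses, m_total = _mass_terms(params, pert)
    sin_slope = math.sin(pert.platform_angle)
    load_drag = (params.load_drag_coupling * pert.load_offset
                 if pert.load_mass > 0.0 else 0.0)

    th, thd, ph, phd = state.theta, state.theta_dot, state.phi, state.phi_dot
    h = dt / n_substeps
    args = (tau, params, masses, m_total, sin_slope, load_drag)
    for _ in range(n_substeps):
        a1, b1 = _derivatives(th, thd, phd, *args)
        th2, thd2, phd2 = th + 0.5 * h * thd, thd + 0.5 * h * a1, phd + 0.5 * h * b1
        a2, b2 = _derivatives(th2, thd2, phd2, *args)
        th3, thd3, phd3 = th + 0.5 * h * thd2, thd + 0.5 * h * a2, phd + 0.5 * h * b2
        a3, b3 = _derivatives(th3, thd3, phd3, *args)
        th4, thd4, phd4 = th + h * thd3, thd + h * a3, phd + h * b3
        a4, b4 = _derivatives(th4, thd4, phd4, *args)
        ph += h / 6.0 * (phd + 2.0 * phd2 + 2.0 * phd3 + phd4)
        th += h / 6.0 * (thd + 2.0 * thd2 + 2.0 * thd3 + thd4)
        phd += h / 6.0 * (b1 + 2.0 * b2 + 2.0 * b3 + b4)
        thd += h / 6.0 * (a1 + 2.0 * a2 + 2.0 * a3 + a4)

    if not all(map(math.isfinite, (th, thd, ph, phd))):
        raise PlantBlowUpError(f"non-finite plant state: {(th, thd, ph, phd)}")
    state.theta, state.theta_dot = th, thd
    state.phi, state.phi_dot = ph, phd
    if abs(th) > params.fall_threshold:
        state.fallen = True
    return state


def mechanical_energy(state: PlantState, params: PlantParams,
                      pert: Perturbation | None = None) -> float:
    """Total mechanical energy; conserved for u = 0 with zero friction."""
    if pert is None:
        pert = Perturbation()
    masses, m_total = _mass_terms(params, pert)
    r = params.wheel_radius
    m11 = m_total * r * r + params.wheel_inertia
    m12 = 0.0
    m22 = params.body_inertia
    pe = m_total * params.gravity * r * math.sin(pert.platform_angle) * state.phi
    for m, length, delta in masses:
        a = state.theta + delta
        m12 += m * r * length * math.cos(a)
        m22 += m * length * length
        pe += m * params.gravity * length * math.cos(a)
    ke = 0.5 * (m11 * state.phi_dot**2 + 2 * m12 * state.phi_dot * state.theta_dot
                + m22 * state.theta_dot**2)
    return ke + pe


def reference_trajectory(
    t: float, freq: float = 0.25, amplitude: float = math.pi
) -> tuple[float, float, float, float]:
    """(phi_ref, phi_dot_ref, theta_ref, theta_dot_ref) at time t.

    The wheel reference is ``amplitude * sin(2 pi freq t)``; the tilt
    reference is identically zero.
    """
    if freq <= 0:
        raise ValueError("freq must be positive")
    w = 2.0 * math.pi * freq
    return amplitude * math.sin(w * t), amplitude * w * math.cos(w * t), 0.0, 0.0


@dataclass(frozen=True)
class SensorNoise:
    """Optional encoder quantization and gyro noise (both default off)."""

    encoder_quantum: float = 0.0  # rad
    gyro_sd: float = 0.0  # rad/s


def read_sensors(
    state: PlantState,
    noise: SensorNoise | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float, float, float]:
    """Measured (theta, theta_dot, phi, phi_dot)."""
    th, thd, ph, phd = state.theta, state.theta_dot, state.phi, state.phi_dot
    if noise is not None:
        if noise.encoder_quantum > 0.0:
            q = noise.encoder_quantum
            ph = round(ph / q) * q
        if noise.gyro_sd > 0.0:
            if rng is None:
                raise ValueError("gyro noise requires an rng")
            thd += float(rng.normal(0.0, noise.gyro_sd))
    return th, thd, ph, phd
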