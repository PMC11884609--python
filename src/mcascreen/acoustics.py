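"""Standing-wave acoustic field, radiation force and drop deflection kinematics.

Two confocal spherical caps of ultrasonic piston transducers (40 kHz in air)
generate a standing wave along their common axis (y).  The module computes
the complex pressure amplitude by superposing spherical waves with circular-
piston directivity, derives the observables of the two optical
characterisation methods (Schlieren: x-integrated pressure gradient along y;
shadowgraphy: x-integrated Laplacian, proportional to the pressure itself for
sinusoidal fields), measures the inter-node spacing, and models the
deflection of falling millimetric drops by an acoustic radiation force (ARF)
of constant magnitude during a finite actuation time.

Units are SI throughout (m, s, kg, Pa, N) unless noted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import j1

from .errors import ConfigurationError, FitError, InputError

__all__ = [
    "TransducerCapPair",
    "TransducerArray",
    "FieldGrid",
    "PressureField",
    "ARFParams",
    "DropState",
    "KineticModel",
    "TrajectoryFitResult",
    "build_caps",
    "piston_field",
    "amplitude_map",
    "schlieren_proxy",
    "shadowgraph_proxy",
    "node_spacing",
    "arf",
    "invert_arf",
    "critical_radius_gravity",
    "simulate_trajectory",
    "fit_trajectory_force",
]

SPEED_OF_SOUND_AIR = 343.0  # m/s at 20 degC
AIR_DENSITY = 1.2  # kg/m^3
WATER_DENSITY = 1.0e3  # kg/m^3
G = 9.81  # m/s^2


@dataclass
class TransducerCapPair:
    """Geometry and drive of the two facing spherical transducer caps.

    Each cap holds ``n_per_cap`` transducers on a sphere of radius
    ``cap_radius`` centered on the common focus (origin), arranged in
    concentric rings (``ring_layout`` counts at ``ring_angles_deg`` polar
    angles from the cap axis, +y / -y).  All transducer normals point at the
    focus.  ``relative_phase`` shifts the second cap's drive.
    """

    cap_radius: float = 86e-3
    n_per_cap: int = 36
    ring_layout: Tuple[int, ...] = (6, 12, 18)
    ring_angles_deg: Tuple[float, ...] = (4.0, 8.0, 12.0)
    piston_radius: float = 4.5e-3
    f: float = 40e3
    drive: float = 1.0
    relative_phase: float = 0.0

    def __post_init__(self) -> None:
        if sum(self.ring_layout) != self.n_per_cap:
            raise ConfigurationError(
                f"ring counts {self.ring_layout} do not sum to {self.n_per_cap}"
            )
        if len(self.ring_layout) != len(self.ring_angles_deg):
            raise ConfigurationError("one polar angle per ring is required")
        if self.cap_radius <= 0 or self.piston_radius <= 0 or self.f <= 0:
            raise ConfigurationError("cap_radius, piston_radius and f must be positive")

    @property
    def wavelength(self) -> float:
        return SPEED_OF_SOUND_AIR / self.f

    @property
    def wavenumber(self) -> float:
        return 2.0 * math.pi / self.wavelength

    @property
    def period(self) -> float:
        return 1.0 / self.f


@dataclass
class TransducerArray:
    """Realised transducer layout: positions, unit normals and phases."""

    positions: np.ndarray  # (n, 3)
    normals: np.ndarray  # (n, 3), unit, pointing at the focus
    phases: np.ndarray  # (n,)
    spec: TransducerCapPair


@dataclass
class FieldGrid:
    """Simulation grid conventions: extents of 4λ, steps λ/25 (x), λ/50 (y, z).

    Axes are returned centered on the focus.  ``n_time`` samples per period
    (Ta/40 step) are used for peak-to-peak maps.
    """

    wavelength: float
    extent_wavelengths: float = 4.0
    step_x_fraction: float = 1 / 25
    step_yz_fraction: float = 1 / 50
    n_time: int = 40

    def axis(self, fraction: float) -> np.ndarray:
        half = self.extent_wavelengths * self.wavelength / 2.0
        step = fraction * self.wavelength
        n = int(round(2 * half / step))
        return -half + step * np.arange(n + 1)

    @property
    def x(self) -> np.ndarray:
        return self.axis(self.step_x_fraction)

    @property
    def y(self) -> np.ndarray:
        return self.axis(self.step_yz_fraction)

    @property
    def z(self) -> np.ndarray:
        return self.axis(self.step_yz_fraction)


@dataclass
class PressureField:
    """Complex pressure amplitude sampled on a set of points or a grid."""

    amplitude: np.ndarray  # complex
    axes: Tuple[np.ndarray, ...]  # one per grid dimension
    wavelength: float


@dataclass
class ARFParams:
    """Constants of the small-drop radiation-force expression.

    phi: acoustic contrast factor between air and water (~5/6); rho0, c0: air
    density and speed of sound; lam_a: acoustic wavelength.  The expression
    is a good approximation while Rd/lam_a < 0.3.
    """

    phi: float = 5.0 / 6.0
    rho0: float = AIR_DENSITY
    c0: float = SPEED_OF_SOUND_AIR
    lam_a: float = SPEED_OF_SOUND_AIR / 40e3

    def __post_init__(self) -> None:
        if min(self.phi, self.rho0, self.c0, self.lam_a) <= 0:
            raise InputError("all ARF parameters must be positive")


@dataclass
class DropState:
    """A falling culture-medium drop (volume in µL; SI elsewhere)."""

    Vd_uL: float = 50.0
    rho_w: float = WATER_DENSITY
    gamma: float = 0.072  # surface tension, N/m
    y: float = 0.0
    z: float = 0.0
    vy: float = 0.0
    vz: float = 0.0

    def __post_init__(self) -> None:
        if self.Vd_uL <= 0:
            raise ConfigurationError("drop volume must be positive")

    @property
    def volume_m3(self) -> float:
        return self.Vd_uL * 1e-9

    @property
    def Rd(self) -> float:
        """Equivalent spherical radius (m): (3V / 4π)^(1/3)."""
        return (3.0 * self.volume_m3 / (4.0 * math.pi)) ** (1.0 / 3.0)

    @property
    def m(self) -> float:
        """Drop mass (kg)."""
        return self.rho_w * self.volume_m3


@dataclass
class KineticModel:
    """Two-phase deflection kinematics: constant axial ARF, then free fall.

    Fa acts along y for a duration dt_a from rest; the drop leaves the
    actuation zone with v0 = Fa * dt_a / m and is then ballistic.  Gravity
    acts along z throughout.
    """

    Fa: float = 2.5e-4
    dt_a: float = 0.03
    g: float = G

    def __post_init__(self) -> None:
        if self.Fa < 0 or self.dt_a < 0:
            raise ConfigurationError("Fa and dt_a must be >= 0")

    def v0(self, m: float) -> float:
        return self.Fa * self.dt_a / m


@dataclass
class TrajectoryFitResult:
    """Recovered axial force and fit diagnostics."""

    Fa_hat: float
    residual_norm: float
    n: int
    t0: float = 0.0


def build_caps(spec: TransducerCapPair | None = None) -> TransducerArray:
    """Place the transducers of both caps; deterministic.

    The two caps are mirror images about the focal (y=0) plane, each
    transducer facing its counterpart, so the superposed fields form a
    standing wave along y with spherical iso-phase surfaces.
    """
    spec = spec or TransducerCapPair()
    positions: List[np.ndarray] = []
    phases: List[float] = []
    for sign, phase in ((+1.0, 0.0), (-1.0, spec.relative_phase)):
        for count, ang_deg in zip(spec.ring_layout, spec.ring_angles_deg):
            theta = math.radians(ang_deg)
            for j in range(count):
                phi_az = 2.0 * math.pi * j / count
                positions.append(
                    spec.cap_radius
                    * np.array(
                        [
                            math.sin(theta) * math.cos(phi_az),
                            sign * math.cos(theta),
                            math.sin(theta) * math.sin(phi_az),
                        ]
                    )
                )
                phases.append(phase)
    pos = np.array(positions)
    normals = -pos / np.linalg.norm(pos, axis=1)[:, None]
    return TransducerArray(positions=pos, normals=normals, phases=np.array(phases), spec=spec)


def piston_field(
    caps: TransducerArray,
    points: np.ndarray,
    drive: Optional[float] = None,
    r_floor: float = 1e-6,
) -> np.ndarray:
    """Complex pressure amplitude at ``points`` (shape (..., 3), m).

    Each transducer contributes a spherical wave (drive/r)·Dir(θ)·exp(ikr)
    with the far-field circular-piston directivity
    Dir(θ) = 2 J1(ka sinθ)/(ka sinθ), Dir(0)=1, θ measured from the
    transducer normal.  Points closer than ``r_floor`` to a transducer are
    skipped (NaN) with a warning.
    """
    spec = caps.spec
    drive = spec.drive if drive is None else drive
    k = spec.wavenumber
    ka = k * spec.piston_radius
    pts = np.asarray(points, dtype=float)
    flat = pts.reshape(-1, 3)
    total = np.zeros(flat.shape[0], dtype=complex)
    bad = np.zeros(flat.shape[0], dtype=bool)
    for pos, nrm, ph in zip(caps.positions, caps.normals, caps.phases):
        rv = flat - pos
        r = np.linalg.norm(rv, axis=1)
        close = r < r_floor
        bad |= close
        r_safe = np.where(close, 1.0, r)
        cos_t = np.clip((rv @ nrm) / r_safe, -1.0, 1.0)
        sin_t = np.sqrt(1.0 - cos_t**2)
        x = ka * sin_t
        with np.errstate(invalid="ignore", divide="ignore"):
            direc = np.where(x < 1e-12, 1.0, 2.0 * j1(x) / np.where(x < 1e-12, 1.0, x))
        total += (drive / r_safe) * direc * np.exp(1j * (k * r + ph))
    if bad.any():
        warnings.warn("some points coincide with a transducer; returned NaN there")
        total[bad] = np.nan
    return total.reshape(pts.shape[:-1])


def amplitude_map(complex_amplitude: np.ndarray, n_time: int = 40) -> np.ndarray:
    """Peak-to-peak pressure over one period from the complex amplitude.

    The real signal Re(p̂ e^{-iωt}) is sampled at ``n_time`` instants over
    one period; for a pure tone the result approaches 2|p̂| as the sampling
    refines (within 0.5% at 40 samples).
    """
    if n_time < 2:
        raise InputError("need at least 2 time samples per period")
    p = np.asarray(complex_amplitude)
    phases = np.exp(-1j * 2.0 * np.pi * np.arange(n_time) / n_time)
    signal = np.real(p[..., None] * phases)
    return signal.max(axis=-1) - signal.min(axis=-1)


def schlieren_proxy(amplitude_3d: np.ndarray, dy: float, x_axis: int = 0, y_axis: int = 1) -> np.ndarray:
    """Schlieren-contrast forward model: x-projected pressure gradient along y.

    The optical contrast of Schlieren deflectometry is proportional to the
    pressure gradient integrated along the optical (x) axis; this sums the
    3-D amplitude map over x and applies a centered finite difference along
    y.  The output is comparable to a measured Schlieren map up to a global
    scale factor.
    """
    amp = np.asarray(amplitude_3d, dtype=float)
    if amp.shape[y_axis] < 3:
        raise InputError("grid too small for the centered difference stencil")
    projected = amp.sum(axis=x_axis)
    # after summing over x, the y axis index shifts down if it followed x
    y_ax = y_axis - 1 if y_axis > x_axis else y_axis
    return np.gradient(projected, dy, axis=y_ax)


def shadowgraph_proxy(
    complex_amplitude_3d: np.ndarray, steps: Tuple[float, float, float], x_axis: int = 0
) -> np.ndarray:
    """Shadowgraph forward model: x-projected Laplacian of the pressure.

    For sinusoidal (single-wavenumber) fields the Laplacian is proportional
    to the pressure itself (∇²p = -k²p), so this proxy visualises the
    pressure field directly.
    """
    p = np.asarray(complex_amplitude_3d)
    if min(p.shape) < 3:
        raise InputError("grid too small for the Laplacian stencil")
    lap = np.zeros_like(p)
    for ax, h in enumerate(steps):
        lap += (np.roll(p, -1, axis=ax) - 2 * p + np.roll(p, 1, axis=ax)) / h**2
    # roll wraps around; blank the boundary planes where the stencil is invalid
    for ax in range(3):
        sl = [slice(None)] * 3
        sl[ax] = 0
        lap[tuple(sl)] = 0
        sl[ax] = -1
        lap[tuple(sl)] = 0
    return lap.sum(axis=x_axis)


def node_spacing(
    y: np.ndarray,
    amplitude: np.ndarray,
    window: Optional[Tuple[float, float]] = None,
) -> float:
    """Mean spacing between adjacent amplitude nodes along a line profile.

    Local minima of the peak-to-peak profile are located and refined to
    sub-grid precision with a parabolic fit through the three bracketing
    samples; the mean of adjacent spacings (within ``window`` if given) is
    returned.  For a standing wave the spacing is half a wavelength.
    """
    y = np.asarray(y, dtype=float)
    amp = np.asarray(amplitude, dtype=float)
    if y.shape != amp.shape or y.ndim != 1:
        raise InputError("y and amplitude must be matching 1-D arrays")
    minima: List[float] = []
    for i in range(1, len(y) - 1):
        if amp[i] < amp[i - 1] and amp[i] <= amp[i + 1]:
            denom = amp[i - 1] - 2 * amp[i] + amp[i + 1]
            offset = 0.0 if denom == 0 else (amp[i - 1] - amp[i + 1]) / (2.0 * denom)
            minima.append(y[i] + offset * (y[i] - y[i - 1]))
    if window is not None:
        minima = [m for m in minima if window[0] <= m <= window[1]]
    if len(minima) < 2:
        raise FitError("fewer than two nodes found in the profile")
    return float(np.mean(np.diff(sorted(minima))))


def arf(Rd: float, pa: float, params: ARFParams | None = None) -> float:
    """Acoustic radiation force on a small drop in a standing wave.

    Fa = 2π² φ Rd³ pa² / (λa ρ0 c0²), valid while Rd/λa < 0.3 (a warning is
    emitted beyond).
    """
    params = params or ARFParams()
    if Rd < 0 or pa < 0:
        raise InputError("Rd and pa must be >= 0")
    if Rd / params.lam_a >= 0.3:
        warnings.warn("Rd/lam_a >= 0.3: small-drop ARF expression out of validity range")
    return (
        2.0
        * math.pi**2
        * params.phi
        * Rd**3
        * pa**2
        / (params.lam_a * params.rho0 * params.c0**2)
    )


def invert_arf(Fa: float, Rd: float, params: ARFParams | None = None) -> float:
    """Acoustic pressure amplitude that produces a given radiation force.

    Exact inverse of :func:`arf`:
    pa = sqrt(Fa λa ρ0 c0² / (2π² φ Rd³)).
    """
    params = params or ARFParams()
    if Fa <= 0:
        raise InputError("Fa must be positive")
    if Rd <= 0:
        raise InputError("Rd must be positive")
    return math.sqrt(
        Fa * params.lam_a * params.rho0 * params.c0**2 / (2.0 * math.pi**2 * params.phi * Rd**3)
    )


def critical_radius_gravity(gamma: float, rho_w: float = WATER_DENSITY, g: float = G) -> float:
    """Pendant-drop detachment radius from the surface-tension/gravity balance.

    R = sqrt(gamma / (rho g)) — the capillary length at which the weight of
    the growing pendant drop overcomes surface tension.
    """
    if min(gamma, rho_w, g) <= 0:
        raise InputError("gamma, rho_w and g must be positive")
    return math.sqrt(gamma / (rho_w * g))


def _y_basis(t: np.ndarray, m: float, dt_a: float) -> np.ndarray:
    """y(t) per unit force under the two-phase model (closed form)."""
    t = np.asarray(t, dtype=float)
    accel_phase = np.clip(t, 0.0, dt_a)
    coast = np.clip(t - dt_a, 0.0, None)
    return (accel_phase**2 / 2.0 + dt_a * coast) / m


def simulate_trajectory(
    drop: DropState | None = None,
    model: KineticModel | None = None,
    duration: float = 0.3,
    dt: float = 5e-3,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form (t, y, z) series of a deflected falling drop.

    Constant axial force Fa for t <= dt_a starting from rest, ballistic
    afterwards; gravity along z throughout, so z(t) = g t²/2 always.  No
    integrator is involved: the sampled trajectory is exact.
    """
    drop = drop or DropState()
    model = model or KineticModel()
    if dt <= 0 or duration <= 0:
        raise InputError("duration and dt must be positive")
    t = np.arange(0.0, duration + dt / 2.0, dt)
    y = drop.y + model.Fa * _y_basis(t, drop.m, model.dt_a)
    z = drop.z + model.g * t**2 / 2.0
    return t, y, z


def fit_trajectory_force(
    t: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    m: float,
    dt_a: float,
    g: float = G,
) -> TrajectoryFitResult:
    """Recover the axial force by least squares under the two-phase model.

    The vertical coordinate registers the time origin (z = g (t-t0)²/2, so
    t0 = mean(t - sqrt(2 z / g))); the axial coordinate is then linear in Fa
    through the closed-form basis, and the slope is the fitted force.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (t.shape == y.shape == z.shape) or t.ndim != 1:
        raise InputError("t, y, z must be matching 1-D arrays")
    if t.size < 4 or np.ptp(t) == 0:
        raise FitError("need >= 4 samples spanning a nonzero time range")
    t0 = float(np.mean(t - np.sqrt(np.clip(2.0 * z / g, 0.0, None))))
    ts = t - t0
    basis = _y_basis(ts, m, dt_a)
    denom = float(basis @ basis)
    if denom == 0:
        raise FitError("degenerate time base: no actuation-phase samples")
    # solve jointly for Fa and an axial offset (robust to a shifted origin)
    A = np.column_stack([basis, np.ones_like(basis)])
    coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    fa_hat = float(coef[0])
    residual = float(np.linalg.norm(y - A @ coef))
    return TrajectoryFitResult(Fa_hat=fa_hat, residual_norm=residual, n=t.size, t0=t0)
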