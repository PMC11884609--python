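"""Synthetic multicellular-aggregate populations and bright-field rendering.

Stands in for the instrument camera: draws parametric spheroid/cyst
geometries with realistic size and shape statistics, renders noiseless or
noisy bright-field frames with a Beer-Lambert absorption model, and produces
Poisson arrival streams for the encapsulation stage.

Optical model
-------------
An aggregate is a prolate ellipsoid with in-plane semi-axes ``a >= b`` and
out-of-plane semi-axis equal to ``b`` (the image is a 2-D projection; this
choice makes the center chord of a sphere exactly its diameter ``D``).  A
cyst carries a concentric monolayer shell of thickness ``t``; its lumen is
perfectly transparent, so the optical path through a cyst is the outer-chord
minus inner-chord difference.  Transmitted intensity follows
``I = I0 * exp(-L / h0)`` with ``L`` the chord length and ``h0`` the tissue
attenuation length.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .imaging import Frame

__all__ = [
    "OpticsConfig",
    "MCAGeometry",
    "PopulationConfig",
    "ArrivalStream",
    "sample_population",
    "chord_length",
    "render_frame",
    "generate_arrival_stream",
    "write_stack",
    "write_ground_truth",
]


@dataclass
class OpticsConfig:
    """Bright-field forward-model parameters.

    I0: incident intensity (arbitrary units).  h0: attenuation length (µm).
    pixel_scale: µm per pixel.  frame_size: pixels per side.  noise_sd:
    additive Gaussian noise standard deviation, relative to I0.
    """

    I0: float = 1.0
    h0: float = 140.0
    pixel_scale: float = 3.0
    frame_size: int = 256
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.I0 <= 0 or self.h0 <= 0 or self.pixel_scale <= 0:
            raise ConfigurationError("I0, h0 and pixel_scale must be positive")
        if self.frame_size < 1:
            raise ConfigurationError("frame_size must be >= 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


@dataclass
class MCAGeometry:
    """One spheroid or cyst: semi-axes (µm), orientation and shell thickness.

    kind: "spheroid" or "cyst".  a >= b > 0 are the in-plane semi-major and
    semi-minor axes; theta is the in-plane orientation (rad); t is the cyst
    monolayer thickness (µm, 0 for spheroids); center is the (x, y) offset of
    the aggregate from the frame center, in µm.
    """

    kind: str
    a: float
    b: float
    theta: float = 0.0
    t: float = 0.0
    center: tuple = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.kind not in ("spheroid", "cyst"):
            raise ConfigurationError("kind must be 'spheroid' or 'cyst'")
        if not (self.a >= self.b > 0):
            raise ConfigurationError("need a >= b > 0")
        if self.kind == "cyst" and not (0 < self.t < self.b):
            raise ConfigurationError("cyst thickness must satisfy 0 < t < b")
        if self.kind == "spheroid" and self.t != 0:
            raise ConfigurationError("spheroids have t = 0")

    @property
    def D(self) -> float:
        """Equivalent (projected-area) diameter 2*sqrt(a*b), µm."""
        return 2.0 * math.sqrt(self.a * self.b)

    @property
    def eccentricity(self) -> float:
        return math.sqrt(1.0 - (self.b / self.a) ** 2)


@dataclass
class PopulationConfig:
    """Distributional parameters of a synthetic MCA population.

    Diameters are drawn from a normal truncated below at ``diameter_floor``;
    eccentricities from a Beta distribution with the configured mean, clipped
    to [0, 0.95].  Cyst eccentricities are additionally capped at
    ``cyst_eccentricity_max``: cysts are near-spherical epithelial
    monolayers, whereas the apparent-eccentricity statistics describe plain
    spheroid populations (the cap also keeps the concentric shell
    t = D/ratio inside the minor axis, which requires e < ~0.79).
    """

    n: int = 100
    diameter_mean: float = 330.0
    diameter_sd: float = 60.0
    eccentricity_mean: float = 0.57
    cyst_fraction: float = 0.0
    cyst_thickness_ratio: float = 3.24
    cyst_eccentricity_max: float = 0.5
    diameter_floor: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ConfigurationError("n must be >= 0")
        if self.diameter_mean <= 0 or self.diameter_sd < 0:
            raise ConfigurationError("invalid diameter distribution")
        if not 0 <= self.eccentricity_mean < 1:
            raise ConfigurationError("eccentricity_mean must be in [0, 1)")
        if not 0 <= self.cyst_fraction <= 1:
            raise ConfigurationError("cyst_fraction must be in [0, 1]")
        if self.cyst_thickness_ratio <= 2:
            # t = D/ratio with ratio <= 2 would exceed the radius of a sphere
            raise ConfigurationError("cyst_thickness_ratio must exceed 2")
        if not 0 <= self.cyst_eccentricity_max < 0.787:
            raise ConfigurationError("cyst_eccentricity_max must be in [0, 0.787)")
        if self.diameter_floor <= 0:
            raise ConfigurationError("diameter_floor must be positive")


@dataclass
class ArrivalStream:
    """Detection timestamps of aggregates at the capillary exit."""

    timestamps: np.ndarray
    rate: float
    duration: float

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.timestamps.size and (
            np.any(np.diff(self.timestamps) <= 0)
            or self.timestamps[0] < 0
            or self.timestamps[-1] > self.duration
        ):
            raise ConfigurationError("timestamps must be strictly increasing in [0, duration]")


# Beta shape parameters reproducing the configured eccentricity mean:
# mean = alpha/(alpha+beta); alpha+beta = 5 fixes a realistic spread (~0.2 sd).
_ECC_CONCENTRATION = 5.0


def sample_population(config: PopulationConfig) -> List[MCAGeometry]:
    """Draw a reproducible population of spheroid/cyst geometries.

    Equivalent diameters D follow a truncated normal; apparent eccentricities
    e follow a Beta law with the configured mean; the in-plane semi-axes
    solve D = 2*sqrt(a*b) and e^2 = 1 - b^2/a^2.  Cysts get a shell of
    thickness t = D / cyst_thickness_ratio.
    """
    rng = np.random.default_rng(config.seed)
    if config.n == 0:
        return []
    if config.diameter_sd == 0:
        diameters = np.full(config.n, config.diameter_mean)
    else:
        lo = (config.diameter_floor - config.diameter_mean) / config.diameter_sd
        diameters = stats.truncnorm.rvs(
            lo,
            np.inf,
            loc=config.diameter_mean,
            scale=config.diameter_sd,
            size=config.n,
            random_state=rng,
        )
    alpha = config.eccentricity_mean * _ECC_CONCENTRATION
    beta = (1.0 - config.eccentricity_mean) * _ECC_CONCENTRATION
    if alpha <= 0:  # degenerate all-spherical population
        eccs = np.zeros(config.n)
    else:
        eccs = np.clip(rng.beta(alpha, beta, size=config.n), 0.0, 0.95)
    kinds = np.where(rng.random(config.n) < config.cyst_fraction, "cyst", "spheroid")
    thetas = rng.uniform(0.0, math.pi, size=config.n)
    out: List[MCAGeometry] = []
    for D, e, kind, theta in zip(diameters, eccs, kinds, thetas):
        if kind == "cyst":
            e = min(e, config.cyst_eccentricity_max)
        q = math.sqrt(1.0 - e**2)  # = b/a
        a = D / (2.0 * math.sqrt(q))
        b = D * math.sqrt(q) / 2.0
        t = D / config.cyst_thickness_ratio if kind == "cyst" else 0.0
        out.append(MCAGeometry(kind=str(kind), a=a, b=b, theta=float(theta), t=t))
    return out


def chord_length(geometry: MCAGeometry, point: Union[Sequence[float], np.ndarray]) -> np.ndarray:
    """Optical path length (µm) through an aggregate at in-plane point(s).

    ``point`` is (x, y) in µm relative to the frame center (an array of
    points may have any leading shape with a trailing axis of length 2).
    For a spheroid the chord through the prolate ellipsoid (out-of-plane
    semi-axis b) is ``2 b sqrt(1 - r^2)`` with r the normalised elliptical
    radius; for a cyst the transparent-lumen chord (through the inner,
    shell-offset ellipsoid) is subtracted.  Points outside the outline give 0.
    """
    pts = np.asarray(point, dtype=float)
    scalar = pts.ndim == 1
    pts = np.atleast_2d(pts)
    u = pts[..., 0] - geometry.center[0]
    v = pts[..., 1] - geometry.center[1]
    ct, st = math.cos(geometry.theta), math.sin(geometry.theta)
    x = u * ct + v * st
    y = -u * st + v * ct

    def _ellipsoid_chord(sa: float, sb: float) -> np.ndarray:
        r2 = (x / sa) ** 2 + (y / sb) ** 2
        return 2.0 * sb * np.sqrt(np.clip(1.0 - r2, 0.0, None))

    L = _ellipsoid_chord(geometry.a, geometry.b)
    if geometry.kind == "cyst":
        L = np.clip(L - _ellipsoid_chord(geometry.a - geometry.t, geometry.b - geometry.t), 0.0, None)
    return L[0] if scalar else L.reshape(np.asarray(point).shape[:-1])


def render_frame(
    geometry: Union[MCAGeometry, Sequence[MCAGeometry], None],
    optics: OpticsConfig | None = None,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    shell_ring_amplitude: float = 0.0,
) -> Frame:
    """Render a bright-field frame of zero, one or several aggregates.

    Per pixel: ``I = I0 * exp(-L/h0) + noise`` clipped to >= 0, with L the
    summed chord length over all aggregates.  The hydrogel capsule is not
    rendered by default; ``shell_ring_amplitude`` adds an optional faint dark
    ring just outside each outline for robustness experiments.
    """
    optics = optics or OpticsConfig()
    n = optics.frame_size
    geometries: Sequence[MCAGeometry]
    if geometry is None:
        geometries = []
    elif isinstance(geometry, MCAGeometry):
        geometries = [geometry]
    else:
        geometries = list(geometry)

    half = (n - 1) / 2.0
    coords = (np.arange(n) - half) * optics.pixel_scale
    xx, yy = np.meshgrid(coords, coords)
    pts = np.stack([xx, yy], axis=-1)

    half_extent = n * optics.pixel_scale / 2.0
    L = np.zeros((n, n))
    attenuation_extra = np.zeros((n, n))
    for g in geometries:
        if abs(g.center[0]) + g.a > half_extent or abs(g.center[1]) + g.a > half_extent:
            warnings.warn("geometry extends beyond the frame; it will be clipped")
        L += chord_length(g, pts)
        if shell_ring_amplitude > 0:
            u = xx - g.center[0]
            v = yy - g.center[1]
            ct, st = math.cos(g.theta), math.sin(g.theta)
            xr = u * ct + v * st
            yr = -u * st + v * ct
            r = np.sqrt((xr / g.a) ** 2 + (yr / g.b) ** 2)
            ring_w = 2.0 * optics.pixel_scale / (2.0 * g.b)
            attenuation_extra += shell_ring_amplitude * np.exp(-((r - 1.1) ** 2) / (2 * ring_w**2))

    pixels = optics.I0 * np.exp(-L / optics.h0) * (1.0 - attenuation_extra)
    if optics.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        pixels = pixels + rng.normal(0.0, optics.noise_sd * optics.I0, size=pixels.shape)
    return Frame(np.clip(pixels, 0.0, None), optics.pixel_scale)


def generate_arrival_stream(
    rate: float, duration: float, seed: Optional[int] = None
) -> ArrivalStream:
    """Homogeneous Poisson arrival process of aggregates at the capillary.

    Inter-arrival times are exponential with mean 1/rate; ``rate=0`` yields
    an empty stream.
    """
    if rate < 0:
        raise ConfigurationError("rate must be >= 0")
    if duration <= 0:
        raise ConfigurationError("duration must be positive")
    if rate == 0:
        return ArrivalStream(np.empty(0), rate, duration)
    rng = np.random.default_rng(seed)
    # draw with a safety margin, extend if the tail was not reached
    times: list = []
    t = 0.0
    n_guess = max(16, int(rate * duration * 1.5))
    while t <= duration:
        gaps = rng.exponential(1.0 / rate, size=n_guess)
        for g in gaps:
            t += g
            if t > duration:
                break
            times.append(t)
    return ArrivalStream(np.array(times), rate, duration)


def write_stack(
    frames: Sequence[Frame],
    path: Union[str, Path],
    fmt: str = "tiff",
    counts_per_unit: int = 10000,
) -> List[Path]:
    """Write frames as a 16-bit multi-page TIFF or a PNG sequence.

    Intensities are stored as ``round(I * counts_per_unit)`` in uint16; the
    scale is recorded in the TIFF description so readers can undo it.
    Returns the written path(s).
    """
    import imageio.v3 as iio
    import tifffile

    path = Path(path)
    arrays = [
        np.clip(np.round(f.pixels * counts_per_unit), 0, 65535).astype(np.uint16) for f in frames
    ]
    if fmt == "tiff":
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(
            path,
            np.stack(arrays) if arrays else np.zeros((0, 1, 1), np.uint16),
            photometric="minisblack",
            description=f"counts_per_unit={counts_per_unit}",
        )
        return [path]
    if fmt == "png":
        path.mkdir(parents=True, exist_ok=True)
        written = []
        for i, arr in enumerate(arrays):
            p = path / f"frame_{i:05d}.png"
            iio.imwrite(p, arr)
            written.append(p)
        return written
    raise ConfigurationError("fmt must be 'tiff' or 'png'")


def write_ground_truth(geometries: Sequence[MCAGeometry], path: Union[str, Path]) -> pd.DataFrame:
    """Write one ground-truth CSV row per geometry (kind, D, e, theta, t)."""
    df = pd.DataFrame(
        {
            "frame": np.arange(len(geometries)),
            "kind": [g.kind for g in geometries],
            "D_um": [g.D for g in geometries],
            "e": [g.eccentricity for g in geometries],
            "theta_rad": [g.theta for g in geometries],
            "t_um": [g.t for g in geometries],
        }
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return df
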