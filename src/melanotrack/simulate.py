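"""Synthetic trajectory and geometry generation.

Each trajectory is built from one of the elementary motion processes that
compose intracellular cargo movement — free diffusion, constant-velocity
directed transport (with or without a diffusive component), elastic tethering
to a fixed point, and confinement — optionally degraded by Gaussian
localization noise and pixel quantization, in that order, mirroring the
physical imaging chain.

Discretization is exact, not Euler: Brownian steps are Gaussian with variance
2·D·Δt per coordinate, and the tethered process uses the exact discrete
Ornstein–Uhlenbeck update, so closed-form ensemble checks are tight at any
frame interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np

from .core import AcquisitionSettings, Trajectory
from .errors import InvalidParameterError

PROCESSES = ("brownian", "directional", "brownian_drift", "tethered", "confined")


@dataclass(frozen=True)
class SimulationParams:
    """Specification of one generating process.

    Parameters
    ----------
    process : str
        One of ``brownian``, ``directional``, ``brownian_drift``,
        ``tethered``, ``confined``.
    D : float
        Diffusion coefficient, μm²/s.
    V : float
        Transport speed, μm/s (directional processes).
    heading : float
        Direction of transport, radians.
    k : float
        Tether relaxation rate, 1/s (tethered process).
    box_side : float, optional
        Side of the reflecting square box, μm (confined process).
    noise_sigma : float
        Per-coordinate Gaussian localization noise, μm, applied after the
        process when using :func:`generate_population`.
    origin : tuple of float
        Starting position (and tether/box centre), μm.
    seed : int, optional
        Seed for the process' own randomness when simulated standalone.
    """

    process: str
    D: float = 0.0
    V: float = 0.0
    heading: float = 0.0
    k: float = 0.0
    box_side: Optional[float] = None
    box_center: Optional[Tuple[float, float]] = None  # defaults to origin
    noise_sigma: float = 0.0
    origin: Tuple[float, float] = (0.0, 0.0)
    seed: Optional[int] = None

    def __post_init__(self):
        if self.process not in PROCESSES:
            raise InvalidParameterError(f"unknown process {self.process!r}")
        if self.D < 0:
            raise InvalidParameterError("D must be >= 0")
        if self.V < 0:
            raise InvalidParameterError("V must be >= 0")
        if self.k < 0:
            raise InvalidParameterError("k must be >= 0")
        if self.noise_sigma < 0:
            raise InvalidParameterError("noise_sigma must be >= 0")
        if self.process == "confined":
            if self.box_side is None or not self.box_side > 0:
                raise InvalidParameterError("confined motion needs box_side > 0")
        if self.process == "tethered" and not self.k > 0:
            raise InvalidParameterError("tethered motion needs k > 0")


def _rng_for(params: SimulationParams, rng: Optional[np.random.Generator]):
    if rng is not None:
        return rng
    return np.random.default_rng(params.seed)


def _blank(params, settings, positions, track_id):
    return Trajectory(
        track_id=track_id,
        frames=np.arange(settings.n_frames),
        positions=positions,
        settings=settings,
        provenance=params,
    )


def simulate_brownian(
    params: SimulationParams,
    settings: AcquisitionSettings,
    rng: Optional[np.random.Generator] = None,
    track_id: str = "sim",
) -> Trajectory:
    """Free 2D diffusion: independent Gaussian increments N(0, 2·D·Δt) per axis.

    Ensemble MSD is 4·D·τ at every lag.
    """
    if params.process not in ("brownian", "brownian_drift"):
        raise InvalidParameterError("params.process must be brownian/brownian_drift")
    rng = _rng_for(params, rng)
    n, dt = settings.n_frames, settings.frame_interval
    steps = rng.normal(0.0, math.sqrt(2.0 * params.D * dt), size=(n - 1, 2)) \
        if params.D > 0 else np.zeros((n - 1, 2))
    pos = np.empty((n, 2))
    pos[0] = params.origin
    np.cumsum(steps, axis=0, out=pos[1:])
    pos[1:] += params.origin
    if params.process == "brownian_drift" and params.V > 0:
        t = np.arange(n)[:, None] * dt
        drift = params.V * t * np.array([math.cos(params.heading), math.sin(params.heading)])
        pos = pos + drift
    return _blank(params, settings, pos, track_id)


def simulate_directional(
    params: SimulationParams,
    settings: AcquisitionSettings,
    rng: Optional[np.random.Generator] = None,
    track_id: str = "sim",
) -> Trajectory:
    """Deterministic constant-velocity transport along a fixed heading.

    Noiseless MSD is exactly V²·τ² at every lag.
    """
    if params.process != "directional":
        raise InvalidParameterError("params.process must be 'directional'")
    n, dt = settings.n_frames, settings.frame_interval
    t = np.arange(n)[:, None] * dt
    u = np.array([math.cos(params.heading), math.sin(params.heading)])
    pos = np.asarray(params.origin) + params.V * t * u
    return _blank(params, settings, pos, track_id)


def simulate_tethered(
    params: SimulationParams,
    settings: AcquisitionSettings,
    rng: Optional[np.random.Generator] = None,
    track_id: str = "sim",
) -> Trajectory:
    """Elastic tethering to a fixed point: exact discrete Ornstein–Uhlenbeck.

    Per coordinate, about the origin, with relaxation rate ``k`` and diffusion
    ``D``::

        x[i+1] = origin + (x[i] − origin)·e^(−kΔt) + N(0, (D/k)(1 − e^(−2kΔt)))

    The stationary variance is D/k per coordinate, hence a long-lag ensemble
    MSD plateau of 4·D/k in 2D.
    """
    if params.process != "tethered":
        raise InvalidParameterError("params.process must be 'tethered'")
    rng = _rng_for(params, rng)
    n, dt = settings.n_frames, settings.frame_interval
    decay = math.exp(-params.k * dt)
    sd = math.sqrt((params.D / params.k) * (1.0 - decay**2)) if params.D > 0 else 0.0
    origin = np.asarray(params.origin, dtype=float)
    pos = np.empty((n, 2))
    pos[0] = origin
    innov = rng.normal(0.0, sd, size=(n - 1, 2)) if sd > 0 else np.zeros((n - 1, 2))
    x = np.zeros(2)  # displacement from tether point
    for i in range(1, n):
        x = x * decay + innov[i - 1]
        pos[i] = origin + x
    return _blank(params, settings, pos, track_id)


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold coordinates into [lo, hi] by mirror reflection (any excursion size)."""
    width = hi - lo
    y = np.mod(x - lo, 2.0 * width)
    y = width - np.abs(y - width)
    return lo + y


def simulate_confined(
    params: SimulationParams,
    settings: AcquisitionSettings,
    rng: Optional[np.random.Generator] = None,
    track_id: str = "sim",
) -> Trajectory:
    """Diffusion inside an axis-aligned square with reflecting walls.

    Proposed Brownian increments are folded back per axis (mirror reflection,
    repeated implicitly for large excursions), which preserves the uniform
    equilibrium distribution; the long-lag ensemble MSD plateau is
    box_side²/3 in 2D.
    """
    if params.process != "confined":
        raise InvalidParameterError("params.process must be 'confined'")
    L = params.box_side
    cx, cy = params.box_center if params.box_center is not None else params.origin
    lo = np.array([cx - L / 2.0, cy - L / 2.0])
    hi = np.array([cx + L / 2.0, cy + L / 2.0])
    start = np.asarray(params.origin, dtype=float)
    if np.any(start < lo) or np.any(start > hi):
        raise InvalidParameterError("origin lies outside the confinement box")
    rng = _rng_for(params, rng)
    n, dt = settings.n_frames, settings.frame_interval
    sd = math.sqrt(2.0 * params.D * dt)
    steps = rng.normal(0.0, sd, size=(n - 1, 2)) if params.D > 0 else np.zeros((n - 1, 2))
    pos = np.empty((n, 2))
    pos[0] = start
    for i in range(1, n):
        proposal = pos[i - 1] + steps[i - 1]
        pos[i, 0] = _reflect(proposal[0], lo[0], hi[0])
        pos[i, 1] = _reflect(proposal[1], lo[1], hi[1])
    return _blank(params, settings, pos, track_id)


_SIMULATORS = {
    "brownian": simulate_brownian,
    "brownian_drift": simulate_brownian,
    "directional": simulate_directional,
    "tethered": simulate_tethered,
    "confined": simulate_confined,
}


def simulate(
    params: SimulationParams,
    settings: AcquisitionSettings,
    rng: Optional[np.random.Generator] = None,
    track_id: str = "sim",
) -> Trajectory:
    """Simulate one trajectory of the process named in ``params``."""
    return _SIMULATORS[params.process](params, settings, rng=rng, track_id=track_id)


def add_localization_noise(
    traj: Trajectory,
    noise_sigma: float,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Trajectory:
    """Add independent N(0, σ²) localization error to every coordinate.

    Returns a new trajectory; the input is unmodified. In 2D the noise offsets
    the ensemble MSD by 4σ² at every positive lag.
    """
    if noise_sigma < 0:
        raise InvalidParameterError("noise_sigma must be >= 0")
    if noise_sigma == 0:
        return traj.with_positions(traj.positions.copy())
    if rng is None:
        rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sigma, size=traj.positions.shape)
    return traj.with_positions(traj.positions + noise)


def quantize_to_pixels(traj: Trajectory) -> Trajectory:
    """Round every coordinate to the nearest multiple of the pixel size.

    Idempotent; the per-coordinate quantization error is at most half a pixel.
    """
    px = traj.settings.pixel_size
    return traj.with_positions(np.round(traj.positions / px) * px)


def generate_population(
    spec: Sequence[Tuple[SimulationParams, int]],
    settings: AcquisitionSettings,
    seed: int,
    noise_sigma: Optional[float] = None,
    quantize: bool = False,
    id_prefix: str = "sim",
) -> list:
    """Generate a labelled population of trajectories from (params, count) pairs.

    One root seed spawns independent per-trajectory child streams by index, so
    the population is reproducible and individual members are independent.
    Noise (from each trajectory's params unless overridden) and optional pixel
    quantization are applied after the process, in that order. The returned
    trajectories carry their generating params as provenance; the shuffle
    order is deterministic in the seed.
    """
    spec = list(spec)
    if not spec:
        raise InvalidParameterError("population spec is empty")
    if any(count < 0 for _, count in spec):
        raise InvalidParameterError("counts must be >= 0")
    total = sum(count for _, count in spec)
    root = np.random.SeedSequence(seed)
    children = root.spawn(total + 1)
    trajs = []
    i = 0
    for params, count in spec:
        for _ in range(count):
            rng = np.random.default_rng(children[i])
            traj = simulate(params, settings, rng=rng, track_id=f"{id_prefix}-{i:04d}")
            sigma = params.noise_sigma if noise_sigma is None else noise_sigma
            if sigma > 0:
                traj = add_localization_noise(traj, sigma, rng=rng)
            if quantize:
                traj = quantize_to_pixels(traj)
            trajs.append(traj)
            i += 1
    order = np.random.default_rng(children[total]).permutation(total)
    return [trajs[j] for j in order]


def wt_like_spec(
    D: float = 2.5e-4,
    V: float = 0.04,
    n_brownian: int = 60,
    n_directional: int = 15,
) -> list:
    """Population spec emulating a control-like melanosome population.

    Mostly diffusive with a minority of directed tracks; every track keeps
    the diffusive background (transport superimposes drift on diffusion, as
    in real recordings). Magnitudes are chosen so per-track total distances
    over 5 min land near the low tens of μm.
    """
    return [
        (SimulationParams("brownian", D=D), n_brownian),
        (SimulationParams("brownian_drift", D=D, V=V, heading=0.8), n_directional),
    ]


def knockdown_like_spec(
    D: float = 2.5e-4,
    V: float = 0.06,
    n_brownian: int = 30,
    n_directed: int = 45,
) -> list:
    """Population spec emulating a retrograde-motor-depleted population.

    A majority of tracks carry a directed (drift) component on top of
    diffusion, yielding longer total/Euclidean distances, fewer pauses and a
    right-shifted MSD-exponent distribution relative to :func:`wt_like_spec`.
    """
    return [
        (SimulationParams("brownian", D=D), n_brownian),
        (SimulationParams("brownian_drift", D=D, V=V, heading=-0.4), n_directed),
    ]


def generate_cell_geometry(
    nucleus_radius: float,
    cell_radius: float,
    nucleus_offset: float = 0.0,
    seed: Optional[int] = None,
    wobble: float = 0.0,
    band_width: float = 2.0,
    resolution: int = 256,
):
    """Synthetic circular nucleus + cell outlines for spatial quantification.

    The nucleus centre is displaced by ``nucleus_offset`` μm along +x from the
    cell centre, so large offsets make the perinuclear band protrude beyond
    the cell edge (exercising out-of-cell subtraction); disjoint geometries
    are permitted as a degenerate case. ``wobble`` adds a seeded radial
    perturbation (fractional amplitude) to both outlines for polygonal,
    non-circular variants.
    """
    from .spatial import CellGeometry, _circle_polygon  # deferred: avoid cycle

    if not nucleus_radius > 0 or not cell_radius > 0:
        raise InvalidParameterError("radii must be > 0")
    rng = np.random.default_rng(seed)

    def outline(center, radius):
        if wobble > 0:
            n = 4 * resolution
            theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
            r = radius * (1.0 + wobble * rng.uniform(-1.0, 1.0, size=n))
            from shapely.geometry import Polygon

            pts = np.column_stack(
                [center[0] + r * np.cos(theta), center[1] + r * np.sin(theta)]
            )
            return Polygon(pts).buffer(0)
        return _circle_polygon(center, radius, resolution)

    nucleus = outline((nucleus_offset, 0.0), nucleus_radius)
    cell = outline((0.0, 0.0), cell_radius)
    return CellGeometry(nucleus=nucleus, cell=cell, band_width=band_width)
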