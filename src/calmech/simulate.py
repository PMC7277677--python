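"""Synthetic calcium-imaging movies and AFM force curves with known ground truth.

The movie forward model mirrors the signal shape assumed by the analysis:
somatic Ca2+ transients with an instantaneous rise and a first-order
exponential decay, riding on a constant baseline, attenuated by a
multiplicative whole-frame photobleaching decay, plus additive Gaussian
camera noise.  Event trains are homogeneous Poisson processes; an optional
group of cells shares a single train to emulate network synchrony.

The force-curve generator evaluates the Hertz sphere-on-plane contact model
F(delta) = (4/3) * E/(1-nu^2) * sqrt(R) * delta^(3/2)
on an indentation grid up to a force setpoint, with additive force noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from calmech.mechanics import ForceCurve

__all__ = [
    "SimConfig",
    "GroundTruth",
    "MovieStack",
    "ForceCurveSimConfig",
    "generate_ground_truth",
    "render_movie",
    "generate_force_curve",
]


@dataclass
class SimConfig:
    """Parameters of a synthetic spontaneous-activity movie.

    Defaults follow the acquisition geometry of the analysed recordings
    (640x250 px, 20 s at 30 Hz) and physiologically plausible transient
    parameters (event rate 0.05-0.6 Hz, tau 1-2 s, dF/F a few percent).
    """

    frame_count: int = 600
    frame_rate: float = 30.0          # Hz
    height: int = 250                 # px
    width: int = 640                  # px
    n_cells: int = 5
    soma_radius: int = 4              # px, hard-disk footprint
    event_rate: float = 0.3           # Hz per cell
    tau_true: float = 1.5             # s, decay constant
    amp_true: float = 0.06            # dF/F fraction at the peak
    baseline: float = 1000.0          # counts
    bleach_fraction: float = 0.1      # intensity lost over the recording
    noise_sd: float = 2.0             # counts, additive Gaussian
    noise_model: str = "gaussian"     # "gaussian" or "poisson"
    sync_group: list[int] = field(default_factory=list)
    seed: int = 0

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.frame_count / self.frame_rate

    def validate(self) -> None:
        if self.frame_count < 1:
            raise ValueError("frame_count must be >= 1")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if not 0 <= self.bleach_fraction < 1:
            raise ValueError("bleach_fraction must lie in [0, 1)")
        if self.amp_true < 0:
            raise ValueError("amp_true must be non-negative")
        if self.event_rate < 0:
            raise ValueError("event_rate must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError("noise_model must be 'gaussian' or 'poisson'")
        if any(i < 0 or i >= self.n_cells for i in self.sync_group):
            raise ValueError("sync_group indices must reference existing cells")
        if self.n_cells and 2 * self.soma_radius + 1 > min(self.height, self.width):
            raise ValueError("soma_radius too large for the frame")


@dataclass
class GroundTruth:
    """Truth sidecar for a synthetic movie: footprints, event times, parameters."""

    cell_centers: np.ndarray          # (n_cells, 2) int, (row, col)
    footprint_masks: np.ndarray       # (n_cells, H, W) bool, pairwise disjoint
    event_times: list[np.ndarray]     # seconds, per cell
    tau_true: float
    amp_true: float
    bleach_fraction: float

    def to_dict(self) -> dict:
        return {
            "cell_centers": self.cell_centers.tolist(),
            "event_times": [t.tolist() for t in self.event_times],
            "tau_true": self.tau_true,
            "amp_true": self.amp_true,
            "bleach_fraction": self.bleach_fraction,
        }


@dataclass
class MovieStack:
    """A T x H x W intensity stack with its frame rate."""

    data: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("stack must be T x H x W")
        if not np.all(np.isfinite(self.data)) or np.any(self.data < 0):
            raise ValueError("intensities must be finite and non-negative")

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds, frame 0 at t = 0."""
        return np.arange(self.data.shape[0]) / self.frame_rate


@dataclass
class ForceCurveSimConfig:
    """Parameters of a synthetic nanoindentation curve.

    Probe defaults match a 6.65 um silica microsphere glued to a ~4 N/m
    cantilever, driven to a 120 nN force setpoint; the sample is treated as
    an incompressible elastic half-space (nu = 0.5).
    """

    E_true: float = 100e3             # Pa
    poisson_ratio: float = 0.5
    sphere_radius: float = 3.325e-6   # m
    spring_constant: float = 4.0      # N/m
    max_force: float = 120e-9         # N
    noise_sd: float = 0.0             # N
    n_points: int = 200
    seed: int = 0

    def validate(self) -> None:
        if self.E_true <= 0:
            raise ValueError("E_true must be positive")
        if not 0 <= self.poisson_ratio <= 0.5:
            raise ValueError("poisson_ratio must lie in [0, 0.5]")
        if self.sphere_radius <= 0 or self.spring_constant <= 0:
            raise ValueError("sphere_radius and spring_constant must be positive")
        if self.max_force <= 0:
            raise ValueError("max_force must be positive")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")


def _place_centers(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample non-overlapping disk centers fully inside the frame."""
    r = config.soma_radius
    centers: list[tuple[int, int]] = []
    max_tries = 1000 * max(config.n_cells, 1)
    tries = 0
    while len(centers) < config.n_cells:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"cannot place {config.n_cells} non-overlapping somata of "
                f"radius {r} in a {config.height}x{config.width} frame"
            )
        row = int(rng.integers(r, config.height - r))
        col = int(rng.integers(r, config.width - r))
        if all((row - cr) ** 2 + (col - cc) ** 2 > (2 * r + 1) ** 2
               for cr, cc in centers):
            centers.append((row, col))
    return np.array(centers, dtype=int).reshape(config.n_cells, 2)


def _disk_mask(center: tuple[int, int], radius: int,
               shape: tuple[int, int]) -> np.ndarray:
    rows, cols = np.ogrid[: shape[0], : shape[1]]
    return (rows - center[0]) ** 2 + (cols - center[1]) ** 2 <= radius**2


def generate_ground_truth(config: SimConfig) -> GroundTruth:
    """Draw cell positions and Poisson event trains for a synthetic movie.

    Cells listed in ``config.sync_group`` share one event train; all other
    cells receive independent homogeneous Poisson trains at
    ``config.event_rate``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    centers = _place_centers(config, rng)
    shape = (config.height, config.width)
    masks = np.stack(
        [_disk_mask(tuple(c), config.soma_radius, shape) for c in centers]
    ) if config.n_cells else np.zeros((0,) + shape, dtype=bool)

    def poisson_train() -> np.ndarray:
        n = rng.poisson(config.event_rate * config.duration)
        return np.sort(rng.uniform(0.0, config.duration, size=n))

    sync = set(config.sync_group)
    shared = poisson_train() if sync else None
    event_times = [
        shared.copy() if i in sync else poisson_train()
        for i in range(config.n_cells)
    ]
    return GroundTruth(
        cell_centers=centers,
        footprint_masks=masks,
        event_times=event_times,
        tau_true=config.tau_true,
        amp_true=config.amp_true,
        bleach_fraction=config.bleach_fraction,
    )


def transient_kernel(t: np.ndarray, event_times: np.ndarray,
                     tau: float) -> np.ndarray:
    """Sum of instantaneous-rise / exponential-decay transients at ``t``.

    Each event contributes exp(-(t - t_e)/tau) for t >= t_e and 0 before.
    """
    if len(event_times) == 0:
        return np.zeros_like(t, dtype=float)
    dt = t[:, None] - np.asarray(event_times)[None, :]
    return np.where(dt >= 0, np.exp(-dt / tau), 0.0).sum(axis=1)


def bleach_profile(t: np.ndarray, bleach_fraction: float,
                   duration: float) -> np.ndarray:
    """Multiplicative photobleaching decay exp(-lambda t).

    lambda is chosen so that a fraction ``bleach_fraction`` of the intensity
    is lost over ``duration``.
    """
    if bleach_fraction == 0:
        return np.ones_like(t, dtype=float)
    lam = -np.log(1.0 - bleach_fraction) / duration
    return np.exp(-lam * t)


def render_movie(truth: GroundTruth, config: SimConfig) -> MovieStack:
    """Render a movie from ground truth.

    Soma pixels carry ``baseline * (1 + amp * sum of kernels) * bleach(t)``,
    background pixels ``baseline * bleach(t)``; additive noise everywhere.
    """
    config.validate()
    if len(truth.event_times) != config.n_cells:
        raise ValueError("ground truth inconsistent with config")
    rng = np.random.default_rng(config.seed + 1)  # independent of placement
    t = np.arange(config.frame_count) / config.frame_rate
    bleach = bleach_profile(t, config.bleach_fraction, config.duration)

    stack = np.broadcast_to(
        (config.baseline * bleach)[:, None, None],
        (config.frame_count, config.height, config.width),
    ).copy()
    for mask, times in zip(truth.footprint_masks, truth.event_times):
        signal = config.baseline * (
            1.0 + config.amp_true * transient_kernel(t, times, config.tau_true)
        ) * bleach
        stack[:, mask] = signal[:, None]

    if config.noise_model == "poisson":
        stack = rng.poisson(stack).astype(float)
    elif config.noise_sd > 0:
        stack = stack + rng.normal(0.0, config.noise_sd, size=stack.shape)
    return MovieStack(data=np.clip(stack, 0.0, None), frame_rate=config.frame_rate)


def hertz_force(delta: np.ndarray, E: float, poisson_ratio: float,
                sphere_radius: float) -> np.ndarray:
    """Hertz sphere-on-plane force at indentation ``delta`` (SI units)."""
    delta = np.asarray(delta, dtype=float)
    return (4.0 / 3.0) * (E / (1.0 - poisson_ratio**2)) \
        * np.sqrt(sphere_radius) * np.clip(delta, 0.0, None) ** 1.5


def generate_force_curve(config: ForceCurveSimConfig) -> ForceCurve:
    """Generate a synthetic indentation curve up to the force setpoint.

    The maximum indentation solves F(delta_max) = max_force for the Hertz
    model; the abscissa is indentation directly (piezo-to-indentation
    conversion is exercised separately on hard-surface calibration curves).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    delta_max = (
        3.0 * config.max_force * (1.0 - config.poisson_ratio**2)
        / (4.0 * config.E_true * np.sqrt(config.sphere_radius))
    ) ** (2.0 / 3.0)
    delta = np.linspace(0.0, delta_max, config.n_points)
    force = hertz_force(delta, config.E_true, config.poisson_ratio,
                        config.sphere_radius)
    if config.noise_sd > 0:
        force = force + rng.normal(0.0, config.noise_sd, size=force.shape)
    return ForceCurve(
        displacement=delta,
        force=force,
        spring_constant=config.spring_constant,
        sphere_radius=config.sphere_radius,
        poisson_ratio=config.poisson_ratio,
        is_indentation=True,
    )
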