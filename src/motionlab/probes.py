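"""Probe stimuli for in-silico electrophysiology and psychophysics.

Drifting sinusoidal gratings, 135-degree plaids, random-dot fields
(phi / reverse-phi, coherence, opponency) and the two-frame edge
stimuli/filters used in the cross-correlation simulation.  All stimuli
share the corpus conventions: frames indexed ``[y, x, t]``, x rightward,
y upward, direction counterclockwise from rightward, intensities in
[-1, 1].

Grating parameters are expressed as periods (px/cycle spatially,
frames/cycle temporally); drift speed is spatial_period/temporal_period
px/frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import warnings

import numpy as np

from .corpus import MotionSequence

__all__ = [
    "GratingSpec",
    "PlaidSpec",
    "DotSpec",
    "grating",
    "plaid",
    "dot_sequence",
    "edge_stimulus",
    "edge_filter",
]

DEFAULT_SIZE = 32
DEFAULT_FRAMES = 6


@dataclass(frozen=True)
class GratingSpec:
    direction: float  # deg CCW from rightward
    spatial_period: float  # px/cycle
    temporal_period: float  # frames/cycle
    phase: float = 0.0  # deg
    size: int = DEFAULT_SIZE
    n_frames: int = DEFAULT_FRAMES
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.spatial_period <= 0 or self.temporal_period <= 0:
            raise ValueError("grating periods must be positive")
        if not 0 < self.amplitude <= 1:
            raise ValueError("amplitude must lie in (0, 1]")

    @property
    def speed(self) -> float:
        """Drift speed in px/frame."""
        return self.spatial_period / self.temporal_period


@dataclass(frozen=True)
class PlaidSpec:
    pattern_direction: float
    separation: float = 135.0
    spatial_period: float = 12.0
    temporal_period: float = 6.0
    phase: float = 0.0
    size: int = DEFAULT_SIZE
    n_frames: int = DEFAULT_FRAMES
    amplitude: float = 1.0

    @property
    def component_directions(self) -> tuple[float, float]:
        half = self.separation / 2.0
        return (
            (self.pattern_direction - half) % 360.0,
            (self.pattern_direction + half) % 360.0,
        )


@dataclass(frozen=True)
class DotSpec:
    n_dots: int = 5
    dot_radius: float = 4.0
    dot_value: float = 1.0
    background_value: float = 0.0
    speed: float = 3.0
    signal_direction: float = 0.0
    coherence: float = 1.0
    polarity_reversal: bool = False  # reverse-phi: dots flip sign after frame 1
    n_motion_frames: int = DEFAULT_FRAMES  # frames actually containing dots
    n_frames: int = DEFAULT_FRAMES
    size: int = DEFAULT_SIZE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dots < 1:
            raise ValueError("need at least one dot")
        if not 0.0 <= self.coherence <= 1.0:
            raise ValueError("coherence must lie in [0, 1]")
        if not (-1 <= self.dot_value <= 1 and -1 <= self.background_value <= 1):
            raise ValueError("dot and background values must lie in [-1, 1]")
        if self.dot_radius >= self.size:
            raise ValueError("dot radius must be smaller than the image")


def grating(spec: GratingSpec) -> MotionSequence:
    """Drifting sinusoidal luminance grating.

    Luminance at (x, y, t) is ``A * sin(2*pi*(f_s * u - f_t * t) + phase)``
    where ``u`` is position along the drift direction, so the pattern
    moves at ``spatial_period / temporal_period`` px/frame toward
    ``direction``.
    """
    fs = 1.0 / spec.spatial_period
    ft = 1.0 / spec.temporal_period
    theta = np.radians(spec.direction)
    y, x, t = np.meshgrid(
        np.arange(spec.size),
        np.arange(spec.size),
        np.arange(spec.n_frames),
        indexing="ij",
    )
    u = x * np.cos(theta) + y * np.sin(theta)
    frames = spec.amplitude * np.sin(
        2.0 * np.pi * (fs * u - ft * t) + np.radians(spec.phase)
    )
    v = spec.speed
    return MotionSequence(
        frames=frames,
        v_x=v * np.cos(theta),
        v_y=v * np.sin(theta),
    )


def plaid(spec: PlaidSpec) -> MotionSequence:
    """Superposition of two half-amplitude gratings split about the
    pattern direction; the sum stays in [-1, 1]."""
    d1, d2 = spec.component_directions
    common = dict(
        spatial_period=spec.spatial_period,
        temporal_period=spec.temporal_period,
        phase=spec.phase,
        size=spec.size,
        n_frames=spec.n_frames,
        amplitude=spec.amplitude / 2.0,
    )
    g1 = grating(GratingSpec(direction=d1, **common))
    g2 = grating(GratingSpec(direction=d2, **common))
    theta = np.radians(spec.pattern_direction)
    # pattern drifts at component_speed / cos(separation/2) along its axis
    cos_half = np.cos(np.radians(spec.separation / 2.0))
    pattern_speed = (spec.spatial_period / spec.temporal_period) / cos_half if cos_half != 0 else np.nan
    return MotionSequence(
        frames=g1.frames + g2.frames,
        v_x=pattern_speed * np.cos(theta),
        v_y=pattern_speed * np.sin(theta),
    )


def _raster_dots(
    canvas: np.ndarray, centers: np.ndarray, radius: float, value: float, size: int
) -> None:
    """Draw filled discs with wrap-around, overlapping with occlusion.

    A pixel belongs to a disc when its centre lies within ``radius`` of
    the (subpixel, wrapped) dot centre; no anti-aliasing.  All dots in a
    frame share one value, so occlusion order is immaterial and the
    union of discs can be painted at once.
    """
    coords = np.arange(size)
    cx = centers[:, 0] % size
    cy = centers[:, 1] % size
    dx = np.abs(coords[None, :] - cx[:, None])
    dy = np.abs(coords[None, :] - cy[:, None])
    dx = np.minimum(dx, size - dx)  # toroidal distance
    dy = np.minimum(dy, size - dy)
    # covered[j, y, x] via separable squared distances
    covered = (dy[:, :, None] ** 2 + dx[:, None, :] ** 2) <= radius * radius
    canvas[covered.any(axis=0)] = value


def dot_sequence(spec: DotSpec) -> MotionSequence:
    """Random-dot kinematogram.

    A fraction ``coherence`` of dots translate along ``signal_direction``;
    each remaining noise dot keeps an independent uniform-random direction
    for the whole sequence.  All dots move at ``speed`` px/frame and wrap
    at the image edges.  With ``polarity_reversal`` the dot value is
    negated from the second frame onward (reverse-phi); frames beyond
    ``n_motion_frames`` are uniform background.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.size
    pos0 = rng.uniform(0.0, size, size=(spec.n_dots, 2))  # (x, y)
    n_signal = int(round(spec.coherence * spec.n_dots))
    dirs = np.full(spec.n_dots, np.radians(spec.signal_direction))
    if n_signal < spec.n_dots:
        dirs[n_signal:] = rng.uniform(0.0, 2.0 * np.pi, size=spec.n_dots - n_signal)
    vel = spec.speed * np.stack([np.cos(dirs), np.sin(dirs)], axis=1)
    frames = np.full((size, size, spec.n_frames), spec.background_value)
    sig_v = spec.speed * np.array(
        [np.cos(np.radians(spec.signal_direction)), np.sin(np.radians(spec.signal_direction))]
    )
    for k in range(min(spec.n_motion_frames, spec.n_frames)):
        value = spec.dot_value
        if spec.polarity_reversal and k >= 1:
            value = -spec.dot_value
        centers = pos0 + k * vel
        canvas = frames[:, :, k]
        _raster_dots(canvas, centers, spec.dot_radius, value, size)
    return MotionSequence(frames=frames, v_x=float(sig_v[0]), v_y=float(sig_v[1]))


def _edge_frame(size: int, midline: float, flip: bool = False) -> np.ndarray:
    """White(+1)/black(-1) vertical half-fields: white left of the
    midline, black right (flipped when ``flip``)."""
    col = np.where(np.arange(size) < midline, 1.0, -1.0)
    if flip:
        col = -col
    return np.tile(col, (size, 1))


def _edge_volume(size: int, displacement: float, leftward: bool, flip_t0: bool, flip_t1: bool) -> np.ndarray:
    mid = size / 2.0
    f0 = _edge_frame(size, mid, flip_t0)
    d = -displacement if leftward else displacement
    f1 = _edge_frame(size, mid + d, flip_t1)
    return np.stack([f0, f1], axis=2)


def edge_stimulus(displacement: float, reverse_polarity: bool = False, size: int = 16) -> MotionSequence:
    """Two-frame edge stimulus: abutting white/black vertical half-fields
    centred on the midline at t=0, displaced rightward at t=1; with
    ``reverse_polarity`` the second frame is additionally negated
    (reverse-phi)."""
    if displacement not in (1, 2, 3):
        warnings.warn(
            f"edge displacement {displacement} outside the canonical 1-3 px range",
            stacklevel=2,
        )
    vol = _edge_volume(size, displacement, leftward=False, flip_t0=False, flip_t1=reverse_polarity)
    return MotionSequence(frames=vol, v_x=float(displacement), v_y=0.0)


def edge_filter(
    displacement: float,
    polarity_order: str = "light-dark",
    direction: str = "+vx",
    size: int = 8,
) -> np.ndarray:
    """Spatiotemporal edge filter (size x size x 2): a white/black edge on
    the midline at t=0 moving by ``displacement`` px rightward ('+vx') or
    leftward ('-vx') at t=1.  ``polarity_order`` sets which side is white:
    'light-dark' puts white on the left."""
    if direction not in {"+vx", "-vx"}:
        raise ValueError("direction must be '+vx' or '-vx'")
    if polarity_order not in {"light-dark", "dark-light"}:
        raise ValueError("polarity_order must be 'light-dark' or 'dark-light'")
    flip = polarity_order == "dark-light"
    return _edge_volume(size, displacement, leftward=direction == "-vx", flip_t0=flip, flip_t1=flip)
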