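"""Synthetic naturalistic motion corpus.

Training stimuli are 32x32x6 grayscale sequences showing a rigidly
translating textured surface viewed through a window.  The textures are
Gaussian random fields with a power-law (approximately 1/f) amplitude
spectrum, the dominant second-order statistic of natural images; an
optional ingest path accepts user-supplied grayscale images instead.

Conventions used throughout the package:

* frames are indexed ``[y, x, t]``; x increases rightward, y upward;
* direction is measured in degrees counterclockwise from rightward
  (0 deg = motion toward +x);
* a sequence moving at speed ``s`` in direction ``d`` has ground-truth
  velocity ``v_x = s*cos(d)``, ``v_y = s*sin(d)`` in px/frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "Image",
    "MotionSequence",
    "Corpus",
    "synth_texture",
    "load_image_dir",
    "translate_patch",
    "build_corpus",
    "save_corpus",
    "load_corpus",
]

PATCH_SIZE = 32
N_FRAMES = 6
SPEED_RANGE = (0.8, 3.8)
TRAIN_FRACTION = 0.75


@dataclass
class Image:
    """A grayscale source image from which motion windows are cropped."""

    pixels: np.ndarray  # (height, width), float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("Image requires a 2-D pixel array")
        if min(self.pixels.shape) < 40:
            raise ValueError(
                "source image must be at least 40x40 px to crop a "
                "translating 32 px window"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite values")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class MotionSequence:
    """A (y, x, t) intensity volume with known ground-truth velocity.

    ``v_x``/``v_y`` are px/frame; ``frames`` is expected to lie in
    [-1, 1] once scaled.  Probe stimuli reuse this container with the
    generating parameters stored the same way.
    """

    frames: np.ndarray  # (y, x, t)
    v_x: float
    v_y: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3 or self.frames.shape[2] < 2:
            raise ValueError("frames must be (y, x, t) with at least 2 frames")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("sequence contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[2]

    @property
    def speed(self) -> float:
        return float(np.hypot(self.v_x, self.v_y))

    @property
    def direction(self) -> float:
        """Direction in degrees in [0, 360); meaningless at speed 0."""
        return float(np.degrees(np.arctan2(self.v_y, self.v_x)) % 360.0)


@dataclass
class Corpus:
    """Disjoint train/test sets of labelled motion sequences."""

    train: list[MotionSequence]
    test: list[MotionSequence]
    seed: int
    speed_range: tuple[float, float] = SPEED_RANGE
    n_frames: int = N_FRAMES
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.train) + len(self.test)


def synth_texture(
    width: int, height: int, spectral_exponent: float = 1.0, seed: int = 0
) -> Image:
    """Generate a power-law-spectrum Gaussian random field texture.

    The radially averaged amplitude spectrum falls off approximately as
    ``frequency ** -spectral_exponent`` (exponent 1 reproduces the 1/f
    statistic of natural scenes; exponent 0 is white noise).  The field
    is zero-mean, unit-variance and deterministic per seed.
    """
    if width <= 0 or height <= 0:
        raise ValueError("texture dimensions must be positive")
    if width < 40 or height < 40:
        raise ValueError("texture must be at least 40x40 px")
    if spectral_exponent < 0:
        raise ValueError("spectral_exponent must be >= 0")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((height, width))
    spectrum = np.fft.fft2(white)
    fy = np.fft.fftfreq(height)[:, None]
    fx = np.fft.fftfreq(width)[None, :]
    radius = np.hypot(fy, fx)
    radius[0, 0] = np.inf  # kill DC; also avoids division by zero
    spectrum *= radius ** (-spectral_exponent)
    # zero the Nyquist row/column (even sizes): their subpixel phase
    # shift is not representable in a real image, so removing them makes
    # fractional translation well-defined and exactly invertible
    spectrum[np.abs(fy[:, 0]) == 0.5, :] = 0.0
    spectrum[:, np.abs(fx[0, :]) == 0.5] = 0.0
    pixels = np.fft.ifft2(spectrum).real
    pixels -= pixels.mean()
    sd = pixels.std()
    if sd > 0:
        pixels /= sd
    return Image(pixels)


def load_image_dir(path: str | Path) -> list[Image]:
    """Ingest a directory of user grayscale images (plain-text .npy/.txt).

    Provided as the hook for training on real photographs; images must be
    2-D and at least 40x40 px.
    """
    images = []
    for p in sorted(Path(path).iterdir()):
        if p.suffix == ".npy":
            images.append(Image(np.load(p)))
        elif p.suffix in {".txt", ".csv"}:
            images.append(Image(np.loadtxt(p, delimiter="," if p.suffix == ".csv" else None)))
    if not images:
        raise ValueError(f"no loadable images found in {path}")
    return images


def _sample_window(
    source: np.ndarray,
    x0: float,
    y0: float,
    patch_size: int,
    n_frames: int,
    v_x: float,
    v_y: float,
    interpolation: str,
) -> np.ndarray:
    """Crop ``n_frames`` windows showing content translating at (v_x, v_y).

    Frame k samples the source at window origin minus k*(v_x, v_y): the
    content appears displaced by +k*v, accumulated continuously rather
    than re-rounded per frame.
    """
    h, w = source.shape
    ys = np.arange(patch_size, dtype=np.float64)
    xs = np.arange(patch_size, dtype=np.float64)
    frames = np.empty((patch_size, patch_size, n_frames))
    if interpolation == "fourier":
        # Fourier shift of the whole source, then integer crop.
        fsrc = np.fft.fft2(source)
        fy = np.fft.fftfreq(h)[:, None]
        fx = np.fft.fftfreq(w)[None, :]
        iy0, ix0 = int(round(y0)), int(round(x0))
        for k in range(n_frames):
            shift = np.exp(2j * np.pi * (fy * (-k * v_y) + fx * (-k * v_x)))
            shifted = np.fft.ifft2(fsrc * np.exp(2j * np.pi * (fy * (y0 - iy0) + fx * (x0 - ix0))) * shift).real
            frames[:, :, k] = shifted[iy0 : iy0 + patch_size, ix0 : ix0 + patch_size]
        return frames
    for k in range(n_frames):
        yy = y0 - k * v_y + ys
        xx = x0 - k * v_x + xs
        if yy.min() < 0 or xx.min() < 0 or yy.max() > h - 1 or xx.max() > w - 1:
            raise ValueError("translating window leaves the source image")
        grid_y, grid_x = np.meshgrid(yy, xx, indexing="ij")
        frames[:, :, k] = map_coordinates(source, [grid_y, grid_x], order=1, mode="nearest")
    return frames


def translate_patch(
    source: Image,
    speed: float,
    direction: float,
    n_frames: int = N_FRAMES,
    patch_size: int = PATCH_SIZE,
    origin: tuple[float, float] | None = None,
    interpolation: str = "bilinear",
    scale: bool = True,
) -> MotionSequence:
    """Crop a translating window from ``source``.

    The window content moves at ``speed`` px/frame toward ``direction``
    (degrees CCW from rightward); subpixel positions are sampled with
    bilinear interpolation by default (``interpolation='fourier'`` uses
    exact spectral shifting).  ``origin`` is the (x, y) of the window's
    low corner in frame 0; by default the window is centred so the full
    excursion fits.
    """
    if speed < 0:
        raise ValueError("speed must be >= 0")
    if interpolation not in {"bilinear", "fourier"}:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    v_x = speed * np.cos(np.radians(direction))
    v_y = speed * np.sin(np.radians(direction))
    travel = speed * (n_frames - 1)
    if origin is None:
        x0 = (source.width - patch_size) / 2.0
        y0 = (source.height - patch_size) / 2.0
    else:
        x0, y0 = origin
    # the fourier backend treats the source as periodic (wrap-around),
    # so only bilinear sampling needs the window to stay in bounds
    if interpolation == "bilinear" and (
        min(x0, x0 - (n_frames - 1) * v_x) < 0
        or min(y0, y0 - (n_frames - 1) * v_y) < 0
        or max(x0, x0 - (n_frames - 1) * v_x) + patch_size - 1 > source.width - 1
        or max(y0, y0 - (n_frames - 1) * v_y) + patch_size - 1 > source.height - 1
    ):
        raise ValueError(
            f"window origin ({x0:.1f}, {y0:.1f}) with travel {travel:.1f} px "
            "leaves the source image"
        )
    frames = _sample_window(
        source.pixels, x0, y0, patch_size, n_frames, v_x, v_y, interpolation
    )
    if scale:
        frames = scale_to_unit(frames)
    return MotionSequence(frames=frames, v_x=float(v_x), v_y=float(v_y))


def scale_to_unit(frames: np.ndarray) -> np.ndarray:
    """Min-max scale a sequence to [-1, 1] (per-sequence, full range)."""
    lo, hi = frames.min(), frames.max()
    if hi == lo:
        return np.zeros_like(frames)
    return 2.0 * (frames - lo) / (hi - lo) - 1.0


def build_corpus(
    n_sequences: int,
    speed_range: tuple[float, float] = SPEED_RANGE,
    n_frames: int = N_FRAMES,
    seed: int = 0,
    n_textures: int = 200,
    texture_size: int = 128,
    spectral_exponent: float = 1.0,
    sources: list[Image] | None = None,
    interpolation: str = "bilinear",
) -> Corpus:
    """Generate a labelled corpus of translating-texture sequences.

    Speeds and directions are drawn uniformly from ``speed_range`` and
    [0, 360); each sequence is min-max scaled to [-1, 1] and the corpus
    is split 75/25 into disjoint train/test sets.  ``sources`` overrides
    the synthetic textures with user images.
    """
    if n_sequences < 4:
        raise ValueError("need at least 4 sequences for a 75/25 split")
    lo, hi = speed_range
    if lo < 0 or hi < lo:
        raise ValueError("invalid speed range")
    rng = np.random.default_rng(seed)
    if sources is None:
        tex_seeds = rng.integers(0, 2**31 - 1, size=n_textures)
        sources = [
            synth_texture(texture_size, texture_size, spectral_exponent, int(s))
            for s in tex_seeds
        ]
    max_travel = hi * (n_frames - 1)
    sequences = []
    for _ in range(n_sequences):
        img = sources[rng.integers(len(sources))]
        speed = rng.uniform(lo, hi)
        direction = rng.uniform(0.0, 360.0)
        v_x = speed * np.cos(np.radians(direction))
        v_y = speed * np.sin(np.radians(direction))
        # place the window so the whole excursion stays in bounds
        x_lo = max(0.0, (n_frames - 1) * v_x)
        x_hi = img.width - PATCH_SIZE - max(0.0, -(n_frames - 1) * v_x)
        y_lo = max(0.0, (n_frames - 1) * v_y)
        y_hi = img.height - PATCH_SIZE - max(0.0, -(n_frames - 1) * v_y)
        if x_hi < x_lo or y_hi < y_lo:
            raise ValueError(
                f"source images too small for travel {max_travel:.1f} px"
            )
        origin = (rng.uniform(x_lo, x_hi), rng.uniform(y_lo, y_hi))
        sequences.append(
            translate_patch(
                img,
                speed,
                direction,
                n_frames=n_frames,
                origin=origin,
                interpolation=interpolation,
            )
        )
    order = rng.permutation(n_sequences)
    n_train = int(round(TRAIN_FRACTION * n_sequences))
    train = [sequences[i] for i in order[:n_train]]
    test = [sequences[i] for i in order[n_train:]]
    return Corpus(
        train=train,
        test=test,
        seed=seed,
        speed_range=(lo, hi),
        n_frames=n_frames,
        meta={"n_textures": n_textures, "spectral_exponent": spectral_exponent},
    )


def _stack(split: list[MotionSequence]) -> tuple[np.ndarray, np.ndarray]:
    stim = np.stack([s.frames for s in split]).astype(np.float32)
    labels = np.array([[s.v_x, s.v_y] for s in split], dtype=np.float64)
    return stim, labels


def save_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write the corpus to HDF5 (groups train/test) with a JSON sidecar."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        for name, split in (("train", corpus.train), ("test", corpus.test)):
            stim, labels = _stack(split)
            g = f.create_group(name)
            g.create_dataset("stimuli", data=stim, compression=None)
            g.create_dataset("labels", data=labels)
        f.attrs["seed"] = corpus.seed
        f.attrs["speed_range"] = corpus.speed_range
        f.attrs["n_frames"] = corpus.n_frames
    sidecar = {
        "seed": corpus.seed,
        "speed_range": list(corpus.speed_range),
        "n_frames": corpus.n_frames,
        "n_train": len(corpus.train),
        "n_test": len(corpus.test),
        "generator_version": 1,
        **corpus.meta,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_corpus(path: str | Path) -> Corpus:
    with h5py.File(path, "r") as f:
        splits = {}
        for name in ("train", "test"):
            stim = f[name]["stimuli"][...]
            labels = f[name]["labels"][...]
            splits[name] = [
                MotionSequence(frames=stim[i].astype(np.float64), v_x=labels[i, 0], v_y=labels[i, 1])
                for i in range(stim.shape[0])
            ]
        return Corpus(
            train=splits["train"],
            test=splits["test"],
            seed=int(f.attrs["seed"]),
            speed_range=tuple(float(v) for v in f.attrs["speed_range"]),
            n_frames=int(f.attrs["n_frames"]),
        )
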