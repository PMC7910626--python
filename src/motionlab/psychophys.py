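"""Behavioural experiments on the trained network.

Random-dot kinematograms probe the network the way a psychophysicist
probes an observer: direction discrimination as a function of motion
coherence (with Weibull thresholds), speed estimation under reduced
coherence, per-unit speed opponency, and the pooling test asking
whether the 50%-coherence response is simply the average of the 0% and
100% responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .model import ModelParams, forward_batch, to_polar
from .probes import DotSpec, dot_sequence

__all__ = [
    "PsychometricCurve",
    "OpponencyCurve",
    "PoolingResult",
    "WeibullFit",
    "weibull",
    "weibull_fit",
    "speed_opponency_curves",
    "coherence_direction_task",
    "coherence_speed_task",
    "pooling_prediction",
]

DIRECTION_COHERENCES = np.logspace(np.log10(0.001), np.log10(0.2), 7)
SPEED_COHERENCES = np.linspace(0.2, 1.0, 5)
OPPONENCY_SPEEDS = 2.0 ** np.linspace(np.log2(0.8), np.log2(3.8), 8)

# coherence-task dot parameters: 333 white dots (radius 2) on black,
# all moving at 3 px/frame
COHERENCE_DOTS = dict(n_dots=333, dot_radius=2.0, dot_value=1.0,
                      background_value=-1.0, speed=3.0)


@dataclass
class WeibullFit:
    alpha: float  # threshold-scale: performance 1-(1-chance)/e at x=alpha
    beta: float  # slope
    chance: float
    ok: bool
    message: str = ""


@dataclass
class PsychometricCurve:
    task: str  # 'direction' or 'speed'
    coherences: np.ndarray
    values: np.ndarray  # proportion correct, or relative speed estimate
    n_trials: int
    raw_speeds: np.ndarray | None = None  # speed task: unnormalised estimates
    weibull: WeibullFit | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class OpponencyCurve:
    unit: int
    speeds: np.ndarray
    preferred: np.ndarray  # response to dots in the preferred direction
    opposite: np.ndarray


@dataclass
class PoolingResult:
    activity_0: np.ndarray  # per-MT-unit mean activity at 0% coherence
    activity_50: np.ndarray
    activity_100: np.ndarray
    r: float
    p: float
    n: int
    r_100_only: float  # control: 100% response alone as the predictor

    @property
    def predicted_50(self) -> np.ndarray:
        return 0.5 * (self.activity_0 + self.activity_100)


def weibull(x, alpha, beta, chance=0.5):
    """Weibull psychometric function, floored at chance and saturating
    at 1: ``P(x) = 1 - (1 - chance) * exp(-(x/alpha)**beta)``."""
    return 1.0 - (1.0 - chance) * np.exp(-((np.asarray(x, dtype=float) / alpha) ** beta))


def weibull_fit(x, pc, chance: float = 0.5) -> WeibullFit:
    """Least-squares Weibull fit of proportion correct vs coherence.

    The threshold is reported at the conventional ``1 - (1 - chance)/e``
    point, which is exactly ``alpha``.  A curve with no rise above
    chance is non-identifiable and returned flagged.
    """
    x = np.asarray(x, dtype=float)
    pc = np.asarray(pc, dtype=float)
    if x.size != pc.size or x.size < 3:
        raise ValueError("need matching x/pc vectors of length >= 3")
    if np.all(np.abs(pc - chance) < 0.5 / 100):
        return WeibullFit(np.nan, np.nan, chance, False, "performance flat at chance")
    try:
        popt, _ = curve_fit(
            lambda xx, a, b: weibull(xx, a, b, chance),
            x, pc,
            p0=[float(np.median(x)), 1.5],
            bounds=([1e-9, 1e-3], [np.inf, 100.0]),
            maxfev=20000,
        )
    except RuntimeError as e:
        return WeibullFit(np.nan, np.nan, chance, False, f"fit failed: {e}")
    return WeibullFit(float(popt[0]), float(popt[1]), chance, True)


def speed_opponency_curves(
    params: ModelParams,
    unit: int,
    preferred_direction: float,
    speeds: np.ndarray = OPPONENCY_SPEEDS,
    n_repeats: int = 20,
    seed: int = 0,
    n_dots: int = 5,
    dot_radius: float = 4.0,
) -> OpponencyCurve:
    """MT-unit response to dots drifting in its preferred vs opposite
    direction across a log2-spaced speed grid (white dots on black,
    full-length motion), averaged over dot placements."""
    if preferred_direction is None or not np.isfinite(preferred_direction):
        raise ValueError(f"unit {unit} has no defined preferred direction")
    if not 0 <= unit < params.arch.n_mt_units:
        raise ValueError(f"unknown MT unit {unit}")
    rng = np.random.default_rng(seed)
    stim_seeds = rng.integers(0, 2**31 - 1, size=n_repeats)
    resp = {0.0: [], 180.0: []}
    for offset in (0.0, 180.0):
        direction = (preferred_direction + offset) % 360.0
        for speed in speeds:
            batch = np.stack([
                dot_sequence(DotSpec(
                    n_dots=n_dots, dot_radius=dot_radius, dot_value=1.0,
                    background_value=-1.0, speed=float(speed),
                    signal_direction=direction,
                    n_frames=params.arch.input_size[2],
                    size=params.arch.input_size[0], seed=int(s),
                )).frames
                for s in stim_seeds
            ]).astype(np.float32)
            _, mt, _ = forward_batch(params, batch)
            resp[offset].append(float(mt[:, unit].mean()))
    return OpponencyCurve(
        unit=unit,
        speeds=np.asarray(speeds, dtype=float),
        preferred=np.array(resp[0.0]),
        opposite=np.array(resp[180.0]),
    )


def _coherence_batch(
    params: ModelParams, coherence: float, directions: np.ndarray,
    seeds: np.ndarray, n_dots: int, dot_radius: float,
) -> np.ndarray:
    return np.stack([
        dot_sequence(DotSpec(
            n_dots=n_dots, dot_radius=dot_radius,
            dot_value=COHERENCE_DOTS["dot_value"],
            background_value=COHERENCE_DOTS["background_value"],
            speed=COHERENCE_DOTS["speed"],
            signal_direction=float(d), coherence=float(coherence),
            n_frames=params.arch.input_size[2],
            size=params.arch.input_size[0], seed=int(s),
        )).frames
        for d, s in zip(directions, seeds)
    ]).astype(np.float32)


def coherence_direction_task(
    params: ModelParams,
    coherences: np.ndarray = DIRECTION_COHERENCES,
    trials: int = 100,
    seed: int = 0,
    fit: bool = True,
) -> PsychometricCurve:
    """Direction discrimination vs motion coherence.

    Each trial presents a 333-dot kinematogram with a random signal
    direction; the decoded direction is scored correct when within
    +/-90 deg of the signal direction.  Trials whose decoded speed is
    zero have no direction and are scored by a seeded coin flip
    (chance), flagged.  A Weibull function is fitted to the mean
    performance.
    """
    rng = np.random.default_rng(seed)
    flags: list[str] = []
    pcs = []
    for c in np.asarray(coherences, dtype=float):
        directions = rng.uniform(0.0, 360.0, size=trials)
        seeds = rng.integers(0, 2**31 - 1, size=trials)
        batch = _coherence_batch(params, c, directions, seeds,
                                 COHERENCE_DOTS["n_dots"], COHERENCE_DOTS["dot_radius"])
        _, _, out = forward_batch(params, batch)
        correct = np.empty(trials, dtype=bool)
        for i in range(trials):
            est = to_polar(out[i, 0], out[i, 1])
            if est.direction is None:
                correct[i] = rng.random() < 0.5
                flags.append(f"coherence {c:g} trial {i}: zero decoded speed, coin flip")
            else:
                diff = abs((est.direction - directions[i] + 180.0) % 360.0 - 180.0)
                correct[i] = diff <= 90.0
        pcs.append(correct.mean())
    curve = PsychometricCurve(
        task="direction",
        coherences=np.asarray(coherences, dtype=float),
        values=np.array(pcs),
        n_trials=trials,
        flags=flags,
    )
    if fit:
        curve.weibull = weibull_fit(curve.coherences, curve.values)
    return curve


def coherence_speed_task(
    params: ModelParams,
    coherences: np.ndarray = SPEED_COHERENCES,
    n_dots: int = 10,
    trials: int = 100,
    seed: int = 0,
) -> PsychometricCurve:
    """Speed estimation vs motion coherence with a sparse (10-dot)
    kinematogram.

    Reported values are decoded speeds normalised by the decoded speed
    at full coherence, isolating the coherence-induced bias from any
    generic speed offset of the network; raw estimates are kept
    alongside.
    """
    rng = np.random.default_rng(seed)
    cohs = np.asarray(coherences, dtype=float)
    mean_speeds = []
    for c in cohs:
        directions = rng.uniform(0.0, 360.0, size=trials)
        seeds = rng.integers(0, 2**31 - 1, size=trials)
        batch = _coherence_batch(params, c, directions, seeds,
                                 n_dots, COHERENCE_DOTS["dot_radius"])
        _, _, out = forward_batch(params, batch)
        mean_speeds.append(float(np.hypot(out[:, 0], out[:, 1]).mean()))
    raw = np.array(mean_speeds)
    if not np.any(cohs == 1.0):
        norm = raw[np.argmax(cohs)]
    else:
        norm = raw[np.flatnonzero(cohs == 1.0)[0]]
    flags = []
    if norm == 0.0:
        flags.append("zero decoded speed at full coherence; relative values undefined")
        rel = np.full_like(raw, np.nan)
    else:
        rel = raw / norm
    return PsychometricCurve(
        task="speed", coherences=cohs, values=rel, n_trials=trials,
        raw_speeds=raw, flags=flags,
    )


def pooling_prediction(
    models: list[ModelParams],
    trials: int = 50,
    seed: int = 0,
) -> PoolingResult:
    """Does averaging the 0% and 100% coherence responses predict the
    50% response?

    Per-MT-unit mean activities (coherence-task stimuli, averaged over
    trials and networks) at the three coherence levels; the headline
    number is the Pearson correlation across units between the actual
    50% activity and the 0/100 average.  The 100%-only control shows
    the pooled predictor is not trivially inherited from the signal
    response.
    """
    from scipy.stats import pearsonr

    if not models:
        raise ValueError("need at least one model")
    n_mt = models[0].arch.n_mt_units
    if n_mt < 3:
        raise ValueError("need at least 3 MT units for a correlation")
    acts = {0.0: np.zeros(n_mt), 0.5: np.zeros(n_mt), 1.0: np.zeros(n_mt)}
    for params in models:
        rng = np.random.default_rng(seed)  # same stimuli for every network
        for c in (0.0, 0.5, 1.0):
            directions = rng.uniform(0.0, 360.0, size=trials)
            seeds = rng.integers(0, 2**31 - 1, size=trials)
            batch = _coherence_batch(params, c, directions, seeds,
                                     COHERENCE_DOTS["n_dots"],
                                     COHERENCE_DOTS["dot_radius"])
            _, mt, _ = forward_batch(params, batch)
            acts[c] += mt.mean(axis=0)
    for c in acts:
        acts[c] /= len(models)
    predicted = 0.5 * (acts[0.0] + acts[1.0])
    r, p = pearsonr(predicted, acts[0.5])
    r100, _ = pearsonr(acts[1.0], acts[0.5])
    return PoolingResult(
        activity_0=acts[0.0], activity_50=acts[0.5], activity_100=acts[1.0],
        r=float(r), p=float(p), n=n_mt, r_100_only=float(r100),
    )
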