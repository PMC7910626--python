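"""Unit characterisation: tuning batteries and selectivity classification.

Two classification axes, both using the same partial-correlation /
Fisher-z machinery:

* **direction**: is a unit selective for the motions of a plaid's
  component gratings, or for the plaid pattern's own direction?
  A unit's grating direction-tuning curve provides ideal "component"
  (curve resampled at +/- half the plaid separation and summed) and
  "pattern" (the curve itself) predictions for its plaid response.
* **spectral**: is a unit independently tuned to spatial and temporal
  frequency (cardinal ridge in its spectral response map), or tuned to
  speed (ridge along a constant-speed diagonal)?  Oriented 2-D Gaussian
  fits with the orientation fixed at 0 or at the constant-speed diagonal
  provide the two ideal predictions.

Partial correlations control for the correlation between the two ideal
predictions; Fisher-z transformed values are compared with a one-sided
z criterion (default 1.28, i.e. 90% confidence, the convention of the
plaid-classification literature).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .model import ModelParams, _im2col, forward_batch
from .probes import GratingSpec, PlaidSpec, grating, plaid

__all__ = [
    "ResponseTensor",
    "TuningSummary",
    "SpectralMap",
    "GaussianFit",
    "SelectivityClass",
    "grating_battery",
    "plaid_battery",
    "preferred_tuning",
    "partial_correlation",
    "fisher_z",
    "classify_direction_selectivity",
    "spectral_battery",
    "spectral_map",
    "fit_spectral_gaussian",
    "classify_speed_tuning",
    "pattern_speed_correlation",
]

Z_CRITERION = 1.28  # one-sided 90% confidence, Fisher-z units

DIRECTION_GRID = 16
SF_PERIODS = (8.0, 25.0, 10)  # px/cycle, log-spaced
TF_PERIODS = (4.0, 25.0, 10)  # frames/cycle, log-spaced
SPECTRAL_SF_PERIODS = (8.0, 33.0, 6)
SPECTRAL_TF_PERIODS = (4.0, 500.0, 6)
N_PHASES = 32


@dataclass
class ResponseTensor:
    """Phase-averaged responses on a direction x sf x tf battery.

    ``values`` has shape (n_units, n_directions, n_sf, n_tf); periods are
    stored in px/cycle and frames/cycle.
    """

    layer: str  # 'v1' or 'mt'
    values: np.ndarray
    directions: np.ndarray
    spatial_periods: np.ndarray
    temporal_periods: np.ndarray

    @property
    def n_units(self) -> int:
        return self.values.shape[0]


@dataclass
class TuningSummary:
    unit: int
    preferred_direction: float | None  # deg
    preferred_sf: float | None  # cycles/px
    preferred_tf: float | None  # cycles/frame
    preferred_speed: float | None  # px/frame = tf/sf
    tied: bool = False
    defined: bool = True


@dataclass
class SpectralMap:
    """Responses over a 6x6 spatial x temporal period grid at the unit's
    preferred direction."""

    unit: int
    values: np.ndarray  # (n_sf, n_tf)
    spatial_periods: np.ndarray
    temporal_periods: np.ndarray
    direction: float


@dataclass
class GaussianFit:
    offset: float
    amplitude: float
    x0: float
    y0: float
    theta: float
    sigma_x: float
    sigma_y: float
    prediction: np.ndarray
    goodness_r: float
    converged: bool
    mode: str

    @property
    def abc(self) -> tuple[float, float, float]:
        return gaussian_abc(self.theta, self.sigma_x, self.sigma_y)


@dataclass
class SelectivityClass:
    axis: str  # 'direction' or 'spectral'
    unit: int
    r_p: float
    r_c: float
    r_cp: float
    R_p: float
    R_c: float
    Z_p: float
    Z_c: float
    label: str  # component/pattern/independent/speed/unclassed
    index: float  # Z_p - Z_c (pattern index) or Z_speed - Z_independent
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# batteries


def _log_grid(lo: float, hi: float, n: int) -> np.ndarray:
    return np.logspace(np.log10(lo), np.log10(hi), n)


def _battery_responses(
    params: ModelParams,
    specs: list[GratingSpec | PlaidSpec],
    make,
    n_phases: int,
    readout: str,
    chunk: int = 32,
) -> tuple[np.ndarray, np.ndarray]:
    """Phase-averaged V1 and MT responses to a list of stimulus specs.

    Returns (v1, mt) with shapes (n_kernels, n_specs) and (n_mt,
    n_specs).  The V1 readout is the centre pixel of each activity map
    by default (``readout='mean'`` averages the map) -- a convolutional
    kernel has one tuning, its spatial position is arbitrary.

    A sinusoid (or sum of co-phased sinusoids) at starting phase ``ph``
    is ``cos(ph) * S(0) + sin(ph) * S(90)``, and the convolution stage
    is linear, so only the two quadrature stimuli per condition are
    convolved; the rectification and dense stages are then evaluated
    per phase on the cheap linear combination.
    """
    if readout not in {"center", "mean"}:
        raise ValueError(f"unknown V1 readout {readout!r}")
    arch = params.arch
    h, w, t = arch.map_size
    n_pos = h * w * t
    centre = (h // 2) * w * t + (w // 2) * t
    phases = np.radians(np.arange(n_phases) * (360.0 / n_phases))
    cosps = np.cos(phases).astype(np.float32)
    sinps = np.sin(phases).astype(np.float32)
    n_specs = len(specs)
    v1_out = np.empty((arch.n_kernels, n_specs))
    mt_out = np.empty((arch.n_mt_units, n_specs))
    kmat = params.v1_kernels.reshape(arch.n_kernels, -1).astype(np.float32)
    v1_off = params.v1_offsets.astype(np.float32)
    mt_w = params.mt_weights.T.astype(np.float32)  # (n_v1, n_mt)
    mt_off = params.mt_offsets.astype(np.float32)
    for start in range(0, n_specs, chunk):
        block = specs[start : start + chunk]
        m = len(block)
        stims = np.stack(
            [make(s, ph).frames for s in block for ph in (0.0, 90.0)]
        ).astype(np.float32)
        cols = _im2col(stims, arch)  # (2m, n_pos, k)
        pre = cols @ kmat.T  # (2m, n_pos, n_kernels), offset added later
        A = pre[0::2]
        B = pre[1::2]
        v1_acc = np.zeros((m, arch.n_kernels), dtype=np.float64)
        mt_acc = np.zeros((m, arch.n_mt_units), dtype=np.float64)
        for c, s in zip(cosps, sinps):
            a = np.maximum(c * A + s * B + v1_off, 0.0)  # (m, n_pos, K)
            if readout == "center":
                v1_acc += a[:, centre, :]
            else:
                v1_acc += a.mean(axis=1)
            a_flat = a.transpose(0, 2, 1).reshape(m, -1)  # kernel-major
            mt_acc += np.maximum(a_flat @ mt_w + mt_off, 0.0)
        v1_out[:, start : start + m] = (v1_acc / n_phases).T
        mt_out[:, start : start + m] = (mt_acc / n_phases).T
    return v1_out, mt_out


def grating_battery(
    params: ModelParams,
    n_directions: int = DIRECTION_GRID,
    sf_periods: tuple[float, float, int] = SF_PERIODS,
    tf_periods: tuple[float, float, int] = TF_PERIODS,
    n_phases: int = N_PHASES,
    readout: str = "center",
) -> tuple[ResponseTensor, ResponseTensor]:
    """Drifting-grating battery: directions x spatial periods x temporal
    periods, phase-averaged.  Defaults enumerate 16 x 10 x 10 = 1600
    conditions.  Returns (v1_tensor, mt_tensor)."""
    directions = np.arange(n_directions) * (360.0 / n_directions)
    sps = _log_grid(*sf_periods)
    tps = _log_grid(*tf_periods)
    specs = [
        GratingSpec(direction=d, spatial_period=sp, temporal_period=tp,
                    size=params.arch.input_size[0], n_frames=params.arch.input_size[2])
        for d in directions
        for sp in sps
        for tp in tps
    ]
    v1, mt = _battery_responses(
        params, specs, lambda s, ph: grating(GratingSpec(
            direction=s.direction, spatial_period=s.spatial_period,
            temporal_period=s.temporal_period, phase=ph, size=s.size,
            n_frames=s.n_frames)), n_phases, readout)
    shape = (-1, len(directions), len(sps), len(tps))
    return (
        ResponseTensor("v1", v1.reshape(shape), directions, sps, tps),
        ResponseTensor("mt", mt.reshape(shape), directions, sps, tps),
    )


def plaid_battery(
    params: ModelParams,
    spatial_period: float,
    temporal_period: float,
    separation: float = 135.0,
    n_directions: int = DIRECTION_GRID,
    n_phases: int = N_PHASES,
    readout: str = "center",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Plaid direction-tuning curves at a fixed spatial/temporal period.

    Returns (directions, v1_curves, mt_curves) with curve shapes
    (n_units, n_directions)."""
    directions = np.arange(n_directions) * (360.0 / n_directions)
    specs = [
        PlaidSpec(pattern_direction=d, separation=separation,
                  spatial_period=spatial_period, temporal_period=temporal_period,
                  size=params.arch.input_size[0], n_frames=params.arch.input_size[2])
        for d in directions
    ]
    v1, mt = _battery_responses(
        params, specs, lambda s, ph: plaid(PlaidSpec(
            pattern_direction=s.pattern_direction, separation=s.separation,
            spatial_period=s.spatial_period, temporal_period=s.temporal_period,
            phase=ph, size=s.size, n_frames=s.n_frames)), n_phases, readout)
    return directions, v1, mt


def preferred_tuning(tensor: ResponseTensor, unit: int) -> TuningSummary:
    """Preferred direction / sf / tf by grid argmax; speed = tf / sf.

    Periods are converted to frequencies (cycles/px, cycles/frame).  An
    all-zero tensor yields an undefined summary; exact ties are broken
    toward the lowest flat index and flagged.
    """
    vals = tensor.values[unit]
    if np.all(vals == 0):
        return TuningSummary(unit, None, None, None, None, defined=False)
    flat = int(np.argmax(vals))
    tied = int(np.sum(vals == vals.flat[flat])) > 1
    if tied:
        warnings.warn(f"unit {unit}: tied maximum in tuning tensor", stacklevel=2)
    i_dir, i_sf, i_tf = np.unravel_index(flat, vals.shape)
    sf = 1.0 / tensor.spatial_periods[i_sf]
    tf = 1.0 / tensor.temporal_periods[i_tf]
    return TuningSummary(
        unit=unit,
        preferred_direction=float(tensor.directions[i_dir]),
        preferred_sf=float(sf),
        preferred_tf=float(tf),
        preferred_speed=float(tf / sf),
        tied=tied,
    )


# ---------------------------------------------------------------------------
# partial correlation / Fisher z


def partial_correlation(r_p: float, r_c: float, r_cp: float) -> tuple[float, float]:
    """First-order partial correlations of data with two correlated
    predictions.

    ``R_p = (r_p - r_c*r_cp) / sqrt((1 - r_c^2)(1 - r_cp^2))``; ``R_c``
    by exchanging r_c and r_p.
    """
    for name, r in (("r_p", r_p), ("r_c", r_c), ("r_cp", r_cp)):
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"{name}={r} outside [-1, 1]")
    den_p = np.sqrt((1.0 - r_c**2) * (1.0 - r_cp**2))
    den_c = np.sqrt((1.0 - r_p**2) * (1.0 - r_cp**2))
    if den_p == 0.0 or den_c == 0.0:
        raise ZeroDivisionError(
            "degenerate partial correlation: |r_c|, |r_p| or |r_cp| is 1"
        )
    R_p = (r_p - r_c * r_cp) / den_p
    R_c = (r_c - r_p * r_cp) / den_c
    return float(R_p), float(R_c)


def fisher_z(r: float, n: int) -> float:
    """Fisher r-to-z with sampling SD 1/sqrt(n - 3); r clipped at
    +/-0.9999 to keep the transform finite."""
    r = float(np.clip(r, -0.9999, 0.9999))
    return float(np.arctanh(r) * np.sqrt(n - 3))


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = np.std(a), np.std(b)
    if sa == 0.0 or sb == 0.0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def _apply_rule(
    axis: str,
    unit: int,
    data: np.ndarray,
    pred_p: np.ndarray,
    pred_c: np.ndarray,
    n: int,
    labels: tuple[str, str],
    criterion: float,
) -> SelectivityClass:
    """Shared decision rule for both classification axes.

    ``pred_p``/``labels[0]`` is the 'complex' prediction (pattern or
    speed), ``pred_c``/``labels[1]`` the 'simple' one (component or
    independent); the index is Z_p - Z_c.
    """
    flags: list[str] = []
    r_p, r_c, r_cp = _corr(data, pred_p), _corr(data, pred_c), _corr(pred_p, pred_c)
    if np.isnan(r_p) or np.isnan(r_c) or np.isnan(r_cp):
        return SelectivityClass(axis, unit, np.nan, np.nan, np.nan, np.nan,
                                np.nan, np.nan, np.nan, "unclassed", np.nan,
                                ["zero-variance"])
    # a noiseless, perfectly fitting prediction gives |r| = 1, which
    # makes the partials degenerate; clip just inside +/-1 (mirroring
    # the Fisher-z clipping) so exact fits classify decisively
    clip = lambda r: float(np.clip(r, -0.9999, 0.9999))
    R_p, R_c = partial_correlation(clip(r_p), clip(r_c), clip(r_cp))
    Z_p, Z_c = fisher_z(R_p, n), fisher_z(R_c, n)
    if Z_p - max(Z_c, 0.0) >= criterion:
        label = labels[0]
    elif Z_c - max(Z_p, 0.0) >= criterion:
        label = labels[1]
    else:
        label = "unclassed"
    return SelectivityClass(axis, unit, r_p, r_c, r_cp, R_p, R_c, Z_p, Z_c,
                            label, Z_p - Z_c, flags)


def classify_direction_selectivity(
    grating_curve: np.ndarray,
    plaid_curve: np.ndarray,
    separation: float = 135.0,
    unit: int = -1,
    criterion: float = Z_CRITERION,
    min_pref_null_ratio: float | None = 2.0,
) -> SelectivityClass:
    """Component- vs pattern-motion classification of a direction-tuning
    pair.

    The component prediction is the grating curve resampled at +/- half
    the plaid separation and summed; the pattern prediction is the
    grating curve itself.  Both are correlated against the plaid
    response, partialed, Fisher-z transformed (n = number of directions)
    and passed through the four-way rule; the scalar index is
    Z_pattern - Z_component.

    Units that are not direction selective (peak grating response below
    ``min_pref_null_ratio`` times the response to the opposite
    direction) cannot meaningfully be assigned a component/pattern
    label -- their near-flat curves let the partial-correlation
    machinery amplify sub-1% shared variance into spurious
    significance -- and are recorded unclassed with a flag (pass
    ``None`` to disable the guard).
    """
    g = np.asarray(grating_curve, dtype=float)
    p = np.asarray(plaid_curve, dtype=float)
    if g.shape != p.shape or g.ndim != 1:
        raise ValueError("grating and plaid curves must be equal-length vectors")
    n = g.size
    step = 360.0 / n
    shift = separation / 2.0 / step
    if abs(shift - round(shift)) > 1e-9:
        raise ValueError(
            f"half-separation {separation / 2} deg is not a multiple of the "
            f"{step} deg direction grid"
        )
    k = int(round(shift))
    if min_pref_null_ratio is not None:
        null = g[(int(np.argmax(g)) + n // 2) % n]
        if g.max() < min_pref_null_ratio * null:
            return SelectivityClass("direction", unit, np.nan, np.nan, np.nan,
                                    np.nan, np.nan, np.nan, np.nan, "unclassed",
                                    np.nan, ["weak-direction-tuning"])
    comp_pred = np.roll(g, k) + np.roll(g, -k)
    return _apply_rule("direction", unit, p, g, comp_pred, n,
                       ("pattern", "component"), criterion)


# ---------------------------------------------------------------------------
# spectral maps and oriented-Gaussian fits


def spectral_battery(
    params: ModelParams,
    n_directions: int = DIRECTION_GRID,
    sf_periods: tuple[float, float, int] = SPECTRAL_SF_PERIODS,
    tf_periods: tuple[float, float, int] = SPECTRAL_TF_PERIODS,
    n_phases: int = N_PHASES,
    readout: str = "center",
) -> tuple[ResponseTensor, ResponseTensor]:
    """Grating battery on the wider 6 x 6 period grid used for spectral
    response maps (36 conditions per direction)."""
    return grating_battery(params, n_directions, sf_periods, tf_periods,
                           n_phases, readout)


def spectral_map(tensor: ResponseTensor, unit: int, summary: TuningSummary | None = None) -> SpectralMap:
    """Extract a unit's sf x tf response map at its preferred direction."""
    if not 0 <= unit < tensor.n_units:
        raise ValueError(f"unknown unit {unit}")
    vals = tensor.values[unit]
    if summary is not None and summary.defined:
        i_dir = int(np.argmin(np.abs(
            (tensor.directions - summary.preferred_direction + 180) % 360 - 180)))
    else:
        i_dir = int(np.unravel_index(np.argmax(vals), vals.shape)[0])
    return SpectralMap(
        unit=unit,
        values=vals[i_dir],
        spatial_periods=tensor.spatial_periods,
        temporal_periods=tensor.temporal_periods,
        direction=float(tensor.directions[i_dir]),
    )


def gaussian_abc(theta: float, sigma_x: float, sigma_y: float) -> tuple[float, float, float]:
    """Quadratic-form coefficients of an oriented 2-D Gaussian."""
    a = np.cos(theta) ** 2 / (2 * sigma_x**2) + np.sin(theta) ** 2 / (2 * sigma_y**2)
    b = -np.sin(2 * theta) / (4 * sigma_x**2) + np.sin(2 * theta) / (4 * sigma_y**2)
    c = np.sin(theta) ** 2 / (2 * sigma_x**2) + np.cos(theta) ** 2 / (2 * sigma_y**2)
    return float(a), float(b), float(c)


def gaussian2d(x, y, p, A, x0, y0, theta, sigma_x, sigma_y):
    a, b, c = gaussian_abc(theta, sigma_x, sigma_y)
    dx, dy = x - x0, y - y0
    return p + A * np.exp(-(a * dx**2 + 2 * b * dx * dy + c * dy**2))


def fit_spectral_gaussian(
    smap: SpectralMap,
    orientation_mode: str = "free",
    n_restarts: int = 10,
    seed: int = 0,
) -> GaussianFit:
    """Nonlinear least-squares fit of an oriented 2-D Gaussian to a
    spectral map in log2-period coordinates.

    ``orientation_mode='cardinal'`` fixes theta = 0 (independent sf/tf
    tuning: the ridge is axis-aligned); ``'radial'`` fixes theta at the
    constant-speed diagonal (45 deg in log-period coordinates, since
    speed = spatial period / temporal period); ``'free'`` fits theta.
    Initialised from the map's argmax and second moments with seeded
    random restarts; returns the best fit and its Pearson correlation
    with the data.
    """
    if orientation_mode not in {"cardinal", "radial", "free"}:
        raise ValueError(f"unknown orientation_mode {orientation_mode!r}")
    vals = np.asarray(smap.values, dtype=float)
    x = np.log2(smap.spatial_periods)
    y = np.log2(smap.temporal_periods)
    X, Y = np.meshgrid(x, y, indexing="ij")
    span_x = x.max() - x.min()
    span_y = y.max() - y.min()
    rng = np.random.default_rng(seed)
    amp0 = vals.max() - vals.min()
    if amp0 == 0.0:
        return GaussianFit(float(vals.mean()), 0.0, float(x.mean()), float(y.mean()),
                           0.0, 1.0, 1.0, np.full_like(vals, vals.mean()),
                           np.nan, False, orientation_mode)
    i0, j0 = np.unravel_index(np.argmax(vals), vals.shape)
    fixed_theta = {"cardinal": 0.0, "radial": np.pi / 4.0}.get(orientation_mode)

    def unpack(q):
        if fixed_theta is None:
            return q[0], q[1], q[2], q[3], q[4], q[5], q[6]
        return q[0], q[1], q[2], q[3], fixed_theta, q[4], q[5]

    def resid(q):
        return (gaussian2d(X, Y, *unpack(q)) - vals).ravel()

    base = [vals.min(), amp0, x[i0], y[j0], 0.3 * span_x + 1e-3, 0.3 * span_y + 1e-3]
    if fixed_theta is None:
        base = base[:4] + [0.0] + base[4:]
    lo = [-np.inf, 0.0, x.min() - span_x, y.min() - span_y]
    hi = [np.inf, np.inf, x.max() + span_x, y.max() + span_y]
    if fixed_theta is None:
        lo += [-np.pi / 2]
        hi += [np.pi / 2]
    lo += [1e-3, 1e-3]
    hi += [5 * span_x + 1, 5 * span_y + 1]
    best, best_cost = None, np.inf
    for trial in range(n_restarts):
        q0 = np.array(base, dtype=float)
        if trial > 0:
            jitter = rng.normal(0, 0.2, size=q0.size)
            q0 = q0 * (1 + jitter) + rng.normal(0, 0.05, size=q0.size)
            q0 = np.clip(q0, np.array(lo) + 1e-9, np.array(hi) - 1e-9)
            q0 = np.where(np.isfinite(q0), q0, np.array(base))
        try:
            sol = optimize.least_squares(resid, q0, bounds=(lo, hi), max_nfev=2000)
        except Exception:
            continue
        if sol.cost < best_cost:
            best, best_cost = sol, sol.cost
    if best is None:
        return GaussianFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                           np.full_like(vals, np.nan), np.nan, False, orientation_mode)
    p, A, x0, y0, theta, sx, sy = unpack(best.x)
    pred = gaussian2d(X, Y, p, A, x0, y0, theta, sx, sy)
    r = _corr(pred.ravel(), vals.ravel())
    return GaussianFit(float(p), float(A), float(x0), float(y0), float(theta),
                       float(sx), float(sy), pred, r, bool(best.success),
                       orientation_mode)


def classify_speed_tuning(
    smap: SpectralMap,
    criterion: float = Z_CRITERION,
    seed: int = 0,
) -> SelectivityClass:
    """Independent- vs speed-tuning classification of a spectral map.

    Correlates the map with its cardinal-constrained and diagonal
    (constant-speed) constrained Gaussian fits, then applies the same
    partial-correlation / Fisher-z rule as the direction axis (n = map
    cells); the scalar index is Z_speed - Z_independent.
    """
    fit_card = fit_spectral_gaussian(smap, "cardinal", seed=seed)
    fit_rad = fit_spectral_gaussian(smap, "radial", seed=seed)
    n = smap.values.size
    if not (fit_card.converged and fit_rad.converged):
        return SelectivityClass("spectral", smap.unit, np.nan, np.nan, np.nan,
                                np.nan, np.nan, np.nan, np.nan, "unclassed",
                                np.nan, ["fit-failure"])
    return _apply_rule("spectral", smap.unit, smap.values.ravel(),
                       fit_rad.prediction.ravel(), fit_card.prediction.ravel(),
                       n, ("speed", "independent"), criterion)


def classify_network(
    params: ModelParams,
    battery: tuple[ResponseTensor, ResponseTensor] | None = None,
    spectral: tuple[ResponseTensor, ResponseTensor] | None = None,
    n_phases: int = N_PHASES,
    criterion: float = Z_CRITERION,
) -> dict[str, dict[str, list]]:
    """Run both classification axes on every V1 kernel and MT unit.

    Plaid batteries are cached per distinct preferred (sf, tf) pair, so
    units sharing a spectral preference share one battery.  Returns
    ``{layer: {'summaries': [...], 'direction': [...], 'spectral': [...]}}``
    with parallel per-unit lists (entries are None for untuned units).
    """
    if battery is None:
        battery = grating_battery(params, n_phases=n_phases)
    if spectral is None:
        spectral = spectral_battery(params, n_phases=n_phases)
    v1_t, mt_t = battery
    sv1, smt = spectral
    plaid_cache: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
    out: dict[str, dict[str, list]] = {}
    for layer, tensor, stensor in (("v1", v1_t, sv1), ("mt", mt_t, smt)):
        summaries = [preferred_tuning(tensor, u) for u in range(tensor.n_units)]
        d_classes: list[SelectivityClass | None] = []
        s_classes: list[SelectivityClass | None] = []
        for s in summaries:
            if not s.defined:
                d_classes.append(None)
                s_classes.append(None)
                continue
            i_sf = int(np.argmin(np.abs(tensor.spatial_periods - 1.0 / s.preferred_sf)))
            i_tf = int(np.argmin(np.abs(tensor.temporal_periods - 1.0 / s.preferred_tf)))
            key = (i_sf, i_tf)
            if key not in plaid_cache:
                _, pv1, pmt = plaid_battery(
                    params, tensor.spatial_periods[i_sf], tensor.temporal_periods[i_tf],
                    n_directions=tensor.directions.size, n_phases=n_phases)
                plaid_cache[key] = (pv1, pmt)
            pcurve = plaid_cache[key][0 if layer == "v1" else 1][s.unit]
            gcurve = tensor.values[s.unit, :, i_sf, i_tf]
            d_classes.append(classify_direction_selectivity(
                gcurve, pcurve, unit=s.unit, criterion=criterion))
            s_classes.append(classify_speed_tuning(
                spectral_map(stensor, s.unit, s), criterion=criterion))
        out[layer] = {"summaries": summaries, "direction": d_classes,
                      "spectral": s_classes}
    return out


def pattern_speed_correlation(
    direction_classes: list[SelectivityClass],
    spectral_classes: list[SelectivityClass],
) -> tuple[float, float, int]:
    """Pearson correlation between pattern and speed indices across MT
    units (pooled over networks); units unclassified on both axes are
    omitted.  Returns (r, p, n)."""
    from scipy.stats import pearsonr

    if len(direction_classes) != len(spectral_classes):
        raise ValueError("class lists must be parallel (one pair per unit)")
    xs, ys = [], []
    for d, s in zip(direction_classes, spectral_classes):
        if d.label == "unclassed" and s.label == "unclassed":
            continue
        if np.isnan(d.index) or np.isnan(s.index):
            continue
        xs.append(d.index)
        ys.append(s.index)
    if len(xs) < 3:
        raise ValueError("fewer than 3 classified units: correlation undefined")
    r, p = pearsonr(xs, ys)
    return float(r), float(p), len(xs)
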