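"""Analyses that open the trained network's wiring and dynamics.

* V1->MT weight profiles aligned to each MT unit's preferred direction
  (or its direction of maximum excitation / inhibition);
* median-split connectivity: do slow-speed MT units read out from
  high-spatial / low-temporal-frequency V1 kernels?
* +v_x / -v_x direction subpopulations and their responses to phi and
  reverse-phi dot motion, including the decoded speed biases;
* a model-free cross-correlation simulation of edge stimuli against
  mirror-image spatiotemporal filters, explaining why reverse-phi speed
  is misestimated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import correlate

from .model import ModelParams, forward_batch, to_polar
from .probes import DotSpec, dot_sequence, edge_filter, edge_stimulus
from .tuning import TuningSummary

__all__ = [
    "WeightProfile",
    "ConnectivitySplit",
    "SubpopulationLabels",
    "kernel_mt_weights",
    "aligned_weight_profile",
    "speed_split_connectivity",
    "direction_subpopulations",
    "reverse_phi_experiment",
    "edge_crosscorr_sim",
]

REVERSE_PHI_SPEEDS = np.linspace(1.0, 3.5, 5)


@dataclass
class WeightProfile:
    mode: str  # 'preferred-direction' | 'max-excitation' | 'max-inhibition'
    offsets: np.ndarray  # degrees, relative to the anchor
    mean: np.ndarray
    sd: np.ndarray
    n_excluded: int = 0


@dataclass
class ConnectivitySplit:
    median_speed: float
    slow_mt: np.ndarray  # MT unit ids
    fast_mt: np.ndarray
    slow_v1_sf: np.ndarray  # preferred sf of V1 kernels feeding each group
    fast_v1_sf: np.ndarray
    slow_v1_tf: np.ndarray
    fast_v1_tf: np.ndarray
    n_excluded: int = 0

    def summary(self) -> pd.DataFrame:
        rows = []
        for grp, sf, tf in (("slow", self.slow_v1_sf, self.slow_v1_tf),
                            ("fast", self.fast_v1_sf, self.fast_v1_tf)):
            rows.append({"group": grp, "mean_sf": np.mean(sf) if len(sf) else np.nan,
                         "mean_tf": np.mean(tf) if len(tf) else np.nan, "n": len(sf)})
        return pd.DataFrame(rows)


@dataclass
class SubpopulationLabels:
    mt: list[str | None]  # '+vx' | '-vx' | None (exact-zero weight)
    v1: list[str | None]
    flags: list[str] = field(default_factory=list)


def kernel_mt_weights(params: ModelParams, collapse: str = "mean") -> np.ndarray:
    """One scalar V1->MT weight per (MT unit, kernel).

    Dense weights are collapsed over the 27x27 spatial positions of each
    kernel's map (mean by default, max by config): a convolutional
    kernel has a single direction preference, so spatial position is
    uninformative.  Returns (n_mt, n_kernels).
    """
    arch = params.arch
    n_pos = arch.n_v1_units // arch.n_kernels
    w = params.mt_weights.reshape(arch.n_mt_units, arch.n_kernels, n_pos)
    if collapse == "mean":
        return w.mean(axis=2)
    if collapse == "max":
        return w.max(axis=2)
    raise ValueError(f"unknown collapse {collapse!r}")


def _direction_bins(directions: np.ndarray, pref: float) -> int:
    return int(np.argmin(np.abs((directions - pref + 180.0) % 360.0 - 180.0)))


def aligned_weight_profile(
    params: ModelParams,
    v1_tuning: list[TuningSummary],
    mt_tuning: list[TuningSummary],
    mode: str = "preferred-direction",
    n_bins: int = 16,
    collapse: str = "mean",
) -> WeightProfile:
    """Average V1->MT weight as a function of direction offset.

    For each MT unit, per-kernel weights are binned by the kernels'
    preferred directions, circularly shifted so the anchor sits at
    offset 0 (the MT unit's preferred direction, or its max-excitation /
    max-inhibition direction), then averaged over MT units.  Kernels
    with undefined tuning are excluded and counted.
    """
    if mode not in {"preferred-direction", "max-excitation", "max-inhibition"}:
        raise ValueError(f"unknown alignment mode {mode!r}")
    directions = np.arange(n_bins) * (360.0 / n_bins)
    w = kernel_mt_weights(params, collapse)
    tuned = [t for t in v1_tuning if t.defined]
    n_excluded = len(v1_tuning) - len(tuned)
    bin_of = np.array([_direction_bins(directions, t.preferred_direction) for t in tuned])
    kernels = np.array([t.unit for t in tuned])
    profiles = []
    for m, mtune in enumerate(mt_tuning):
        binned = np.full(n_bins, np.nan)
        for b in range(n_bins):
            sel = kernels[bin_of == b]
            if sel.size:
                binned[b] = w[m, sel].mean()
        if np.all(np.isnan(binned)):
            continue
        if mode == "preferred-direction":
            if not mtune.defined:
                continue
            anchor = _direction_bins(directions, mtune.preferred_direction)
        elif mode == "max-excitation":
            anchor = int(np.nanargmax(binned))
        else:
            anchor = int(np.nanargmin(binned))
        profiles.append(np.roll(binned, -anchor))
    prof = np.array(profiles)
    offsets = directions.copy()
    offsets[offsets >= 180.0] -= 360.0
    return WeightProfile(
        mode=mode,
        offsets=offsets,
        mean=np.nanmean(prof, axis=0),
        sd=np.nanstd(prof, axis=0),
        n_excluded=n_excluded,
    )


def speed_split_connectivity(
    params: ModelParams,
    v1_tuning: list[TuningSummary],
    mt_tuning: list[TuningSummary],
    collapse: str = "mean",
) -> ConnectivitySplit:
    """Median-split MT units by preferred speed and collect the preferred
    spatial/temporal frequencies of the V1 kernels maximally (most
    positively) connected to each group."""
    w = kernel_mt_weights(params, collapse)
    speeds = np.array([t.preferred_speed if t.defined else np.nan for t in mt_tuning])
    ok_mt = ~np.isnan(speeds)
    median = float(np.median(speeds[ok_mt]))
    order = np.argsort(speeds[ok_mt], kind="stable")
    mt_ids = np.flatnonzero(ok_mt)[order]
    half = mt_ids.size // 2
    slow_set, fast_set = set(mt_ids[:half].tolist()), set(mt_ids[half:].tolist())
    groups: dict[str, dict[str, list[float]]] = {
        "slow": {"sf": [], "tf": []},
        "fast": {"sf": [], "tf": []},
    }
    n_excluded = 0
    for t in v1_tuning:
        if not t.defined:
            n_excluded += 1
            continue
        col = w[:, t.unit]
        best = int(np.argmax(col))
        if col[best] <= 0.0:
            n_excluded += 1
            continue
        grp = "slow" if best in slow_set else "fast"
        groups[grp]["sf"].append(t.preferred_sf)
        groups[grp]["tf"].append(t.preferred_tf)
    return ConnectivitySplit(
        median_speed=median,
        slow_mt=np.array(sorted(slow_set)),
        fast_mt=np.array(sorted(fast_set)),
        slow_v1_sf=np.array(groups["slow"]["sf"]),
        fast_v1_sf=np.array(groups["fast"]["sf"]),
        slow_v1_tf=np.array(groups["slow"]["tf"]),
        fast_v1_tf=np.array(groups["fast"]["tf"]),
        n_excluded=n_excluded,
    )


def direction_subpopulations(params: ModelParams, collapse: str = "mean") -> SubpopulationLabels:
    """Label MT units '+vx'/'-vx' by the sign of their weight to the v_x
    output; each V1 kernel inherits the label of the MT unit to which it
    is most positively weighted.  Exact-zero deciding weights leave a
    unit unlabeled (None) and flagged."""
    vx_w = params.out_weights[0]  # (n_mt,)
    flags: list[str] = []
    mt_labels: list[str | None] = []
    for m, wv in enumerate(vx_w):
        if wv == 0.0:
            mt_labels.append(None)
            flags.append(f"mt:{m}:zero-weight")
        else:
            mt_labels.append("+vx" if wv > 0 else "-vx")
    w = kernel_mt_weights(params, collapse)
    v1_labels: list[str | None] = []
    for k in range(params.arch.n_kernels):
        col = w[:, k]
        best = int(np.argmax(col))
        if col[best] <= 0.0:
            v1_labels.append(None)
            flags.append(f"v1:{k}:no-positive-weight")
        else:
            v1_labels.append(mt_labels[best])
    return SubpopulationLabels(mt=mt_labels, v1=v1_labels, flags=flags)


def _subpop_activity(
    v1_flat: np.ndarray, mt: np.ndarray, labels: SubpopulationLabels, arch
) -> dict[str, float]:
    """Mean rectified activity per (layer, subpopulation); V1 maps are
    averaged over positions."""
    n_pos = arch.n_v1_units // arch.n_kernels
    v1_per_kernel = v1_flat.reshape(-1, arch.n_kernels, n_pos).mean(axis=(0, 2))
    out = {}
    for name in ("+vx", "-vx"):
        v1_sel = [k for k, lab in enumerate(labels.v1) if lab == name]
        mt_sel = [m for m, lab in enumerate(labels.mt) if lab == name]
        out[f"v1{name}"] = float(v1_per_kernel[v1_sel].mean()) if v1_sel else np.nan
        out[f"mt{name}"] = float(mt.mean(axis=0)[mt_sel].mean()) if mt_sel else np.nan
    return out


def reverse_phi_experiment(
    models: list[ModelParams],
    speeds: np.ndarray = REVERSE_PHI_SPEEDS,
    n_stim_seeds: int = 20,
    seed: int = 0,
    n_dots: int = 5,
    dot_radius: float = 4.0,
) -> pd.DataFrame:
    """Decoded velocity and subpopulation activity for phi / reverse-phi
    dot motion.

    Stimuli are two motion frames of white dots on mid-gray (remaining
    frames uniform gray), displaced rightward at each speed; the
    reverse-phi variant flips dot polarity on the second frame.  Results
    are averaged over stimulus seeds; subpopulation activities are
    normalised per network (by the network's maximum across conditions)
    before averaging, so no single network dominates.  Requires trained
    models.
    """
    for i, m in enumerate(models):
        if m.trained_epochs == 0:
            raise ValueError(f"model {i} is untrained: reverse-phi results would be meaningless")
    rng = np.random.default_rng(seed)
    stim_seeds = rng.integers(0, 2**31 - 1, size=n_stim_seeds)
    rows = []
    for net_id, params in enumerate(models):
        labels = direction_subpopulations(params)
        net_rows = []
        for reverse in (False, True):
            for speed in speeds:
                batch = np.stack([
                    dot_sequence(DotSpec(
                        n_dots=n_dots, dot_radius=dot_radius, dot_value=1.0,
                        background_value=0.0, speed=float(speed),
                        signal_direction=0.0, polarity_reversal=reverse,
                        n_motion_frames=2, n_frames=params.arch.input_size[2],
                        size=params.arch.input_size[0], seed=int(s),
                    )).frames
                    for s in stim_seeds
                ]).astype(np.float32)
                v1_flat, mt, out = forward_batch(params, batch)
                est = to_polar(*out.mean(axis=0))
                acts = _subpop_activity(v1_flat, mt, labels, params.arch)
                net_rows.append({
                    "network": net_id,
                    "stimulus": "reverse-phi" if reverse else "phi",
                    "displacement_speed": float(speed),
                    "decoded_vx": float(out[:, 0].mean()),
                    "decoded_vy": float(out[:, 1].mean()),
                    "decoded_speed": est.speed,
                    "decoded_direction": est.direction,
                    **acts,
                })
        df = pd.DataFrame(net_rows)
        for layer in ("v1", "mt"):
            cols = [f"{layer}+vx", f"{layer}-vx"]
            peak = np.nanmax(df[cols].to_numpy())
            if peak > 0:
                df[cols] = df[cols] / peak
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


def edge_crosscorr_sim(
    displacements: tuple[int, ...] = (1, 2, 3),
    stim_size: int = 16,
    filter_size: int = 8,
) -> pd.DataFrame:
    """Model-free cross-correlation of phi / reverse-phi edge stimuli
    with direction-tuned edge filters.

    For every displacement x stimulus polarity x filter direction x
    filter polarity order: the valid-mode 3-D cross-correlation is
    rectified (negative values set to zero, emulating the network's
    ReLU), averaged, and the whole table normalised to its maximum.
    Deterministic and bit-reproducible.
    """
    rows = []
    for d in displacements:
        for reverse in (False, True):
            stim = edge_stimulus(d, reverse_polarity=reverse, size=stim_size).frames
            for direction in ("+vx", "-vx"):
                for order in ("light-dark", "dark-light"):
                    filt = edge_filter(d, polarity_order=order, direction=direction,
                                       size=filter_size)
                    cc = correlate(stim, filt, mode="valid")
                    val = float(np.maximum(cc, 0.0).mean())
                    rows.append({
                        "displacement": d,
                        "stimulus": "reverse-phi" if reverse else "phi",
                        "filter_direction": direction,
                        "polarity_order": order,
                        "mean_rectified_cc": val,
                    })
    df = pd.DataFrame(rows)
    peak = df["mean_rectified_cc"].max()
    if peak > 0:
        df["mean_rectified_cc"] = df["mean_rectified_cc"] / peak
    return df
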