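"""Intersite phase clustering (ISPC) functional connectivity.

ISPC for a channel pair is the trial-clustering of the phase difference,
``|n^-1 sum_r exp(i (k_x - k_y)_r)|``: the consistency across trials of the
phase relation between two sites at a time-frequency point. Values are
baseline-corrected, thresholded by a two-sided bootstrap, and pairs whose
phase-difference distribution clusters around 0 or pi (the signature of
volume conduction from a shared source) are excluded with circular v tests.
The connectivity degree (CD) of a channel is its fraction of significantly
connected partners, normalized by (channels - 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.stats import norm

from .io_preprocess import window_slice
from .timefreq import TFDecomp

__all__ = [
    "ISPCMap",
    "ConnectivityDegree",
    "ispc_map",
    "ispc_significant",
    "connectivity_degree",
    "REGIONS",
]

#: Electrode-label prefixes defining the regional profiles.
REGIONS = {
    "frontal": ("M2", "M1"),
    "parietal": ("S1", "RS", "PA"),
    "occipital": ("V2", "V1"),
}


def region_of(label: str) -> str:
    for region, prefixes in REGIONS.items():
        if label.startswith(prefixes):
            return region
    raise KeyError(f"channel label {label!r} matches no region")


@dataclass
class ISPCMap:
    """ISPC per unordered channel pair x frequency x time."""

    values: np.ndarray  # raw ISPC in [0, 1], or masked corrected values
    pairs: list[tuple[int, int]]
    frequencies: np.ndarray
    time_axis: np.ndarray
    rate: float
    channel_labels: list[str]
    corrected: np.ndarray | None = None  # baseline-corrected masked values
    mask: np.ndarray | None = None
    excluded: np.ndarray | None = None  # (n_pairs, n_freqs) volume-conduction flags
    params: dict = field(default_factory=dict)

    def slice(self, window: tuple[float, float]) -> slice:
        return window_slice(self.time_axis, self.rate, window)

    def band_sel(self, band: tuple[float, float]) -> np.ndarray:
        lo, hi = band
        sel = (self.frequencies >= lo) & (self.frequencies <= hi)
        if not sel.any():
            raise ValueError(f"band {band} outside the frequency grid")
        return sel


@dataclass
class ConnectivityDegree:
    cd: np.ndarray  # per-channel, in [0, 1]
    window: tuple[float, float]
    band: tuple[float, float]
    connected: np.ndarray  # (n_pairs,) bool
    regional: dict  # region -> mean CD


def _pair_phasors(tf: TFDecomp, sl: slice) -> list[np.ndarray]:
    """Unit phasors per channel on the selected time range."""
    out = []
    for ch in range(tf.coefficients.shape[1]):
        c = tf.coefficients[:, ch, :, sl]
        mag = np.abs(c)
        mag[mag == 0] = 1.0
        out.append((c / mag).astype(np.complex64))
    return out


def ispc_map(
    tf: TFDecomp,
    crop: tuple[float, float] | None = None,
    freq_band: tuple[float, float] | None = None,
) -> ISPCMap:
    """Raw ISPC for every unordered channel pair.

    *crop* restricts the time range (typically baseline through the
    connectivity windows) and *freq_band* the frequency rows; the full
    pair x frequency x time array for long epochs is otherwise the largest
    object in the analysis.
    """
    if tf.coefficients.shape[1] < 2:
        raise ValueError("ISPC requires at least 2 channels")
    if tf.n_trials < 2:
        raise ValueError("ISPC requires at least 2 trials")
    sl = tf.slice(crop) if crop is not None else slice(0, tf.time_axis.size)
    f_sel = tf.band(freq_band) if freq_band is not None else np.ones(
        tf.frequencies.size, dtype=bool)
    phasors = [p[:, f_sel, :] for p in _pair_phasors(tf, sl)]
    pairs = list(combinations(range(len(phasors)), 2))
    n_f, n_t = phasors[0].shape[1], phasors[0].shape[2]
    values = np.empty((len(pairs), n_f, n_t), dtype=np.float32)
    for k, (i, j) in enumerate(pairs):
        values[k] = np.abs((phasors[i] * np.conj(phasors[j])).mean(axis=0))
    return ISPCMap(
        values=values,
        pairs=pairs,
        frequencies=tf.frequencies[f_sel],
        time_axis=tf.time_axis[sl],
        rate=tf.rate,
        channel_labels=tf.channel_labels,
    )


def _vtest_u(angles_phasor: np.ndarray, mu: float) -> float:
    """Gaussian v-test statistic for clustering of unit phasors toward mu."""
    n = angles_phasor.shape[0]
    mean = angles_phasor.mean()
    r = np.abs(mean)
    theta = np.angle(mean)
    v = n * r * np.cos(theta - mu)
    return float(v * np.sqrt(2.0 / n))


def ispc_significant(
    ispc: ISPCMap,
    tf: TFDecomp,
    baseline: tuple[float, float] = (-0.5, -0.2),
    n_perm: int = 500,
    alpha: float = 0.05,
    vtest_alpha: float = 0.05,
    seed: int | None = None,
    vtest_window: tuple[float, float] | None = None,
) -> ISPCMap:
    """Baseline-correct, bootstrap-threshold and volume-conduction-filter.

    Per pair and frequency the baseline-mean ISPC is subtracted; a two-sided
    bootstrap (resampling (trial, baseline-time) pairs with replacement)
    yields percentile thresholds for the corrected values, and entries whose
    trial phase-difference distribution shows significant v-test clustering
    toward 0 or toward pi (pooled over *vtest_window*, default the
    post-stimulus part of the map) are excluded (set to 0).
    """
    if n_perm < 1.0 / alpha:
        raise ValueError("n_perm too small to resolve the requested alpha")
    if seed is None:
        raise ValueError("the bootstrap requires an explicit seed")
    bsl = ispc.slice(baseline)
    base_mean = ispc.values[:, :, bsl].mean(axis=2)  # (pairs, freqs)
    corrected = ispc.values - base_mean[:, :, None]

    # phasors restricted to the map's own time and frequency axes
    tf_sl = tf.slice((float(ispc.time_axis[0]), float(ispc.time_axis[-1]) + 0.5 / tf.rate))
    f_sel = np.isin(tf.frequencies, ispc.frequencies)
    phasors = [p[:, f_sel, :] for p in _pair_phasors(tf, tf_sl)]
    n_trials = phasors[0].shape[0]
    rng = np.random.default_rng(seed)
    idx = rng.integers(bsl.start, bsl.stop, size=(n_perm, n_trials))
    rho = rng.integers(0, n_trials, size=(n_perm, n_trials))

    if vtest_window is None:
        vtest_window = (0.0, float(ispc.time_axis[-1]) + 0.5 / ispc.rate)
    v_sl = ispc.slice(vtest_window)
    z_crit = norm.ppf(1 - vtest_alpha)

    n_pairs, n_f = len(ispc.pairs), ispc.frequencies.size
    neg = np.empty((n_pairs, n_f), dtype=np.float32)
    pos = np.empty((n_pairs, n_f), dtype=np.float32)
    excluded = np.zeros((n_pairs, n_f), dtype=bool)
    for k, (i, j) in enumerate(ispc.pairs):
        diff = phasors[i] * np.conj(phasors[j])  # (trials, f, t)
        # bootstrap: gather resampled (trial, baseline-time) pairs
        d_t = np.moveaxis(diff, 2, 1)  # (trials, t, f)
        gathered = d_t[rho, idx]  # (n_perm, trials, f)
        null = np.abs(gathered.mean(axis=1)) - base_mean[k][None, :]
        neg[k] = np.quantile(null, alpha / 2, axis=0)
        pos[k] = np.quantile(null, 1 - alpha / 2, axis=0)
        # volume-conduction v tests on per-trial pooled phase differences
        pooled = diff[:, :, v_sl].mean(axis=2)  # (trials, f) mean phasor per trial
        unit = pooled / np.where(np.abs(pooled) == 0, 1, np.abs(pooled))
        for f in range(n_f):
            if (_vtest_u(unit[:, f], 0.0) > z_crit) or (_vtest_u(unit[:, f], np.pi) > z_crit):
                excluded[k, f] = True

    mask = (corrected < neg[:, :, None]) | (corrected > pos[:, :, None])
    mask &= ~excluded[:, :, None]
    masked = np.where(mask, corrected, 0.0)
    return ISPCMap(
        values=ispc.values,
        pairs=ispc.pairs,
        frequencies=ispc.frequencies,
        time_axis=ispc.time_axis,
        rate=ispc.rate,
        channel_labels=ispc.channel_labels,
        corrected=masked,
        mask=mask,
        excluded=excluded,
        params={"n_perm": n_perm, "alpha": alpha, "vtest_alpha": vtest_alpha,
                "seed": seed, "baseline": baseline, "vtest_window": vtest_window},
    )


def connectivity_degree(
    ispc: ISPCMap,
    band: tuple[float, float] = (5.0, 14.0),
    window: tuple[float, float] = (0.08, 0.18),
) -> ConnectivityDegree:
    """Connectivity degree per channel in a band and time window.

    A pair is connected when its band- and window-mean of the masked,
    baseline-corrected ISPC is strictly positive. CD is the per-channel
    connected-partner count normalized by (channels - 1); regional means
    are computed over the fixed frontal/parietal/occipital electrode map.
    """
    if ispc.corrected is None:
        raise ValueError("run ispc_significant first")
    sel = ispc.band_sel(band)
    sl = ispc.slice(window)
    vals = ispc.corrected[:, sel, sl]
    if vals.size == 0:
        raise ValueError("empty selection")
    pair_mean = vals.mean(axis=(1, 2))
    connected = pair_mean > 0
    n_ch = len(ispc.channel_labels)
    counts = np.zeros(n_ch)
    for k, (i, j) in enumerate(ispc.pairs):
        if connected[k]:
            counts[i] += 1
            counts[j] += 1
    cd = counts / (n_ch - 1)
    regional: dict[str, float] = {}
    for region in REGIONS:
        members = [i for i, lab in enumerate(ispc.channel_labels) if region_of(lab) == region]
        regional[region] = float(cd[members].mean()) if members else float("nan")
    return ConnectivityDegree(cd=cd, window=window, band=band,
                              connected=connected, regional=regional)
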