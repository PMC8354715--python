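"""End-to-end per-session analysis driver.

``session_metrics`` runs the full chain on one epoch set and returns the
scalar summaries the group analyses consume: PCIst (full and 0.08-0.6 s
response windows), channel-mean ITPC drop time, mean HF (20-40 Hz) relative
power in 0.08-0.18 s, OFF-period summary, late-HF probability, connectivity
degree in the two analysis windows, and the spectral exponent of the
spontaneous background.

Problem sizes follow the study design the generator emulates: 90 trials,
16 channels, 500 samples/s, epochs of -5 to 5 s. The Morlet decomposition
is retained on -0.55 to 0.85 s (statistics live in -0.5 to 0.8 s; the
convolution itself runs on the full epoch).
"""

from __future__ import annotations

import numpy as np

from . import connectivity as conn
from . import evoked_features as feat
from . import phase_locking as pl
from . import timefreq as tfr
from .io_preprocess import EpochSet, interpolate_stim_artifact, reject_trials
from .pcist import PCIstParams, pcist

__all__ = ["session_metrics", "MIN_CHANNELS_CONNECTIVITY"]

#: Sessions with more than two dropped channels are excluded from connectivity.
MIN_CHANNELS_CONNECTIVITY = 14

TF_CROP = (-0.55, 0.85)
ITPC_BANDS = [(8.0, 40.0), (1.0, 4.0)]
POWER_BANDS = [tfr.BANDS["HF"], tfr.BANDS["LF"]]


def session_metrics(
    epochs: EpochSet,
    seed: int,
    n_perm: int = 500,
    with_connectivity: bool = True,
) -> dict:
    """Full analysis of one session; returns a flat metric dictionary."""
    epochs = interpolate_stim_artifact(epochs)
    epochs, rejection = reject_trials(epochs)

    tf = tfr.morlet_tf(epochs, crop=TF_CROP)
    pm = tfr.bootstrap_mask_power(tf, n_perm=n_perm, alpha=0.05,
                                  seed=seed + 1, bands=POWER_BANDS)
    n_ch = len(epochs.channel_labels)
    hf_db = tfr.band_average(pm, tfr.BANDS["HF"], (0.08, 0.18))
    off = feat.off_period_summary(
        [feat.detect_hf_suppression(pm, ch) for ch in range(n_ch)]
    )
    late = feat.detect_late_hf(pm)

    itpc = pl.itpc_mask(pl.itpc_map(tf), tf, n_perm=n_perm, alpha=0.01,
                        seed=seed + 2, bands=ITPC_BANDS)
    drops = pl.drop_times(itpc)

    out = {
        "n_rejected": int(rejection.rejected.size),
        "hf_db": float(hf_db),
        "off_fraction": off["fraction_detected"],
        "off_start_s": off["start_s"],
        "off_end_s": off["end_s"],
        "late_hf_probability": late.probability,
        "itpc_drop_s": float(drops.drop_s.mean()),
        "itpc_drop_censored_fraction": float(drops.censored.mean()),
    }

    if with_connectivity and n_ch >= MIN_CHANNELS_CONNECTIVITY:
        ispc = conn.ispc_map(tf, crop=(-0.5, 0.35), freq_band=(5.0, 14.0))
        ispc = conn.ispc_significant(ispc, tf, n_perm=n_perm, alpha=0.05,
                                     seed=seed + 3, vtest_window=(0.08, 0.30))
        cd_early = conn.connectivity_degree(ispc, window=(0.08, 0.18))
        cd_late = conn.connectivity_degree(ispc, window=(0.18, 0.3))
        out.update({
            "cd_early": float(cd_early.cd.mean()),
            "cd_late": float(cd_late.cd.mean()),
            "cd_late_regional": cd_late.regional,
        })
    elif with_connectivity:
        out["connectivity_excluded_reason"] = (
            f"{16 - n_ch} dropped channels exceed the 2-channel limit"
        )
    del tf

    erp = epochs.erp()
    res = pcist(erp, epochs.time_axis, epochs.rate)
    res_late = pcist(erp, epochs.time_axis, epochs.rate,
                     PCIstParams(response_window=(0.08, 0.6)))
    out["pcist"] = res.value
    out["pcist_n_components"] = res.n_components
    out["pcist_08_06"] = res_late.value

    # spontaneous 1/f slope on a frontal-occipital derivation when available
    labels = epochs.channel_labels
    if "M2R1" in labels and "V2R" in labels:
        deriv = (epochs.kept()[:, labels.index("M2R1"), :]
                 - epochs.kept()[:, labels.index("V2R"), :])[:, None, :]
        spont = EpochSet(
            data=deriv, time_axis=epochs.time_axis, rate=epochs.rate,
            channel_labels=["M2R1-V2R"], channel_xy=np.zeros((1, 2)),
            kept_mask=np.ones(deriv.shape[0], dtype=bool), state=epochs.state,
        )
        spec = tfr.periodogram_mean(spont, window=(-5.0, -1.0), channel=0)
        out["spectral_exponent"] = tfr.spectral_exponent(spec)
    return out
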