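"""Session I/O and preprocessing of continuous multichannel epidural EEG.

The preprocessing chain mirrors a standard evoked-potential workflow:
re-reference to the common average (or a bipolar derivation), zero-phase
band-pass filter 0.5-80 Hz (Butterworth, 3rd order), anti-aliased
downsampling to 500 samples/s, epoching from -5 to +5 s around each stimulus,
per-trial baseline (-1 to 0 s) offset correction, cubic-spline interpolation
of the stimulus artifact (0-5 ms), and rejection of trials whose baseline
root-mean-square exceeds the across-trial mean by more than three standard
deviations.

Time windows throughout the package are half-open ``[a, b)`` on the sample
grid, with t = 0 the first post-stimulus sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction

import h5py
import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, resample_poly, sosfiltfilt

__all__ = [
    "Session",
    "EpochSet",
    "RejectionReport",
    "read_session",
    "write_session",
    "condition_signal",
    "interpolate_stim_artifact",
    "epoch_and_correct",
    "reject_trials",
    "write_epochs",
    "read_epochs",
]

STATES = ("wake", "propofol", "sevoflurane", "ketamine", "synthetic")


class FormatError(ValueError):
    """A file does not conform to the declared on-disk layout."""


class IntegrityError(ValueError):
    """Internally inconsistent session or epoch data."""


def window_slice(time_axis: np.ndarray, rate: float, window: tuple[float, float]) -> slice:
    """Half-open ``[a, b)`` slice of a uniform time axis containing t = 0."""
    a, b = window
    if a >= b:
        raise ValueError(f"empty window {window}")
    i0 = int(round(-time_axis[0] * rate))
    lo = i0 + int(round(a * rate))
    hi = i0 + int(round(b * rate))
    lo = max(lo, 0)
    hi = min(hi, time_axis.size)
    if hi <= lo:
        raise ValueError(f"window {window} outside the time axis")
    return slice(lo, hi)


@dataclass
class Session:
    """A continuous multichannel recording with stimulus events.

    Attributes
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    rate : float
        Sampling rate in samples/s.
    channel_labels : list of str
        Unique electrode identifiers (e.g. ``M2L1`` ... ``V1R``).
    channel_xy : ndarray, shape (n_channels, 2)
        Electrode grid coordinates in mm, bregma-referenced (x lateral,
        y rostro-caudal).
    events : ndarray, shape (n_events, 2)
        Stimulus onsets: column 0 onset time (s), column 1 intensity (uA).
    state : str
        One of ``wake``, ``propofol``, ``sevoflurane``, ``ketamine``,
        ``synthetic``.
    reference : str
        ``raw``, ``common_average`` or ``bipolar(A-B)``.
    """

    signal: np.ndarray
    rate: float
    channel_labels: list[str]
    channel_xy: np.ndarray
    events: np.ndarray
    state: str
    reference: str = "raw"
    subject_id: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.channel_xy = np.asarray(self.channel_xy, dtype=float)
        self.events = np.asarray(self.events, dtype=float).reshape(-1, 2)
        if self.rate <= 0:
            raise IntegrityError("sampling rate must be positive")
        # a bipolar derivation legitimately collapses the montage to one trace
        min_ch = 1 if self.reference.startswith("bipolar") else 2
        if self.signal.ndim != 2 or self.signal.shape[0] < min_ch:
            raise IntegrityError("signal must be (channels, samples) with >= 2 channels")
        if len(self.channel_labels) != self.signal.shape[0]:
            raise IntegrityError(
                f"{len(self.channel_labels)} labels for {self.signal.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise IntegrityError("channel labels must be unique")
        dur = self.signal.shape[1] / self.rate
        if self.events.size and (self.events[:, 0].min() < 0 or self.events[:, 0].max() >= dur):
            raise IntegrityError("event times must lie within [0, duration)")
        if self.state not in STATES:
            raise IntegrityError(f"unknown state {self.state!r}")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"no channel labelled {label!r}") from None


@dataclass
class EpochSet:
    """Trials x channels x time, with the time axis locked to the stimulus."""

    data: np.ndarray  # (n_trials, n_channels, n_times), uV
    time_axis: np.ndarray  # s, strictly increasing, contains 0
    rate: float
    channel_labels: list[str]
    channel_xy: np.ndarray
    kept_mask: np.ndarray
    state: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        self.kept_mask = np.asarray(self.kept_mask, dtype=bool)
        if self.data.ndim != 3:
            raise IntegrityError("epoch data must be (trials, channels, time)")
        if self.time_axis.size != self.data.shape[2]:
            raise IntegrityError("time axis length mismatch")
        if np.any(np.diff(self.time_axis) <= 0):
            raise IntegrityError("time axis must be strictly increasing")
        if not np.any(np.isclose(self.time_axis, 0.0, atol=1e-9)):
            raise IntegrityError("time axis must include t = 0")
        if self.kept_mask.size != self.data.shape[0]:
            raise IntegrityError("kept_mask length mismatch")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def slice(self, window: tuple[float, float]) -> slice:
        return window_slice(self.time_axis, self.rate, window)

    def kept(self) -> np.ndarray:
        """Data of kept trials only."""
        return self.data[self.kept_mask]

    def erp(self) -> np.ndarray:
        """Trial-averaged response (channels x time) over kept trials."""
        return self.kept().mean(axis=0)


@dataclass
class RejectionReport:
    baseline_rms: np.ndarray  # per-trial, uV
    threshold: float  # uV
    rejected: np.ndarray  # indices into the trial axis


# ---------------------------------------------------------------------------
# Native HDF5 layout
# ---------------------------------------------------------------------------

def write_session(session: Session, path, ground_truth: dict | None = None) -> None:
    """Write a session to the native HDF5 layout.

    Layout: ``/signal`` (channels x samples, float32, attrs ``rate_hz``,
    ``unit``), ``/events/{onset_s,intensity_uA}``, ``/channels/{label,x_mm,
    y_mm}``, root attrs ``state``, ``subject_id``, ``reference`` and, for
    synthetic sessions, ``seed`` plus a ``/ground_truth`` group.
    """
    with h5py.File(path, "w") as f:
        d = f.create_dataset("signal", data=session.signal.astype(np.float64))
        d.attrs["rate_hz"] = float(session.rate)
        d.attrs["unit"] = "uV"
        ev = f.create_group("events")
        ev.create_dataset("onset_s", data=session.events[:, 0])
        ev.create_dataset("intensity_uA", data=session.events[:, 1])
        ch = f.create_group("channels")
        ch.create_dataset("label", data=np.array(session.channel_labels, dtype="S16"))
        ch.create_dataset("x_mm", data=session.channel_xy[:, 0])
        ch.create_dataset("y_mm", data=session.channel_xy[:, 1])
        f.attrs["state"] = session.state
        f.attrs["subject_id"] = session.subject_id
        f.attrs["reference"] = session.reference
        if session.seed is not None:
            f.attrs["seed"] = int(session.seed)
        if ground_truth is not None:
            _write_tree(f.create_group("ground_truth"), ground_truth)


def _write_tree(group: h5py.Group, tree: dict) -> None:
    for key, val in tree.items():
        if isinstance(val, dict):
            _write_tree(group.create_group(key), val)
        elif isinstance(val, str):
            group.attrs[key] = val
        elif np.isscalar(val):
            group.attrs[key] = val
        else:
            group.create_dataset(key, data=np.asarray(val))


def _read_tree(group: h5py.Group) -> dict:
    out: dict = {k: v for k, v in group.attrs.items()}
    for key, val in group.items():
        out[key] = _read_tree(val) if isinstance(val, h5py.Group) else val[()]
    return out


def read_session(path, format: str = "hdf5", events_path=None) -> Session:
    """Read a session from the native HDF5 layout or import from EDF.

    For EDF, the events are supplied as a two-column delimited text file
    (``onset_s  intensity_uA``) via *events_path* (no events if omitted).
    """
    if format == "hdf5":
        return _read_session_h5(path)
    if format == "edf":
        return _read_session_edf(path, events_path)
    raise ValueError(f"unknown format {format!r}")


def _require(f: h5py.File, name: str):
    if name not in f:
        raise FormatError(f"missing dataset or group {name!r}")
    return f[name]


def _read_session_h5(path) -> Session:
    with h5py.File(path, "r") as f:
        sig = _require(f, "signal")
        if "rate_hz" not in sig.attrs:
            raise FormatError("missing attribute 'rate_hz' on /signal")
        rate = float(sig.attrs["rate_hz"])
        signal = sig[()]
        ev = _require(f, "events")
        events = np.column_stack([_require(ev, "onset_s")[()], _require(ev, "intensity_uA")[()]])
        ch = _require(f, "channels")
        labels = [s.decode() for s in _require(ch, "label")[()]]
        xy = np.column_stack([_require(ch, "x_mm")[()], _require(ch, "y_mm")[()]])
        if len(labels) != signal.shape[0]:
            raise IntegrityError("channel label count does not match the signal")
        return Session(
            signal=signal,
            rate=rate,
            channel_labels=labels,
            channel_xy=xy,
            events=events,
            state=str(f.attrs.get("state", "synthetic")),
            reference=str(f.attrs.get("reference", "raw")),
            subject_id=str(f.attrs.get("subject_id", "")),
            seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
        )


def read_ground_truth(path) -> dict | None:
    with h5py.File(path, "r") as f:
        if "ground_truth" not in f:
            return None
        return _read_tree(f["ground_truth"])


def _read_session_edf(path, events_path) -> Session:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    signal = raw.get_data() * 1e6  # mne returns volts
    labels = list(raw.ch_names)
    if events_path is not None:
        events = np.loadtxt(events_path, ndmin=2)
        if events.shape[1] != 2:
            raise FormatError("events file must have two columns: onset_s intensity_uA")
    else:
        events = np.empty((0, 2))
    n = signal.shape[0]
    xy = np.zeros((n, 2))  # EDF headers carry no grid geometry
    return Session(
        signal=signal,
        rate=float(raw.info["sfreq"]),
        channel_labels=labels,
        channel_xy=xy,
        events=events,
        state="synthetic",
    )


def write_epochs(epochs: EpochSet, path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("epochs")
        g.create_dataset("data", data=epochs.data)
        g.create_dataset("time_axis_s", data=epochs.time_axis)
        g.create_dataset("kept_mask", data=epochs.kept_mask)
        ch = g.create_group("channels")
        ch.create_dataset("label", data=np.array(epochs.channel_labels, dtype="S16"))
        ch.create_dataset("x_mm", data=epochs.channel_xy[:, 0])
        ch.create_dataset("y_mm", data=epochs.channel_xy[:, 1])
        g.attrs["rate_hz"] = epochs.rate
        g.attrs["state"] = epochs.state
        for k, v in epochs.provenance.items():
            g.attrs[f"prov_{k}"] = str(v)


def read_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        g = _require(f, "epochs")
        ch = _require(g, "channels")
        prov = {
            k[len("prov_"):]: str(v) for k, v in g.attrs.items() if k.startswith("prov_")
        }
        return EpochSet(
            data=_require(g, "data")[()],
            time_axis=_require(g, "time_axis_s")[()],
            rate=float(g.attrs["rate_hz"]),
            channel_labels=[s.decode() for s in ch["label"][()]],
            channel_xy=np.column_stack([ch["x_mm"][()], ch["y_mm"][()]]),
            kept_mask=_require(g, "kept_mask")[()],
            state=str(g.attrs.get("state", "synthetic")),
            provenance=prov,
        )


# ---------------------------------------------------------------------------
# Conditioning
# ---------------------------------------------------------------------------

def _rereference(
    session: Session, scheme: str
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Return (signal, labels, xy) under the requested reference scheme."""
    labels = session.channel_labels
    if scheme == "raw":
        return session.signal, list(labels), session.channel_xy
    if scheme == "common_average":
        sig = session.signal - session.signal.mean(axis=0, keepdims=True)
        return sig, list(labels), session.channel_xy
    if scheme.startswith("bipolar(") and scheme.endswith(")"):
        pair = scheme[len("bipolar("):-1]
        try:
            a, b = pair.split("-")
        except ValueError:
            raise ValueError(f"bipolar scheme must name a pair 'A-B', got {scheme!r}") from None
        for name in (a, b):
            if name not in labels:
                raise ValueError(f"bipolar scheme names absent channel {name!r}")
        deriv = session.signal[labels.index(a)] - session.signal[labels.index(b)]
        mid = 0.5 * (
            session.channel_xy[labels.index(a)] + session.channel_xy[labels.index(b)]
        )
        return deriv[None, :], [pair], mid[None, :]
    raise ValueError(f"unknown reference scheme {scheme!r}")


def condition_signal(
    session: Session,
    reference_scheme: str = "common_average",
    band: tuple[float, float] = (0.5, 80.0),
    order: int = 3,
    target_rate: float = 500.0,
) -> Session:
    """Re-reference, band-pass and downsample a continuous session.

    The filter is a zero-phase (forward-backward) Butterworth band-pass of the
    stated order, applied before polyphase anti-aliased resampling to
    *target_rate*. Event times are unchanged (they are in seconds).
    """
    if session.rate < 2 * band[1]:
        raise ValueError("sampling rate must be at least twice the band upper edge")
    if target_rate > session.rate:
        raise ValueError("cannot resample upwards")
    signal, labels, xy = _rereference(session, reference_scheme)
    sos = butter(order, band, btype="bandpass", fs=session.rate, output="sos")
    signal = sosfiltfilt(sos, signal, axis=1)
    if target_rate != session.rate:
        frac = Fraction(target_rate / session.rate).limit_denominator(10000)
        signal = resample_poly(signal, frac.numerator, frac.denominator, axis=1)
    return replace(
        session,
        signal=signal,
        rate=float(target_rate),
        channel_labels=labels,
        channel_xy=xy,
        reference=reference_scheme,
    )


def epoch_and_correct(
    session: Session,
    window: tuple[float, float] = (-5.0, 5.0),
    baseline: tuple[float, float] = (-1.0, 0.0),
) -> EpochSet:
    """Extract one epoch per event and subtract the per-trial baseline mean.

    Events lying too close to the recording edges for a full epoch are
    skipped; their indices are recorded in ``provenance['skipped_events']``.
    """
    rate = session.rate
    n_pre = int(round(-window[0] * rate))
    n_post = int(round(window[1] * rate))
    n_time = n_pre + n_post
    time_axis = (np.arange(n_time) - n_pre) / rate
    epochs, skipped = [], []
    for i, (onset, _) in enumerate(session.events):
        k0 = int(round(onset * rate))
        lo, hi = k0 - n_pre, k0 + n_post
        if lo < 0 or hi > session.signal.shape[1]:
            skipped.append(i)
            continue
        epochs.append(session.signal[:, lo:hi])
    if not epochs:
        raise ValueError("no event has a full epoch of signal around it")
    data = np.stack(epochs)
    bsl = window_slice(time_axis, rate, baseline)
    data = data - data[:, :, bsl].mean(axis=2, keepdims=True)
    return EpochSet(
        data=data,
        time_axis=time_axis,
        rate=rate,
        channel_labels=list(session.channel_labels),
        channel_xy=session.channel_xy,
        kept_mask=np.ones(data.shape[0], dtype=bool),
        state=session.state,
        provenance={
            "window": window,
            "baseline": baseline,
            "reference": session.reference,
            "skipped_events": skipped,
        },
    )


def interpolate_stim_artifact(
    epochs: EpochSet,
    window: tuple[float, float] = (0.0, 0.005),
    n_anchor: int = 10,
) -> EpochSet:
    """Replace the stimulus-artifact window by cubic-spline interpolation.

    The spline is anchored on *n_anchor* samples flanking the window on each
    side; samples outside the window are returned bit-identical.
    """
    sl = epochs.slice(window)
    if sl.start - n_anchor < 0 or sl.stop + n_anchor > epochs.time_axis.size:
        raise ValueError("artifact window too close to the epoch edge for anchoring")
    anchors = np.r_[np.arange(sl.start - n_anchor, sl.start), np.arange(sl.stop, sl.stop + n_anchor)]
    inside = np.arange(sl.start, sl.stop)
    flat = epochs.data.reshape(-1, epochs.time_axis.size)
    spline = CubicSpline(anchors, flat[:, anchors].T)
    out = epochs.data.copy().reshape(-1, epochs.time_axis.size)
    out[:, inside] = spline(inside).T
    return replace(
        epochs,
        data=out.reshape(epochs.data.shape),
        provenance={**epochs.provenance, "artifact_window": window, "artifact_anchors": n_anchor},
    )


def reject_trials(
    epochs: EpochSet,
    baseline: tuple[float, float] = (-1.0, 0.0),
) -> tuple[EpochSet, RejectionReport]:
    """Mark trials with high baseline rms as rejected.

    The per-trial rms pools channels (rms of the concatenated channel
    baselines); the threshold is the across-trial mean + 3 sample standard
    deviations, with a strict ``>`` comparison (so a zero-SD degenerate set
    rejects nothing).
    """
    if epochs.n_trials < 2:
        raise ValueError("trial rejection needs at least 2 trials")
    bsl = epochs.slice(baseline)
    seg = epochs.data[:, :, bsl]
    rms = np.sqrt((seg**2).mean(axis=(1, 2)))
    threshold = float(rms.mean() + 3 * rms.std(ddof=1))
    rejected = np.flatnonzero(rms > threshold)
    mask = epochs.kept_mask.copy()
    mask[rejected] = False
    out = replace(epochs, kept_mask=mask,
                  provenance={**epochs.provenance, "rejection_baseline": baseline})
    return out, RejectionReport(baseline_rms=rms, threshold=threshold, rejected=rejected)
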