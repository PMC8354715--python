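"""Synthetic stimulation sessions with known ground truth.

The generator emulates the statistical structure of epidural EEG responses
to intracortical electrical stimulation in the states the analysis chain
distinguishes:

- a 1/f^|beta| background with a state-dependent spectral exponent (shallow
  in wakefulness and under ketamine, steep under propofol/sevoflurane),
  produced by inverse-FFT spectral shaping with random phases;
- a stimulus-locked early deflection (6-50 ms) and a bank of damped,
  phase-locked oscillations whose locked duration sets the ground-truth
  ITPC drop time (the locked portion carries identical phase across trials,
  nothing is locked beyond it);
- a slow (<4 Hz) evoked half-wave;
- an OFF period, realized as multiplicative attenuation of the >15 Hz
  content inside its window (the slow component is left intact, so HF
  suppression and the SC co-occur);
- late high-frequency bursts with per-trial random phase (power without
  phase locking), present per channel with a state-dependent probability;
- a common 10 Hz coupling source with fixed per-channel phase offsets in
  multiples of pi/2 and per-trial random global phase: intersite phase
  differences are trial-consistent (functional connectivity) while the
  intertrial phase is uniform. Offsets at odd multiples of pi/2 survive the
  volume-conduction v tests; even multiples (0, pi) are excluded by design,
  mimicking the zero-lag contamination the analysis must reject.

Evoked amplitudes decay exponentially with electrode distance from the
stimulation site. All draws are recorded in a ground-truth dictionary
sufficient to predict the expected analysis outputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import h5py
import numpy as np

from . import io_preprocess as iop
from .io_preprocess import EpochSet, Session

__all__ = [
    "StateTemplate",
    "GRID_LABELS",
    "GRID_XY",
    "template",
    "simulate_session",
    "paired_conditions",
    "write_session",
]

#: 16-electrode epidural grid (mm, bregma-referenced), symmetric about the midline.
GRID_LABELS = [
    "M2L1", "M2R1", "M2L2", "M2R2", "M1L", "M1R", "S1L", "S1R",
    "RSL", "RSR", "PAL", "PAR", "V2L", "V2R", "V1L", "V1R",
]
GRID_XY = np.array([
    (-1.5, 5.0), (1.5, 5.0), (-1.5, 2.0), (1.5, 2.0),
    (-1.5, -1.0), (1.5, -1.0), (-4.5, -1.0), (4.5, -1.0),
    (-1.5, -4.0), (1.5, -4.0), (-4.5, -4.0), (4.5, -4.0),
    (-1.5, -7.0), (1.5, -7.0), (-4.5, -7.0), (4.5, -7.0),
])
STIM_XY = np.array([1.45, 3.7])  # bipolar stimulation electrode, right M2


@dataclass
class StateTemplate:
    """Generative parameters of one behavioural/anesthetic state."""

    name: str
    background_exponent: float  # 1/f slope of the spontaneous background
    background_rms_uv: float = 25.0
    background_knee_hz: float = 8.0  # aperiodic knee: flat below, f^beta above
    slow_wave_uv: float = 0.0  # spontaneous slow oscillation (anesthesia)
    slow_wave_hz: float = 1.0
    early_amp_uv: float = 120.0  # stimulus-locked first deflection
    locked_amp_uv: float = 45.0  # phase-locked oscillation bank
    locked_duration_s: float = 0.30
    locked_freq_ranges: tuple = ((10.0, 18.0), (15.0, 25.0))
    off_depth_db: float = 0.0  # 0 disables; negative = HF suppression depth
    off_window_s: tuple = (0.08, 0.18)
    sc_amp_uv: float = 30.0  # evoked slow half-wave
    sc_peak_s: float = 0.12
    sc_jitter_s: float = 0.12  # per-trial/channel latency jitter (half-range)
    sc_travel_s_per_mm: float = 0.008  # latency increase with distance from stim
    late_hf_prob: float = 1.0  # per-channel probability of an HF burst
    late_hf_amp_uv: float = 18.0
    late_hf_band: tuple = (25.0, 35.0)
    late_hf_onset_range: tuple = (0.05, 0.12)
    coupling_amp_uv: float = 12.0  # common-source functional coupling
    coupling_freq_hz: float = 6.0
    coupling_window_s: tuple = (0.05, 0.35)
    region_coupling_gain: dict = field(
        default_factory=lambda: {"frontal": 0.6, "parietal": 1.0, "occipital": 1.6}
    )
    distance_decay_mm: float = 12.0
    artifact_uv: float = 0.0
    stim_intensity_ua: float = 50.0

    def validate(self) -> None:
        if self.locked_duration_s < 0 or self.locked_duration_s > 0.8:
            raise ValueError("locked duration must lie in [0, 0.8] s")
        if self.off_depth_db > 0:
            raise ValueError("OFF depth is expressed in dB <= 0")
        if not (0 <= self.late_hf_prob <= 1):
            raise ValueError("late HF probability must lie in [0, 1]")
        for v in (self.background_rms_uv, self.early_amp_uv, self.locked_amp_uv,
                  self.sc_amp_uv, self.late_hf_amp_uv, self.coupling_amp_uv,
                  self.distance_decay_mm):
            if v < 0:
                raise ValueError("amplitudes and scales must be nonnegative")
        if self.off_window_s[0] >= self.off_window_s[1]:
            raise ValueError("OFF window must be nonempty")


_TEMPLATES = {
    "wake": dict(
        background_exponent=-1.4, locked_duration_s=0.30, off_depth_db=0.0,
        sc_amp_uv=30.0, sc_peak_s=0.12, late_hf_prob=1.0,
        late_hf_onset_range=(0.05, 0.12), late_hf_amp_uv=22.0, coupling_amp_uv=12.0,
        locked_amp_uv=50.0,
    ),
    "propofol": dict(
        background_exponent=-3.0, slow_wave_uv=65.0, locked_duration_s=0.08,
        locked_freq_ranges=((12.0, 16.0), (14.0, 18.0)),
        off_depth_db=-4.0, sc_amp_uv=75.0, sc_peak_s=0.25, late_hf_prob=0.0,
        coupling_amp_uv=3.0,
    ),
    "sevoflurane": dict(
        background_exponent=-2.8, slow_wave_uv=60.0, locked_duration_s=0.09,
        locked_freq_ranges=((12.0, 16.0), (14.0, 18.0)),
        off_depth_db=-3.5, sc_amp_uv=70.0, sc_peak_s=0.22, late_hf_prob=0.0,
        coupling_amp_uv=4.0,
    ),
    "ketamine": dict(
        background_exponent=-1.0, locked_duration_s=0.28, off_depth_db=-3.0,
        locked_freq_ranges=((6.0, 10.0), (8.0, 12.0)), locked_amp_uv=30.0,
        sc_amp_uv=50.0, sc_peak_s=0.18, late_hf_prob=0.9,
        late_hf_onset_range=(0.20, 0.45), coupling_amp_uv=9.0,
    ),
    # background only: for surrogate/null calibrations
    "noise": dict(
        background_exponent=-1.4, early_amp_uv=0.0, locked_amp_uv=0.0,
        locked_duration_s=0.0, sc_amp_uv=0.0, late_hf_prob=0.0,
        coupling_amp_uv=0.0,
    ),
}


def template(state: str, **overrides) -> StateTemplate:
    """Default template for a named state, with optional field overrides."""
    if state not in _TEMPLATES:
        raise KeyError(f"unknown state {state!r}; known: {sorted(_TEMPLATES)}")
    t = StateTemplate(name=state, **{**_TEMPLATES[state], **overrides})
    t.validate()
    return t


def _shaped_noise(rng, n_sig, n_ch, n_time, rate, exponent, rms_uv, f_floor=0.5):
    """1/f^|exponent| noise via inverse-FFT amplitude shaping, unit-exact rms."""
    freqs = np.fft.rfftfreq(n_time, d=1.0 / rate)
    amp = np.where(freqs > 0, np.maximum(freqs, f_floor) ** (exponent / 2.0), 0.0)
    phases = rng.uniform(0, 2 * np.pi, size=(n_sig, n_ch, freqs.size))
    spec = amp[None, None, :] * np.exp(1j * phases)
    x = np.fft.irfft(spec, n=n_time, axis=2)
    rms = np.sqrt((x**2).mean(axis=2, keepdims=True))
    rms[rms == 0] = 1.0
    return x * (rms_uv / rms)


def _background(rng, n_trials, n_ch, t, rate, exponent, rms_uv, knee_hz,
                block_edge_s: float = -1.0):
    """Blockwise-shaped background noise.

    The epoch is generated as two independently shaped blocks split at
    *block_edge_s* (the end of the spontaneous-activity window), so the
    baseline periodogram of the first block is leakage-exact: its FFT grid
    coincides with the generation grid and the measured log-log slope equals
    the template exponent to machine precision in expectation.
    """
    k_edge = int(round((block_edge_s - t[0]) * rate))
    out = np.empty((n_trials, n_ch, t.size))
    out[:, :, :k_edge] = _shaped_noise(rng, n_trials, n_ch, k_edge, rate,
                                       exponent, rms_uv, f_floor=knee_hz)
    out[:, :, k_edge:] = _shaped_noise(rng, n_trials, n_ch, t.size - k_edge,
                                       rate, exponent, rms_uv, f_floor=knee_hz)
    return out


def _ramped_env(t, start, stop, ramp=0.03):
    """Unit envelope over [start, stop] with sin^2 ramps."""
    env = np.zeros_like(t)
    inside = (t >= start) & (t <= stop)
    env[inside] = 1.0
    up = (t >= start) & (t < start + ramp)
    env[up] = np.sin(0.5 * np.pi * (t[up] - start) / ramp) ** 2
    down = (t > stop - ramp) & (t <= stop)
    env[down] = np.sin(0.5 * np.pi * (stop - t[down]) / ramp) ** 2
    return env


def _early_waveform(t, amp, t0=0.025, sigma=0.012):
    w = -(t - t0) * np.exp(-((t - t0) ** 2) / (2 * sigma**2))
    peak = np.abs(w).max()
    return amp * w / peak if peak > 0 else w


def _split_hf(x, rate, cutoff=15.0):
    """Exact spectral split of the last axis at *cutoff* Hz."""
    spec = np.fft.rfft(x, axis=-1)
    freqs = np.fft.rfftfreq(x.shape[-1], d=1.0 / rate)
    hf = np.fft.irfft(spec * (freqs > cutoff), n=x.shape[-1], axis=-1)
    return x - hf, hf


def simulate_session(
    tmpl: StateTemplate,
    n_trials: int = 90,
    n_channels: int = 16,
    rate: float = 500.0,
    epoch: tuple[float, float] = (-5.0, 5.0),
    seed: int | None = None,
    channel_gains: np.ndarray | None = None,
    continuous: bool = False,
):
    """Generate a session with the template's statistical structure.

    Returns ``(EpochSet, ground_truth)`` by default (epochs are already
    offset-corrected on the -1-0 s baseline), or ``(Session, ground_truth)``
    when *continuous* is set, with per-trial segments laid out consecutively
    and one stimulus event at each segment center. Identical seeds give
    bit-identical output.
    """
    tmpl.validate()
    if n_channels < 2 or n_channels > 16:
        raise ValueError("n_channels must lie in [2, 16]")
    rng = np.random.default_rng(seed)
    labels = GRID_LABELS[:n_channels]
    xy = GRID_XY[:n_channels]
    n_time = int(round((epoch[1] - epoch[0]) * rate))
    t = epoch[0] + np.arange(n_time) / rate

    # --- session-level draws (all recorded in the ground truth) -----------
    if channel_gains is None:
        channel_gains = np.exp(rng.normal(0.0, 0.1, size=n_channels))
    dist = np.linalg.norm(xy - STIM_XY[None, :], axis=1)
    evoked_gain = np.exp(-dist / tmpl.distance_decay_mm) * channel_gains
    # one zero-lag oscillation bank per session: the locked response is a
    # spatially coherent (volume-conducted-like) pattern, so the v tests can
    # legitimately reject its channel pairs while the lagged coupling source
    # below carries the functional connectivity
    lock_f = np.array([rng.uniform(lo, hi) for lo, hi in tmpl.locked_freq_ranges])
    lock_phase = rng.uniform(0, 2 * np.pi, size=lock_f.shape)
    late_flags = rng.random(n_channels) < tmpl.late_hf_prob
    late_onset = rng.uniform(*tmpl.late_hf_onset_range, size=n_channels)
    late_freq = rng.uniform(*tmpl.late_hf_band, size=n_channels)
    coupling_offset = (np.arange(n_channels) % 4) * (np.pi / 2)
    from .connectivity import region_of

    coupling_gain = np.array(
        [tmpl.region_coupling_gain[region_of(lab)] for lab in labels]
    ) * channel_gains

    # --- deterministic (trial-invariant, phase-locked) evoked parts -------
    locked = np.zeros((n_channels, n_time))
    if tmpl.early_amp_uv > 0:
        w = _early_waveform(np.clip(t, 0, 0.1), 1.0)
        w[t < 0] = 0.0
        locked += tmpl.early_amp_uv * evoked_gain[:, None] * w[None, :]
    if tmpl.locked_amp_uv > 0 and tmpl.locked_duration_s > 0:
        dur = tmpl.locked_duration_s
        env = _ramped_env(t, 0.01, dur, ramp=min(0.03, dur / 2)) * np.exp(-np.maximum(t, 0) / 1.5)
        # the two oscillators carry distinct spatial profiles (stim-centered
        # vs posterior-weighted), giving the phase-locked response more than
        # one principal component, as multi-source cortical activations do
        posterior = np.exp(-np.linalg.norm(xy - np.array([0.0, -5.5]), axis=1) / 8.0) \
            * channel_gains
        profiles = [evoked_gain, posterior]
        for osc in range(lock_f.size):
            carrier = np.cos(2 * np.pi * lock_f[osc] * t + lock_phase[osc])
            prof = profiles[osc % len(profiles)]
            locked += tmpl.locked_amp_uv / lock_f.size * prof[:, None] \
                * (env * carrier)[None, :]
    # slow component: built per trial below (its latency jitters trial to
    # trial, so unlike the oscillation bank it is not phase-locked at alpha
    # frequencies; it travels away from the stimulation site)

    # --- background + per-trial stochastic parts ---------------------------
    data = _background(rng, n_trials, n_channels, t, rate,
                       tmpl.background_exponent, tmpl.background_rms_uv,
                       tmpl.background_knee_hz)
    if tmpl.slow_wave_uv > 0:
        sw_phase = rng.uniform(0, 2 * np.pi, size=n_trials)
        data += tmpl.slow_wave_uv * np.sin(
            2 * np.pi * tmpl.slow_wave_hz * t[None, None, :] + sw_phase[:, None, None]
        )
    data += locked[None, :, :]
    if tmpl.sc_amp_uv > 0:
        # Gaussian half-wave: spectrally compact (no onset/offset edges), so
        # the trial-to-trial latency jitter leaves nothing phase-locked at
        # alpha/beta frequencies; width p/3 keeps it essentially zero at t=0
        sc_jit = rng.uniform(-tmpl.sc_jitter_s, tmpl.sc_jitter_s,
                             size=(n_trials, n_channels))
        peak = tmpl.sc_peak_s + dist * tmpl.sc_travel_s_per_mm
        width = tmpl.sc_peak_s / 3.0
        tt = t[None, None, :] - sc_jit[:, :, None] - peak[None, :, None]
        data += -tmpl.sc_amp_uv * evoked_gain[None, :, None] \
            * np.exp(-(tt**2) / (2 * width**2))
    if tmpl.late_hf_amp_uv > 0 and late_flags.any():
        hf_phase = rng.uniform(0, 2 * np.pi, size=(n_trials, n_channels))
        hf_jit = rng.uniform(0.7, 1.3, size=(n_trials, n_channels))
        for ch in np.flatnonzero(late_flags):
            tt = t - late_onset[ch]
            env = np.where(
                (tt >= 0) & (tt <= 0.4),
                np.sin(0.5 * np.pi * np.clip(tt / 0.03, 0, 1)) ** 2 * np.exp(-np.maximum(tt, 0) / 0.15),
                0.0,
            )
            burst = np.cos(2 * np.pi * late_freq[ch] * t[None, :] + hf_phase[:, ch][:, None])
            data[:, ch, :] += (tmpl.late_hf_amp_uv * channel_gains[ch]
                               * hf_jit[:, ch][:, None] * env[None, :] * burst)
    if tmpl.coupling_amp_uv > 0:
        psi = rng.uniform(0, 2 * np.pi, size=n_trials)
        env = _ramped_env(t, *tmpl.coupling_window_s)
        phase = (2 * np.pi * tmpl.coupling_freq_hz * t[None, None, :]
                 + psi[:, None, None] + coupling_offset[None, :, None])
        data += tmpl.coupling_amp_uv * coupling_gain[None, :, None] * env[None, None, :] \
            * np.cos(phase)

    # --- OFF period: attenuate >15 Hz content inside its window -----------
    if tmpl.off_depth_db < 0:
        g0 = 10.0 ** (tmpl.off_depth_db / 20.0)
        profile = _ramped_env(t, *tmpl.off_window_s, ramp=0.01)
        gain_t = 1.0 + (g0 - 1.0) * profile
        for lo in range(0, n_trials, 10):  # chunked: the FFT split is memory-heavy
            lf, hf = _split_hf(data[lo:lo + 10], rate)
            data[lo:lo + 10] = lf + hf * gain_t[None, None, :]

    if tmpl.artifact_uv > 0:
        spike = np.where((t >= 0) & (t < 0.004),
                         np.exp(-np.maximum(t, 0) / 0.001), 0.0)
        data += tmpl.artifact_uv * spike[None, None, :]

    ground_truth = {
        "seed": -1 if seed is None else int(seed),
        "state": tmpl.name,
        "template": {k: (np.asarray(v, dtype=float) if not isinstance(v, (str, dict))
                         else v)
                     for k, v in asdict(tmpl).items() if not isinstance(v, dict)},
        "channel_gains": channel_gains,
        "evoked_gain": evoked_gain,
        "locked_freqs": lock_f,
        "locked_phases": lock_phase,
        "locked_duration_s": float(tmpl.locked_duration_s),
        "off_depth_db": float(tmpl.off_depth_db),
        "off_window_s": np.asarray(tmpl.off_window_s),
        "late_hf_flags": late_flags,
        "late_hf_onsets": late_onset,
        "late_hf_freqs": late_freq,
        "coupling_offsets": coupling_offset,
        "spectral_exponent": float(tmpl.background_exponent),
    }

    if continuous:
        signal = np.transpose(data, (1, 0, 2)).reshape(n_channels, -1)
        events = np.column_stack([
            -epoch[0] + (epoch[1] - epoch[0]) * np.arange(n_trials),
            np.full(n_trials, tmpl.stim_intensity_ua),
        ])
        session = Session(
            signal=signal, rate=rate, channel_labels=list(labels), channel_xy=xy,
            events=events, state=tmpl.name if tmpl.name in iop.STATES else "synthetic",
            reference="raw", subject_id=f"synthetic-{tmpl.name}",
            seed=seed,
        )
        return session, ground_truth

    bsl = iop.window_slice(t, rate, (-1.0, 0.0))
    data = data - data[:, :, bsl].mean(axis=2, keepdims=True)
    epochs = EpochSet(
        data=data, time_axis=t, rate=rate, channel_labels=list(labels),
        channel_xy=xy, kept_mask=np.ones(n_trials, dtype=bool),
        state=tmpl.name if tmpl.name in iop.STATES else "synthetic",
        provenance={"generator": tmpl.name, "seed": seed},
    )
    return epochs, ground_truth


def paired_conditions(
    wake_template: StateTemplate,
    anesthesia_template: StateTemplate,
    n_pairs: int,
    seed: int | None = None,
    **session_kwargs,
) -> list[tuple[tuple, tuple]]:
    """Within-subject condition pairs with shared structural randomness.

    Each pair shares its per-channel gains (the stable anatomy of one
    animal) while background noise and per-trial draws are independent;
    per-pair seeds derive deterministically from the master seed.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    wake_template.validate()
    anesthesia_template.validate()
    master = np.random.default_rng(seed)
    n_ch = session_kwargs.get("n_channels", 16)
    out = []
    for _ in range(n_pairs):
        gains = np.exp(master.normal(0.0, 0.1, size=n_ch))
        s_w, s_a = master.integers(0, 2**31 - 1, size=2)
        out.append((
            simulate_session(wake_template, seed=int(s_w), channel_gains=gains,
                             **session_kwargs),
            simulate_session(anesthesia_template, seed=int(s_a), channel_gains=gains,
                             **session_kwargs),
        ))
    return out


def write_session(session, ground_truth: dict | None, path) -> None:
    """Write a (Session | EpochSet) with its ground truth to the native layout."""
    if isinstance(session, Session):
        iop.write_session(session, path, ground_truth=ground_truth)
        return
    iop.write_epochs(session, path)
    if ground_truth is not None:
        with h5py.File(path, "a") as f:
            iop._write_tree(f.create_group("ground_truth"), ground_truth)
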