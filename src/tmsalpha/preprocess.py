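"""Epoching and cleaning of TMS-EEG sessions.

The chain, in fixed order: segment 6 s trials around each pulse
(-2 .. +4 s), replace the stimulation artifact (-5 .. +10 ms) by a
straight line with matched white noise, common-average reference +
0.5 Hz order-2 Butterworth high-pass (zero-phase) + anti-aliased
downsampling, then automated amplitude-based trial rejection.
Permuting interpolation and filtering changes the result (the filter
smears the artifact), so the order is part of the contract.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import signal

from .containers import EpochSet, Recording
from .trigger import TriggerEvent

EPOCH_SPAN = (-2.0, 4.0)
ARTIFACT_CUT = (-0.005, 0.010)
NOISE_REF = (-0.060, -0.010)


def epoch_recording(
    recording: Recording,
    events,
    tmin: float = EPOCH_SPAN[0],
    tmax: float = EPOCH_SPAN[1],
) -> EpochSet:
    """Cut one trial per event, t = 0 at the pulse.

    ``events`` may be TriggerEvent objects or plain times in seconds.
    The epoch uses the half-open convention [tmin, tmax): exactly
    ``round((tmax - tmin) * fs)`` samples per trial.  Events whose
    window would leave the recording are dropped and logged.
    """
    fs = recording.sampling_rate
    times_s = np.asarray(
        [e.time if isinstance(e, TriggerEvent) else float(e) for e in events]
    )
    n_samp = int(round((tmax - tmin) * fs))
    rel_times = tmin + np.arange(n_samp) / fs
    trials = []
    kept = []
    log: dict[int, str] = {}
    for i, t0 in enumerate(times_s):
        i0 = int(round((t0 + tmin) * fs))
        i1 = i0 + n_samp
        if i0 < 0 or i1 > recording.n_samples:
            log[i] = f"event at {t0:.3f} s too close to recording edge"
            continue
        trials.append(recording.data[:, i0:i1])
        kept.append(i)
    if not trials:
        raise ValueError("no usable events: all trials fall outside the recording")
    return EpochSet(
        np.stack(trials), rel_times, fs, list(recording.channel_names), kept, log
    )


def interpolate_artifact(
    epochs: EpochSet,
    cut: tuple[float, float] = ARTIFACT_CUT,
    noise_ref: tuple[float, float] = NOISE_REF,
    rng: np.random.Generator | None = None,
) -> EpochSet:
    """Replace the stimulation artifact by a straight line plus white noise.

    Per trial and channel, samples with ``cut[0] <= t <= cut[1]`` are
    replaced by the line joining the nearest samples outside the cut,
    plus zero-mean white noise whose SD equals the SD of the linearly
    detrended ``noise_ref`` segment.  No sample outside the cut window
    is modified.
    """
    if cut[0] <= epochs.times[0] or cut[1] >= epochs.times[-1]:
        raise ValueError(f"cut window {cut} not strictly inside the epoch")
    if rng is None:
        rng = np.random.default_rng(0)
    out = epochs.copy()
    t = out.times
    cut_idx = np.flatnonzero((t >= cut[0]) & (t <= cut[1]))
    if cut_idx.size == 0:
        return out
    i_lo, i_hi = cut_idx[0] - 1, cut_idx[-1] + 1
    if i_lo < 0 or i_hi >= t.size:
        raise ValueError("cut window touches the epoch boundary")
    ref_idx = np.flatnonzero((t >= noise_ref[0]) & (t <= noise_ref[1]))
    if ref_idx.size < 4:
        raise ValueError("noise_ref window too short")
    frac = (t[cut_idx] - t[i_lo]) / (t[i_hi] - t[i_lo])
    for tr in range(out.n_trials):
        for ch in range(out.n_channels):
            seg = out.data[tr, ch, ref_idx]
            sd = float(np.std(signal.detrend(seg)))
            line = out.data[tr, ch, i_lo] + frac * (
                out.data[tr, ch, i_hi] - out.data[tr, ch, i_lo]
            )
            out.data[tr, ch, cut_idx] = line + rng.normal(0.0, sd, size=cut_idx.size)
    return out


def reference_filter_resample(
    epochs: EpochSet,
    highpass: float = 0.5,
    order: int = 2,
    target_fs: float = 250.0,
    alpha_band_hi: float = 13.0,
    zero_phase: bool = True,
) -> EpochSet:
    """Common-average reference, high-pass, anti-aliased downsampling.

    The high-pass is a Butterworth of the given order applied forward-
    backward by default (zero phase; switchable to causal).  Integer
    decimation factors use a single-stage order-8 zero-phase IIR
    anti-alias filter; non-integer ratios fall back to polyphase
    resampling.
    """
    fs = epochs.sampling_rate
    if target_fs >= fs:
        raise ValueError("target_fs must be below the current sampling rate")
    if target_fs <= 2 * alpha_band_hi:
        raise ValueError(
            f"target_fs {target_fs} Hz violates Nyquist for the {alpha_band_hi} Hz "
            "band edge"
        )
    out = epochs.copy()
    out.data = out.data - out.data.mean(axis=1, keepdims=True)  # CAR
    sos = signal.butter(order, highpass, btype="highpass", fs=fs, output="sos")
    if zero_phase:
        out.data = signal.sosfiltfilt(sos, out.data, axis=-1)
    else:
        out.data = signal.sosfilt(sos, out.data, axis=-1)
    ratio = fs / target_fs
    if abs(ratio - round(ratio)) < 1e-9:
        q = int(round(ratio))
        if q > 1:
            out.data = signal.decimate(out.data, q, n=8, ftype="iir", zero_phase=True, axis=-1)
            out.times = out.times[::q]
    else:
        frac = math.gcd(int(round(target_fs * 1000)), int(round(fs * 1000)))
        up = int(round(target_fs * 1000)) // frac
        down = int(round(fs * 1000)) // frac
        out.data = signal.resample_poly(out.data, up, down, axis=-1)
        n_new = out.data.shape[-1]
        out.times = epochs.times[0] + np.arange(n_new) / target_fs
    out.sampling_rate = float(target_fs)
    return out


def reject_trials(epochs: EpochSet, abs_amp_bound: float = 100.0) -> EpochSet:
    """Drop trials containing any sample with ``|x| > abs_amp_bound``.

    An automated, reproducible replacement for by-eye rejection of
    muscle/movement/electrical artifacts.  Raises if nothing survives.
    """
    if abs_amp_bound <= 0:
        raise ValueError("abs_amp_bound must be positive")
    peak = np.abs(epochs.data).max(axis=(1, 2))
    keep = peak <= abs_amp_bound
    if not keep.any():
        raise ValueError(
            f"all {epochs.n_trials} trials exceed |x| <= {abs_amp_bound}; "
            "review the bound"
        )
    out = epochs.copy()
    for pos, ok in enumerate(keep):
        if not ok:
            out.rejection_log[epochs.kept_trial_ids[pos]] = (
                f"amplitude {peak[pos]:.1f} exceeds bound {abs_amp_bound:.1f}"
            )
    out.data = epochs.data[keep]
    out.kept_trial_ids = [
        tid for tid, ok in zip(epochs.kept_trial_ids, keep) if ok
    ]
    return out


def preprocess_session(
    recording: Recording,
    events,
    abs_amp_bound: float = 100.0,
    target_fs: float = 250.0,
    rng: np.random.Generator | None = None,
) -> EpochSet:
    """The full fixed-order chain: epoch, interpolate, reference/filter/resample, reject."""
    epochs = epoch_recording(recording, events)
    epochs = interpolate_artifact(epochs, rng=rng)
    epochs = reference_filter_resample(epochs, target_fs=target_fs)
    return reject_trials(epochs, abs_amp_bound)
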