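"""Emulation of the real-time alpha-burst detector that triggered TMS.

The online system analysed one occipital channel in non-overlapping
250 ms windows with an FFT and fired the stimulator whenever 8-13 Hz
band power exceeded a per-subject threshold, enforcing a 5 s minimum
inter-stimulus interval.  This module reproduces that algorithm
offline: rectangular windows, no taper, no overlap, power summed over
the DFT bins that fall inside the band (inclusive band edges).

The threshold is calibrated as a quantile of window band powers over a
rest recording; an optional exponential-horizon running quantile lets
the threshold track slow drifts of the ongoing alpha level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import ALPHA_BAND, Recording


@dataclass
class TriggerConfig:
    """Configuration of the online alpha-burst detector."""

    window_len: float = 0.25
    band: tuple[float, float] = ALPHA_BAND
    threshold: float | None = None
    min_isi: float = 5.0
    channel: str | int = "POz"
    adapt: bool = False
    adapt_quantile: float = 0.9
    adapt_horizon: int = 240  # windows; e-folding scale of the running quantile

    def __post_init__(self) -> None:
        if self.band[0] >= self.band[1]:
            raise ValueError("band must be (low, high) with low < high")
        if self.min_isi < self.window_len:
            raise ValueError("min_isi must be at least one window length")

    def window_samples(self, sampling_rate: float) -> int:
        n_f = self.window_len * sampling_rate
        n = int(round(n_f))
        if abs(n_f - n) > 1e-9:
            raise ValueError(
                f"window_len {self.window_len} s is not an integer number of "
                f"samples at {sampling_rate} Hz"
            )
        return n


@dataclass
class TriggerEvent:
    """One detector firing: time of the end of the detecting window."""

    time: float
    window_power: float
    threshold_at_time: float

    def __post_init__(self) -> None:
        if self.window_power < self.threshold_at_time:
            raise ValueError("event power below its threshold")


def window_band_power(
    window: np.ndarray, sampling_rate: float, band: tuple[float, float] = ALPHA_BAND
) -> float:
    """Band power of one analysis window.

    The window is mean-removed (no other detrending), transformed with a
    rectangular-window DFT, and the mean-square contributions of the bins
    whose frequency f satisfies ``band[0] <= f <= band[1]`` are summed.
    For an on-bin sinusoid of amplitude a inside the band the result is
    a**2 / 2.
    """
    x = np.asarray(window, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("window must be 1-D with at least 2 samples")
    nyq = sampling_rate / 2.0
    if not (0 <= band[0] < band[1] <= nyq):
        raise ValueError(
            f"band {band} outside valid range (0, {nyq}) Hz at "
            f"{sampling_rate} Hz sampling"
        )
    n = x.size
    spec = np.fft.rfft(x - x.mean())
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    # one-sided mean-square weights: DC and (even-n) Nyquist bins appear once
    w = np.full(freqs.size, 2.0)
    w[0] = 1.0
    if n % 2 == 0:
        w[-1] = 1.0
    power = w * np.abs(spec) ** 2 / n**2
    mask = (freqs >= band[0]) & (freqs <= band[1])
    return float(power[mask].sum())


def window_powers(
    recording: Recording, cfg: TriggerConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Band power of every complete non-overlapping window.

    Returns (window end times in s, band powers).  The window grid starts
    at sample 0; a trailing partial window is ignored.
    """
    ch = recording.channel_index(cfg.channel)
    n_win_samp = cfg.window_samples(recording.sampling_rate)
    n_windows = recording.n_samples // n_win_samp
    x = recording.data[ch, : n_windows * n_win_samp].reshape(n_windows, n_win_samp)
    # vectorised equivalent of window_band_power applied per row
    spec = np.fft.rfft(x - x.mean(axis=1, keepdims=True), axis=1)
    freqs = np.fft.rfftfreq(n_win_samp, d=1.0 / recording.sampling_rate)
    if not (0 <= cfg.band[0] < cfg.band[1] <= recording.sampling_rate / 2):
        raise ValueError(f"band {cfg.band} outside Nyquist range")
    w = np.full(freqs.size, 2.0)
    w[0] = 1.0
    if n_win_samp % 2 == 0:
        w[-1] = 1.0
    mask = (freqs >= cfg.band[0]) & (freqs <= cfg.band[1])
    powers = (w[mask] * np.abs(spec[:, mask]) ** 2).sum(axis=1) / n_win_samp**2
    ends = (np.arange(1, n_windows + 1) * n_win_samp) / recording.sampling_rate
    return ends, powers


def calibrate_threshold(
    rest_recording: Recording, cfg: TriggerConfig, quantile: float = 0.9
) -> float:
    """Detection threshold as a quantile of rest window band powers.

    The study quantified the first threshold on a rest recording without
    TMS; the procedure itself was not described, so a quantile of
    non-overlapping window band powers (default 0.90) is used as the
    simplest reproducible rule.
    """
    if not 0 <= quantile <= 1:
        raise ValueError("quantile must be in [0, 1]")
    _, powers = window_powers(rest_recording, cfg)
    if powers.size < 10:
        raise ValueError(
            f"rest recording gives only {powers.size} windows; at least 10 needed"
        )
    return float(np.quantile(powers, quantile))


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    cw /= cw[-1]
    return float(np.interp(q, cw, v))


def detect_triggers(recording: Recording, cfg: TriggerConfig) -> list[TriggerEvent]:
    """Run the window scan and return the trigger events.

    Events fire at the end of each non-overlapping window whose band
    power exceeds the threshold, suppressing events within ``min_isi``
    of the previous one.  The scan is causal: the decision at time t
    uses only samples up to t.  With ``adapt`` enabled the threshold is
    the ``adapt_quantile`` of exponentially down-weighted recent window
    powers (e-folding horizon ``adapt_horizon`` windows), seeded from
    the calibrated value.
    """
    if cfg.threshold is None:
        raise ValueError("cfg.threshold is not set; calibrate first")
    ends, powers = window_powers(recording, cfg)
    events: list[TriggerEvent] = []
    threshold = float(cfg.threshold)
    history: list[float] = []
    last_time = -np.inf
    for t, p in zip(ends, powers):
        if cfg.adapt:
            history.append(float(p))
            if len(history) > 8 * cfg.adapt_horizon:
                history = history[-8 * cfg.adapt_horizon :]
            if len(history) >= 10:
                vals = np.asarray(history)
                ages = np.arange(vals.size - 1, -1, -1, dtype=float)
                weights = np.exp(-ages / cfg.adapt_horizon)
                threshold = _weighted_quantile(vals, weights, cfg.adapt_quantile)
        if p > threshold and t - last_time >= cfg.min_isi:
            events.append(TriggerEvent(float(t), float(p), threshold))
            last_time = t
    return events
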