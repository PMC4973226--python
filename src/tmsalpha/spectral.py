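"""Alpha-band Hilbert envelope and ERS/ERD normalisation.

"Alpha power" here is the magnitude of the analytic signal of the
alpha-band-filtered trace (the absolute value of the Hilbert transform,
not its square; a squared-envelope switch exists).  ERS/ERD is the
percent change of the trial-averaged power relative to the time-mean
over the pre-stimulus baseline window; the basic rest-state level is
the time-mean (and SD) over the rest window further from the pulse.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .containers import ALPHA_BAND, PRE_TMS_BASELINE, REST_WINDOW, PowerTimecourse


def alpha_envelope(
    trials: np.ndarray,
    times: np.ndarray,
    sampling_rate: float,
    band: tuple[float, float] = ALPHA_BAND,
    order: int = 4,
    squared: bool = False,
    subject: str = "",
    condition: str = "",
) -> list[PowerTimecourse]:
    """Per-trial alpha envelope of scout traces (trials x time).

    Zero-phase Butterworth band-pass, then analytic-signal magnitude.
    Each trace is mirror-padded by one filter length per side before
    filtering and the pads are trimmed afterwards, so the reported
    samples are free of edge transients.
    """
    x = np.atleast_2d(np.asarray(trials, dtype=float))
    if sampling_rate <= 2 * band[1]:
        raise ValueError("sampling rate must exceed twice the band upper edge")
    pad = int(round(sampling_rate / band[0] * order))  # one filter length
    if x.shape[1] < 3 * pad:
        raise ValueError(
            f"epoch of {x.shape[1]} samples shorter than 3 filter lengths ({3 * pad})"
        )
    sos = signal.butter(order, band, btype="bandpass", fs=sampling_rate, output="sos")
    xp = np.pad(x, ((0, 0), (pad, pad)), mode="reflect")
    filt = signal.sosfiltfilt(sos, xp, axis=-1)
    env = np.abs(signal.hilbert(filt, axis=-1))[:, pad:-pad]
    if squared:
        env = env**2
    return [
        PowerTimecourse(env[i], times, subject=subject, condition=condition)
        for i in range(env.shape[0])
    ]


def average_power(per_trial: list[PowerTimecourse]) -> PowerTimecourse:
    """Pointwise mean across trials (common time axis required)."""
    if not per_trial:
        raise ValueError("need at least one trial")
    first = per_trial[0]
    for p in per_trial[1:]:
        if p.times.shape != first.times.shape or not np.allclose(p.times, first.times):
            raise ValueError("trials have mismatched time axes")
        if p.units_flag != first.units_flag:
            raise ValueError("trials have mismatched units")
    values = np.mean([p.values for p in per_trial], axis=0)
    return PowerTimecourse(
        values,
        first.times.copy(),
        subject=first.subject,
        condition=first.condition,
        baseline_window=first.baseline_window,
        rest_window=first.rest_window,
        units_flag=first.units_flag,
    )


def ers_erd(
    power: PowerTimecourse,
    baseline_window: tuple[float, float] = PRE_TMS_BASELINE,
) -> PowerTimecourse:
    """Percent ERS/ERD: 100 * (P(t) - Pb) / Pb, Pb = baseline time-mean."""
    if power.units_flag != "raw":
        raise ValueError("ers_erd expects a raw power trace")
    mask = power.window_mask(baseline_window)
    pb = float(power.values[mask].mean())
    if pb <= 0:
        raise ValueError(f"baseline mean {pb} is not positive")
    return PowerTimecourse(
        100.0 * (power.values - pb) / pb,
        power.times.copy(),
        subject=power.subject,
        condition=power.condition,
        baseline_window=baseline_window,
        rest_window=power.rest_window,
        units_flag="percent",
    )


def rest_state_level(
    power: PowerTimecourse, rest_window: tuple[float, float] = REST_WINDOW
) -> tuple[float, float]:
    """Time-mean and time-SD of the trace over the rest window."""
    mask = power.window_mask(rest_window)
    seg = power.values[mask]
    return float(seg.mean()), float(seg.std())


def baseline_power(
    power: PowerTimecourse, baseline_window: tuple[float, float] = PRE_TMS_BASELINE
) -> float:
    """Time-mean raw power over the pre-stimulus baseline window."""
    mask = power.window_mask(baseline_window)
    return float(power.values[mask].mean())
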