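"""Core in-memory containers shared across the pipeline.

The pipeline passes three kinds of objects between stages: a continuous
multichannel :class:`Recording`, a trial-segmented :class:`EpochSet`
(trials x channels x time, t = 0 at the stimulation pulse), and a
:class:`PowerTimecourse` holding an alpha-envelope trace either in raw
envelope units or as percent ERS/ERD relative to a baseline window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: pre-stimulus baseline used for ERS/ERD normalisation (s)
PRE_TMS_BASELINE = (-0.4, -0.1)
#: window taken as the basic resting alpha level (s)
REST_WINDOW = (-1.9, -0.5)
#: alpha band (Hz)
ALPHA_BAND = (8.0, 13.0)


@dataclass
class Recording:
    """Continuous multichannel signal.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolt-scale units.
    sampling_rate : float
        Sampling rate in Hz.
    channel_names : list of str
        One label per row of ``data``.
    events : ndarray of float
        Stimulation event times in seconds (may be empty).
    meta : dict
        Free-form provenance (detection threshold, seeds, ...).
    """

    data: np.ndarray
    sampling_rate: float
    channel_names: list[str]
    events: np.ndarray = field(default_factory=lambda: np.empty(0))
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        self.events = np.atleast_1d(np.asarray(self.events, dtype=float))

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel_index(self, channel: str | int) -> int:
        if isinstance(channel, (int, np.integer)):
            if not 0 <= channel < self.n_channels:
                raise ValueError(f"channel index {channel} out of range")
            return int(channel)
        try:
            return self.channel_names.index(channel)
        except ValueError:
            raise ValueError(
                f"channel {channel!r} not in {self.channel_names}"
            ) from None


@dataclass
class EpochSet:
    """Stimulation-locked trials.

    ``data`` is trials x channels x time; ``times`` is the common epoch
    time axis in seconds with t = 0 at the pulse.  ``kept_trial_ids``
    tracks original trial indices across rejection; ``rejection_log``
    maps a dropped trial id to the reason it was dropped.
    """

    data: np.ndarray
    times: np.ndarray
    sampling_rate: float
    channel_names: list[str]
    kept_trial_ids: list[int] = field(default_factory=list)
    rejection_log: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (trials x channels x time)")
        if self.data.shape[2] != self.times.size:
            raise ValueError("time axis length does not match data")
        if not self.kept_trial_ids:
            self.kept_trial_ids = list(range(self.data.shape[0]))

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def time_mask(self, window: tuple[float, float]) -> np.ndarray:
        lo, hi = window
        return (self.times >= lo) & (self.times <= hi)

    def copy(self) -> "EpochSet":
        return EpochSet(
            self.data.copy(),
            self.times.copy(),
            self.sampling_rate,
            list(self.channel_names),
            list(self.kept_trial_ids),
            dict(self.rejection_log),
        )


@dataclass
class PowerTimecourse:
    """Alpha power (envelope) trace for one subject and condition.

    ``units_flag`` is ``"raw"`` for envelope magnitude and ``"percent"``
    for ERS/ERD relative to ``baseline_window``.
    """

    values: np.ndarray
    times: np.ndarray
    subject: str = ""
    condition: str = ""
    baseline_window: tuple[float, float] = PRE_TMS_BASELINE
    rest_window: tuple[float, float] = REST_WINDOW
    units_flag: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.shape != self.times.shape:
            raise ValueError("values and times must have the same shape")
        if self.units_flag not in ("raw", "percent"):
            raise ValueError("units_flag must be 'raw' or 'percent'")
        if self.units_flag == "raw" and np.any(self.values < -1e-12):
            raise ValueError("raw envelope values must be non-negative")

    def window_mask(self, window: tuple[float, float]) -> np.ndarray:
        lo, hi = window
        mask = (self.times >= lo) & (self.times <= hi)
        if not mask.any():
            raise ValueError(f"window {window} outside time axis")
        return mask
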