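"""Closed-loop TMS-EEG session and cohort generator with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* continuous EEG = 1/f background noise + an 8-13 Hz alpha carrier whose
  envelope is a constant base level plus Poisson-arriving Hann-shaped
  bursts with lognormal amplitudes (a stochastic slow modulation with a
  directly controllable burst rate);
* stimulation pulses placed by running the *same* window scan as the
  online detector (non-overlapping 250 ms FFT windows, threshold from a
  rest-segment quantile, 5 s minimum ISI) on the signal as it is built,
  so every pulse sits at the end of a supra-threshold window;
* per pulse, a large biphasic artifact confined to -5..10 ms around the
  pulse, a TEP with N100/P200 deflections that is strictly zero after
  0.5 s, and a multiplicative alpha-envelope modulation: a dip back to
  the rest level (event-related desynchronisation relative to the high
  pre-pulse baseline), then a condition-dependent event-related
  synchronisation bump above rest whose half-height width equals the
  configured ``ers_duration``, then a crossfade back to the background
  envelope.

The stimulator fires one artifact-width (5 ms) after the end of the
detecting window, mimicking trigger-to-pulse latency; this keeps the
detecting window free of artifact so an offline re-run of the detector
reproduces the embedded trigger times exactly.

Cohorts draw per-subject condition parameters around condition means
with a shared subject effect plus a condition-specific residual, and can
also produce trial-averaged scout envelope traces directly from the same
profile model (``CohortDataset.trace``) for Monte-Carlo studies where
synthesising full sessions would be needlessly slow.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import ALPHA_BAND, Recording
from .trigger import TriggerConfig, calibrate_threshold, window_band_power

DEFAULT_CHANNELS = ["Fz", "Cz", "Pz", "P3", "POz", "Oz", "O1", "O2"]
#: relative alpha-envelope strength per default channel (occipital dominant)
DEFAULT_ALPHA_WEIGHTS = [0.15, 0.3, 0.5, 0.5, 1.0, 0.9, 0.8, 0.8]
#: relative TEP strength per default channel (fronto-central dominant)
DEFAULT_TEP_WEIGHTS = [1.0, 0.8, 0.6, 0.6, 0.5, 0.4, 0.4, 0.4]
#: sensor-level occipital scout used when the inverse step is skipped
OCCIPITAL_SCOUT = ["POz", "Oz", "O1", "O2"]


@dataclass(frozen=True)
class TEPTemplate:
    """Parametric biphasic TMS-evoked potential (two Gabor-like deflections)."""

    n100_latency: float = 0.1
    n100_amp: float = -8.0
    n100_width: float = 0.03
    p200_latency: float = 0.2
    p200_amp: float = 6.0
    p200_width: float = 0.045
    support_end: float = 0.5

    def waveform(self, sampling_rate: float) -> np.ndarray:
        """Sampled template on [0, support_end); exactly zero at the end."""
        t = np.arange(0.0, self.support_end, 1.0 / sampling_rate)
        w = self.n100_amp * np.exp(-0.5 * ((t - self.n100_latency) / self.n100_width) ** 2)
        w += self.p200_amp * np.exp(-0.5 * ((t - self.p200_latency) / self.p200_width) ** 2)
        # cosine taper over the last 50 ms enforces hard-zero support end
        taper_start = self.support_end - 0.05
        m = t > taper_start
        w[m] *= 0.5 * (1 + np.cos(np.pi * (t[m] - taper_start) / 0.05))
        return w


@dataclass(frozen=True)
class Condition:
    """Induced-alpha response parameters of one stimulation site."""

    ers_amp_pct: float
    ers_duration: float


#: default condition set: stimulation of a default-mode node (MPFC) induces a
#: higher and longer occipital alpha ERS than stimulation of a dorsal-attention
#: node (SPL); durations are the group means the estimator should recover.
DEFAULT_CONDITIONS = {
    "MPFC": Condition(ers_amp_pct=35.0, ers_duration=1.08),
    "SPL": Condition(ers_amp_pct=20.0, ers_duration=0.8),
}


@dataclass
class SimulationConfig:
    """Full generative parameter set for one closed-loop session.

    Amplitudes are in microvolt-scale units.  ``burst_amp_dist`` gives
    (mu, sigma) of the log of burst envelope amplitudes.  ``ers_amp_pct``
    / ``ers_duration`` act as per-session overrides; normally they are
    supplied by the condition mapping in ``conditions``.
    """

    sampling_rate: float = 1000.0
    n_channels: int = 8
    channel_names: list[str] = field(default_factory=lambda: list(DEFAULT_CHANNELS))
    alpha_freq: float = 10.0
    alpha_band: tuple[float, float] = ALPHA_BAND
    alpha_base: float = 4.0
    burst_rate: float = 40.0  # bursts / min
    burst_amp_dist: tuple[float, float] = (1.25, 0.35)
    burst_len: tuple[float, float] = (0.3, 0.9)
    noise_1f_exponent: float = 1.0
    noise_sd: float = 3.0
    tep_template: TEPTemplate = field(default_factory=TEPTemplate)
    artifact_amp: float = 500.0
    erd_dip_depth: float = 0.8  # envelope dips to this fraction of its pre-pulse value
    erd_reach: float = 0.3
    ers_onset: float = 0.45
    ers_rise: float = 0.1
    # Recovery time of the background burst process after the induced
    # response: the envelope crossfades from the deterministic profile's rest
    # level back to the stochastic background over this many seconds
    # (spontaneous bursting resumes gradually after the perturbation).  It
    # also keeps the late epoch tail quasi-deterministic, so rest-referenced
    # z-scores there reflect the profile, not background burst wander.
    crossfade: float = 1.5
    ers_amp_pct: float | None = None
    ers_duration: float | None = None
    conditions: dict[str, Condition] = field(
        default_factory=lambda: dict(DEFAULT_CONDITIONS)
    )
    n_trials_target: int = 70
    min_isi: float = 5.0
    rest_duration: float = 60.0
    max_session: float = 900.0
    # Generator's threshold quantile.  Deliberately lower than the offline
    # calibration default: with a high threshold the detector waits long after
    # the 5 s lockout, so the pre-pulse rest window is conditioned on
    # sub-threshold power and sits below the unconditioned post-response
    # background, biasing rest-referenced statistics.  At 0.6 the wait is
    # typically well under the 0.5 s gap between rest window and pulse, so the
    # rest window lies inside the refractory period and stays unbiased.
    detect_quantile: float = 0.6
    trigger_channel: str = "POz"
    pulse_latency: float = 0.005  # trigger-to-pulse latency, = artifact pre-width
    outlier_rate: float = 0.05  # fraction of trials with a muscle-like burst
    outlier_amp: float = 400.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ers_duration is not None and self.ers_duration <= 0:
            raise ValueError("ers_duration must be positive")
        if self.ers_onset < 0:
            raise ValueError("ers_onset must be non-negative")
        lo, hi = self.alpha_band
        if not lo < hi < self.sampling_rate / 2:
            raise ValueError("alpha_band must satisfy lo < hi < Nyquist")
        if len(self.channel_names) != self.n_channels:
            if self.n_channels <= len(DEFAULT_CHANNELS):
                self.channel_names = list(DEFAULT_CHANNELS[: self.n_channels])
            else:
                self.channel_names = [f"EEG{i:02d}" for i in range(self.n_channels)]

    def alpha_weights(self) -> np.ndarray:
        if self.channel_names == DEFAULT_CHANNELS[: self.n_channels]:
            return np.asarray(DEFAULT_ALPHA_WEIGHTS[: self.n_channels])
        w = np.full(self.n_channels, 0.5)
        w[self.channel_names.index(self.trigger_channel)] = 1.0
        return w

    def tep_weights(self) -> np.ndarray:
        if self.channel_names == DEFAULT_CHANNELS[: self.n_channels]:
            return np.asarray(DEFAULT_TEP_WEIGHTS[: self.n_channels])
        return np.full(self.n_channels, 0.6)

    def condition_params(self, condition: str | None) -> Condition:
        if self.ers_amp_pct is not None and self.ers_duration is not None:
            return Condition(self.ers_amp_pct, self.ers_duration)
        if condition is None or condition not in self.conditions:
            raise ValueError(
                f"condition {condition!r} not in {sorted(self.conditions)} and no "
                "explicit ers_amp_pct/ers_duration override given"
            )
        return self.conditions[condition]


@dataclass
class GroundTruth:
    """Generative truth of one session, the recovery target for the analysis."""

    trigger_times: np.ndarray  # detector window-end times (s)
    pulse_times: np.ndarray  # stimulation times = trigger + pulse latency (s)
    true_ers_amp_pct: float
    true_ers_duration: float
    true_rest_envelope: float
    threshold: float
    pre_trigger_envelopes: np.ndarray = field(default_factory=lambda: np.empty(0))
    #: per-trial ambient alpha level the envelope relaxes back to (the mean
    #: background envelope over that trial's rest window)
    rest_anchors: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        t = np.sort(np.asarray(self.trigger_times, dtype=float))
        if t.size > 1 and np.any(np.diff(t) < 5.0 - 1e-9):
            # min ISI is config-dependent; 5 s is the default contract and the
            # generator passes its own value, so only warn-level check here
            pass


# ---------------------------------------------------------------------------
# background signal components


def one_over_f_noise(
    n_samples: int, sampling_rate: float, exponent: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian noise with amplitude spectrum proportional to f**(-exponent/2)."""
    if sd == 0:
        return np.zeros(n_samples)
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shaping, n=n_samples)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def burst_envelope(
    n_samples: int, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Base alpha level plus Poisson-arriving Hann-shaped bursts."""
    fs = config.sampling_rate
    env = np.full(n_samples, config.alpha_base, dtype=float)
    duration = n_samples / fs
    n_bursts = rng.poisson(config.burst_rate / 60.0 * duration)
    mu, sigma = config.burst_amp_dist
    for _ in range(n_bursts):
        t0 = rng.uniform(0, duration)
        length = rng.uniform(*config.burst_len)
        amp = float(rng.lognormal(mu, sigma))
        i0 = int(round(t0 * fs))
        n = max(int(round(length * fs)), 2)
        i1 = min(i0 + n, n_samples)
        tau = np.arange(i1 - i0) / n
        env[i0:i1] += amp * np.sin(np.pi * tau) ** 2
    return env


def _raised_cos(n: int) -> np.ndarray:
    """Monotone 0 -> 1 raised-cosine ramp over n samples."""
    return 0.5 * (1 - np.cos(np.pi * np.arange(n) / max(n, 1)))


def trial_envelope_profile(
    e0: float,
    rest_level: float,
    ers_amp_pct: float,
    ers_duration: float,
    config: SimulationConfig,
    sampling_rate: float | None = None,
) -> np.ndarray:
    """Deterministic post-pulse alpha-envelope profile (absolute units).

    Starting from the pre-pulse value ``e0``: a raised-cosine dip to
    ``min(erd_dip_depth * e0, rest_level)`` — the envelope relaxes back
    to the rest level, undershooting it slightly when the triggering
    burst was weak — reached at ``erd_reach`` s, held until
    ``ers_onset``; a raised-cosine rise (``ers_rise`` s) to the ERS peak
    ``rest_level * (1 + ers_amp_pct/100)``; a plateau of
    ``ers_duration - ers_rise`` s; a raised-cosine fall back to
    ``rest_level``.  The full width of the ERS bump at half its height
    above rest is therefore ``ers_duration`` by construction, which is
    what the downstream duration estimator recovers.  The profile ends
    at the rest level; the caller crossfades back to the background.
    """
    fs = sampling_rate or config.sampling_rate
    dip = min(config.erd_dip_depth * e0, rest_level)
    peak = rest_level * (1.0 + ers_amp_pct / 100.0)
    reach = min(config.erd_reach, config.ers_onset)
    plateau = max(ers_duration - config.ers_rise, 0.0)

    n_reach = int(round(reach * fs))
    n_hold = int(round((config.ers_onset - reach) * fs))
    n_rise = int(round(config.ers_rise * fs))
    n_plateau = int(round(plateau * fs))

    parts = [
        e0 + (dip - e0) * _raised_cos(n_reach),
        np.full(n_hold, dip),
        dip + (peak - dip) * _raised_cos(n_rise),
        np.full(n_plateau, peak),
        peak + (rest_level - peak) * _raised_cos(n_rise),
    ]
    return np.concatenate(parts)


def _artifact_waveform(config: SimulationConfig) -> np.ndarray:
    """Biphasic stimulation artifact on [-pulse_latency, +2*pulse_latency)."""
    fs = config.sampling_rate
    lat = config.pulse_latency
    t = np.arange(-lat, 2 * lat, 1.0 / fs)
    w = np.sin(2 * np.pi * t / (2 * lat)) * np.exp(-((t / lat) ** 2))
    return config.artifact_amp * w


def simulate_session(
    config: SimulationConfig, condition: str | None = None
) -> tuple[Recording, GroundTruth]:
    """Generate one closed-loop stimulation session.

    Returns the continuous recording (pulse times in ``Recording.events``
    and detector metadata in ``Recording.meta``) and the ground truth.
    Raises ``RuntimeError`` if fewer than ``n_trials_target`` pulses at
    least 2 s from the session start fit inside ``max_session`` seconds.
    """
    cond = config.condition_params(condition)
    fs = config.sampling_rate
    ss = np.random.SeedSequence((int(config.seed) & 0x7FFFFFFF, 1))
    rest_rng, sess_rng = [np.random.default_rng(s) for s in ss.spawn(2)]

    rest = _simulate_rest_with_rng(config, rest_rng)
    rest_ref = rest.meta["rest_envelope_mean"]
    tcfg = TriggerConfig(
        channel=config.trigger_channel, min_isi=config.min_isi, band=config.alpha_band
    )
    threshold = calibrate_threshold(rest, tcfg, config.detect_quantile)

    n_win = tcfg.window_samples(fs)
    est_len = config.n_trials_target * (config.min_isi + 3.0) + 20.0
    n_total = int(round(min(est_len, config.max_session) * fs))
    n_max = int(round(config.max_session * fs))

    phase = sess_rng.uniform(0, 2 * np.pi)
    env = burst_envelope(n_total, config, sess_rng)
    noise = np.stack(
        [
            one_over_f_noise(n_total, fs, config.noise_1f_exponent, config.noise_sd, sess_rng)
            for _ in range(config.n_channels)
        ]
    )
    resp = np.zeros((config.n_channels, n_total))

    w_alpha = config.alpha_weights()
    w_tep = config.tep_weights()
    i_trig = config.channel_names.index(config.trigger_channel)
    artifact = _artifact_waveform(config)
    n_art_pre = int(round(config.pulse_latency * fs))
    tep = config.tep_template.waveform(fs)

    def extend(n_new_total: int) -> None:
        nonlocal env, noise, resp, n_total
        n_add = n_new_total - n_total
        if n_add <= 0:
            return
        env = np.concatenate([env, burst_envelope(n_add, config, sess_rng)])
        noise = np.concatenate(
            [
                noise,
                np.stack(
                    [
                        one_over_f_noise(
                            n_add, fs, config.noise_1f_exponent, config.noise_sd, sess_rng
                        )
                        for _ in range(config.n_channels)
                    ]
                ),
            ],
            axis=1,
        )
        resp = np.concatenate([resp, np.zeros((config.n_channels, n_add))], axis=1)
        n_total = n_new_total

    def trig_window(i0: int) -> np.ndarray:
        t_seg = (np.arange(i0, i0 + n_win)) / fs
        alpha_seg = env[i0 : i0 + n_win] * np.cos(
            2 * np.pi * config.alpha_freq * t_seg + phase
        )
        return w_alpha[i_trig] * alpha_seg + noise[i_trig, i0 : i0 + n_win] + resp[
            i_trig, i0 : i0 + n_win
        ]

    trigger_times: list[float] = []
    pre_envs: list[float] = []
    anchors: list[float] = []
    n_usable = 0
    last_trig = -np.inf
    i0 = 0
    while n_usable < config.n_trials_target:
        if i0 + n_win > n_total:
            if n_total >= n_max:
                raise RuntimeError(
                    f"burst_rate {config.burst_rate}/min too low: only "
                    f"{n_usable} of {config.n_trials_target} usable pulses "
                    f"within max_session={config.max_session} s"
                )
            extend(min(n_total + int(60 * fs), n_max))
        t_end = (i0 + n_win) / fs
        p = window_band_power(trig_window(i0), fs, config.alpha_band)
        if p > threshold and t_end - last_trig >= config.min_isi:
            last_trig = t_end
            trigger_times.append(t_end)
            t_pulse = t_end + config.pulse_latency
            i_pulse = int(round(t_pulse * fs))
            e0 = float(env[min(i_pulse, n_total - 1)])
            pre_envs.append(e0)
            # the trial relaxes back to its own recent ambient alpha level:
            # the envelope mean over this trial's rest window (-1.9..-0.5 s)
            a0_ = max(i_pulse - int(1.9 * fs), 0)
            a1_ = max(i_pulse - int(0.5 * fs), a0_ + 1)
            anchor = float(env[a0_:a1_].mean())
            anchors.append(anchor)
            profile = trial_envelope_profile(
                e0, anchor, cond.ers_amp_pct, cond.ers_duration, config
            )
            n_fade = int(round(config.crossfade * fs))
            need = i_pulse + profile.size + n_fade + int(4.5 * fs)
            if need > n_total:
                extend(min(max(need, n_total + int(60 * fs)), n_max))
            env[i_pulse : i_pulse + profile.size] = profile
            u = _raised_cos(n_fade)
            j0 = i_pulse + profile.size
            env[j0 : j0 + n_fade] = (1 - u) * anchor + u * env[j0 : j0 + n_fade]
            # additive response: artifact (-5..10 ms) + TEP (0..0.5 s)
            a0 = i_pulse - n_art_pre
            resp[:, a0 : a0 + artifact.size] += np.outer(
                np.ones(config.n_channels), artifact
            )
            resp[:, i_pulse : i_pulse + tep.size] += np.outer(w_tep, tep)
            if sess_rng.uniform() < config.outlier_rate:
                # muscle-like high-amplitude burst somewhere in the epoch
                dt = sess_rng.uniform(0.6, 3.5)
                m0 = i_pulse + int(round(dt * fs))
                n_m = int(0.05 * fs)
                ch = sess_rng.integers(config.n_channels)
                resp[ch, m0 : m0 + n_m] += config.outlier_amp * np.sin(
                    np.pi * np.arange(n_m) / n_m
                )
            if t_pulse >= 2.0:
                n_usable += 1
        i0 += n_win

    n_keep = min(int(round((last_trig + 4.5) * fs)), n_total)
    t_axis = np.arange(n_keep) / fs
    alpha = env[:n_keep] * np.cos(2 * np.pi * config.alpha_freq * t_axis + phase)
    data = w_alpha[:, None] * alpha[None, :] + noise[:, :n_keep] + resp[:, :n_keep]
    pulse_times = np.asarray(trigger_times) + config.pulse_latency
    rec = Recording(
        data,
        fs,
        list(config.channel_names),
        events=pulse_times,
        meta={
            "threshold": threshold,
            "rest_envelope_mean": rest_ref,
            "condition": condition,
            "seed": int(config.seed),
            "detect_quantile": config.detect_quantile,
            "trigger_channel": config.trigger_channel,
        },
    )
    truth = GroundTruth(
        trigger_times=np.asarray(trigger_times),
        pulse_times=pulse_times,
        true_ers_amp_pct=cond.ers_amp_pct,
        true_ers_duration=cond.ers_duration,
        true_rest_envelope=float(np.mean(anchors)) if anchors else rest_ref,
        threshold=threshold,
        pre_trigger_envelopes=np.asarray(pre_envs),
        rest_anchors=np.asarray(anchors),
    )
    return rec, truth


def _simulate_rest_with_rng(
    config: SimulationConfig, rng: np.random.Generator
) -> Recording:
    fs = config.sampling_rate
    n = int(round(config.rest_duration * fs))
    t = np.arange(n) / fs
    env = burst_envelope(n, config, rng)
    carrier = np.cos(2 * np.pi * config.alpha_freq * t + rng.uniform(0, 2 * np.pi))
    w = config.alpha_weights()
    data = w[:, None] * (env * carrier)[None, :]
    for ch in range(config.n_channels):
        data[ch] += one_over_f_noise(n, fs, config.noise_1f_exponent, config.noise_sd, rng)
    rec = Recording(data, fs, list(config.channel_names))
    rec.meta["rest_envelope_mean"] = float(env.mean())
    return rec


def simulate_rest(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> Recording:
    """Rest recording (no TMS), drawn from the session's calibration stream."""
    if rng is None:
        ss = np.random.SeedSequence((int(config.seed) & 0x7FFFFFFF, 1))
        rng = np.random.default_rng(ss.spawn(2)[0])
    return _simulate_rest_with_rng(config, rng)


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class CohortDataset:
    """Per-subject generative parameters for a two-condition cohort.

    ``params`` has one row per subject x condition with the drawn ERS
    amplitude/duration and a derived session seed.  ``session`` builds
    the full closed-loop recording for one cell; ``trace`` builds the
    trial-averaged occipital envelope trace directly from the same
    profile model (fast path for Monte-Carlo replication studies).
    """

    params: pd.DataFrame
    config: SimulationConfig
    seed: int
    n_redraws: int = 0
    trace_fs: float = 250.0
    trace_span: tuple[float, float] = (-2.0, 4.0)
    # relative SD of the smoothed trace noise, calibrated to the rest-window
    # variability the full session generator produces in trial-averaged scout
    # envelopes (~4.5% of the rest level at the default 70 trials)
    trace_noise_frac: float = 0.045
    baseline_elev: float = 0.35
    baseline_tau: float = 0.3

    def _row(self, subject: int, condition: str) -> pd.Series:
        m = (self.params.subject == subject) & (self.params.condition == condition)
        if not m.any():
            raise KeyError(f"no cell (subject={subject}, condition={condition})")
        return self.params[m].iloc[0]

    def session(self, subject: int, condition: str) -> tuple[Recording, GroundTruth]:
        row = self._row(subject, condition)
        cfg = replace(
            self.config,
            ers_amp_pct=float(row.ers_amp_pct),
            ers_duration=float(row.ers_duration),
            seed=int(row.seed),
        )
        return simulate_session(cfg, condition)

    def trace(self, subject: int, condition: str):
        """Trial-averaged occipital alpha envelope trace for one cell.

        Pre-pulse: rest level with an exponentially rising elevation
        toward t=0 (alpha-triggered pulses condition the baseline on a
        burst).  Post-pulse: the trial envelope profile with the drawn
        parameters.  Smoothed Gaussian noise emulates the residual trial
        -averaging variability of the envelope.
        """
        from .containers import PowerTimecourse

        row = self._row(subject, condition)
        rng = np.random.default_rng(
            np.random.SeedSequence(
                (self.seed & 0x7FFFFFFF, 2, int(subject), hash(condition) & 0xFFFF)
            )
        )
        fs = self.trace_fs
        times = np.arange(
            self.trace_span[0], self.trace_span[1] + 0.5 / fs, 1.0 / fs
        )
        level = float(np.exp(rng.normal(np.log(5.0), 0.2)))
        values = np.full(times.size, level)
        pre = times < 0
        values[pre] = level * (
            1.0 + self.baseline_elev * np.exp(times[pre] / self.baseline_tau)
        )
        e0 = level * (1.0 + self.baseline_elev)
        profile = trial_envelope_profile(
            e0,
            level,
            float(row.ers_amp_pct),
            float(row.ers_duration),
            self.config,
            sampling_rate=fs,
        )
        i0 = int(np.searchsorted(times, 0.0))
        n_prof = min(profile.size, times.size - i0)
        values[i0 : i0 + n_prof] = profile[:n_prof]
        # smoothed residual noise with ~100 ms correlation
        from scipy.ndimage import gaussian_filter1d

        white = rng.standard_normal(times.size)
        smooth = gaussian_filter1d(white, sigma=0.1 * fs, mode="reflect")
        s = smooth.std()
        if s > 0:
            values = values + smooth * (self.trace_noise_frac * level / s)
        values = np.clip(values, 0.0, None)
        return PowerTimecourse(
            values, times, subject=f"S{subject:02d}", condition=condition
        )


def simulate_cohort(
    config: SimulationConfig,
    n_subjects: int = 10,
    between_subject_sd: float = 0.48,
    seed: int | None = None,
    within_subject_sd: float = 0.19,
    amp_between_sd: float = 0.25,
    amp_within_sd: float = 0.10,
) -> CohortDataset:
    """Draw per-subject condition parameters around the condition means.

    Durations follow ``mean_c + shared_subject_effect + residual`` with
    the shared effect SD ``between_subject_sd`` and the residual SD
    ``within_subject_sd``, both expressed as fractions of the grand mean
    duration.  The shared effect makes the two conditions correlated
    within a subject, as required for the marginal spreads and the
    paired comparison to be simultaneously realistic.  Non-positive
    draws are redrawn (truncation) and counted in ``n_redraws``.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be at least 2")
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(np.random.SeedSequence((int(seed) & 0x7FFFFFFF, 3)))
    conds = sorted(config.conditions)
    grand_dur = float(np.mean([config.conditions[c].ers_duration for c in conds]))
    grand_amp = float(np.mean([config.conditions[c].ers_amp_pct for c in conds]))
    rows = []
    n_redraws = 0
    for s in range(n_subjects):
        # rejection-sample the whole subject: a deeply negative shared effect
        # can make positive draws unreachable, so it is redrawn too
        for _ in range(1000):
            shared_d = rng.normal(0.0, between_subject_sd * grand_dur)
            shared_a = rng.normal(0.0, amp_between_sd * grand_amp)
            durs = {
                c: config.conditions[c].ers_duration
                + shared_d
                + rng.normal(0.0, within_subject_sd * grand_dur)
                for c in conds
            }
            amps = {
                c: config.conditions[c].ers_amp_pct
                + shared_a
                + rng.normal(0.0, amp_within_sd * grand_amp)
                for c in conds
            }
            if all(d > 0.15 for d in durs.values()) and all(
                a > 5.0 for a in amps.values()
            ):
                break
            n_redraws += 1
        else:
            raise RuntimeError("could not draw positive subject parameters")
        for c in conds:
            dur, amp = durs[c], amps[c]
            rows.append(
                {
                    "subject": s,
                    "condition": c,
                    "ers_amp_pct": amp,
                    "ers_duration": dur,
                    "seed": int(
                        np.random.SeedSequence(
                            (int(seed) & 0x7FFFFFFF, 4, s, conds.index(c))
                        ).generate_state(1)[0]
                        & 0x7FFFFFFF
                    ),
                }
            )
    params = pd.DataFrame(rows)
    return CohortDataset(params=params, config=config, seed=int(seed), n_redraws=n_redraws)


# ---------------------------------------------------------------------------
# gain fixture


def make_gain_fixture(
    n_channels: int = 32,
    n_sources: int = 200,
    seed: int | None = None,
    identity: bool = False,
) -> np.ndarray:
    """Random full-row-rank gain matrix with heterogeneous column norms.

    A stand-in lead field for exercising the depth-weighted minimum-norm
    inverse; column norms are spread over roughly two orders of
    magnitude so depth weighting is non-trivial.  ``identity=True``
    returns the identity (requires ``n_channels == n_sources``).
    """
    if n_channels < 2:
        raise ValueError("n_channels must be at least 2")
    if identity:
        if n_channels != n_sources:
            raise ValueError("identity gain requires n_channels == n_sources")
        return np.eye(n_channels)
    rng = np.random.default_rng(seed)
    for attempt in range(10):
        g = rng.standard_normal((n_channels, n_sources))
        scales = np.exp(rng.normal(0.0, 0.8, size=n_sources))
        g = g * scales[None, :]
        if np.linalg.matrix_rank(g) == n_channels:
            return g
        g += 1e-6 * rng.standard_normal(g.shape)  # perturb and retry
    raise RuntimeError("could not draw a full-row-rank gain matrix")
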