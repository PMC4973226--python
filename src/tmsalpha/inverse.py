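"""Whitened, depth-weighted L2 minimum-norm inverse on a given gain matrix.

Orientation-constrained sources (one scalar time course each).  The
kernel is

    K = R G' (G R G' + lambda2 C)^(-1),    R = diag(||g_i||^(-2 gamma))

computed after whitening by C^(-1/2), with gamma the depth-weighting
order (0.5 by default) and lambda2 the ridge regularisation, set by a
signal-to-noise heuristic when not given.  The anatomical forward model
is out of scope; the gain matrix is a provided fixture, and the whole
pipeline can equally run at the sensor level by averaging a channel
scout instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import EpochSet


@dataclass
class Scout:
    """An index set of sources (or channels) averaged into one trace."""

    source_indices: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        idx = np.asarray(self.source_indices, dtype=int)
        if idx.size == 0:
            raise ValueError("scout must contain at least one index")
        if len(np.unique(idx)) != idx.size:
            raise ValueError("scout indices must be unique")
        if np.any(idx < 0):
            raise ValueError("scout indices must be non-negative")
        self.source_indices = idx


@dataclass
class InverseOperator:
    gain: np.ndarray
    noise_cov: np.ndarray
    depth_order: float
    lambda2: float
    kernel: np.ndarray = field(repr=False, default=None)


def _check_spd(c: np.ndarray) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("noise covariance must be square")
    if not np.allclose(c, c.T, rtol=1e-10, atol=1e-12):
        raise ValueError("noise covariance must be symmetric")
    try:
        np.linalg.cholesky(c)
    except np.linalg.LinAlgError:
        raise ValueError("noise covariance must be positive definite") from None
    return c


def build_inverse_operator(
    gain: np.ndarray,
    noise_cov: np.ndarray,
    depth_order: float = 0.5,
    lambda2: float | None = None,
    snr: float = 3.0,
) -> InverseOperator:
    """Assemble the minimum-norm kernel.

    When ``lambda2`` is None it is set to ``scale / snr**2`` with
    ``scale`` the channel-average diagonal of the whitened, depth-
    weighted model covariance — the usual 1/SNR^2 heuristic on a
    trace-normalised problem.
    """
    g = np.asarray(gain, dtype=float)
    c = _check_spd(noise_cov)
    if g.shape[0] != c.shape[0]:
        raise ValueError("gain and noise covariance channel counts differ")
    if lambda2 is not None and lambda2 < 0:
        raise ValueError("lambda2 must be non-negative")

    # whiten: W = C^(-1/2) via eigendecomposition
    evals, evecs = np.linalg.eigh(c)
    whitener = evecs @ np.diag(evals**-0.5) @ evecs.T
    gw = whitener @ g

    col_norms = np.linalg.norm(g, axis=0)
    if np.any(col_norms == 0):
        raise ValueError("gain matrix has a zero column")
    r = col_norms ** (-2.0 * depth_order)  # diagonal of the source prior R

    grg = (gw * r[None, :]) @ gw.T
    if lambda2 is None:
        lambda2 = float(np.trace(grg) / grg.shape[0] / snr**2)
    kernel = (r[:, None] * gw.T) @ np.linalg.solve(
        grg + lambda2 * np.eye(grg.shape[0]), whitener
    )
    return InverseOperator(g, c, depth_order, float(lambda2), kernel)


def apply_inverse(inv: InverseOperator, epochs: EpochSet) -> EpochSet:
    """Project sensor epochs to source time courses (linear, per trial)."""
    if epochs.n_channels != inv.kernel.shape[1]:
        raise ValueError(
            f"epochs have {epochs.n_channels} channels; kernel expects "
            f"{inv.kernel.shape[1]}"
        )
    src = np.einsum("sc,tcj->tsj", inv.kernel, epochs.data)
    return EpochSet(
        src,
        epochs.times.copy(),
        epochs.sampling_rate,
        [f"src{i}" for i in range(src.shape[1])],
        list(epochs.kept_trial_ids),
        dict(epochs.rejection_log),
    )


def scout_timecourse(src: EpochSet, scout: Scout) -> np.ndarray:
    """Unweighted mean across scout sources: trials x time."""
    if np.any(scout.source_indices >= src.n_channels):
        raise ValueError("scout index out of range")
    return src.data[:, scout.source_indices, :].mean(axis=1)


def sensor_scout_timecourse(epochs: EpochSet, channels: list[str]) -> np.ndarray:
    """Sensor-level scout: average the named channels (trials x time)."""
    idx = [epochs.channel_names.index(c) for c in channels]
    return epochs.data[:, idx, :].mean(axis=1)
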