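"""Inferential statistics: Mann-Whitney U, temporal cluster-based
permutation test, induced-alpha duration, and paired duration comparison.

All four procedures are implemented here rather than delegated: the
Mann-Whitney p-value is exact by enumeration for small samples (tie-
corrected normal approximation otherwise); the cluster test forms
maximal contiguous runs of same-sign supra-threshold paired-t values,
scores each by its signed t-mass, and calibrates against the max
|mass| distribution under sign flips of the paired differences (full
enumeration whenever 2^n does not exceed the permutation budget,
Monte-Carlo with the (b+1)/(m+1) estimator otherwise); the induced-
alpha duration is the longest contiguous run for which the rest-state
z-scored power exceeds the two-sided 5% normal critical value 1.96.
SciPy supplies only distribution lookups (t and normal CDFs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb, erf, sqrt

import numpy as np
from scipy import stats as sps

from .containers import REST_WINDOW, PowerTimecourse

Z_CRIT_5PCT = 1.96  # two-sided 5% standard-normal critical value


# ---------------------------------------------------------------------------
# Mann-Whitney U


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for sample x: #{(i,j): x_i > y_j} + 0.5 #{x_i == y_j}."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mann_whitney_u(x, y, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    ``mode='exact'`` enumerates all C(n+m, n) labelings of the pooled
    values (feasible and the default for n+m <= 12) and returns
    min(1, 2 * min(P(U <= u), P(U >= u))).  ``mode='approx'`` uses the
    tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = x.size, y.size
    u_obs = _u_statistic(x, y)
    if mode == "auto":
        mode = "exact" if n + m <= 12 else "approx"
    if mode == "exact":
        pooled = np.concatenate([x, y])
        total = comb(n + m, n)
        n_le = n_ge = 0
        idx_all = range(n + m)
        for c in combinations(idx_all, n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(c)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            if u <= u_obs + 1e-12:
                n_le += 1
            if u >= u_obs - 1e-12:
                n_ge += 1
        p = min(1.0, 2.0 * min(n_le, n_ge) / total)
        return u_obs, p
    if mode != "approx":
        raise ValueError("mode must be 'exact', 'approx' or 'auto'")
    pooled = np.concatenate([x, y])
    nn = n + m
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum())) / (nn * (nn - 1))
    mu = n * m / 2.0
    var = n * m / 12.0 * ((nn + 1) - tie_term)
    if var <= 0:
        return u_obs, 1.0
    z = (abs(u_obs - mu) - 0.5) / sqrt(var)
    z = max(z, 0.0)
    p = 2.0 * (1.0 - 0.5 * (1.0 + erf(z / sqrt(2.0))))
    return u_obs, min(1.0, p)


# ---------------------------------------------------------------------------
# temporal cluster-based permutation test


@dataclass
class Cluster:
    start: int  # first sample index of the run
    stop: int  # last sample index (inclusive)
    mass: float  # signed sum of t over the run
    p: float = np.nan
    time_extent: tuple[float, float] | None = None


@dataclass
class ClusterTestResult:
    t_trace: np.ndarray
    clusters: list[Cluster]
    n_permutations: int
    alpha: float
    first_level_threshold: float
    full_enumeration: bool = False
    times: np.ndarray | None = None

    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p < self.alpha]


#: stand-in for an infinite paired t (zero-variance, non-zero-mean differences)
_T_DEGENERATE = 1e6


def _finite_t(mean: np.ndarray, sd: np.ndarray, n: int) -> np.ndarray:
    """Paired t with zero-variance columns mapped to +/- a large sentinel."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / sqrt(n))
    return np.where(np.isfinite(t), t, np.sign(mean) * _T_DEGENERATE)


def _runs(code: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of constant non-zero value in a 1-D +1/0/-1 code."""
    runs = []
    start = None
    for i, v in enumerate(code):
        if v != 0 and (start is None or code[start] != v):
            if start is not None and code[start] != 0:
                runs.append((start, i - 1))
            start = i
        elif v == 0 and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(code) - 1))
    return runs


def _clusters_from_t(t: np.ndarray, thresh: float) -> list[Cluster]:
    code = np.where(t > thresh, 1, np.where(t < -thresh, -1, 0))
    out = []
    for a, b in _runs(code):
        out.append(Cluster(a, b, float(t[a : b + 1].sum())))
    return out


def _max_cluster_mass(tmat: np.ndarray, thresh: float) -> np.ndarray:
    """Max |signed cluster mass| per row of a permutations x time t array.

    Vectorised: rows are flattened with a zero separator so runs never
    span rows; run boundaries come from changes of the +1/0/-1 supra-
    threshold code, and masses from a cumulative sum of thresholded t.
    """
    n_perm, n_t = tmat.shape
    code = np.where(tmat > thresh, 1, np.where(tmat < -thresh, -1, 0))
    codef = np.concatenate([code, np.zeros((n_perm, 1), dtype=code.dtype)], axis=1).ravel()
    # per-row cumulative sums with a leading zero column: run masses are
    # differences within one row, so rounding stays at row scale
    tf2 = np.concatenate(
        [np.zeros((n_perm, 1)), np.where(code != 0, tmat, 0.0), np.zeros((n_perm, 1))],
        axis=1,
    )
    cs = np.cumsum(tf2, axis=1).ravel()
    prev = np.concatenate([[0], codef[:-1]])
    starts = np.flatnonzero((codef != 0) & (codef != prev))
    nxt = np.concatenate([codef[1:], [0]])
    stops = np.flatnonzero((codef != 0) & (codef != nxt))  # inclusive
    rows = starts // (n_t + 1)
    cols_start = starts % (n_t + 1)
    cols_stop = stops % (n_t + 1)
    masses = cs[rows * (n_t + 2) + cols_stop + 1] - cs[rows * (n_t + 2) + cols_start]
    out = np.zeros(n_perm)
    np.maximum.at(out, rows, np.abs(masses))
    return out


def cluster_permutation_test(
    a: np.ndarray,
    b: np.ndarray,
    n_perm: int = 10000,
    alpha: float = 0.05,
    seed: int | None = None,
    first_level_alpha: float = 0.05,
    times: np.ndarray | None = None,
) -> ClusterTestResult:
    """Paired-t temporal cluster permutation test between conditions a and b.

    ``a`` and ``b`` are subjects x time arrays with matched rows.  The
    first-level statistic is the paired t per time point, thresholded
    two-sided at ``first_level_alpha``; clusters are maximal contiguous
    runs of same-sign supra-threshold t, scored by their signed t-sum
    ("mass").  The null distribution of the maximum |mass| is built by
    flipping the sign of each subject's difference trace: exhaustively
    over all 2^n patterns when 2^n <= n_perm (deterministic), otherwise
    by ``n_perm`` random flips with the (b+1)/(m+1) p estimator.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("a and b must have the same shape")
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    diff = a - b
    t_thresh = float(sps.t.ppf(1.0 - first_level_alpha / 2.0, df=n - 1))

    full = 2**n <= n_perm
    if full:
        # k = 0 is the identity pattern (all +1)
        signs = np.array(
            [[1 if (k >> i) & 1 == 0 else -1 for i in range(n)] for k in range(2**n)],
            dtype=float,
        )
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))

    # t under sign flips: the sum of squares per time point is flip-invariant
    ssq = (diff**2).sum(axis=0)
    mean_p = signs @ diff / n
    var_p = np.clip((ssq - n * mean_p**2) / (n - 1), 0.0, None)
    t_null = _finite_t(mean_p, np.sqrt(var_p), n)
    null_max = _max_cluster_mass(t_null, t_thresh)

    if full:
        # the observed t is the identity row of the same computation, so the
        # enumerated p can never fall below 1/2^n
        t_obs = t_null[0]
    else:
        mean_o = np.ones(n) @ diff / n
        var_o = np.clip((ssq - n * mean_o**2) / (n - 1), 0.0, None)
        t_obs = _finite_t(mean_o, np.sqrt(var_o), n)
    clusters = _clusters_from_t(t_obs, t_thresh)

    n_eff = signs.shape[0]
    for c in clusters:
        # relative tolerance absorbs the rounding difference between the
        # cumulative-sum path and the direct cluster sum
        tol = 1e-9 * max(abs(c.mass), 1.0)
        exceed = int((null_max >= abs(c.mass) - tol).sum())
        c.p = exceed / n_eff if full else (exceed + 1) / (n_eff + 1)
        if times is not None:
            c.time_extent = (float(times[c.start]), float(times[c.stop]))
    return ClusterTestResult(
        t_obs, clusters, n_eff, alpha, t_thresh, full_enumeration=full, times=times
    )


# ---------------------------------------------------------------------------
# induced-alpha duration


@dataclass
class DurationEstimate:
    z_trace: np.ndarray
    threshold: float
    duration: float
    supra_runs: list[tuple[float, float]]
    rest_mean: float
    rest_sd: float
    times: np.ndarray = field(default_factory=lambda: np.empty(0))


def induced_duration(
    power: PowerTimecourse,
    rest_window: tuple[float, float] = REST_WINDOW,
    threshold: float = Z_CRIT_5PCT,
    search_window: tuple[float, float] = (0.0, 4.0),
    rule: str = "longest",
) -> DurationEstimate:
    """Duration of the induced alpha response.

    The trace is z-scored against the mean and SD of its rest window,
    and the time for which z exceeds ``threshold`` (the two-sided 5%
    normal critical value by default) inside ``search_window`` is the
    induced-alpha duration.  Multiple supra-threshold runs are resolved
    by the longest run (``rule='longest'``, default) or by their total
    length (``rule='total'``).  Run length counts its samples times the
    sample period.
    """
    mask = power.window_mask(rest_window)
    rest_mean = float(power.values[mask].mean())
    rest_sd = float(power.values[mask].std())
    if rest_sd == 0:
        raise ValueError("rest-window SD is zero: degenerate baseline")
    z = (power.values - rest_mean) / rest_sd
    dt = float(np.median(np.diff(power.times)))
    in_search = (power.times > search_window[0]) & (power.times <= search_window[1])
    supra = (z > threshold) & in_search
    runs: list[tuple[float, float]] = []
    lengths: list[float] = []
    idx = np.flatnonzero(supra)
    if idx.size:
        splits = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate([[0], splits + 1])
        stops = np.concatenate([splits, [idx.size - 1]])
        for s, e in zip(starts, stops):
            i0, i1 = idx[s], idx[e]
            runs.append((float(power.times[i0]), float(power.times[i1])))
            lengths.append((i1 - i0 + 1) * dt)
    if not lengths:
        duration = 0.0
    elif rule == "longest":
        duration = max(lengths)
    elif rule == "total":
        duration = float(sum(lengths))
    else:
        raise ValueError("rule must be 'longest' or 'total'")
    return DurationEstimate(
        z, threshold, duration, runs, rest_mean, rest_sd, times=power.times.copy()
    )


def ar1_noise(
    n_rows: int, n_times: int, phi: float, rng: np.random.Generator
) -> np.ndarray:
    """Stationary AR(1) Gaussian noise (unit innovation SD) per row."""
    x = np.empty((n_rows, n_times))
    x[:, 0] = rng.standard_normal(n_rows) / sqrt(1.0 - phi**2)
    innov = rng.standard_normal((n_rows, n_times - 1))
    for t in range(1, n_times):
        x[:, t] = phi * x[:, t - 1] + innov[:, t - 1]
    return x


def cluster_test_fwer(
    n_datasets: int = 1000,
    n_subjects: int = 10,
    n_times: int = 150,
    phi: float = 0.8,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical familywise error rate of the cluster permutation test.

    Simulates datasets of two conditions with identical generative
    parameters (autocorrelated AR(1) Gaussian noise per subject and
    condition), runs the test on each, and returns the fraction of
    datasets yielding at least one significant cluster.  Under a valid
    procedure this fraction stays at or below ``alpha`` up to
    Monte-Carlo error.
    """
    rng = np.random.default_rng(np.random.SeedSequence((int(seed) & 0x7FFFFFFF, 77)))
    n_false = 0
    for _ in range(n_datasets):
        a = ar1_noise(n_subjects, n_times, phi, rng)
        b = ar1_noise(n_subjects, n_times, phi, rng)
        res = cluster_permutation_test(
            a, b, n_perm=n_perm, alpha=alpha, seed=int(rng.integers(2**31))
        )
        n_false += bool(res.significant())
    return n_false / n_datasets


def compare_durations(d_a, d_b) -> tuple[float, float]:
    """Paired t-test on per-subject induced-alpha durations.

    Returns the t statistic and two-sided p from the t distribution
    with n-1 degrees of freedom.
    """
    d_a = np.asarray(d_a, dtype=float)
    d_b = np.asarray(d_b, dtype=float)
    if d_a.shape != d_b.shape or d_a.size < 2:
        raise ValueError("need two equal-length samples of size >= 2")
    d = d_a - d_b
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return 0.0, 1.0  # identical samples: no evidence either way
        raise ValueError("zero variance of paired differences")
    n = d.size
    t = d.mean() / (sd / sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), df=n - 1))
    return float(t), min(1.0, p)
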