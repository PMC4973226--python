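"""End-to-end orchestration on synthetic cohorts.

``run_pipeline`` composes the stages in the study's order — simulate a
two-condition cohort, re-detect the triggers with the online emulator,
preprocess, extract the occipital scout alpha envelope, normalise
against the two baselines, and run the inferential layer — and returns
a ReportBundle whose tables mirror the study's Results structure:
per-subject pre-TMS baseline power, rest-state percent level and
induced-alpha durations, plus the group Mann-Whitney on baselines, the
three cluster comparisons (condition vs condition, each condition vs
its rest-state level) and the paired t on durations.

All randomness flows from one master seed through named substreams, so
a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import PRE_TMS_BASELINE, REST_WINDOW, PowerTimecourse, Recording
from .preprocess import preprocess_session
from .inverse import sensor_scout_timecourse
from .simulate import (
    OCCIPITAL_SCOUT,
    GroundTruth,
    SimulationConfig,
    simulate_cohort,
)
from .spectral import alpha_envelope, average_power, baseline_power, ers_erd, rest_state_level
from .stats import (
    ClusterTestResult,
    cluster_permutation_test,
    compare_durations,
    induced_duration,
    mann_whitney_u,
)
from .trigger import TriggerConfig, detect_triggers


def default_config(seed: int = 0) -> dict:
    """Declarative demo configuration (10 subjects, 2 conditions)."""
    return {
        "seed": int(seed),
        "simulation": {"seed": int(seed)},
        "cohort": {
            "n_subjects": 10,
            "between_subject_sd": 0.48,
            "within_subject_sd": 0.19,
        },
        "analysis": {
            "scout": list(OCCIPITAL_SCOUT),
            "target_fs": 250.0,
            "abs_amp_bound": 100.0,
            "n_perm": 10000,
            "alpha": 0.05,
            "search_window": [0.0, 4.0],
        },
    }


def config_hash(config: dict) -> str:
    """Stable hash over the analysis-relevant configuration."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class SubjectAnalysis:
    subject: str
    condition: str
    n_trials_kept: int
    baseline_power: float
    rest_pct_mean: float
    rest_pct_sd: float
    duration: float
    raw_trace: PowerTimecourse
    percent_trace: PowerTimecourse


@dataclass
class ReportBundle:
    subject_table: pd.DataFrame
    group_table: pd.DataFrame
    cluster_results: dict[str, ClusterTestResult]
    traces: dict[tuple[str, str], PowerTimecourse]
    provenance: dict = field(default_factory=dict)

    def to_dir(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.subject_table.to_csv(out / "subjects.tsv", sep="\t", index=False)
        self.group_table.to_csv(out / "group.tsv", sep="\t", index=False)
        clusters = {
            name: [
                {
                    "start_s": c.time_extent[0] if c.time_extent else c.start,
                    "end_s": c.time_extent[1] if c.time_extent else c.stop,
                    "mass": c.mass,
                    "p": c.p,
                }
                for c in res.clusters
            ]
            for name, res in self.cluster_results.items()
        }
        (out / "clusters.json").write_text(json.dumps(clusters, indent=2))
        rows = []
        for (subj, cond), trace in self.traces.items():
            for t, v in zip(trace.times, trace.values):
                rows.append(
                    {"subject": subj, "condition": cond, "time_s": t, "percent": v}
                )
        pd.DataFrame(rows).to_csv(out / "traces.tsv", sep="\t", index=False)
        (out / "provenance.json").write_text(
            json.dumps(self.provenance, indent=2, default=str)
        )


def analyze_session(
    recording: Recording,
    analysis: dict,
    subject: str,
    condition: str,
    rng: np.random.Generator,
) -> SubjectAnalysis:
    """One session through trigger re-detection, preprocessing and spectra."""
    tcfg = TriggerConfig(
        channel=recording.meta.get("trigger_channel", "POz"),
        threshold=recording.meta["threshold"],
    )
    events = detect_triggers(recording, tcfg)
    latency = recording.meta.get("pulse_latency", 0.005)
    pulse_times = np.asarray([e.time for e in events]) + latency
    epochs = preprocess_session(
        recording,
        pulse_times,
        abs_amp_bound=analysis.get("abs_amp_bound", 100.0),
        target_fs=analysis.get("target_fs", 250.0),
        rng=rng,
    )
    scout = sensor_scout_timecourse(epochs, analysis.get("scout", OCCIPITAL_SCOUT))
    per_trial = alpha_envelope(
        scout, epochs.times, epochs.sampling_rate, subject=subject, condition=condition
    )
    raw = average_power(per_trial)
    pct = ers_erd(raw, PRE_TMS_BASELINE)
    rest_pct_mean, rest_pct_sd = rest_state_level(pct, REST_WINDOW)
    est = induced_duration(
        raw,
        REST_WINDOW,
        search_window=tuple(analysis.get("search_window", (0.0, 4.0))),
    )
    return SubjectAnalysis(
        subject=subject,
        condition=condition,
        n_trials_kept=epochs.n_trials,
        baseline_power=baseline_power(raw, PRE_TMS_BASELINE),
        rest_pct_mean=rest_pct_mean,
        rest_pct_sd=rest_pct_sd,
        duration=est.duration,
        raw_trace=raw,
        percent_trace=pct,
    )


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> ReportBundle:
    """Run the full synthetic-cohort analysis described by a config."""
    if not isinstance(config, dict):
        from .io import load_config

        config = load_config(config)
    cfg = {**default_config(), **config}
    analysis = {**default_config()["analysis"], **cfg.get("analysis", {})}
    seed = int(cfg.get("seed", 0))
    sim_cfg = SimulationConfig(**cfg.get("simulation", {"seed": seed}))
    cohort_cfg = {**default_config()["cohort"], **cfg.get("cohort", {})}

    cohort = simulate_cohort(
        sim_cfg,
        n_subjects=int(cohort_cfg["n_subjects"]),
        between_subject_sd=float(cohort_cfg["between_subject_sd"]),
        within_subject_sd=float(cohort_cfg["within_subject_sd"]),
        seed=seed,
    )
    conditions = sorted(sim_cfg.conditions)
    results: list[SubjectAnalysis] = []
    for s in range(int(cohort_cfg["n_subjects"])):
        for ci, cond in enumerate(conditions):
            rec, _truth = cohort.session(s, cond)
            rng = np.random.default_rng(
                np.random.SeedSequence((seed & 0x7FFFFFFF, 5, s, ci))
            )
            results.append(analyze_session(rec, analysis, f"S{s:02d}", cond, rng))

    subject_table = pd.DataFrame(
        [
            {
                "subject": r.subject,
                "condition": r.condition,
                "n_trials_kept": r.n_trials_kept,
                "baseline_power": r.baseline_power,
                "rest_pct_mean": r.rest_pct_mean,
                "rest_pct_sd": r.rest_pct_sd,
                "duration_s": r.duration,
            }
            for r in results
        ]
    )

    # group level -----------------------------------------------------------
    cond_a, cond_b = conditions[0], conditions[1]
    by_cond = {
        c: [r for r in results if r.condition == c] for c in conditions
    }
    baselines = {c: np.array([r.baseline_power for r in by_cond[c]]) for c in conditions}
    u, p_mw = mann_whitney_u(baselines[cond_a], baselines[cond_b])

    times = results[0].percent_trace.times
    post = times > 0
    n_perm = int(analysis["n_perm"])
    alpha = float(analysis["alpha"])
    pct = {
        c: np.vstack([r.percent_trace.values[post] for r in by_cond[c]])
        for c in conditions
    }
    rest_const = {
        c: np.vstack(
            [np.full(post.sum(), r.rest_pct_mean) for r in by_cond[c]]
        )
        for c in conditions
    }
    cluster_results = {
        f"{cond_a}_vs_{cond_b}": cluster_permutation_test(
            pct[cond_a], pct[cond_b], n_perm=n_perm, alpha=alpha,
            seed=seed * 7 + 1 & 0x7FFFFFFF, times=times[post],
        ),
        f"{cond_a}_vs_rest": cluster_permutation_test(
            pct[cond_a], rest_const[cond_a], n_perm=n_perm, alpha=alpha,
            seed=seed * 7 + 2 & 0x7FFFFFFF, times=times[post],
        ),
        f"{cond_b}_vs_rest": cluster_permutation_test(
            pct[cond_b], rest_const[cond_b], n_perm=n_perm, alpha=alpha,
            seed=seed * 7 + 3 & 0x7FFFFFFF, times=times[post],
        ),
    }
    durations = {c: np.array([r.duration for r in by_cond[c]]) for c in conditions}
    t_dur, p_dur = compare_durations(durations[cond_a], durations[cond_b])

    group_rows = [
        {
            "comparison": f"baseline {cond_a} vs {cond_b} (Mann-Whitney U)",
            "statistic": u,
            "p": p_mw,
            "detail": json.dumps(
                {c: float(baselines[c].mean()) for c in conditions}
            ),
        },
        {
            "comparison": f"duration {cond_a} vs {cond_b} (paired t)",
            "statistic": t_dur,
            "p": p_dur,
            "detail": json.dumps(
                {c: float(durations[c].mean()) for c in conditions}
            ),
        },
    ]
    for name, res in cluster_results.items():
        sig = res.significant()
        best = min(res.clusters, key=lambda c: c.p, default=None)
        group_rows.append(
            {
                "comparison": f"cluster {name}",
                "statistic": best.mass if best else np.nan,
                "p": best.p if best else np.nan,
                "detail": json.dumps(
                    [
                        {"window_s": list(c.time_extent), "p": c.p}
                        for c in sig
                    ]
                ),
            }
        )
    group_table = pd.DataFrame(group_rows)

    bundle = ReportBundle(
        subject_table=subject_table,
        group_table=group_table,
        cluster_results=cluster_results,
        traces={(r.subject, r.condition): r.percent_trace for r in results},
        provenance={
            "config_hash": config_hash(
                {"simulation": cfg.get("simulation", {}), "cohort": cohort_cfg,
                 "analysis": analysis, "seed": seed}
            ),
            "seed": seed,
            "version": __version__,
            "n_redraws": cohort.n_redraws,
            "trial_retention": {
                c: f"{np.mean([r.n_trials_kept for r in by_cond[c]]):.1f} +/- "
                f"{np.std([r.n_trials_kept for r in by_cond[c]]):.1f}"
                for c in conditions
            },
        },
    )
    if out_dir is not None:
        bundle.to_dir(out_dir)
    return bundle


def plot_grand_average(bundle: ReportBundle, path: str | Path) -> None:
    """Grand-average ERS/ERD traces with annotated significant windows."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    conditions = sorted({c for _, c in bundle.traces})
    fig, ax = plt.subplots(figsize=(8, 4))
    for cond in conditions:
        traces = [v for (s, c), v in bundle.traces.items() if c == cond]
        grand = np.mean([t.values for t in traces], axis=0)
        ax.plot(traces[0].times, grand, label=cond)
    y0 = ax.get_ylim()[0]
    offset = 0
    for name, res in bundle.cluster_results.items():
        for c in res.significant():
            if c.time_extent:
                ax.plot(c.time_extent, [y0 + offset] * 2, lw=3)
                ax.annotate(
                    f"{name} p={c.p:.3g}",
                    (c.time_extent[0], y0 + offset),
                    fontsize=6,
                )
                offset += 2
    ax.axvline(0.0, color="k", ls=":")
    ax.set_xlabel("time relative to pulse (s)")
    ax.set_ylabel("alpha power (% ERS/ERD vs pre-TMS baseline)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
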