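"""End-to-end orchestration: simulate -> preprocess -> source -> statistics.

A :class:`RunConfig` pins every analysis parameter (filter edges, epoch
window, shell geometry, regularization, statistical window and alphas) to
the study defaults; cohort size and permutation count default to a
desk-scale run that completes in minutes on one CPU.  ``run_pipeline``
executes all stages deterministically from a single seed and returns a
JSON-serializable report; identical config and seed give an identical
report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .cluster_stats import (
    MixedDesign,
    extract_cluster_mean,
    grid_adjacency,
    merge_clusters,
    paired_ttest,
    permutation_cluster_test,
    polynomial_contrast,
    spatial_adjacency,
)
from .preprocessing import preprocess_recording
from .psychometrics import behavioural_stats, bpi_table, median_split
from .source_model import (
    activity_magnitude,
    apply_inverse,
    build_source_shell,
    forward_leadfield,
    make_sensor_layout,
    mne_inverse_operator,
)
from .synthetic import (
    CATEGORIES,
    TASKS,
    Cohort,
    default_effect_spec,
    make_cohort,
    make_stimulus_set,
    make_trial_sequence,
    simulate_cohort_responses,
    simulate_sensor_recording,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of one pipeline run.

    Analysis parameters default to the study values (0.1/48 Hz filters,
    300 Hz working rate, 800 ms epochs with 150 ms baseline, 350 shell
    sites at 87% of the head radius, lambda 0.1 MEG / 0.2 EEG, 50-550 ms
    statistics window, alpha 0.05 at both levels); simulation sizes default
    to a desk-scale cohort.
    """

    seed: int = 0
    # cohort / design
    n_an: int = 8
    n_hc: int = 8
    n_per_category: int = 11
    n_repeats: int = 3
    max_run: int = 3
    isi_center_s: float = 1.25
    isi_jitter_s: float = 0.5
    stim_duration_s: float = 0.8
    lapse: float = 0.0
    bar_reference_bmi: float = 19.61
    # sensors & simulation
    modality: str = "meg"
    n_sensors: int = 64
    head_radius_m: float = 0.09
    acq_rate_hz: float = 600.0
    noise_sd: float = 5e-14
    line_noise_amp: float = 0.0
    effect_amplitude: float = 2e-8
    task_effect: float = 1.0
    picture_effect: float = 1.0
    group_picture_effect: float = 1.0
    # preprocessing
    highpass_hz: float = 0.1
    lowpass_hz: float = 48.0
    bandstop_hz: float | None = 60.0
    working_rate_hz: float = 300.0
    epoch_tmin_s: float = -0.2
    epoch_tmax_s: float = 0.6
    baseline_s: tuple[float, float] = (-0.15, 0.0)
    z_threshold: float = 4.0
    # source model
    n_sites: int = 350
    radius_fraction: float = 0.87
    lambda_meg: float = 0.1
    lambda_eeg: float = 0.2
    # statistics
    window_ms: tuple[float, float] = (50.0, 550.0)
    point_alpha: float = 0.05
    cluster_alpha: float = 0.05
    n_perm: int = 200
    gg_threshold: float = 0.75
    effects: tuple[str, ...] = ("task", "picture", "picture*group")

    @property
    def lam(self) -> float:
        return self.lambda_meg if self.modality == "meg" else self.lambda_eeg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["baseline_s"] = list(d["baseline_s"])
        d["window_ms"] = list(d["window_ms"])
        d["effects"] = list(d["effects"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        for key in ("baseline_s", "window_ms", "effects"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def paper_preset(cls, **overrides) -> "RunConfig":
        """Full-scale preset: study cohort sizes and 1000 permutations."""
        base = dict(n_an=29, n_hc=30, n_perm=1000)
        base.update(overrides)
        return cls(**base)


def validate_config(config: RunConfig) -> list[str]:
    """Check every config invariant; returns the list of violations."""
    v: list[str] = []
    if config.n_an < 2 or config.n_hc < 2:
        v.append("n_an and n_hc must both be >= 2")
    if config.n_per_category < 1:
        v.append("n_per_category must be >= 1")
    if config.n_repeats < 1:
        v.append("n_repeats must be >= 1")
    if config.max_run < 1:
        v.append("max_run must be >= 1")
    if not 0.0 <= config.lapse < 0.5:
        v.append("lapse must lie in [0, 0.5)")
    if config.bar_reference_bmi <= 0:
        v.append("bar_reference_bmi must be positive")
    if config.modality not in ("meg", "eeg"):
        v.append("modality must be 'meg' or 'eeg'")
    if config.highpass_hz >= config.lowpass_hz:
        v.append("highpass_hz must lie below lowpass_hz")
    if config.lowpass_hz >= config.working_rate_hz / 2:
        v.append("lowpass_hz must lie below the working Nyquist rate")
    if config.working_rate_hz > config.acq_rate_hz:
        v.append("working_rate_hz must not exceed acq_rate_hz")
    if config.epoch_tmin_s >= config.epoch_tmax_s:
        v.append("epoch_tmin_s must precede epoch_tmax_s")
    if not (config.epoch_tmin_s <= config.baseline_s[0] < config.baseline_s[1] <= config.epoch_tmax_s):
        v.append("baseline_s must lie inside the epoch window")
    if config.n_sites < 4:
        v.append("n_sites must be >= 4")
    if not 0.0 < config.radius_fraction < 1.0:
        v.append("radius_fraction must lie in (0, 1)")
    if config.lambda_meg < 0 or config.lambda_eeg < 0:
        v.append("lambda must be >= 0")
    if not (1000 * config.epoch_tmin_s <= config.window_ms[0] < config.window_ms[1] <= 1000 * config.epoch_tmax_s):
        v.append("window_ms must lie inside the epoch window")
    for name in ("point_alpha", "cluster_alpha"):
        a = getattr(config, name)
        if not 0.0 < a < 1.0:
            v.append(f"{name} must lie in (0, 1)")
    if config.n_perm < 100:
        v.append("n_perm must be >= 100")
    if config.isi_center_s - config.isi_jitter_s <= 0:
        v.append("isi jitter exceeds the isi center")
    return v


def _behavioural_stage(config: RunConfig, cohort: Cohort, seed: int) -> dict:
    stimulus_set = make_stimulus_set(config.n_per_category, seed=seed)
    responses = simulate_cohort_responses(
        cohort, stimulus_set, n_repeats=config.n_repeats,
        max_run=config.max_run, seed=seed + 1,
    )
    actual = {s.subject_id: s.actual_bmi for s in cohort.subjects}
    bpi = bpi_table(responses, actual, bar_reference=config.bar_reference_bmi)
    stats = behavioural_stats(bpi)
    an_body = bpi[(bpi["group"] == "AN") & (bpi["kind"] == "body")].dropna(subset=["bpi"])
    split = median_split(an_body[["subject_id", "bpi"]]) if len(an_body) >= 2 else None
    return {
        "responses": responses,
        "bpi": bpi,
        "stats": stats,
        "median_split": split,
    }


def build_geometry(config: RunConfig):
    """Source shell, sensor layout, leadfield and inverse operator."""
    n_orient = 2 if config.modality == "meg" else 3
    shell = build_source_shell(config.head_radius_m, config.n_sites,
                               config.radius_fraction, n_orient=n_orient)
    layout = make_sensor_layout(config.n_sensors, config.modality, config.head_radius_m)
    leadfield = forward_leadfield(shell, layout)
    inverse = mne_inverse_operator(leadfield, config.lam)
    return shell, layout, leadfield, inverse


def simulate_recordings(config: RunConfig, cohort: Cohort, leadfield, seed: int) -> dict:
    """Continuous sensor recordings per subject, keyed by subject id."""
    effects = default_effect_spec(
        config.n_sites,
        amplitude=config.effect_amplitude,
        task_effect=config.task_effect,
        picture_effect=config.picture_effect,
        group_picture_effect=config.group_picture_effect,
        seed=seed,
    )
    stimulus_set = make_stimulus_set(config.n_per_category, seed=seed)
    subject_seeds = np.random.SeedSequence(seed).spawn(len(cohort))
    recordings = {}
    for subject, sseed in zip(cohort.subjects, subject_seeds):
        rngs = [np.random.default_rng(s) for s in sseed.spawn(len(TASKS) + 1)]
        sequences = {
            task: make_trial_sequence(
                stimulus_set, n_repeats=config.n_repeats, max_run=config.max_run,
                isi_center_s=config.isi_center_s, isi_jitter_s=config.isi_jitter_s,
                stim_duration_s=config.stim_duration_s, seed=rng,
            )
            for task, rng in zip(TASKS, rngs)
        }
        recordings[subject.subject_id] = simulate_sensor_recording(
            subject, leadfield, sequences, effects,
            noise_sd=config.noise_sd, sample_rate_hz=config.acq_rate_hz,
            line_noise_amp=config.line_noise_amp, seed=rngs[-1],
        )
    return recordings


def preprocess_all(config: RunConfig, recordings: dict) -> dict:
    """Filter/resample/epoch/baseline/screen/average each recording."""
    return {
        sid: preprocess_recording(
            rec,
            highpass_hz=config.highpass_hz, lowpass_hz=config.lowpass_hz,
            bandstop_hz=config.bandstop_hz, target_hz=config.working_rate_hz,
            tmin=config.epoch_tmin_s, tmax=config.epoch_tmax_s,
            baseline=config.baseline_s, z_threshold=config.z_threshold,
        )
        for sid, rec in recordings.items()
    }


def source_activity_matrix(config: RunConfig, evoked_sets: dict, inverse):
    """Assemble (n_subjects, n_cells, n_sites, n_times) activity in nAm.

    Cells are ordered task x picture (task slowest); the time axis is the
    statistics window.  Subject order follows the dict order of
    ``evoked_sets``.
    """
    cell_keys = [(t, c) for t in TASKS for c in CATEGORIES]
    maps, times_out = [], None
    for sid, evoked in evoked_sets.items():
        times_ms = evoked.times * 1000.0
        win = (times_ms >= config.window_ms[0]) & (times_ms <= config.window_ms[1])
        times_out = times_ms[win]
        cell_lookup = {
            (row["task"], row["category"]): i for i, row in evoked.cells.iterrows()
        }
        per_cell = []
        for key in cell_keys:
            if key not in cell_lookup:
                raise ValueError(f"subject {sid}: missing condition cell {key}")
            sensor = evoked.data[cell_lookup[key]][:, win]
            moments = apply_inverse(inverse, sensor)
            per_cell.append(activity_magnitude(moments) * 1e9)  # nAm
        maps.append(np.stack(per_cell))
        logger.info("sourced subject %s", sid)
    return np.stack(maps), times_out


def _simulate_and_source(config: RunConfig, cohort: Cohort, seed: int):
    """Per-subject sensor simulation, preprocessing and source estimation."""
    shell, _layout, leadfield, inverse = build_geometry(config)
    recordings = simulate_recordings(config, cohort, leadfield, seed)
    evoked_sets = preprocess_all(config, recordings)
    x, times_ms = source_activity_matrix(config, evoked_sets, inverse)
    design = MixedDesign(
        within={"task": TASKS, "picture": CATEGORIES},
        groups=np.array([s.group for s in cohort.subjects]),
    )
    return x, design, times_ms, shell


def _cluster_stage(config: RunConfig, x, design, times_ms, shell, seed: int) -> dict:
    adjacency = grid_adjacency(
        x.shape[2], x.shape[3], spatial_adjacency(shell.positions)
    )
    out: dict = {"clusters": [], "contrasts": {}, "posthoc": {}}
    rng = np.random.default_rng(seed)
    for effect in config.effects:
        test = permutation_cluster_test(
            x, design, effect, adjacency,
            n_perm=config.n_perm, point_alpha=config.point_alpha,
            seed=int(rng.integers(2**31)), gg_threshold=config.gg_threshold,
        )
        sig = merge_clusters(test.significant(config.cluster_alpha), adjacency)
        for c in sig:
            lo, hi = c.time_extent_ms(times_ms)
            out["clusters"].append(
                {
                    "effect": effect,
                    "mass": c.mass,
                    "p": c.p,
                    "n_sites": int(len(c.sites)),
                    "n_points": int(len(c.members)),
                    "time_ms": [lo, hi],
                }
            )
        if not sig:
            continue
        top = sig[0]
        means = extract_cluster_mean(x, top)  # (N, n_cells)
        cells = design.cells()
        if effect == "task":
            task_means = {
                t: means[:, (cells["task"] == t).to_numpy()].mean(axis=1)
                for t in TASKS
            }
            out["posthoc"]["task"] = {
                "means": {t: float(v.mean()) for t, v in task_means.items()},
                "body_vs_bar": paired_ttest(task_means["body"], task_means["bar"]),
                "bar_vs_viewing": paired_ttest(task_means["bar"], task_means["viewing"]),
                "body_vs_viewing": paired_ttest(task_means["body"], task_means["viewing"]),
            }
        if effect.startswith("picture"):
            pic_means = np.stack(
                [
                    means[:, (cells["picture"] == c_).to_numpy()].mean(axis=1)
                    for c_ in CATEGORIES
                ],
                axis=1,
            )  # (N, 6)
            groups = design.groups if effect.endswith("group") else None
            for degree, name in ((1, "linear"), (2, "quadratic")):
                res = polynomial_contrast(pic_means, degree, groups=groups)
                out["contrasts"].setdefault(effect, {})[name] = {
                    "F": res.F, "df": list(res.df), "p": res.p,
                    "partial_eta_sq": res.partial_eta_sq,
                    "mean_score": res.mean_score,
                }
            if groups is not None:
                w = polynomial_contrast(pic_means, 1).weights
                scores = pic_means @ w
                out["contrasts"][effect]["linear_trend_by_group"] = {
                    g: float(scores[design.groups == g].mean())
                    for g in design.group_levels
                }
    return out


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Execute every stage and assemble the run report.

    The report carries provenance (config hash, seed), the behavioral BPI
    statistics, the cluster table and the planned contrasts.  With
    ``outdir`` set, response/BPI tables (TSV) and the report (JSON) are
    written there.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    t0 = time.time()
    ss = np.random.SeedSequence(config.seed)
    stage_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]
    cohort = make_cohort(config.n_an, config.n_hc, seed=stage_seeds[0], lapse=config.lapse)

    logger.info("stage 1/3: behavior")
    beh = _behavioural_stage(config, cohort, stage_seeds[1])
    logger.info("stage 2/3: simulation + source estimation")
    x, design, times_ms, shell = _simulate_and_source(config, cohort, stage_seeds[2])
    logger.info("stage 3/3: cluster statistics")
    clusters = _cluster_stage(config, x, design, times_ms, shell, stage_seeds[3])

    cfg_dict = config.to_dict()
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True).encode()
    ).hexdigest()[:16]
    split = beh["median_split"]
    report = {
        "provenance": {"config": cfg_dict, "config_hash": cfg_hash, "seed": config.seed},
        "behavioural": {
            "stats": beh["stats"],
            "group_mean_bpi": {
                f"{g}_{k}": float(v)
                for (g, k), v in beh["bpi"].groupby(["group", "kind"])["bpi"].mean().items()
            },
            "median_split": None
            if split is None
            else {
                "median": split.median,
                "n_an1": int((split.labels["label"] == "AN1").sum()),
                "n_an2": int((split.labels["label"] == "AN2").sum()),
            },
        },
        "clusters": clusters["clusters"],
        "contrasts": clusters["contrasts"],
        "posthoc": clusters["posthoc"],
    }
    logger.info("pipeline finished in %.1f s", time.time() - t0)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_responses(beh["responses"], outdir / "responses.tsv")
        io.write_bpi_table(beh["bpi"], outdir / "bpi.tsv")
        io.write_report(report, outdir / "report.json")
    return report
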