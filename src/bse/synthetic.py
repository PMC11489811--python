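"""Synthetic study generator: stimuli, trial sequences, responses, recordings.

Emulates a body-size-estimation (BSE) study design: 66 computer-generated
body pictures spanning six BMI categories (A, severely underweight, through
F, severely overweight), presented three times each in pseudo-random order
(no more than three consecutive pictures from the same category) in three
tasks — passive viewing, a non-self-referential bar-comparison task and a
self-referential body-comparison task.

Behavioral responses are Bernoulli draws from a subject-level Weibull
psychometric function ``P(wider) = lapse/2 + (1-lapse) * (1 - exp(-(a x)^b))``
whose point of subjective equality (PSE) encodes the subject's body
perception: anorexia-nervosa (AN) subjects carry an upward-shifted PSE in
the self-referential task (overestimation), matched to healthy controls
(HC) in the bar task.

Sensor recordings are built by projecting stereotyped dipole bursts (Hanning
bumps) on a spherical source shell through the spherical-conductor
leadfield, with per-trial amplitudes set by an effect specification over the
(task, category, group) design cells, plus white sensor noise and an
optional 60 Hz monitor line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocessing import Recording
from .source_model import (  # noqa: F401  (re-exported geometry)
    Leadfield,
    SensorLayout,
    SourceSpace,
    make_sensor_layout,
)

CATEGORIES = ("A", "B", "C", "D", "E", "F")

#: BMI (kg/m^2) range per picture category, ordered underweight -> overweight
DEFAULT_CATEGORY_RANGES: dict[str, tuple[float, float]] = {
    "A": (12.19, 14.74),
    "B": (14.77, 17.17),
    "C": (17.19, 19.78),
    "D": (19.80, 29.91),
    "E": (29.92, 32.45),
    "F": (32.46, 56.26),
}

TASKS = ("viewing", "bar", "body")

#: BMI of the picture whose waist matches the comparison bar
BAR_REFERENCE_BMI = 19.61


class ConfigurationError(ValueError):
    pass


class GenerationError(RuntimeError):
    pass


def _rng(seed: int | np.random.Generator, op_tag: int) -> np.random.Generator:
    """Operation-specific stream from an integer seed.

    Folding an op tag into the seed keeps different generator stages
    statistically independent even when a caller reuses one integer seed
    across them (otherwise the uniforms that ordered the trials would be
    reused for, e.g., the response draws and correlate the two).
    """
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng([op_tag, int(seed)])


# ---------------------------------------------------------------------------
# stimuli and trial sequences
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Stimulus:
    stimulus_id: int
    bmi: float
    category: str


@dataclass
class StimulusSet:
    stimuli: list[Stimulus]
    category_ranges: dict[str, tuple[float, float]]

    def __len__(self) -> int:
        return len(self.stimuli)

    @property
    def bmi(self) -> np.ndarray:
        return np.array([s.bmi for s in self.stimuli])

    @property
    def categories(self) -> np.ndarray:
        return np.array([s.category for s in self.stimuli])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stimulus_id": [s.stimulus_id for s in self.stimuli],
                "bmi": self.bmi,
                "category": self.categories,
            }
        )


def _check_ranges(ranges: Mapping[str, tuple[float, float]]) -> None:
    items = list(ranges.items())
    for cat, (lo, hi) in items:
        if lo >= hi:
            raise ConfigurationError(f"category {cat}: empty range [{lo}, {hi}]")
    for (c1, (_, hi)), (c2, (lo, _)) in zip(items, items[1:]):
        if hi >= lo:
            raise ConfigurationError(f"categories {c1} and {c2} overlap or are unordered")


def make_stimulus_set(
    n_per_category: int = 11,
    category_ranges: Mapping[str, tuple[float, float]] | None = None,
    seed: int | np.random.Generator = 0,
) -> StimulusSet:
    """Stimuli with BMIs drawn uniformly inside each category's range."""
    if n_per_category < 1:
        raise ConfigurationError("n_per_category must be >= 1")
    ranges = dict(category_ranges or DEFAULT_CATEGORY_RANGES)
    _check_ranges(ranges)
    rng = _rng(seed, 1)
    stimuli, sid = [], 0
    for cat, (lo, hi) in ranges.items():
        for bmi in np.sort(rng.uniform(lo, hi, n_per_category)):
            stimuli.append(Stimulus(stimulus_id=sid, bmi=float(bmi), category=cat))
            sid += 1
    return StimulusSet(stimuli=stimuli, category_ranges=ranges)


@dataclass
class TrialSequence:
    """Ordered presentation plan: (trial_index, stimulus_id, onset_time s, isi s)."""

    trials: pd.DataFrame  # columns: trial_index, stimulus_id, category, onset_time, isi
    stim_duration: float

    def __len__(self) -> int:
        return len(self.trials)


def max_category_run(categories: Sequence[str]) -> int:
    best = run = 1
    for prev, cur in zip(categories, categories[1:]):
        run = run + 1 if cur == prev else 1
        best = max(best, run)
    return best if len(categories) else 0


def make_trial_sequence(
    stimulus_set: StimulusSet,
    n_repeats: int = 3,
    max_run: int = 3,
    isi_center_s: float = 1.25,
    isi_jitter_s: float = 0.5,
    stim_duration_s: float = 0.8,
    lead_in_s: float = 0.5,
    seed: int | np.random.Generator = 0,
    max_retries: int = 2000,
) -> TrialSequence:
    """Constrained pseudo-random order: runs per category <= ``max_run``.

    Each position draws uniformly (weighted by remaining presentations)
    among the stimuli whose category would not extend a run beyond
    ``max_run``; dead ends trigger a bounded restart.  This keeps category
    transition probabilities approximately equal while honoring the run
    constraint at any sequence length.
    """
    rng = _rng(seed, 2)
    all_ids = np.array([s.stimulus_id for s in stimulus_set.stimuli])
    cats = {s.stimulus_id: s.category for s in stimulus_set.stimuli}
    n_total = len(all_ids) * n_repeats
    perm = None
    for _ in range(max_retries):
        remaining = {sid: n_repeats for sid in all_ids}
        order: list[int] = []
        run_cat, run_len = None, 0
        ok = True
        for _pos in range(n_total):
            allowed = [
                sid for sid, cnt in remaining.items()
                if cnt > 0 and not (cats[sid] == run_cat and run_len >= max_run)
            ]
            if not allowed:
                ok = False
                break
            weights = np.array([remaining[sid] for sid in allowed], dtype=float)
            sid = allowed[rng.choice(len(allowed), p=weights / weights.sum())]
            order.append(sid)
            remaining[sid] -= 1
            if cats[sid] == run_cat:
                run_len += 1
            else:
                run_cat, run_len = cats[sid], 1
        if ok:
            perm = np.array(order)
            break
    if perm is None:
        raise GenerationError(
            f"no sequence satisfying max_run={max_run} found in {max_retries} attempts"
        )
    seq_cats = [cats[i] for i in perm]
    n = len(perm)
    isi = rng.uniform(isi_center_s - isi_jitter_s, isi_center_s + isi_jitter_s, n)
    onsets = lead_in_s + np.concatenate([[0.0], np.cumsum(stim_duration_s + isi[:-1])])
    trials = pd.DataFrame(
        {
            "trial_index": np.arange(n),
            "stimulus_id": perm,
            "category": seq_cats,
            "onset_time": onsets,
            "isi": isi,
        }
    )
    return TrialSequence(trials=trials, stim_duration=stim_duration_s)


# ---------------------------------------------------------------------------
# cohort and behavioral responses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Subject:
    """Latent psychometric truth for one simulated participant.

    ``a_body``/``a_bar`` are the Weibull scale parameters (1/(kg/m^2)) in
    the two reference frames; the PSE follows as ln(2)^(1/beta)/a.
    """

    subject_id: str
    group: str  # "AN" | "HC"
    actual_bmi: float
    a_body: float
    a_bar: float
    beta: float
    lapse: float = 0.0

    def true_a(self, task: str) -> float:
        return self.a_body if task == "body" else self.a_bar

    def true_pse(self, task: str) -> float:
        return np.log(2.0) ** (1.0 / self.beta) / self.true_a(task)


@dataclass
class Cohort:
    subjects: list[Subject]

    def __len__(self) -> int:
        return len(self.subjects)

    def by_group(self, group: str) -> list[Subject]:
        return [s for s in self.subjects if s.group == group]


def _a_from_pse(pse: float, beta: float) -> float:
    return np.log(2.0) ** (1.0 / beta) / pse


def make_cohort(
    n_an: int = 29,
    n_hc: int = 30,
    seed: int | np.random.Generator = 0,
    an_bmi: tuple[float, float] = (15.6, 1.34),
    hc_bmi: tuple[float, float] = (20.34, 1.98),
    an_body_bpi: tuple[float, float] = (125.0, 15.0),
    hc_body_bpi: tuple[float, float] = (104.0, 10.0),
    bar_bpi: tuple[float, float] = (100.0, 8.0),
    log_beta: tuple[float, float] = (np.log(6.0), 0.2),
    lapse: float = 0.0,
) -> Cohort:
    """Cohort whose latent PSEs encode the groups' perception profile.

    Group BMI distributions follow the study samples (AN underweight, HC
    normal weight); the self-referential (body-task) PSE is the actual BMI
    scaled by a group-dependent perception index (AN overestimating around
    125%, HC near 104%), while the bar-task PSE sits at the bar-matching
    BMI scaled by a group-independent index near 100%.
    """
    if not 0.0 <= lapse < 0.5:
        raise ConfigurationError("lapse must lie in [0, 0.5)")
    rng = _rng(seed, 4)
    subjects = []
    for group, n, bmi_p, body_p in (
        ("AN", n_an, an_bmi, an_body_bpi),
        ("HC", n_hc, hc_bmi, hc_body_bpi),
    ):
        for k in range(n):
            bmi = float(np.clip(rng.normal(*bmi_p), 12.5, 35.0))
            beta = float(np.exp(rng.normal(*log_beta)))
            body_bpi = max(rng.normal(*body_p), 60.0)
            bbpi = max(rng.normal(*bar_bpi), 60.0)
            pse_body = bmi * body_bpi / 100.0
            pse_bar = BAR_REFERENCE_BMI * bbpi / 100.0
            subjects.append(
                Subject(
                    subject_id=f"{group.lower()}{k:02d}",
                    group=group,
                    actual_bmi=bmi,
                    a_body=_a_from_pse(pse_body, beta),
                    a_bar=_a_from_pse(pse_bar, beta),
                    beta=beta,
                    lapse=lapse,
                )
            )
    return Cohort(subjects=subjects)


def response_probability(bmi, a: float, beta: float, lapse: float = 0.0):
    """P("wider") for stimulus BMI under the lapse-augmented Weibull model."""
    if a <= 0 or beta <= 0:
        raise ValueError("a and beta must be positive")
    if not 0.0 <= lapse < 0.5:
        raise ValueError("lapse must lie in [0, 0.5)")
    x = np.asarray(bmi, dtype=float)
    f = 1.0 - np.exp(-((a * x) ** beta))
    return lapse / 2.0 + (1.0 - lapse) * f


def simulate_binary_responses(
    trial_sequence: TrialSequence,
    stimulus_set: StimulusSet,
    a: float,
    beta: float,
    lapse: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Bernoulli "wider" (1) / "narrower" (0) responses per trial."""
    rng = _rng(seed, 3)
    stim = stimulus_set.to_frame().set_index("stimulus_id")
    trials = trial_sequence.trials
    bmi = stim.loc[trials["stimulus_id"], "bmi"].to_numpy()
    p = response_probability(bmi, a, beta, lapse)
    resp = (rng.random(len(trials)) < p).astype(int)
    out = trials[["trial_index", "stimulus_id", "category"]].copy()
    out["bmi"] = bmi
    out["response"] = resp
    return out


def simulate_cohort_responses(
    cohort: Cohort,
    stimulus_set: StimulusSet,
    n_repeats: int = 3,
    max_run: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Trial-level response table for both BSE tasks of every subject.

    Columns: subject_id, group, task, trial_index, stimulus_id, bmi,
    category, response (0=narrower, 1=wider).
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    for subject, child in zip(cohort.subjects, ss.spawn(len(cohort))):
        task_rngs = [np.random.default_rng(s) for s in child.spawn(4)]
        for task, rng_seq, rng_resp in (
            ("bar", task_rngs[0], task_rngs[1]),
            ("body", task_rngs[2], task_rngs[3]),
        ):
            seq = make_trial_sequence(
                stimulus_set, n_repeats=n_repeats, max_run=max_run, seed=rng_seq
            )
            df = simulate_binary_responses(
                seq, stimulus_set, subject.true_a(task), subject.beta,
                subject.lapse, seed=rng_resp,
            )
            df.insert(0, "task", task)
            df.insert(0, "group", subject.group)
            df.insert(0, "subject_id", subject.subject_id)
            rows.append(df)
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# sensor-level simulation
# ---------------------------------------------------------------------------

@dataclass
class Effect:
    """One additive source-level effect over the design cells.

    The dipole burst is a Hanning bump over ``window_ms`` (relative to
    stimulus onset) at the listed shell sites, scaled by
    ``amplitude * task_w * category_w * group_w`` for the trial's cell.
    Amplitude in A*m (use ~2e-8 for a 20 nAm burst); missing weights
    default to 1.
    """

    name: str
    amplitude: float
    site_indices: np.ndarray
    window_ms: tuple[float, float] = (100.0, 500.0)
    task_weights: Mapping[str, float] = field(default_factory=dict)
    category_weights: Mapping[str, float] = field(default_factory=dict)
    group_weights: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ConfigurationError("amplitude must be nonnegative")
        if not self.window_ms[0] < self.window_ms[1]:
            raise ConfigurationError("effect onset must precede offset")

    def weight(self, task: str, category: str, group: str) -> float:
        return (
            self.task_weights.get(task, 1.0)
            * self.category_weights.get(category, 1.0)
            * self.group_weights.get(group, 1.0)
        )


EffectSpec = Sequence[Effect]


def default_effect_spec(
    n_sites: int,
    amplitude: float = 2e-8,
    task_effect: float = 1.0,
    picture_effect: float = 1.0,
    group_picture_effect: float = 1.0,
    seed: int = 7,
) -> list[Effect]:
    """Effect structure mirroring the study's findings.

    * task: activity ordered body > bar > viewing, 100-500 ms, broad sites;
    * picture: quadratic profile over categories (extremes strongest);
    * group x picture: AN-specific descending linear trend over categories,
      onset 200 ms, in a focal posterior site set.
    Multiplier arguments scale each component (0 switches it off).
    """
    rng = np.random.default_rng(seed)
    broad = rng.choice(n_sites, size=max(2, n_sites // 4), replace=False)
    focal = rng.choice(n_sites, size=max(2, n_sites // 10), replace=False)
    lin = np.linspace(1.0, -1.0, len(CATEGORIES))  # descending A -> F
    quad = np.array([1.3, 1.05, 0.9, 0.9, 1.05, 1.3])
    effects = [
        Effect(
            name="baseline_visual",
            amplitude=amplitude,
            site_indices=broad,
            window_ms=(100.0, 500.0),
        ),
        Effect(
            name="task",
            amplitude=amplitude * 0.6 * task_effect,
            site_indices=broad,
            window_ms=(100.0, 500.0),
            task_weights={"viewing": 0.0, "bar": 0.6, "body": 1.0},
        ),
        Effect(
            name="picture_quadratic",
            amplitude=amplitude * 0.5 * picture_effect,
            site_indices=broad,
            window_ms=(100.0, 500.0),
            category_weights={c: float(q) for c, q in zip(CATEGORIES, quad)},
        ),
        Effect(
            name="group_picture_linear",
            amplitude=amplitude * 0.8 * group_picture_effect,
            site_indices=focal,
            window_ms=(200.0, 550.0),
            category_weights={c: float(1.0 + 0.5 * w) for c, w in zip(CATEGORIES, lin)},
            group_weights={"AN": 1.0, "HC": 0.0},
        ),
    ]
    return effects


def _hanning_bump(times_s: np.ndarray, onset_s: float, window_s: tuple[float, float]) -> np.ndarray:
    t0 = onset_s + window_s[0]
    t1 = onset_s + window_s[1]
    out = np.zeros_like(times_s)
    inside = (times_s >= t0) & (times_s <= t1)
    phase = (times_s[inside] - t0) / (t1 - t0)
    out[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))
    return out


def simulate_sensor_recording(
    subject: Subject,
    leadfield: Leadfield,
    trial_sequences: Mapping[str, TrialSequence],
    effects: EffectSpec,
    noise_sd: float = 5e-14,
    sample_rate_hz: float = 600.0,
    line_noise_amp: float = 0.0,
    line_noise_hz: float = 60.0,
    task_gap_s: float = 2.0,
    seed: int | np.random.Generator = 0,
) -> Recording:
    """Continuous recording with the tasks concatenated and event markers.

    Each trial adds a Hanning dipole burst at every effect's sites (first
    tangential orientation), scaled by the effect weight for the trial's
    (task, category, group) cell, projected through the leadfield, plus
    white sensor noise and an optional 60 Hz line component.
    """
    if sample_rate_hz < 300:
        raise ConfigurationError("sample_rate_hz must be >= 300")
    n_sens = leadfield.matrix.shape[0]
    rng = _rng(seed, 5)

    # sensor-space template per effect: sum of first-orientation columns
    templates = {}
    for eff in effects:
        sites = np.asarray(eff.site_indices, dtype=int)
        if sites.size and sites.max() >= leadfield.matrix.shape[1]:
            raise ConfigurationError(
                f"effect {eff.name!r} references sites outside the source space"
            )
        templates[eff.name] = leadfield.matrix[:, sites, 0].sum(axis=1)

    # lay the tasks out sequentially
    segments, event_rows = [], []
    offset_s = 0.0
    for task in TASKS:
        if task not in trial_sequences:
            continue
        seq = trial_sequences[task]
        dur = float(seq.trials["onset_time"].iloc[-1] + seq.stim_duration + 1.0)
        n_samp = int(round(dur * sample_rate_hz))
        times = np.arange(n_samp) / sample_rate_hz
        seg = np.zeros((n_sens, n_samp))
        for _, tr in seq.trials.iterrows():
            onset = float(tr["onset_time"])
            for eff in effects:
                w = eff.weight(task, tr["category"], subject.group)
                if w == 0.0:
                    continue
                lo = onset + eff.window_ms[0] / 1000.0
                hi = onset + eff.window_ms[1] / 1000.0
                i0 = max(0, int(np.floor(lo * sample_rate_hz)))
                i1 = min(n_samp, int(np.ceil(hi * sample_rate_hz)) + 1)
                if i1 <= i0:
                    continue
                bump = _hanning_bump(
                    times[i0:i1], onset, (eff.window_ms[0] / 1000.0, eff.window_ms[1] / 1000.0)
                )
                seg[:, i0:i1] += np.outer(templates[eff.name], eff.amplitude * w * bump)
            event_rows.append(
                {
                    "sample": int(round((offset_s + onset) * sample_rate_hz)),
                    "stimulus_id": int(tr["stimulus_id"]),
                    "category": tr["category"],
                    "task": task,
                }
            )
        segments.append(seg)
        offset_s += dur + task_gap_s
        gap = np.zeros((n_sens, int(round(task_gap_s * sample_rate_hz))))
        segments.append(gap)
    data = np.concatenate(segments, axis=1)
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, data.shape)
    if line_noise_amp > 0:
        t = np.arange(data.shape[1]) / sample_rate_hz
        phases = rng.uniform(0, 2 * np.pi, n_sens)
        data = data + line_noise_amp * np.sin(
            2 * np.pi * line_noise_hz * t[None, :] + phases[:, None]
        )
    events = pd.DataFrame(event_rows)
    return Recording(
        data=data,
        sample_rate=sample_rate_hz,
        events=events,
        ch_names=list(leadfield.layout.names),
        modality=leadfield.modality,
    )
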