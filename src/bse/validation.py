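"""Simulation-based calibration checks for the statistical machinery.

These routines answer the questions a reviewer would ask of the pipeline:
does the cluster-permutation procedure hold its family-wise error rate on
pure noise, does the psychometric fit recover the generating parameters at
the study's trial count, and does the full pipeline recover an injected
effect structure?  They are used by the test suite and the reproduction
script, and are part of the public API so users can rerun them at other
settings.
"""

from __future__ import annotations

import logging

import numpy as np

from .cluster_stats import (
    MixedDesign,
    grid_adjacency,
    permutation_cluster_test,
    spatial_adjacency,
)
from .pipeline import RunConfig, run_pipeline
from .psychometrics import fit_weibull, fitted_bmi
from .source_model import fibonacci_sphere
from .synthetic import make_stimulus_set, make_trial_sequence, simulate_binary_responses

logger = logging.getLogger(__name__)


def estimate_null_fwer(
    n_datasets: int = 200,
    n_per_group: int = 10,
    n_levels: int = 6,
    n_sites: int = 40,
    n_times: int = 30,
    n_perm: int = 300,
    point_alpha: float = 0.05,
    cluster_alpha: float = 0.05,
    effect: str = "picture*group",
    seed: int = 0,
) -> dict:
    """Family-wise error rate of the cluster test on pure-noise datasets.

    Simulates Gaussian data with no true effects on a reduced source grid
    (sites on a sphere, Delaunay adjacency) and counts the datasets in
    which any cluster reaches significance.  A calibrated procedure stays
    at or below ``cluster_alpha`` up to binomial Monte-Carlo error.
    """
    positions = fibonacci_sphere(n_sites)
    adjacency = grid_adjacency(n_sites, n_times, spatial_adjacency(positions))
    design = MixedDesign(
        within={"picture": tuple(chr(65 + i) for i in range(n_levels))},
        groups=np.array(["AN"] * n_per_group + ["HC"] * n_per_group),
    )
    ss = np.random.SeedSequence(seed)
    n_false = 0
    for i, child in enumerate(ss.spawn(n_datasets)):
        rng = np.random.default_rng(child)
        x = rng.normal(size=(2 * n_per_group, n_levels, n_sites, n_times))
        test = permutation_cluster_test(
            x, design, effect, adjacency, n_perm=n_perm,
            point_alpha=point_alpha, seed=int(rng.integers(2**31)),
        )
        if any(c.p is not None and c.p < cluster_alpha for c in test.clusters):
            n_false += 1
        if (i + 1) % 50 == 0:
            logger.info("null replicate %d/%d, FWER so far %.3f",
                        i + 1, n_datasets, n_false / (i + 1))
    fwer = n_false / n_datasets
    return {
        "fwer": fwer,
        "n_datasets": n_datasets,
        "binomial_se": float(np.sqrt(cluster_alpha * (1 - cluster_alpha) / n_datasets)),
        "effect": effect,
    }


def psychometric_recovery(
    n_subjects: int = 200,
    a: float = 0.051,
    beta: float = 6.0,
    n_repeats: int = 3,
    seed: int = 0,
) -> dict:
    """Generate-and-refit check at the study's design size (66 x 3 trials).

    Returns the median absolute PSE recovery error (kg/m^2) and the mean
    bias of the implied perception index (percentage points).
    """
    stimulus_set = make_stimulus_set(seed=seed)
    true_pse = float(np.log(2.0) ** (1.0 / beta) / a)
    ss = np.random.SeedSequence(seed)
    errors, bpis = [], []
    for child in ss.spawn(n_subjects):
        rng = np.random.default_rng(child)
        seq = make_trial_sequence(stimulus_set, n_repeats=n_repeats, seed=rng)
        responses = simulate_binary_responses(seq, stimulus_set, a, beta, seed=rng)
        fit = fit_weibull(responses)
        est = fitted_bmi(fit)
        errors.append(est - true_pse)
        bpis.append(100.0 * est / true_pse)
    return {
        "median_abs_pse_error": float(np.median(np.abs(errors))),
        "mean_bpi_bias": float(np.mean(bpis) - 100.0),
        "true_pse": true_pse,
        "n_subjects": n_subjects,
    }


RECOVERY_CONFIG = dict(
    n_an=4, n_hc=4, n_sensors=24, n_sites=60, n_repeats=1, n_perm=100,
    effects=("task", "picture", "picture*group"),
)


def check_recovery_run(report: dict, min_onset_ms: float = 150.0) -> dict:
    """Does one pipeline report match the injected effect structure?

    Checks: significant task cluster with mean activity ordered
    body > bar > viewing; significant picture cluster with a positive
    quadratic trend (extreme categories strongest); significant
    picture-by-group cluster starting mid-latency whose linear trend is
    more descending in the AN group.
    """
    effects = {c["effect"] for c in report["clusters"]}
    task_ok = False
    if "task" in effects and "task" in report["posthoc"]:
        m = report["posthoc"]["task"]["means"]
        task_ok = m["body"] > m["bar"] > m["viewing"]
    quad_ok = False
    if "picture" in effects and "picture" in report["contrasts"]:
        quad = report["contrasts"]["picture"]["quadratic"]
        quad_ok = quad["p"] < 0.05 and quad["mean_score"] > 0
    inter_ok = False
    inter_clusters = [c for c in report["clusters"] if c["effect"] == "picture*group"]
    if inter_clusters and "picture*group" in report["contrasts"]:
        onset = min(c["time_ms"][0] for c in inter_clusters)
        lin = report["contrasts"]["picture*group"]["linear"]
        # AN minus HC linear score negative = more descending trend in AN
        inter_ok = onset >= min_onset_ms and lin["mean_score"] < 0
    return {"task_ordering": task_ok, "picture_quadratic": quad_ok,
            "group_picture_linear": inter_ok,
            "all": task_ok and quad_ok and inter_ok}


def end_to_end_recovery(n_runs: int = 5, seed: int = 0) -> dict:
    """Fraction of seeded pipeline runs recovering the injected structure."""
    results = []
    for r in range(n_runs):
        report = run_pipeline(RunConfig(seed=seed * 1000 + r, **RECOVERY_CONFIG))
        results.append(check_recovery_run(report))
        logger.info("recovery run %d/%d: %s", r + 1, n_runs, results[-1])
    frac = float(np.mean([r["all"] for r in results]))
    return {"fraction_recovered": frac, "n_runs": n_runs, "runs": results}
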