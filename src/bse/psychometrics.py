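"""Weibull psychometric fitting, body perception indices and group statistics.

The depictive size-estimation tasks yield dichotomous "narrower"/"wider"
judgments as a function of stimulus BMI.  A Weibull cumulative distribution
function f(x) = 1 - exp(-(a x)^beta) is fitted to each subject x task slice
by Bernoulli maximum likelihood; the point of subjective equality (PSE,
f = 0.5 by default) is the subject's "fitted BMI".  Body perception indices
(BPI) express estimates relative to a reference (actual BMI for the body
task, the bar-matching BMI 19.61 for the bar task, measured circumference
for the metric task); BPI = 100 means veridical, > 100 overestimation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .synthetic import BAR_REFERENCE_BMI


@dataclass
class FittedPsychometric:
    """Maximum-likelihood Weibull parameters for one subject x task slice."""

    a: float
    beta: float
    n_trials: int
    converged: bool
    neg_log_likelihood: float
    inverted: bool = False  # responses ran opposite to the expected direction
    message: str = ""


def weibull_cdf(x, a: float, beta: float):
    """Weibull psychometric function 1 - exp(-(a x)^beta); domain x >= 0."""
    if a <= 0 or beta <= 0:
        raise ValueError("a and beta must be positive")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("x must be nonnegative")
    return 1.0 - np.exp(-((a * x) ** beta))


def _negloglik(log_params: np.ndarray, bmi: np.ndarray, y: np.ndarray) -> float:
    a, beta = np.exp(log_params)
    with np.errstate(over="ignore"):
        p = 1.0 - np.exp(-((a * bmi) ** beta))
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return -float(np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def fit_weibull(
    responses: pd.DataFrame,
    bmi_col: str = "bmi",
    response_col: str = "response",
    auto_orient: bool = True,
) -> FittedPsychometric:
    """Bernoulli ML fit of (a, beta) to one subject x task response slice.

    Deterministic: a fixed multi-start grid (PSE candidates spanning the
    stimulus range x beta in {1, 3, 6, 12}) followed by bounded
    quasi-Newton in log-parameters.  If responses decrease with BMI the fit
    is performed on flipped responses and flagged ``inverted`` (the
    response coding is then opposite to the assumed direction).
    Degenerate slices (single response category, < 2 distinct BMIs) return
    a non-converged record rather than a silent estimate.
    """
    bmi = responses[bmi_col].to_numpy(dtype=float)
    y = responses[response_col].to_numpy(dtype=float)
    n = len(y)
    if np.unique(bmi).size < 2:
        return FittedPsychometric(np.nan, np.nan, n, False, np.nan,
                                  message="fewer than 2 distinct stimulus BMIs")
    if y.min() == y.max():
        return FittedPsychometric(np.nan, np.nan, n, False, np.nan,
                                  message="all responses identical (boundary)")
    inverted = False
    if auto_orient and np.corrcoef(bmi, y)[0, 1] < 0:
        y = 1.0 - y
        inverted = True

    betas = (1.0, 3.0, 6.0, 12.0)
    pse_grid = np.quantile(bmi, [0.15, 0.3, 0.5, 0.7, 0.85])
    best = None
    for beta0 in betas:
        for pse0 in pse_grid:
            a0 = np.log(2.0) ** (1.0 / beta0) / pse0
            res = optimize.minimize(
                _negloglik,
                x0=np.log([a0, beta0]),
                args=(bmi, y),
                method="L-BFGS-B",
                bounds=[(np.log(1e-6), np.log(10.0)), (np.log(0.05), np.log(200.0))],
            )
            if best is None or res.fun < best.fun - 1e-12:
                best = res
    a, beta = np.exp(best.x)
    return FittedPsychometric(
        a=float(a),
        beta=float(beta),
        n_trials=n,
        converged=bool(best.success),
        neg_log_likelihood=float(best.fun),
        inverted=inverted,
        message=str(best.message),
    )


def fitted_bmi(fit: FittedPsychometric, criterion: float = 0.5) -> float:
    """Invert the fitted curve: the BMI at which P("wider") = ``criterion``.

    With the default criterion 0.5 this is the point of subjective equality.
    """
    if not fit.converged:
        raise ValueError("cannot invert a non-converged fit")
    if not 0.0 < criterion < 1.0:
        raise ValueError("criterion must lie in (0, 1)")
    return float((-np.log(1.0 - criterion)) ** (1.0 / fit.beta) / fit.a)


def compute_bpi(value: float, reference: float) -> float:
    """Body perception index: estimated / reference x 100 (%)."""
    if reference <= 0:
        raise ValueError("reference must be positive")
    if value <= 0:
        raise ValueError("value must be positive")
    return 100.0 * value / reference


def metric_bpi(estimated: np.ndarray, measured: np.ndarray) -> float:
    """Metric-task BPI: mean of the per-body-part estimated/measured ratios.

    ``estimated`` and ``measured`` are the circumferences of waist, upper
    arm and thigh (any consistent length unit).
    """
    estimated = np.asarray(estimated, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if estimated.shape != measured.shape:
        raise ValueError("estimated and measured must have the same shape")
    return float(np.mean([compute_bpi(e, m) for e, m in zip(estimated, measured)]))


def bpi_table(
    responses: pd.DataFrame,
    actual_bmi: dict[str, float],
    bar_reference: float = BAR_REFERENCE_BMI,
    criterion: float = 0.5,
) -> pd.DataFrame:
    """Fit every subject x task slice and tabulate fitted BMIs and BPIs.

    ``actual_bmi`` maps subject_id to the subject's real BMI (the body-task
    reference).  Returns one row per subject x task with columns
    subject_id, group, kind, fitted, reference, bpi, converged.
    """
    rows = []
    for (sid, task), sl in responses.groupby(["subject_id", "task"], sort=True):
        fit = fit_weibull(sl)
        ref = actual_bmi[sid] if task == "body" else bar_reference
        fitted = fitted_bmi(fit, criterion) if fit.converged else np.nan
        rows.append(
            {
                "subject_id": sid,
                "group": sl["group"].iloc[0],
                "kind": task,
                "fitted": fitted,
                "reference": ref,
                "bpi": compute_bpi(fitted, ref) if fit.converged else np.nan,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class MedianSplit:
    labels: pd.DataFrame  # subject_id, label (AN1 | AN2)
    median: float
    degenerate: bool = False


def median_split(bpi: pd.Series | pd.DataFrame, value_col: str = "bpi") -> MedianSplit:
    """Split AN subjects at the median body-task BPI.

    AN1 (slight overestimation) = BPI <= median, AN2 (distinct
    overestimation) = BPI > median; subgroup sizes differ by at most one.
    """
    if isinstance(bpi, pd.DataFrame):
        series = bpi.set_index("subject_id")[value_col]
    else:
        series = bpi
    if len(series) < 2:
        raise ValueError("median split needs at least 2 subjects")
    med = float(series.median())
    labels = np.where(series.to_numpy() <= med, "AN1", "AN2")
    degenerate = (labels == "AN1").all() or (labels == "AN2").all()
    if degenerate:
        warnings.warn("degenerate median split: all subjects on one side", stacklevel=2)
    return MedianSplit(
        labels=pd.DataFrame({"subject_id": series.index, "label": labels}),
        median=med,
        degenerate=degenerate,
    )


def _cohens_d_independent(x: np.ndarray, y: np.ndarray) -> float:
    nx, ny = len(x), len(y)
    sp = np.sqrt(((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2))
    if sp == 0:
        return 0.0
    return float((x.mean() - y.mean()) / sp)


def group_ttest(x: np.ndarray, y: np.ndarray, levene_alpha: float = 0.05) -> dict:
    """Independent-samples t with Welch correction when variances differ.

    Welch is used when Levene's test rejects homogeneity at
    ``levene_alpha`` (this reproduces the fractional degrees of freedom
    convention of mainstream statistics packages).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.allclose(x, x[0]) and np.allclose(y, y[0]) and x[0] == y[0]:
        welch = False
    else:
        welch = stats.levene(x, y).pvalue < levene_alpha
    res = stats.ttest_ind(x, y, equal_var=not welch)
    if welch:
        vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
        df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
    else:
        df = len(x) + len(y) - 2
    return {
        "t": float(res.statistic) if np.isfinite(res.statistic) else 0.0,
        "df": float(df),
        "p": float(res.pvalue) if np.isfinite(res.pvalue) else 1.0,
        "d": _cohens_d_independent(x, y),
        "welch": bool(welch),
    }


def behavioural_stats(bpi: pd.DataFrame) -> dict:
    """Group statistics of the depictive-task BPIs.

    2 (task: bar, body) x 2 (group) mixed ANOVA plus per-task group
    t-tests with Cohen's d.  Expects the output of :func:`bpi_table`
    restricted to converged subjects present in both tasks.
    """
    import pingouin as pg

    df = bpi.dropna(subset=["bpi"]).copy()
    complete = df.groupby("subject_id")["kind"].nunique() == 2
    df = df[df["subject_id"].isin(complete[complete].index)]
    for g in df["group"].unique():
        if df[df["group"] == g]["subject_id"].nunique() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
    aov = pg.mixed_anova(
        data=df, dv="bpi", within="kind", subject="subject_id", between="group"
    )
    out = {"anova": {}}
    for _, row in aov.iterrows():
        source = str(row["Source"]).lower()
        name = {"kind": "task", "interaction": "task*group"}.get(source, source)
        out["anova"][name] = {
            "F": float(row["F"]),
            "df1": float(row["DF1"]),
            "df2": float(row["DF2"]),
            "p": float(row["p_unc"]),
            "partial_eta_sq": float(row["np2"]),
        }
    for task in sorted(df["kind"].unique()):
        sl = df[df["kind"] == task]
        groups = sorted(sl["group"].unique())
        if len(groups) == 2:
            x = sl[sl["group"] == groups[0]]["bpi"].to_numpy()
            y = sl[sl["group"] == groups[1]]["bpi"].to_numpy()
            out[f"ttest_{task}"] = group_ttest(x, y)
    return out
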