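"""Evaluation statistics for multi-environment prediction runs.

Predictive ability is summarized per environment by the Pearson
correlation r_j between predicted and observed yields, and across
environments by the inverse-variance weighted mean

    r_w = sum_j (r_j / V_j) / sum_j (1 / V_j),
    V_j = (1 - r_j^2) / (n_j - 2),

so large, informative environments dominate.  Variance components are
reported as percentage shares, either across environments or within
environments (the environment main effect dropped from numerator and
denominator).  The percentile grid cross-tabulates predicted and
observed performance categories cut at the empirical 20/50/80
percentiles; its corner cells are the top-20% and bottom-20%
classification success rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cross_validation import CVResult
from .trial_data import TrialTable

__all__ = [
    "EnvCorrelation",
    "PercentileGrid",
    "env_correlations",
    "weighted_mean_correlation",
    "variance_percentages",
    "percentile_grid",
    "genotype_overall",
]


@dataclass
class EnvCorrelation:
    environment_id: str
    r: float
    n: int

    @property
    def sampling_variance(self) -> float:
        """V(r_j) = (1 - r_j^2)/(n_j - 2); inf when n_j <= 2."""
        if self.n <= 2:
            return float("inf")
        return (1.0 - self.r**2) / (self.n - 2)


@dataclass
class PercentileGrid:
    """Conditional observed-category proportions given predicted category."""

    cuts: tuple
    matrix: np.ndarray  # rows: observed category (low->high), cols: predicted
    top20_success: float
    bottom20_success: float
    r2: float
    mse: float
    r_w: float | None = None
    empty_categories: bool = False

    def to_frame(self) -> pd.DataFrame:
        labels = _category_labels(self.cuts)
        return pd.DataFrame(self.matrix, index=labels, columns=labels)


def _category_labels(cuts) -> list[str]:
    edges = ["0", *[str(c) for c in cuts], "100"]
    return [f"{a}-{b}%" for a, b in zip(edges[:-1], edges[1:])]


def _categorize(values: np.ndarray, cuts) -> np.ndarray:
    """Assign each value to a percentile category; ties on a cut point
    go to the lower category."""
    thresholds = np.percentile(values, cuts)
    return np.sum(values[:, None] > thresholds[None, :], axis=1)


def env_correlations(
    result: CVResult | pd.DataFrame, *, min_n: int = 3
) -> tuple[list[EnvCorrelation], list[dict]]:
    """Within-environment Pearson correlations of predicted vs observed.

    Pools replicates (every predicted copy of a record counts).
    Returns the eligible entries plus a skip report for environments
    with too few records or degenerate variance.
    """
    df = result.predictions if isinstance(result, CVResult) else result
    entries, skipped = [], []
    for env, sub in df.groupby("env", sort=True):
        obs = sub["observed"].to_numpy(dtype=float)
        pred = sub["predicted"].to_numpy(dtype=float)
        if len(sub) < min_n:
            skipped.append({"env": env, "reason": f"n={len(sub)} < {min_n}"})
            continue
        if np.std(obs) == 0 or np.std(pred) == 0:
            skipped.append({"env": env, "reason": "zero variance"})
            continue
        r = float(stats.pearsonr(pred, obs).statistic)
        entries.append(EnvCorrelation(str(env), r, int(len(sub))))
    return entries, skipped


def weighted_mean_correlation(entries: list[EnvCorrelation]) -> float:
    """Inverse-sampling-variance weighted mean of the r_j.

    Entries with n_j <= 2 or |r_j| = 1 (zero sampling variance, hence
    infinite weight) are excluded.
    """
    num = den = 0.0
    used = 0
    for e in entries:
        V = e.sampling_variance
        if not np.isfinite(V) or V <= 0:
            continue
        num += e.r / V
        den += 1.0 / V
        used += 1
    if used == 0:
        raise ValueError("no environment with finite positive sampling variance")
    return num / den


def variance_percentages(
    components: dict[str, float] | pd.DataFrame, scope: str = "across"
) -> pd.Series:
    """Percentage of variability explained by each model term.

    ``scope="across"`` divides each component by the sum of all of
    them; ``scope="within"`` first drops the environment main effect
    ``E`` from both numerator set and denominator.
    """
    if isinstance(components, pd.DataFrame):
        comp = dict(zip(components["term"], components["estimate"]))
    else:
        comp = dict(components)
    if scope not in ("across", "within"):
        raise ValueError(f"scope must be 'across' or 'within', got {scope!r}")
    if scope == "within":
        comp = {t: v for t, v in comp.items() if t != "E"}
    if any(v < 0 for v in comp.values()):
        raise ValueError("variance components must be nonnegative")
    total = sum(comp.values())
    if total <= 0:
        raise ValueError("all variance components are zero")
    return pd.Series({t: 100.0 * v / total for t, v in comp.items()})


def percentile_grid(
    pred: np.ndarray,
    obs: np.ndarray,
    *,
    cuts: tuple = (20, 50, 80),
    env: np.ndarray | None = None,
) -> PercentileGrid:
    """Conditional percentile cross-tabulation plus regression summaries.

    Both vectors are categorized by their own empirical percentiles
    (linear interpolation between order statistics).  The matrix entry
    [i, j] is the proportion of records in predicted category j whose
    observed value falls in category i; each column sums to 1.  Also
    reports R^2 of regressing observed on predicted, the MSE, and —
    when ``env`` labels are given — the weighted mean correlation.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise ValueError("pred and obs must be 1-D and equally long")
    if len(pred) < 5:
        raise ValueError("need at least 5 points for a percentile grid")
    ncat = len(cuts) + 1
    pcat = _categorize(pred, cuts)
    ocat = _categorize(obs, cuts)
    counts = np.zeros((ncat, ncat))
    np.add.at(counts, (ocat, pcat), 1.0)
    colsum = counts.sum(axis=0)
    empty = bool((colsum == 0).any())
    with np.errstate(invalid="ignore"):
        matrix = np.where(colsum > 0, counts / np.where(colsum == 0, 1, colsum), 0.0)
    lr = stats.linregress(pred, obs)
    r_w = None
    if env is not None:
        df = pd.DataFrame({"env": env, "observed": obs, "predicted": pred})
        entries, _ = env_correlations(df)
        r_w = weighted_mean_correlation(entries)
    return PercentileGrid(
        cuts=tuple(cuts),
        matrix=matrix,
        top20_success=float(matrix[-1, -1]),
        bottom20_success=float(matrix[0, 0]),
        r2=float(lr.rvalue**2),
        mse=float(np.mean((obs - pred) ** 2)),
        r_w=r_w,
        empty_categories=empty,
    )


def genotype_overall(
    result: CVResult | pd.DataFrame, table: TrialTable | None = None
) -> pd.DataFrame:
    """Environment-centered across-environment genotype means.

    Within each environment, observed and predicted values are
    centered at their environment means; the centered values are then
    averaged per line.  When ``table`` is given, the observed centering
    uses the full trial table's environment means rather than the
    prediction subset's.  The output (columns ``observed``,
    ``predicted`` indexed by line) feeds :func:`percentile_grid` for
    the overall-performance assessment.
    """
    df = result.predictions if isinstance(result, CVResult) else result
    df = df.copy()
    if table is not None:
        env_means = table.data.groupby("env")["yield"].mean()
        df["observed"] = df["observed"] - df["env"].map(env_means)
    else:
        df["observed"] = df["observed"] - df.groupby("env")["observed"].transform("mean")
    df["predicted"] = df["predicted"] - df.groupby("env")["predicted"].transform("mean")
    out = df.groupby("line")[["observed", "predicted"]].mean()
    return out


def plot_grid(pred, obs, grid: PercentileGrid | None = None, ax=None):
    """Inspection scatter of predicted vs observed with percentile lines."""
    import matplotlib.pyplot as plt

    grid = grid or percentile_grid(pred, obs)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(pred, obs, s=8, alpha=0.5)
    for c in grid.cuts:
        ax.axvline(np.percentile(pred, c), ls="--", c="gray", lw=0.8)
        ax.axhline(np.percentile(obs, c), ls="--", c="gray", lw=0.8)
    ax.set_xlabel("predicted")
    ax.set_ylabel("observed")
    return ax


def attach_env_stats(result: CVResult) -> CVResult:
    """Compute and attach the per-environment correlation table."""
    entries, skipped = env_correlations(result)
    result.env_stats = pd.DataFrame(
        [
            {
                "env": e.environment_id,
                "r": e.r,
                "n": e.n,
                "sampling_variance": e.sampling_variance,
            }
            for e in entries
        ]
    )
    return result
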