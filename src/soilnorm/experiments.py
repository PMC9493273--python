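"""Validation experiments at the package's reference problem sizes.

These are the simulation studies the package uses to validate itself:

* :func:`oracle_battery` — fixed-variance Gibbs predictions against the
  closed-form BLUP solver on a battery of small configurations,
  reported as Monte-Carlo z-scores;
* :func:`recovery_experiment` — variance-share recovery of the full
  six-term model on a mid-sized unbalanced trial with known truth;
* :func:`scheme_ordering_experiment` — mean weighted correlation of the
  four cross-validation schemes on replicated synthetic trials.

Problem sizes (lines, environments, chain lengths) are fixed reference
choices documented in the methods note; they are deliberately smaller
than a real breeding program so the full battery runs on a laptop.
"""

from __future__ import annotations

import numpy as np

from . import mixed_model as mm
from .cross_validation import partitions, run
from .kernels import genomic_relationship, model_kernels
from .metrics import env_correlations, variance_percentages, weighted_mean_correlation
from .mixed_model import McmcConfig
from .synthetic_data import SimulationConfig, simulate_dataset

__all__ = [
    "oracle_battery",
    "recovery_experiment",
    "scheme_ordering_experiment",
    "cv00_leakage_count",
    "RECOVERY_TRUTH",
]

#: truth variance components (total 100) for the recovery experiment
RECOVERY_TRUTH = {"E": 45.0, "L": 2.0, "S": 12.0, "G": 4.0, "GxE": 11.0, "GxS": 10.0, "R": 16.0}

#: 20 environments over 5 years, three soil textures
_RECOVERY_LAYOUT = (
    ("farmA", "silt_loam"),
    ("farmA", "silt_loam"),
    ("farmA", "clay"),
    ("farmB", "fine_sand"),
)

_ORDERING_LAYOUT = (
    ("farmA", "silt_loam"),
    ("farmA", "clay"),
    ("farmB", "fine_sand"),
)


def oracle_battery(seed: int = 0, n_iter: int = 6000, burn_in: int = 1000) -> list[float]:
    """Max |z| between Gibbs and closed-form BLUP per toy configuration.

    Five configurations varying the model (M1--M3), trial size and the
    fixed variance components.  For each, ~1/3 of records are masked,
    the sampler runs with variances fixed and the intercept pinned to
    the training mean, and each masked prediction is compared with the
    oracle in units of its Monte-Carlo standard error.
    """
    configs = [
        ("M1", dict(n_lines=12, p_markers=40, n_years=2), {"E": 20.0, "L": 4.0, "G": 6.0, "R": 10.0}),
        ("M2", dict(n_lines=12, p_markers=40, n_years=2), {"E": 20.0, "L": 4.0, "G": 6.0, "GxE": 5.0, "R": 10.0}),
        ("M3", dict(n_lines=14, p_markers=50, n_years=2), {"E": 15.0, "L": 3.0, "S": 8.0, "G": 6.0, "GxE": 4.0, "GxS": 4.0, "R": 8.0}),
        ("M1", dict(n_lines=20, p_markers=30, n_years=2), {"E": 5.0, "L": 1.0, "G": 12.0, "R": 4.0}),
        ("M4", dict(n_lines=16, p_markers=40, n_years=2), {"E": 10.0, "L": 2.0, "S": 6.0, "G": 8.0, "GxS": 5.0, "R": 6.0}),
    ]
    out = []
    for i, (model, sim_kw, variances) in enumerate(configs):
        table, markers, _ = simulate_dataset(SimulationConfig(seed=seed + 11 * i, **sim_kw))
        G = genomic_relationship(markers)
        ks = model_kernels(model, table, G)
        y = table.y
        rng = np.random.default_rng(seed + 97 * i)
        n = len(y)
        # a handful of masked records per toy: the per-prediction 3-MCSE
        # check is sized for few simultaneous comparisons
        test = rng.choice(n, max(3, n // 12), replace=False)
        train_mask = ~np.isin(np.arange(n), test)
        oracle = mm.mme_oracle(y, train_mask, ks, variances)
        ym = y.copy()
        ym[test] = np.nan
        res = mm.fit(
            ym,
            ks,
            mcmc=McmcConfig(n_iter=n_iter, burn_in=burn_in, thin=5, seed=seed + i),
            fixed_variances=variances,
            fix_mu=float(y[train_mask].mean()),
        )
        z = np.abs(res.fitted[test] - oracle[test]) / res.fitted_mcse[test]
        out.append(float(z.max()))
    return out


def _recovery_config(seed: int) -> SimulationConfig:
    return SimulationConfig(
        n_lines=200,
        p_markers=500,
        n_years=5,
        env_layout=_RECOVERY_LAYOUT,
        variances=dict(RECOVERY_TRUTH),
        seed=seed,
    )


def recovery_experiment(
    seeds=(1, 2, 3), n_iter: int = 1500, burn_in: int = 500
) -> dict[str, dict[str, float]]:
    """Fit the six-term model to trials with known variance shares.

    200 lines in 5 yearly cohorts, 20 environments, 3 soil textures,
    800 records.  Returns the truth shares, per-seed estimates, their
    across-seed mean, and the largest absolute error in percentage
    points.
    """
    per_seed = []
    for s in seeds:
        table, markers, truth = simulate_dataset(_recovery_config(int(s)))
        G = genomic_relationship(markers)
        ks = model_kernels("M3", table, G)
        res = mm.fit(
            table.y, ks, mcmc=McmcConfig(n_iter=n_iter, burn_in=burn_in, thin=5, seed=int(s))
        )
        shares = variance_percentages(res.var_components, "across")
        per_seed.append(shares)
    mean_shares = {t: float(np.mean([p[t] for p in per_seed])) for t in RECOVERY_TRUTH}
    errors = {t: mean_shares[t] - RECOVERY_TRUTH[t] for t in RECOVERY_TRUTH}
    return {
        "truth": dict(RECOVERY_TRUTH),
        "mean_shares": mean_shares,
        "errors": errors,
        "max_abs_error": max(abs(e) for e in errors.values()),
    }


def _ordering_config(seed: int) -> SimulationConfig:
    return SimulationConfig(
        n_lines=100, p_markers=300, n_years=4, env_layout=_ORDERING_LAYOUT, seed=seed
    )


def scheme_ordering_experiment(
    seeds=tuple(range(10)), *, model: str = "M3", n_iter: int = 600, burn_in: int = 200
) -> dict[str, float]:
    """Mean weighted correlation per CV scheme over replicated trials.

    Each replicate simulates a 100-line, 12-environment program and
    runs all four schemes (one replicate of fivefold for CV2/CV1,
    leave-one-environment-out for CV0/CV00) with short chains.
    """
    acc: dict[str, list[float]] = {s: [] for s in ("CV2", "CV1", "CV0", "CV00")}
    for s in seeds:
        table, markers, _ = simulate_dataset(_ordering_config(int(s) * 7 + 1))
        for scheme in acc:
            res = run(
                model, table, markers, scheme,
                k=5, reps=1, seed=int(s) * 13 + 5,
                n_iter=n_iter, burn_in=burn_in, thin=4,
            )
            entries, _ = env_correlations(res)
            acc[scheme].append(weighted_mean_correlation(entries))
    return {scheme: float(np.mean(vals)) for scheme, vals in acc.items()}


def cv00_leakage_count(table, seeds=(0,)) -> int:
    """Exhaustive leakage check: number of (partition, line) pairs where
    a test-set line also has a training record.  Must be zero."""
    violations = 0
    for _ in seeds:
        for part in partitions("CV00", table):
            test_lines = set(table.data.iloc[part.test]["line"])
            train_lines = set(table.data.iloc[part.train]["line"])
            violations += len(test_lines & train_lines)
    return violations
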