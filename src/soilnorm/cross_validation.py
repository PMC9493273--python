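"""Cross-validation schemes for multi-environment genomic prediction.

Four schemes mirror the breeding questions they simulate:

* **CV2** — tested genotypes, observed environments: plain k-fold over
  records (incomplete field trials).
* **CV1** — untested genotypes, observed environments: k-fold over
  *lines*, so every record of a line shares its fold.
* **CV0** — tested genotypes, unobserved environments: leave one
  environment out.
* **CV00** — untested genotypes, unobserved environments: leave one
  environment out and additionally delete, from the training set,
  every record (anywhere) of the lines appearing in the held-out
  environment.

CV2/CV1 use replicated randomized folds; CV0/CV00 are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimator import ReactionNormGBLUP
from .trial_data import MarkerMatrix, TrialTable, align

__all__ = ["Partition", "CVResult", "SCHEMES", "partitions", "run"]

SCHEMES = ("CV2", "CV1", "CV0", "CV00")


class CVError(ValueError):
    pass


@dataclass
class Partition:
    """One train/test split of the record indices."""

    scheme: str
    replicate: int
    fold: str
    train: np.ndarray
    test: np.ndarray
    empty_train: bool = False

    def __post_init__(self) -> None:
        if np.intersect1d(self.train, self.test).size:
            raise CVError("train and test sets overlap")


@dataclass
class CVResult:
    """Per-record predictions across partitions of one scheme run."""

    model_id: str
    scheme: str
    predictions: pd.DataFrame  # scheme, replicate, fold, line, env, observed, predicted
    env_stats: pd.DataFrame | None = None

    def to_csv(self, path) -> None:
        self.predictions.to_csv(path, index=False)


def _chunks(items: np.ndarray, k: int) -> list[np.ndarray]:
    """Split as evenly as possible into k chunks (sizes differ by <=1)."""
    return [np.sort(c) for c in np.array_split(items, k)]


def partitions(
    scheme: str,
    table: TrialTable,
    *,
    k: int = 5,
    reps: int = 10,
    seed: int = 0,
) -> list[Partition]:
    """Generate the train/test partitions of one scheme.

    CV2/CV1 return ``reps * k`` randomized folds (the replicate r uses
    seed ``seed + r`` so replicates are independent but reproducible);
    CV0/CV00 return one deterministic partition per environment.
    """
    if scheme not in SCHEMES:
        raise CVError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    df = table.data
    n = len(df)
    all_idx = np.arange(n)
    out: list[Partition] = []

    if scheme in ("CV2", "CV1"):
        if scheme == "CV2" and k > n:
            raise CVError(f"k={k} exceeds record count {n}")
        lines = np.array(sorted(df["line"].unique()))
        if scheme == "CV1" and k > len(lines):
            raise CVError(f"k={k} exceeds line count {len(lines)}")
        for rep in range(reps):
            rng = np.random.default_rng(seed + rep)
            if scheme == "CV2":
                folds = _chunks(rng.permutation(n), k)
            else:
                line_folds = _chunks(rng.permutation(lines), k)
                folds = [
                    all_idx[df["line"].isin(fl).to_numpy()] for fl in line_folds
                ]
            for f, test in enumerate(folds):
                train = np.setdiff1d(all_idx, test)
                out.append(Partition(scheme, rep, f"fold{f}", train, test))
        return out

    envs = sorted(df["env"].unique())
    if len(envs) < 2:
        raise CVError("CV0/CV00 need at least 2 environments")
    for env in envs:
        test = all_idx[(df["env"] == env).to_numpy()]
        train = np.setdiff1d(all_idx, test)
        if scheme == "CV00":
            test_lines = set(df.iloc[test]["line"])
            keep = ~df.iloc[train]["line"].isin(test_lines).to_numpy()
            train = train[keep]
        out.append(
            Partition(scheme, 0, env, train, test, empty_train=train.size == 0)
        )
    return out


def run(
    model_id: str,
    table: TrialTable,
    markers: MarkerMatrix,
    scheme: str,
    *,
    k: int = 5,
    reps: int = 10,
    seed: int = 0,
    n_iter: int = 12_000,
    burn_in: int = 2_000,
    thin: int = 5,
    priors=None,
    skip_failures: bool = False,
) -> CVResult:
    """Fit ``model_id`` over every partition of ``scheme`` and collect
    test-record predictions.

    Each partition masks the test phenotypes (NaN) and refits; the
    per-partition sampler seed derives deterministically from ``seed``.
    """
    table, markers, _ = align(table, markers)
    parts = partitions(scheme, table, k=k, reps=reps, seed=seed)
    df = table.data
    X = df[["line", "env", "year", "location", "soil"]]
    y_full = table.y
    rows = []
    for p_i, part in enumerate(parts):
        if part.empty_train:
            continue
        # mask everything outside the training set (for CV00 this also
        # hides the test lines' records in other environments)
        y_masked = np.full_like(y_full, np.nan)
        y_masked[part.train] = y_full[part.train]
        est = ReactionNormGBLUP(
            model=model_id,
            markers=markers,
            n_iter=n_iter,
            burn_in=burn_in,
            thin=thin,
            random_state=(seed + 1000 * p_i) % (2**31 - 1),
            priors=priors,
        )
        try:
            est.fit(X, y_masked)
        except Exception as exc:  # noqa: BLE001 - annotate partition identity
            if skip_failures:
                continue
            raise RuntimeError(
                f"fit failed for {scheme} replicate {part.replicate} "
                f"fold {part.fold}: {exc}"
            ) from exc
        pred = est.fitted_[part.test]
        sub = df.iloc[part.test]
        rows.append(
            pd.DataFrame(
                {
                    "scheme": scheme,
                    "replicate": part.replicate,
                    "fold": part.fold,
                    "line": sub["line"].to_numpy(),
                    "env": sub["env"].to_numpy(),
                    "observed": y_full[part.test],
                    "predicted": pred,
                }
            )
        )
    if not rows:
        raise CVError(f"no partition of scheme {scheme} produced predictions")
    return CVResult(model_id, scheme, pd.concat(rows, ignore_index=True))
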