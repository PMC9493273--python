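"""Simulation of soybean-like multi-environment trial data.

The generator emulates an advanced-yield-trial program: cohorts of
breeding lines evaluated over several years, each year at a handful of
environments with known soil textures (silt loam, clay, fine sand),
giving the unbalanced line × environment incidence typical of such
programs.  Phenotypes follow the full reaction-norm generative model

    y_ijk = mu + E_j + S_k + L_i + g_i + gE_ij + gS_ik + eps_ijk

with E (environment), S (soil), L (line) i.i.d. normal; genomic values
g = X_c b from simulated biallelic markers; and the interaction
deviations gE, gS drawn with the Hadamard covariance structure
(correlated across lines through the genomic relationship G,
independent across environments / soils).

Every sampled effect vector is stored, so phenotypes can be
reconstructed exactly and variance-component recovery can be judged
against known truth.  Two calibration steps keep that truth
well-defined at finite size (both on by default, both optional):

* ``exact_variance_scaling`` — each record-level contribution is
  rescaled so its realized variance equals the configured component
  exactly; with a few dozen environments and only three soil classes
  the raw variance of a finite draw strays far from its expectation.
* ``orthogonalize`` — the environment draw is residualized against the
  soil-group means before scaling.  Soil is constant within an
  environment, so without this step part of the realized environment
  variance is indistinguishable from soil variance, making the
  nominal E/S split unidentifiable no matter how good the fitter is.
  No finer projections are applied (see the comment at the alias
  table): they would distort the within-line correlation structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kernels import genomic_relationship
from .trial_data import MarkerMatrix, TrialTable

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "ENV_LAYOUT_DEFAULT",
    "simulate_markers",
    "simulate_dataset",
]

#: soils of the environments run each year: two silt loam and two clay
#: environments at one farm, one fine sand environment at the other
ENV_LAYOUT_DEFAULT = (
    ("farmA", "silt_loam"),
    ("farmA", "silt_loam"),
    ("farmA", "clay"),
    ("farmA", "clay"),
    ("farmB", "fine_sand"),
)

#: default truth shares (percent of a total variance of 100) chosen to
#: mimic the full six-term model's decomposition on real soybean data
DEFAULT_VARIANCES = {
    "E": 45.7,
    "L": 2.2,
    "S": 12.5,
    "G": 3.5,
    "GxE": 10.9,
    "GxS": 9.5,
    "R": 15.7,
}


@dataclass
class SimulationConfig:
    """Layout, genetics and variance structure of a simulated program.

    Defaults reproduce the scale of a five-year advanced soybean yield
    trial: 797 lines genotyped at ~6k SNPs, five environments per year
    (two silt loam, two clay, one fine sand), each yearly cohort of
    lines observed in all of its year's environments, grand mean 50
    with total variance 100 split as in :data:`DEFAULT_VARIANCES`.
    """

    n_lines: int = 797
    p_markers: int = 6000
    freq_range: tuple = (0.05, 0.95)
    n_years: int = 5
    env_layout: tuple = ENV_LAYOUT_DEFAULT
    carryover: float = 0.0  # fraction of a cohort re-tested the next year
    mu: float = 50.0
    variances: dict = field(default_factory=lambda: dict(DEFAULT_VARIANCES))
    exact_variance_scaling: bool = True
    orthogonalize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.freq_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError(f"invalid allele-frequency range {self.freq_range}")
        if any(v < 0 for v in self.variances.values()):
            raise ValueError("variance components must be nonnegative")
        if self.n_years * len(self.env_layout) < 2:
            raise ValueError("layout must yield at least 2 environments")
        if self.n_lines < 2 * self.n_years:
            raise ValueError("need at least 2 lines per yearly cohort")
        if not 0 <= self.carryover < 1:
            raise ValueError("carryover must be in [0, 1)")


@dataclass
class SyntheticTruth:
    """Everything needed to reconstruct the phenotypes exactly."""

    config: SimulationConfig
    effects: dict[str, np.ndarray]      # record-level contribution per term
    level_effects: dict[str, pd.Series] # per-level values (E_j, S_k, L_i, g_i)
    marker_effects: np.ndarray
    residuals: np.ndarray
    shares: dict[str, float]            # realized record-level variance shares

    def reconstruct(self) -> np.ndarray:
        y = np.full(self.residuals.shape, self.config.mu)
        for v in self.effects.values():
            y = y + v
        return y + self.residuals


def simulate_markers(config: SimulationConfig) -> MarkerMatrix:
    """Biallelic dosages: per marker, codes ~ Binomial(2, q_m) with
    q_m uniform in the configured allele-frequency range."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.freq_range
    q = rng.uniform(lo, hi, size=config.p_markers) if hi > lo else np.full(config.p_markers, lo)
    codes = rng.binomial(2, q[None, :], size=(config.n_lines, config.p_markers))
    lines = [f"g{i:04d}" for i in range(config.n_lines)]
    cols = [f"m{j:05d}" for j in range(config.p_markers)]
    return MarkerMatrix(pd.DataFrame(codes.astype(float), index=lines, columns=cols))


def _scale_to(v: np.ndarray, target_var: float, exact: bool) -> np.ndarray:
    """Center and rescale a record-level contribution to the target
    variance (population variance).  Degenerate vectors are returned
    as zeros when the target is zero and left untouched otherwise."""
    if target_var == 0:
        return np.zeros_like(v)
    if not exact:
        return v
    v = v - v.mean()
    sd = v.std()
    if sd == 0:
        return v
    return v * np.sqrt(target_var) / sd


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[TrialTable, MarkerMatrix, SyntheticTruth]:
    """Draw a full synthetic trial: markers, incidence, phenotypes.

    Cohorts are assigned to years as evenly as possible; every line of
    a cohort is observed in each of its year's environments (plus,
    with probability ``carryover``, in the following year's).  All
    randomness derives from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed + 1)
    markers = simulate_markers(config)
    lines = np.array(markers.line_ids)

    # year cohorts
    cohorts = np.array_split(np.arange(config.n_lines), config.n_years)
    env_rows = []
    records = []
    env_ids, soils_of_env = [], {}
    for yr in range(config.n_years):
        year = 2017 + yr
        for e, (farm, soil) in enumerate(config.env_layout):
            env = f"{year}_{farm}_{soil}_{e}"
            env_ids.append(env)
            soils_of_env[env] = (year, farm, soil)
    for yr in range(config.n_years):
        year = 2017 + yr
        members = list(cohorts[yr])
        if config.carryover > 0 and yr > 0:
            prev = cohorts[yr - 1]
            n_keep = int(round(config.carryover * len(prev)))
            if n_keep:
                members += list(rng.choice(prev, size=n_keep, replace=False))
        year_envs = [e for e in env_ids if soils_of_env[e][0] == year]
        for li in members:
            for env in year_envs:
                records.append((lines[li], env, *soils_of_env[env]))
    rec = pd.DataFrame(records, columns=["line", "env", "year", "location", "soil"])
    rec = rec.drop_duplicates(subset=["line", "env"]).reset_index(drop=True)
    n = len(rec)

    v = config.variances
    exact = config.exact_variance_scaling
    effects: dict[str, np.ndarray] = {}
    level_effects: dict[str, pd.Series] = {}

    # orthonormal bases of the factor-indicator subspaces (for the
    # aliasing projections); computed lazily only when needed
    def _indicator(col: str) -> np.ndarray:
        return pd.get_dummies(rec[col]).to_numpy(dtype=float)

    _basis_cache: dict[tuple, np.ndarray] = {}

    def _basis(cols: tuple) -> np.ndarray:
        if cols not in _basis_cache:
            mats = [np.ones((n, 1))] + [_indicator(c) for c in cols]
            Q, R = np.linalg.qr(np.hstack(mats))
            keep = np.abs(np.diag(R)) > 1e-10
            _basis_cache[cols] = Q[:, keep]
        return _basis_cache[cols]

    # Factor subspaces each term's draw is residualized against.  Only
    # the environment/soil alias is material (soil is constant within
    # an environment, so soil-group means of the E draw are otherwise
    # indistinguishable from soil effects).  Projections against finer
    # factors (e.g. line means of the interaction draws) are *not*
    # applied: with each line observed in only a handful of
    # environments they would force a line's interaction deviations to
    # be negatively dependent, distorting the model's correlation
    # structure.
    _ALIAS = {
        "E": ("soil",),
        "S": (),
        "L": (),
        "G": (),
        "GxE": (),
        "GxS": (),
    }

    def _calibrate(term: str, contrib: np.ndarray, target: float) -> np.ndarray:
        if target == 0:
            return np.zeros_like(contrib)
        if config.orthogonalize and _ALIAS[term]:
            Q = _basis(_ALIAS[term])
            contrib = contrib - Q @ (Q.T @ contrib)
        return _scale_to(contrib, target, exact)

    # main effects: i.i.d. per level, broadcast to records
    for term, col, sd_key in (("E", "env", "E"), ("S", "soil", "S"), ("L", "line", "L")):
        levels = sorted(rec[col].unique())
        draw = rng.normal(0.0, np.sqrt(v.get(sd_key, 0.0)) or 0.0, size=len(levels))
        ser = pd.Series(draw, index=levels)
        contrib = rec[col].map(ser).to_numpy(dtype=float)
        contrib = _calibrate(term, contrib, v.get(sd_key, 0.0))
        effects[term] = contrib
        # store per-level values consistent with the scaled contribution
        level_effects[term] = (
            pd.Series(contrib, index=rec[col].to_numpy()).groupby(level=0).first()
        )

    # genomic main effect: g = X_c b
    X = markers.codes.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    b = rng.normal(size=config.p_markers)
    g_raw = Xc @ b
    g_line = pd.Series(g_raw, index=lines)
    contrib = rec["line"].map(g_line).to_numpy(dtype=float)
    sd = contrib.std()
    scale_b = np.sqrt(v.get("G", 0.0)) / sd if (sd > 0 and v.get("G", 0.0) > 0) else 0.0
    b = b * scale_b
    contrib = _calibrate("G", contrib * scale_b, v.get("G", 0.0))
    effects["G"] = contrib
    level_effects["G"] = (
        pd.Series(contrib, index=rec["line"].to_numpy()).groupby(level=0).first()
    )

    # interaction deviations: correlated across lines via G, independent
    # across environments (gE) and soils (gS); the G factor is only
    # needed when an interaction variance is positive
    Lhalf = None
    if v.get("GxE", 0.0) > 0 or v.get("GxS", 0.0) > 0:
        G_kernel = genomic_relationship(markers).values
        w, V = np.linalg.eigh(G_kernel)
        w = np.clip(w, 0.0, None)
        Lhalf = V * np.sqrt(w)[None, :]
    line_pos = {l: i for i, l in enumerate(lines)}
    for term, col in (("GxE", "env"), ("GxS", "soil")):
        tv = v.get(term, 0.0)
        contrib = np.zeros(n)
        if tv > 0:
            for _, group in rec.groupby(col, sort=True):
                z = Lhalf @ rng.normal(size=len(lines))
                idx = group.index.to_numpy()
                pos = [line_pos[l] for l in group["line"]]
                contrib[idx] = z[pos]
            contrib = _calibrate(term, contrib, tv)
        effects[term] = contrib

    residuals = rng.normal(0.0, np.sqrt(v.get("R", 0.0)) or 0.0, size=n)
    residuals = _scale_to(residuals, v.get("R", 0.0), exact)

    y = np.full(n, config.mu, dtype=float)
    for vec in effects.values():
        y += vec
    y += residuals

    table = TrialTable(
        pd.DataFrame(
            {
                "line": rec["line"],
                "env": rec["env"],
                "year": rec["year"],
                "location": rec["location"],
                "soil": rec["soil"],
                "yield": y,
            }
        )
    )
    total = sum(np.var(e) for e in effects.values()) + np.var(residuals)
    if total > 0:
        shares = {t: 100.0 * np.var(e) / total for t, e in effects.items()}
        shares["R"] = 100.0 * np.var(residuals) / total
    else:  # fully degenerate generative model
        shares = {t: 0.0 for t in (*effects, "R")}
    truth = SyntheticTruth(
        config=config,
        effects=effects,
        level_effects=level_effects,
        marker_effects=b,
        residuals=residuals,
        shares=shares,
    )
    return table, markers, truth
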