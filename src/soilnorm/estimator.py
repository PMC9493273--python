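"""scikit-learn estimator interface to the reaction-norm GBLUP models.

:class:`ReactionNormGBLUP` wraps kernel construction plus the Gibbs
sampler behind the usual ``fit``/``predict`` contract so the models
compose with sklearn model selection.  ``X`` is a DataFrame of factor
columns (``line``, ``env``, ``year``, ``location``, ``soil``) and ``y``
the yields; NaN entries of ``y`` mark records to predict (the sampler
imputes them by data augmentation, so test records participate in the
covariance structure but contribute no likelihood information).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from . import mixed_model
from .kernels import MODEL_TERMS, Kernel, genomic_relationship, model_kernels
from .mixed_model import FitResult, McmcConfig, PriorSpec
from .trial_data import MarkerMatrix, TrialTable

__all__ = ["ReactionNormGBLUP"]

_FACTOR_DEFAULTS = {"year": 0, "location": "loc0", "soil": "s0"}


def _as_trial_table(X: pd.DataFrame, y: np.ndarray) -> TrialTable:
    df = X.copy().reset_index(drop=True)
    for col, default in _FACTOR_DEFAULTS.items():
        if col not in df.columns:
            df[col] = default
    df["yield"] = 0.0  # placeholder; masked values never enter TrialTable checks
    table = TrialTable(df[["line", "env", "year", "location", "soil", "yield"]])
    return table


class ReactionNormGBLUP(BaseEstimator, RegressorMixin):
    """Bayesian multi-kernel GBLUP with G×E / G×S reaction-norm terms.

    Parameters
    ----------
    model : {"M1", "M2", "M3", "M4"}
        Term structure: M1 = E+L+G, M2 adds G×E, M3 adds S, G×E and
        G×S, M4 is M3 without G×E.
    markers : MarkerMatrix or DataFrame, optional
        Lines × markers dosage codes used to build the genomic
        relationship matrix.  Alternatively pass ``relationship``.
    relationship : Kernel or DataFrame, optional
        Precomputed line × line genomic relationship matrix.
    impute, center, scale
        Marker-processing switches for the relationship matrix.
    n_iter, burn_in, thin, random_state
        Gibbs chain settings.
    priors : PriorSpec, optional
        Variance priors; defaults to df=5 with an R2=0.5 split.
    fixed_variances : dict, optional
        {term: sigma^2} held fixed instead of sampled (``"R"`` =
        residual); mainly for validation against the closed-form BLUP.
    fix_mu : float, optional
        Pin the intercept instead of sampling it.

    Attributes
    ----------
    result_ : FitResult
        Full posterior summaries.
    variance_components_ : dict
        Posterior-mean variance per term plus residual ``"R"``.
    fitted_ : ndarray
        Posterior mean of the linear predictor for every training row
        (including masked ones).
    """

    def __init__(
        self,
        model: str = "M3",
        markers=None,
        relationship=None,
        impute: str = "mean",
        center: bool = True,
        scale: bool = True,
        normalize_kernels: bool = False,
        n_iter: int = 12_000,
        burn_in: int = 2_000,
        thin: int = 5,
        random_state: int = 0,
        priors: PriorSpec | None = None,
        fixed_variances: dict | None = None,
        fix_mu: float | None = None,
        keep_samples: bool = False,
    ):
        self.model = model
        self.markers = markers
        self.relationship = relationship
        self.impute = impute
        self.center = center
        self.scale = scale
        self.normalize_kernels = normalize_kernels
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.random_state = random_state
        self.priors = priors
        self.fixed_variances = fixed_variances
        self.fix_mu = fix_mu
        self.keep_samples = keep_samples

    # ------------------------------------------------------------------
    def _relationship(self) -> Kernel:
        if self.relationship is not None:
            if isinstance(self.relationship, Kernel):
                return self.relationship
            df = pd.DataFrame(self.relationship)
            return Kernel(df.to_numpy(dtype=float), [str(i) for i in df.index])
        if self.markers is None:
            raise ValueError("provide either `markers` or `relationship`")
        markers = self.markers
        if not isinstance(markers, MarkerMatrix):
            markers = MarkerMatrix(pd.DataFrame(markers))
        return genomic_relationship(
            markers, impute=self.impute, center=self.center, scale=self.scale
        )

    def fit(self, X: pd.DataFrame, y) -> "ReactionNormGBLUP":
        if self.model not in MODEL_TERMS:
            raise ValueError(f"unknown model {self.model!r}")
        y = np.asarray(y, dtype=float)
        if len(y) != len(X):
            raise ValueError("X and y lengths differ")
        table = _as_trial_table(X, y)
        G = self._relationship()
        kernels = model_kernels(
            self.model, table, G, normalize=self.normalize_kernels
        )
        result: FitResult = mixed_model.fit(
            y,
            kernels,
            self.priors,
            McmcConfig(
                n_iter=self.n_iter,
                burn_in=self.burn_in,
                thin=self.thin,
                seed=self.random_state,
            ),
            fixed_variances=self.fixed_variances,
            fix_mu=self.fix_mu,
            keep_samples=self.keep_samples,
        )
        self.result_ = result
        self.mu_ = result.mu
        self.variance_components_ = dict(result.var_components)
        self.fitted_ = result.fitted
        self.train_index_ = pd.MultiIndex.from_frame(
            table.data[["line", "env"]]
        )
        self.table_ = table
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X: pd.DataFrame | None = None) -> np.ndarray:
        """Posterior-mean predictions.

        With ``X=None`` returns the fitted linear predictor for the
        training rows.  Otherwise rows are matched to training records
        by (line, env); unmatched rows raise, since effects for levels
        never presented to ``fit`` are undefined — include prospective
        records at ``fit`` time with NaN phenotypes instead.
        """
        check_is_fitted(self, "result_")
        if X is None:
            return self.fitted_.copy()
        idx = pd.MultiIndex.from_frame(
            X[["line", "env"]].astype(str).reset_index(drop=True)
        )
        locator = pd.Series(
            np.arange(len(self.train_index_)), index=self.train_index_
        )
        try:
            pos = locator.loc[idx].to_numpy()
        except KeyError as exc:
            raise ValueError(
                "prediction rows must correspond to records seen at fit time "
                f"(missing {exc.args[0]!r}); pass them to fit() with NaN yield"
            ) from None
        return self.fitted_[pos]

    def variance_table(self) -> pd.DataFrame:
        check_is_fitted(self, "result_")
        return self.result_.variance_table()
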