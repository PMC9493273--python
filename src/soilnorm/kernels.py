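"""Covariance kernels for the multi-kernel reaction-norm models.

Model terms act on phenotype records through record-level covariance
matrices: incidence products Z Zᵀ for the categorical main effects
(environment, line, soil), the expanded genomic kernel Z_L G Z_Lᵀ for
marker main effects, and Hadamard (cell-by-cell) products of those for
the marker x environment and marker x soil interactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trial_data import IncidenceMatrix, MarkerMatrix, TrialTable, incidence

__all__ = [
    "Kernel",
    "KernelSet",
    "KernelError",
    "MODEL_TERMS",
    "genomic_relationship",
    "expand_to_records",
    "hadamard",
    "model_kernels",
]

SYMMETRY_TOL = 1e-10
PSD_TOL = 1e-8

#: random terms of each model, in sampling order
MODEL_TERMS: dict[str, tuple[str, ...]] = {
    "M1": ("E", "L", "G"),
    "M2": ("E", "L", "G", "GxE"),
    "M3": ("E", "L", "S", "G", "GxE", "GxS"),
    "M4": ("E", "L", "S", "G", "GxS"),
}


class KernelError(ValueError):
    """Raised for malformed or numerically inadmissible kernels."""


@dataclass
class Kernel:
    """A symmetric PSD covariance matrix with labeled axes.

    ``axis`` says whether rows index entities (e.g. lines) or
    phenotype records.
    """

    values: np.ndarray
    labels: list[str] = field(default_factory=list)
    axis: str = "entity"

    def __post_init__(self) -> None:
        K = np.asarray(self.values, dtype=float)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise KernelError(f"kernel must be square, got shape {K.shape}")
        if self.labels and len(self.labels) != K.shape[0]:
            raise KernelError("label count does not match kernel dimension")
        asym = np.abs(K - K.T).max() if K.size else 0.0
        if asym > SYMMETRY_TOL:
            raise KernelError(f"kernel asymmetry {asym:.3e} exceeds {SYMMETRY_TOL}")
        self.values = (K + K.T) / 2.0

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def is_psd(self, tol: float = PSD_TOL) -> bool:
        w = np.linalg.eigvalsh(self.values)
        top = max(w[-1], 1.0)
        return w[0] >= -tol * top

    def require_psd(self, tol: float = PSD_TOL) -> "Kernel":
        if not self.is_psd(tol):
            raise KernelError("kernel is not positive semidefinite within tolerance")
        return self

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(path)

    @classmethod
    def from_csv(cls, path, axis: str = "entity") -> "Kernel":
        import pandas as pd

        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float), [str(c) for c in df.columns], axis=axis)


@dataclass
class KernelSet:
    """The named record-level kernels of one model (M1--M4)."""

    model_id: str
    kernels: dict[str, Kernel]

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_TERMS:
            raise KernelError(f"unknown model {self.model_id!r}")
        expected = set(MODEL_TERMS[self.model_id])
        if set(self.kernels) != expected:
            raise KernelError(
                f"{self.model_id} requires terms {sorted(expected)}, "
                f"got {sorted(self.kernels)}"
            )
        sizes = {k.n for k in self.kernels.values()}
        if len(sizes) != 1:
            raise KernelError(f"kernels disagree on record count: {sizes}")

    @property
    def terms(self) -> tuple[str, ...]:
        return MODEL_TERMS[self.model_id]

    @property
    def n_records(self) -> int:
        return next(iter(self.kernels.values())).n

    def __getitem__(self, term: str) -> Kernel:
        return self.kernels[term]


def genomic_relationship(
    markers: MarkerMatrix,
    *,
    impute: str = "mean",
    center: bool = True,
    scale: bool = True,
) -> Kernel:
    """Marker-derived relationship matrix G = X_c X_cᵀ / p among lines.

    Missing codes are imputed per marker (``impute="mean"``), each
    marker column is optionally centered at its mean and scaled to unit
    variance, and the cross-product is divided by the marker count.
    Monomorphic markers carry no information and are dropped before
    scaling.
    """
    X = markers.codes.to_numpy(dtype=float).copy()
    if impute == "mean":
        col_mean = np.nanmean(X, axis=0)
        nan_r, nan_c = np.where(np.isnan(X))
        X[nan_r, nan_c] = col_mean[nan_c]
    elif impute == "zero":
        X = np.nan_to_num(X, nan=0.0)
    else:
        raise KernelError(f"unknown imputation policy {impute!r}")
    sd = X.std(axis=0)
    if scale:
        keep = sd > 0
        if not keep.any():
            raise KernelError("all markers monomorphic; relationship undefined")
        X, sd = X[:, keep], sd[keep]
    p = X.shape[1]
    if center:
        X = X - X.mean(axis=0)
    if scale:
        X = X / sd
    G = X @ X.T / p
    return Kernel(G, list(markers.line_ids), axis="entity")


def expand_to_records(entity_kernel: Kernel, Z: IncidenceMatrix) -> Kernel:
    """Lift an entity-level kernel to records: Z K Zᵀ."""
    if entity_kernel.labels and entity_kernel.labels != list(Z.levels):
        raise KernelError(
            "entity kernel labels do not match incidence columns: "
            f"{entity_kernel.labels[:3]}... vs {list(Z.levels)[:3]}..."
        )
    K = Z.values @ entity_kernel.values @ Z.values.T
    return Kernel(K, axis="record")


def hadamard(A: Kernel, B: Kernel) -> Kernel:
    """Cell-by-cell product of two record-level kernels (PSD by Schur)."""
    if A.n != B.n:
        raise KernelError(f"kernel dimensions differ: {A.n} vs {B.n}")
    return Kernel(A.values * B.values, labels=A.labels or B.labels, axis=A.axis)


def model_kernels(
    model_id: str,
    table: TrialTable,
    G: Kernel,
    *,
    normalize: bool = False,
) -> KernelSet:
    """Assemble the record-level kernels for one of the models M1--M4.

    E -> Z_E Z_Eᵀ, L -> Z_L Z_Lᵀ, S -> Z_S Z_Sᵀ, G -> Z_L G Z_Lᵀ,
    GxE -> (Z_L G Z_Lᵀ) # (Z_E Z_Eᵀ), GxS -> (Z_L G Z_Lᵀ) # (Z_S Z_Sᵀ).
    ``normalize`` divides each kernel by its mean diagonal.
    """
    if model_id not in MODEL_TERMS:
        raise KernelError(f"unknown model {model_id!r}")
    Z_E = incidence(table, "environment")
    Z_L = incidence(table, "line")
    G_lines = G
    if G.labels and G.labels != Z_L.levels:
        missing = set(Z_L.levels) - set(G.labels)
        if missing:
            raise KernelError(f"lines missing from genomic kernel: {sorted(missing)}")
        order = [G.labels.index(l) for l in Z_L.levels]
        G_lines = Kernel(G.values[np.ix_(order, order)], list(Z_L.levels))

    built: dict[str, Kernel] = {}
    KE = Kernel(Z_E.values @ Z_E.values.T, axis="record")
    KL = Kernel(Z_L.values @ Z_L.values.T, axis="record")
    KG = expand_to_records(G_lines, Z_L)
    built["E"], built["L"], built["G"] = KE, KL, KG
    if "S" in MODEL_TERMS[model_id] or "GxS" in MODEL_TERMS[model_id]:
        Z_S = incidence(table, "soil")
        KS = Kernel(Z_S.values @ Z_S.values.T, axis="record")
        built["S"] = KS
    if "GxE" in MODEL_TERMS[model_id]:
        built["GxE"] = hadamard(KG, KE)
    if "GxS" in MODEL_TERMS[model_id]:
        built["GxS"] = hadamard(KG, built["S"])
    kernels = {t: built[t] for t in MODEL_TERMS[model_id]}
    if normalize:
        kernels = {
            t: Kernel(k.values / np.mean(np.diag(k.values)), k.labels, k.axis)
            for t, k in kernels.items()
        }
    return KernelSet(model_id, kernels)
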