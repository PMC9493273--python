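"""Phenotype and marker containers for multi-environment trials.

The phenotype table is long format: one record per line x environment,
with each environment nested in a (year, location, soil type) triple.
The marker matrix holds biallelic SNP dosage codes (0/1/2, missing
allowed) for the same lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TrialTable",
    "MarkerMatrix",
    "IncidenceMatrix",
    "TrialDataError",
    "load_phenotype_table",
    "load_marker_matrix",
    "incidence",
    "align",
]

#: canonical semantic roles -> default column names of the phenotype CSV
CANONICAL_COLUMNS = {
    "line": "line",
    "env": "env",
    "year": "year",
    "location": "location",
    "soil": "soil",
    "yield": "yield",
}

FACTORS = ("line", "environment", "soil")


class TrialDataError(ValueError):
    """Raised when trial inputs violate the data contracts."""


@dataclass
class TrialTable:
    """Long-format yield records, one per (line, environment) pair.

    Attributes
    ----------
    data : pandas.DataFrame
        Columns ``line, env, year, location, soil, yield``.  Each
        ``env`` maps to exactly one (year, location, soil) triple and
        each (line, env) pair occurs at most once.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["line", "env", "year", "location", "soil", "yield"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise TrialDataError(f"phenotype table missing columns: {missing}")
        df = self.data.reset_index(drop=True)
        dup = df.duplicated(subset=["line", "env"])
        if dup.any():
            pairs = df.loc[dup, ["line", "env"]].itertuples(index=False)
            raise TrialDataError(
                "duplicate (line, environment) records: "
                + ", ".join(f"({p.line}, {p.env})" for p in pairs)
            )
        y = pd.to_numeric(df["yield"], errors="coerce")
        if not np.isfinite(y.to_numpy(dtype=float)).all():
            bad = df.index[~np.isfinite(y.to_numpy(dtype=float))].tolist()
            raise TrialDataError(f"non-finite yield values at rows {bad}")
        meta = df.groupby("env")[["year", "location", "soil"]].nunique()
        inconsistent = meta.index[(meta > 1).any(axis=1)].tolist()
        if inconsistent:
            raise TrialDataError(
                f"environments mapped to multiple (year, location, soil) "
                f"triples: {inconsistent}"
            )
        df = df.astype({"line": str, "env": str, "soil": str})
        df["yield"] = y.astype(float)
        self.data = df

    # -- basic views ---------------------------------------------------
    @property
    def n_records(self) -> int:
        return len(self.data)

    @property
    def lines(self) -> list[str]:
        return sorted(self.data["line"].unique())

    @property
    def environments(self) -> list[str]:
        return sorted(self.data["env"].unique())

    @property
    def soils(self) -> list[str]:
        return sorted(self.data["soil"].unique())

    @property
    def y(self) -> np.ndarray:
        return self.data["yield"].to_numpy(dtype=float)

    def to_csv(self, path, sep: str = ",") -> None:
        self.data.to_csv(path, sep=sep, index=False)


@dataclass
class MarkerMatrix:
    """Lines x markers dosage codes in {0, 1, 2}, NaN for missing."""

    codes: pd.DataFrame  # index: line IDs, columns: marker IDs, float

    def __post_init__(self) -> None:
        codes = self.codes.astype(float)
        if codes.index.duplicated().any():
            dups = codes.index[codes.index.duplicated()].tolist()
            raise TrialDataError(f"duplicated line IDs in marker matrix: {dups}")
        if codes.shape[1] < 1:
            raise TrialDataError("marker matrix needs at least one marker")
        vals = codes.to_numpy()
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            r, c = np.argwhere(~ok)[0]
            raise TrialDataError(
                f"marker code {vals[r, c]!r} outside {{0,1,2}} at line "
                f"{codes.index[r]!r}, marker {codes.columns[c]!r}"
            )
        codes.index = codes.index.astype(str)
        self.codes = codes

    @property
    def line_ids(self) -> list[str]:
        return list(self.codes.index)

    @property
    def n_lines(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    def missing_fraction(self) -> pd.Series:
        """Per-marker fraction of missing calls."""
        return self.codes.isna().mean(axis=0)

    def filter_missing(self, max_fraction: float = 1.0) -> "MarkerMatrix":
        keep = self.missing_fraction() <= max_fraction
        if not keep.any():
            raise TrialDataError("no markers survive the missing-rate filter")
        return MarkerMatrix(self.codes.loc[:, keep])

    def to_csv(self, path, sep: str = ",") -> None:
        out = self.codes.copy()
        out.index.name = "line"
        # integers where observed, empty cells for missing
        out.to_csv(path, sep=sep, float_format="%.0f", na_rep="")


@dataclass
class IncidenceMatrix:
    """Binary records x factor-levels design matrix (each row sums to 1)."""

    values: np.ndarray
    levels: list[str] = field(default_factory=list)
    factor: str = ""

    def __post_init__(self) -> None:
        Z = np.asarray(self.values, dtype=float)
        if Z.ndim != 2 or Z.shape[1] != len(self.levels):
            raise TrialDataError("incidence shape inconsistent with level labels")
        if not np.array_equal(Z.sum(axis=1), np.ones(Z.shape[0])):
            raise TrialDataError("incidence rows must each sum to exactly 1")
        self.values = Z


def load_phenotype_table(
    path,
    column_map: dict[str, str] | None = None,
    *,
    sep: str = ",",
    duplicate_policy: str = "error",
) -> TrialTable:
    """Read a delimited phenotype file into a validated :class:`TrialTable`.

    Parameters
    ----------
    column_map
        Maps semantic roles (``line, env, year, location, soil, yield``)
        to the file's column names; defaults to the canonical names.
    duplicate_policy
        ``"error"`` rejects duplicate (line, env) rows; ``"mean"``
        averages their yields into a single record.
    """
    colmap = dict(CANONICAL_COLUMNS)
    if column_map:
        colmap.update(column_map)
    df = pd.read_csv(path, sep=sep, comment="#")
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise TrialDataError(f"missing columns in {path}: {missing}")
    df = df.rename(columns={v: k for k, v in colmap.items()})
    df = df[list(CANONICAL_COLUMNS)]
    y = pd.to_numeric(df["yield"], errors="coerce")
    bad = df.index[df["yield"].notna() & y.isna()]
    if len(bad):
        raise TrialDataError(f"non-numeric yield at rows {bad.tolist()}")
    df["yield"] = y
    if duplicate_policy == "mean":
        df = (
            df.groupby(["line", "env", "year", "location", "soil"], as_index=False, sort=False)[
                "yield"
            ].mean()
        )
        df = df[list(CANONICAL_COLUMNS)]
    elif duplicate_policy != "error":
        raise TrialDataError(f"unknown duplicate policy {duplicate_policy!r}")
    return TrialTable(df)


def load_marker_matrix(path, *, sep: str = ",") -> MarkerMatrix:
    """Read a delimited marker file (first column ``line``) into codes."""
    df = pd.read_csv(path, sep=sep, na_values=["", "NA"], comment="#")
    if df.columns[0] != "line":
        raise TrialDataError(
            f"first marker-file column must be 'line', got {df.columns[0]!r}"
        )
    df = df.set_index("line")
    return MarkerMatrix(df)


def incidence(table: TrialTable, factor: str) -> IncidenceMatrix:
    """Build the 0/1 incidence matrix Z connecting records to factor levels.

    ``factor`` is one of ``line``, ``environment`` (alias ``env``) or
    ``soil``; rows follow the table's record order, columns are the
    sorted observed levels.
    """
    colmap = {"line": "line", "environment": "env", "env": "env", "soil": "soil"}
    if factor not in colmap:
        raise TrialDataError(f"unknown factor {factor!r}; expected one of {FACTORS}")
    col = table.data[colmap[factor]]
    levels = sorted(col.unique())
    index = {lev: i for i, lev in enumerate(levels)}
    Z = np.zeros((len(col), len(levels)))
    Z[np.arange(len(col)), [index[v] for v in col]] = 1.0
    return IncidenceMatrix(Z, levels, factor=colmap[factor])


def align(
    table: TrialTable, markers: MarkerMatrix
) -> tuple[TrialTable, MarkerMatrix, dict]:
    """Restrict phenotypes and markers to their common set of lines.

    Returns the restricted pair plus a report of what was dropped.
    Raises :class:`TrialDataError` if no line is shared.
    """
    pheno_lines = set(table.data["line"])
    marker_lines = set(markers.line_ids)
    common = pheno_lines & marker_lines
    if not common:
        raise TrialDataError("no lines shared between phenotypes and markers")
    dropped_pheno = sorted(pheno_lines - common)
    dropped_marker = sorted(marker_lines - common)
    new_table = table
    if dropped_pheno:
        new_table = TrialTable(table.data[table.data["line"].isin(common)])
    new_markers = markers
    if dropped_marker:
        new_markers = MarkerMatrix(markers.codes.loc[markers.codes.index.isin(common)])
    report = {
        "n_common_lines": len(common),
        "dropped_phenotype_lines": dropped_pheno,
        "dropped_marker_lines": dropped_marker,
        "n_records": new_table.n_records,
    }
    return new_table, new_markers, report
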