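"""Input/output and validation for beta matrices, sample metadata and results.

Beta matrices are CpG x sample tables of methylation fractions in [0, 1].
Everything entering the modeling stages is validated here: a malformed input
raises a typed error and never yields a partial object.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SnitchIOError",
    "ValidationError",
    "BetaMatrix",
    "SampleTable",
    "AnalysisConfig",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_table",
    "write_results",
    "read_classification",
]


class SnitchIOError(RuntimeError):
    """File-level I/O failure (missing file, unknown format, unwritable path)."""


class ValidationError(ValueError):
    """Input fails a structural or range invariant."""


# --------------------------------------------------------------------------- #
# core containers
# --------------------------------------------------------------------------- #


class BetaMatrix:
    """CpG-by-sample matrix of beta values, all in [0, 1], no missing values."""

    def __init__(self, values: pd.DataFrame):
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate CpG ids: {dups[:5]}")
        if values.columns.has_duplicates:
            dups = values.columns[values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        arr = values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = values.columns[
                [not pd.api.types.is_numeric_dtype(values[c]) for c in values.columns]
            ].tolist()
            raise ValidationError(f"non-numeric beta columns: {bad[:5]}")
        if np.isnan(arr).any():
            n_na = int(np.isnan(arr).sum())
            raise ValidationError(f"beta matrix contains {n_na} missing values")
        if (arr < 0).any() or (arr > 1).any():
            bad = np.argwhere((arr < 0) | (arr > 1))[0]
            raise ValidationError(
                "value out of [0,1] at CpG "
                f"{values.index[bad[0]]!r}, sample {values.columns[bad[1]]!r}: "
                f"{arr[bad[0], bad[1]]}"
            )
        self._df = values.astype(float)

    @property
    def frame(self) -> pd.DataFrame:
        return self._df

    @property
    def cpg_ids(self) -> list[str]:
        return self._df.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self._df.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self._df.to_numpy()

    @property
    def n_cpg(self) -> int:
        return self._df.shape[0]

    @property
    def n_sample(self) -> int:
        return self._df.shape[1]

    def subset(self, cpg_ids: Sequence[str]) -> "BetaMatrix":
        missing = [c for c in cpg_ids if c not in self._df.index]
        if missing:
            raise ValidationError(f"CpG ids absent from matrix: {missing[:5]}")
        return BetaMatrix(self._df.loc[list(cpg_ids)])

    def __repr__(self) -> str:  # pragma: no cover
        return f"BetaMatrix(n_cpg={self.n_cpg}, n_sample={self.n_sample})"


class SampleTable:
    """Per-sample metadata: age in years (> 0) plus optional covariates."""

    def __init__(self, table: pd.DataFrame):
        if "sample_id" in table.columns:
            table = table.set_index("sample_id")
        if table.index.has_duplicates:
            dups = table.index[table.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        if "age" not in table.columns:
            raise ValidationError("sample table lacks an 'age' column")
        age = pd.to_numeric(table["age"], errors="coerce")
        if age.isna().any():
            bad = table.index[age.isna()].tolist()
            raise ValidationError(f"non-numeric or missing age for samples: {bad[:5]}")
        if not np.isfinite(age).all() or (age <= 0).any():
            bad = table.index[~np.isfinite(age) | (age <= 0)].tolist()
            raise ValidationError(f"non-positive or non-finite age for samples: {bad[:5]}")
        table = table.copy()
        table["age"] = age.astype(float)
        self._df = table

    @property
    def frame(self) -> pd.DataFrame:
        return self._df

    @property
    def sample_ids(self) -> list[str]:
        return self._df.index.tolist()

    @property
    def age(self) -> np.ndarray:
        return self._df["age"].to_numpy()

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self._df.columns if c != "age"]

    def aligned_to(self, beta: BetaMatrix) -> "SampleTable":
        """Reorder rows to match the beta matrix columns (join on id, not order)."""
        mine, theirs = set(self.sample_ids), set(beta.sample_ids)
        if mine != theirs:
            only_beta = sorted(theirs - mine)
            only_meta = sorted(mine - theirs)
            raise ValidationError(
                "sample ids do not match the beta matrix; "
                f"only in beta matrix: {only_beta[:5]}; only in metadata: {only_meta[:5]}"
            )
        return SampleTable(self._df.loc[beta.sample_ids])

    def design(self, covariates: Sequence[str] | None = None) -> pd.DataFrame:
        """Numeric design columns for the requested covariates.

        Categorical columns are dummy-encoded with the first observed level as
        reference, mirroring the treatment-contrast convention of R model fits.
        """
        cov = list(covariates) if covariates is not None else self.covariate_names
        missing = [c for c in cov if c not in self._df.columns]
        if missing:
            raise ValidationError(f"covariate columns not found: {missing}")
        if not cov:
            return pd.DataFrame(index=self._df.index)
        sub = self._df[cov]
        return pd.get_dummies(sub, drop_first=True, dtype=float)

    def reference_row(self, covariates: Sequence[str] | None = None) -> pd.Series:
        """Reference covariate levels: numeric median, first categorical level."""
        design = self.design(covariates)
        ref = {}
        cov = list(covariates) if covariates is not None else self.covariate_names
        numeric = {c for c in cov if pd.api.types.is_numeric_dtype(self._df[c])}
        for col in design.columns:
            ref[col] = float(design[col].median()) if col in numeric else 0.0
        return pd.Series(ref, dtype=float)

    def __repr__(self) -> str:  # pragma: no cover
        return f"SampleTable(n={len(self._df)}, covariates={self.covariate_names})"


@dataclass
class AnalysisConfig:
    """Run configuration: every analysis threshold in one overridable place.

    Defaults follow the published operating point of the pipeline: 1% BH-FDR
    on each test family, dBIC > 2 to call a trajectory nonlinear, a k=5 age
    smooth, a 99.99% FPCA variance cut-off, and Spearman rho > 0.90 cluster
    merging. ``deswan_centers`` is a (start, stop, step) range over ages.
    """

    alpha_lm: float = 0.01
    alpha_gam: float = 0.01
    alpha_white: float = 0.01
    delta_bic_threshold: float = 2.0
    basis_dim_k: int = 5
    pve_threshold: float = 0.9999
    fpca_knots_cap: int = 35
    fpca_knots_frac: float = 0.8
    merge_rho: float = 0.90
    grid_step_years: float = 1.0
    deswan_centers: tuple[int, int, int] = (31, 78, 2)
    deswan_half_width: float = 15.0
    deswan_fdr_levels: tuple[float, ...] = (0.05, 0.01, 0.001)
    min_cluster_size: int = 5
    kmeans_restarts: int = 25
    covariates: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha_lm", "alpha_gam", "alpha_white"):
            a = getattr(self, name)
            if not 0 < a < 1:
                raise ValidationError(f"{name} must lie in (0,1), got {a}")
        if self.delta_bic_threshold < 0:
            raise ValidationError("delta_bic_threshold must be >= 0")
        if not 0 < self.pve_threshold <= 1:
            raise ValidationError("pve_threshold must lie in (0,1]")
        if not 0 < self.merge_rho < 1:
            raise ValidationError("merge_rho must lie in (0,1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        path = Path(path)
        if not path.exists():
            raise SnitchIOError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("deswan_centers", "deswan_fdr_levels", "covariates"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        for key, value in data.items():
            if isinstance(value, tuple):
                data[key] = list(value)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @property
    def deswan_center_ages(self) -> np.ndarray:
        start, stop, step = self.deswan_centers
        return np.arange(start, stop, step, dtype=float)


# --------------------------------------------------------------------------- #
# readers / writers
# --------------------------------------------------------------------------- #

_FORMATS = ("csv", "tsv", "parquet")


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in _FORMATS:
            raise SnitchIOError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in _FORMATS:
        return suffix
    raise SnitchIOError(f"cannot infer format from suffix {path.suffix!r}; pass format=")


def read_beta_matrix(path: str | Path, format: str | None = None) -> BetaMatrix:
    """Read a CpG-by-sample beta matrix from CSV/TSV/parquet.

    The first column (or the parquet index) holds CpG identifiers; every other
    column must be numeric and within [0, 1].
    """
    path = Path(path)
    if not path.exists():
        raise SnitchIOError(f"beta matrix file not found: {path}")
    fmt = _infer_format(path, format)
    if fmt == "parquet":
        df = pd.read_parquet(path)
        if "cpg_id" in df.columns:
            df = df.set_index("cpg_id")
    else:
        df = pd.read_csv(path, sep="\t" if fmt == "tsv" else ",", index_col=0)
    df.index = df.index.astype(str)
    return BetaMatrix(df)


def write_beta_matrix(
    beta: BetaMatrix,
    path: str | Path,
    format: str | None = None,
    round_decimals: int | None = None,
) -> Path:
    """Write a beta matrix; ``round_decimals=3`` mimics array-preprocessing output."""
    path = Path(path)
    fmt = _infer_format(path, format)
    df = beta.frame
    if round_decimals is not None:
        df = df.round(round_decimals)
    if fmt == "parquet":
        df.reset_index(names="cpg_id").to_parquet(path, index=False)
    else:
        df.to_csv(path, sep="\t" if fmt == "tsv" else ",", index_label="cpg_id")
    return path


def read_sample_table(path: str | Path) -> SampleTable:
    path = Path(path)
    if not path.exists():
        raise SnitchIOError(f"sample table file not found: {path}")
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    if "sample_id" not in df.columns:
        raise ValidationError("sample table lacks a 'sample_id' column")
    df["sample_id"] = df["sample_id"].astype(str)
    return SampleTable(df)


def write_results(obj: Any, path: str | Path, format: str | None = None) -> Path:
    """Serialize a result object (DataFrame -> CSV, mapping/dataclass -> JSON)."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    try:
        if fmt == "csv":
            frame = obj if isinstance(obj, pd.DataFrame) else getattr(obj, "to_frame")()
            frame.to_csv(path, index=False)
        elif fmt == "json":
            if hasattr(obj, "to_dict"):
                data = obj.to_dict()
            elif dataclasses.is_dataclass(obj):
                data = dataclasses.asdict(obj)
            else:
                data = obj
            path.write_text(json.dumps(data, indent=1, default=_json_default))
        else:
            raise SnitchIOError(f"unknown results format {fmt!r}")
    except OSError as exc:
        raise SnitchIOError(f"cannot write {path}: {exc}") from exc
    return path


def _json_default(value: Any) -> Any:
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    raise TypeError(f"not JSON-serializable: {type(value)}")


def read_classification(path: str | Path) -> pd.DataFrame:
    """Read back a classification table written by :func:`write_results`."""
    path = Path(path)
    if not path.exists():
        raise SnitchIOError(f"classification file not found: {path}")
    df = pd.read_csv(path)
    required = {"cpg_id", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"classification table lacks columns: {sorted(missing)}")
    return df
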