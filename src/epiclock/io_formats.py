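"""Tabular I/O: beta matrices, sample annotations, coefficient tables, predictions.

All formats are plain CSV (UTF-8, header row mandatory, comma-separated).
Empty cells and the sentinel ``NA`` denote missing values.  Beta matrices are
held probe-major (probes x samples) in memory regardless of file orientation.
Coefficient files follow the published clock convention: a ``CpGmarker``
column of probe ids with one reserved ``(Intercept)`` row, and one or more
numeric coefficient columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BetaMatrix",
    "SampleTable",
    "CoefficientTable",
    "FormatError",
    "BoundsError",
    "INTERCEPT_TOKEN",
    "load_beta_matrix",
    "load_sample_table",
    "load_coefficients",
    "save_beta_matrix",
    "save_sample_table",
    "save_coefficients",
    "save_predictions",
    "load_predictions",
]

INTERCEPT_TOKEN = "(Intercept)"

#: default column names of the coefficient-file dialect; load_coefficients
#: accepts a mapping to rename nonstandard headers onto these.
PROBE_COL = "CpGmarker"
COEF_COL = "CoefficientTraining"
SHRUNK_COL = "CoefficientTrainingShrunk"

_BOUNDS_TOL = 1e-9


class FormatError(ValueError):
    """Structural problem in an input table (duplicates, missing columns...)."""


class BoundsError(ValueError):
    """A numeric value violates its domain (beta outside [0,1], negative age)."""


@dataclass
class BetaMatrix:
    """Probes x samples matrix of methylation beta values.

    ``values`` is a float DataFrame indexed by probe id with sample-id
    columns; missing entries are NaN.  All non-missing values lie in [0, 1].
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()][0]
            raise FormatError(f"duplicate probe id: {dup!r}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        arr = v.to_numpy(dtype=float)
        bad = (arr < -_BOUNDS_TOL) | (arr > 1.0 + _BOUNDS_TOL)
        if np.any(bad & ~np.isnan(arr)):
            i, j = np.argwhere(bad & ~np.isnan(arr))[0]
            raise BoundsError(
                f"beta value {arr[i, j]} outside [0,1] at probe "
                f"{v.index[i]!r}, sample {v.columns[j]!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def missing_per_probe(self) -> pd.Series:
        """Count of missing entries for each probe."""
        return self.values.isna().sum(axis=1)

    def equals(self, other: "BetaMatrix", tol: float = 1e-9) -> bool:
        a, b = self.values, other.values
        if list(a.index) != list(b.index) or list(a.columns) != list(b.columns):
            return False
        x, y = a.to_numpy(float), b.to_numpy(float)
        same_nan = np.isnan(x) == np.isnan(y)
        close = np.isclose(x, y, atol=tol, equal_nan=True)
        return bool(np.all(same_nan) and np.all(close | np.isnan(x)))


@dataclass
class SampleTable:
    """Per-sample annotation: age (years), tissue, dataset id, twin structure.

    ``data`` is indexed by sample_id.  Recognized columns: ``age``,
    ``tissue``, ``dataset_id``, ``sex``, ``pair_id``, ``zygosity``,
    ``passage_number``; any other column is carried through untouched.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        d = self.data
        if d.index.has_duplicates:
            dup = d.index[d.index.duplicated()][0]
            raise FormatError(f"duplicate sample_id: {dup!r}")
        if "age" in d.columns:
            ages = pd.to_numeric(d["age"], errors="coerce")
            neg = ages < 0
            if neg.any():
                sid = d.index[neg.to_numpy().nonzero()[0][0]]
                raise BoundsError(f"negative age for sample {sid!r}")
            self.data = d = d.assign(age=ages)
        if "zygosity" in d.columns:
            self._check_pairs(d)

    @staticmethod
    def _check_pairs(d: pd.DataFrame) -> None:
        zy = d["zygosity"].dropna()
        bad = set(zy.unique()) - {"MZ", "DZ"}
        if bad:
            raise FormatError(f"unknown zygosity labels: {sorted(bad)}")
        if "pair_id" not in d.columns:
            raise FormatError("zygosity column present without pair_id")
        paired = d.loc[zy.index]
        for pid, grp in paired.groupby("pair_id"):
            if len(grp) != 2:
                raise FormatError(
                    f"pair_id {pid!r} occurs {len(grp)} time(s); expected exactly 2"
                )
            if grp["zygosity"].nunique() != 1:
                raise FormatError(f"pair_id {pid!r} has inconsistent zygosity")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def ages(self) -> pd.Series:
        return self.data["age"]

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class CoefficientTable:
    """Sparse clock coefficients plus intercept, with optional extras.

    ``coefficients`` maps probe id -> weight (main column); ``intercept`` is
    stored separately.  ``extras`` keeps any additional per-probe columns from
    the file (shrunken coefficients, young/old median betas, variance...),
    indexed by probe id, with the intercept row dropped.
    """

    coefficients: dict[str, float]
    intercept: float
    extras: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def clock_size(self) -> int:
        return len(self.coefficients)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.coefficients)

    def equals(self, other: "CoefficientTable", tol: float = 1e-9) -> bool:
        if set(self.coefficients) != set(other.coefficients):
            return False
        if abs(self.intercept - other.intercept) > tol:
            return False
        return all(
            abs(w - other.coefficients[p]) <= tol
            for p, w in self.coefficients.items()
        )


# ---------------------------------------------------------------------------
# loaders

def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def _parse_numeric_block(raw: pd.DataFrame, kind: str) -> pd.DataFrame:
    """Parse a string DataFrame into floats; '' and 'NA' become NaN."""
    def parse(col: pd.Series) -> pd.Series:
        cleaned = col.mask(col.isin(["", "NA", "NaN", "nan"]))
        out = pd.to_numeric(cleaned, errors="coerce")
        bad = out.isna() & cleaned.notna()
        if bad.any():
            row = col.index[bad.to_numpy().nonzero()[0][0]]
            raise FormatError(
                f"non-numeric {kind} value {col.loc[row]!r} at row {row!r}, "
                f"column {col.name!r}"
            )
        return out

    return raw.apply(parse)


def load_beta_matrix(path, orientation: str = "probes_as_rows") -> BetaMatrix:
    """Load a beta-value CSV into the canonical probes x samples layout.

    The first column holds row identifiers and the header row holds column
    identifiers.  ``orientation`` declares what the file's rows are:
    ``"probes_as_rows"`` (default) or ``"samples_as_rows"``; the latter is
    transposed on load so downstream code always sees probes x samples.
    """
    if orientation not in ("probes_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    raw = _read_csv(path)
    ids = raw.iloc[:, 0]
    block = raw.iloc[:, 1:].set_axis(ids, axis=0)
    values = _parse_numeric_block(block, "beta")
    if orientation == "samples_as_rows":
        values = values.T
    values.index.name = "probe_id"
    values.columns.name = "sample_id"
    return BetaMatrix(values)


def save_beta_matrix(betas: BetaMatrix, path, orientation: str = "probes_as_rows"):
    values = betas.values if orientation == "probes_as_rows" else betas.values.T
    values.to_csv(path, na_rep="NA", float_format="%.10g",
                  index_label="probe_id" if orientation == "probes_as_rows" else "sample_id")
    return Path(path)


def load_sample_table(path) -> SampleTable:
    """Load a per-sample annotation CSV (must contain sample_id and age)."""
    raw = _read_csv(path)
    if "sample_id" not in raw.columns:
        raise FormatError("sample annotation file lacks a 'sample_id' column")
    if "age" not in raw.columns:
        raise FormatError("sample annotation file lacks an 'age' column")
    d = raw.mask(raw.isin(["", "NA"])).set_index("sample_id")
    age = pd.to_numeric(d["age"], errors="coerce")
    bad = age.isna() & d["age"].notna()
    if bad.any():
        sid = d.index[bad.to_numpy().nonzero()[0][0]]
        raise FormatError(f"non-numeric age for sample {sid!r}")
    d["age"] = age
    if "passage_number" in d.columns:
        d["passage_number"] = pd.to_numeric(d["passage_number"], errors="coerce")
    return SampleTable(d)


def save_sample_table(samples: SampleTable, path):
    samples.data.to_csv(path, na_rep="NA", index_label="sample_id")
    return Path(path)


def load_coefficients(path, column_map: dict[str, str] | None = None) -> CoefficientTable:
    """Load a clock coefficient CSV (published supplementary-table layout).

    Expects a probe-id column ``CpGmarker`` with exactly one reserved
    ``(Intercept)`` row, and a fully populated ``CoefficientTraining``
    column.  ``column_map`` renames nonstandard headers onto this dialect,
    e.g. ``{"probe": "CpGmarker"}``.  Row order is irrelevant.
    """
    raw = _read_csv(path)
    if column_map:
        raw = raw.rename(columns=column_map)
    if PROBE_COL not in raw.columns:
        raise FormatError(f"coefficient file lacks a {PROBE_COL!r} column")
    if COEF_COL not in raw.columns:
        raise FormatError(f"coefficient file lacks a {COEF_COL!r} column")
    probes = raw[PROBE_COL]
    if probes.duplicated().any():
        dup = probes[probes.duplicated()].iloc[0]
        raise FormatError(f"duplicate probe id: {dup!r}")
    n_icpt = int((probes == INTERCEPT_TOKEN).sum())
    if n_icpt != 1:
        raise FormatError(
            f"coefficient file must contain exactly one {INTERCEPT_TOKEN!r} row, "
            f"found {n_icpt}"
        )
    block = raw.set_index(PROBE_COL)
    numeric = _parse_numeric_block(block, "coefficient")
    if numeric[COEF_COL].isna().any():
        missing = numeric.index[numeric[COEF_COL].isna()][0]
        raise FormatError(f"missing {COEF_COL} value for {missing!r}")
    intercept = float(numeric.loc[INTERCEPT_TOKEN, COEF_COL])
    body = numeric.drop(index=INTERCEPT_TOKEN)
    coefficients = dict(body[COEF_COL].astype(float))
    extras = body.drop(columns=[COEF_COL])
    return CoefficientTable(coefficients=coefficients, intercept=intercept, extras=extras)


def save_coefficients(table: CoefficientTable, path):
    rows = pd.DataFrame({COEF_COL: pd.Series(table.coefficients, dtype=float)})
    if not table.extras.empty:
        rows = rows.join(table.extras, how="left")
    icpt = pd.DataFrame({COEF_COL: [table.intercept]}, index=[INTERCEPT_TOKEN])
    out = pd.concat([icpt, rows])
    out.index.name = PROBE_COL
    out.to_csv(path, na_rep="NA", float_format="%.10g")
    return Path(path)


def save_predictions(table: pd.DataFrame, path):
    """Write a per-sample prediction table (sample_id index) to CSV.

    Columns typically include ``dnam_age``, ``age``, ``acceleration_diff``,
    ``acceleration_resid``; missing values are written as NA.  Numeric
    formatting keeps at least 10 significant digits so a round trip
    reproduces predictions to well under 1e-6.
    """
    table.to_csv(path, na_rep="NA", float_format="%.10g", index_label="sample_id")
    return Path(path)


def load_predictions(path) -> pd.DataFrame:
    raw = _read_csv(path)
    if "sample_id" not in raw.columns:
        raise FormatError("prediction file lacks a 'sample_id' column")
    d = raw.mask(raw.isin(["", "NA"])).set_index("sample_id")
    # numeric columns parse cleanly; leave genuinely textual columns alone
    for col in d.columns:
        parsed = pd.to_numeric(d[col], errors="coerce")
        if parsed.notna().sum() >= d[col].notna().sum():
            d[col] = parsed
    return d
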