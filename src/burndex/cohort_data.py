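"""Core data model for per-rat cohort tables and group summary tables.

A cohort is a rats-by-measurements matrix.  Every measurement series is
identified by a :class:`VariableKey` -- an analyte measured in one of the
three sampled blood compartments (hepatic artery HA, portal vein PV,
suprahepatic vena cava SHVC) or as a derived trans-liver flux (FLUX).
Columns are named ``analyte@compartment`` in the CSV dialect, missing
cells are empty, and missingness is represented internally as NaN (never
zero).  Units differ between analytes (mg/dL, uM, %, mmHg, mL/min) and
are carried as opaque metadata only; no conversion is attempted.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

COMPARTMENTS: tuple[str, ...] = ("HA", "PV", "SHVC", "FLUX")
#: the directly measured vessel compartments (fluxes are derived)
VESSELS: tuple[str, ...] = ("HA", "PV", "SHVC")

#: ordered burn-extent levels of the study design (% of total body surface area)
STUDY_LEVELS: tuple[float, ...] = (0.0, 20.0, 40.0)


class CohortError(ValueError):
    """Raised for malformed cohort tables or files."""


class SummaryParseError(ValueError):
    """Raised for malformed group-summary fixture files."""


@dataclass(frozen=True, order=True)
class VariableKey:
    """Identity of one measurement series: an analyte in a compartment."""

    analyte: str
    compartment: str

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise CohortError(
                f"unknown compartment {self.compartment!r}; expected one of {COMPARTMENTS}"
            )
        if not self.analyte or "@" in self.analyte:
            raise CohortError(f"invalid analyte name {self.analyte!r}")

    @property
    def column(self) -> str:
        return f"{self.analyte}@{self.compartment}"

    @classmethod
    def from_column(cls, name: str) -> "VariableKey":
        analyte, sep, compartment = name.rpartition("@")
        if not sep or not analyte:
            raise CohortError(f"column {name!r} is not of the form analyte@compartment")
        return cls(analyte, compartment)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.column


@dataclass(frozen=True)
class GroupLabel:
    """Burn extent as %TBSA; 0 denotes the sham group."""

    tbsa_percent: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.tbsa_percent) or self.tbsa_percent < 0:
            raise CohortError(f"invalid %TBSA {self.tbsa_percent!r}")


@dataclass(frozen=True)
class FluxInputs:
    """Blood flows (mL/min) into the liver and the liver mass (g).

    Outflow through the hepatic veins is taken equal to the summed inflow.
    """

    flow_pv: float
    flow_ha: float
    liver_weight: float

    def __post_init__(self) -> None:
        for name in ("flow_pv", "flow_ha", "liver_weight"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise CohortError(f"{name} must be strictly positive, got {v!r}")


class CohortTable:
    """Rats x measurements with %TBSA group labels; missing cells are NaN."""

    def __init__(
        self,
        values: pd.DataFrame,
        tbsa: pd.Series,
        units: Mapping[str, str] | None = None,
    ) -> None:
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].tolist()
            raise CohortError(f"duplicate rat_id(s): {dups}")
        # validates every column name
        self._variables = [VariableKey.from_column(c) for c in values.columns]
        if len(set(self._variables)) != len(self._variables):
            raise CohortError("duplicate variable columns")
        tbsa = tbsa.reindex(values.index)
        if tbsa.isna().any():
            missing = tbsa.index[tbsa.isna()].tolist()
            raise CohortError(f"missing tbsa label for rat(s): {missing}")
        self.values = values.astype(float)
        self.tbsa = tbsa.astype(float)
        self.units = dict(units or {})

    # -- basic views ---------------------------------------------------
    @property
    def rat_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_rats(self) -> int:
        return len(self.values)

    @property
    def variables(self) -> list[VariableKey]:
        return list(self._variables)

    @property
    def levels(self) -> list[float]:
        return sorted(self.tbsa.unique())

    def group_rats(self, level: float) -> pd.Index:
        return self.values.index[self.tbsa == level]

    def group_sizes(self) -> dict[float, int]:
        return {lv: int((self.tbsa == lv).sum()) for lv in self.levels}

    def concentration_columns(self) -> list[str]:
        """The directly measured vessel series (derived FLUX columns excluded)."""
        return [v.column for v in self._variables if v.compartment != "FLUX"]

    def missing_fraction(self, columns: Sequence[str] | None = None) -> pd.Series:
        cols = list(columns) if columns is not None else list(self.values.columns)
        return self.values[cols].isna().mean(axis=1)

    def copy(self) -> "CohortTable":
        return CohortTable(self.values.copy(), self.tbsa.copy(), self.units)

    def equals(self, other: "CohortTable") -> bool:
        return (
            self.values.sort_index(axis=1).equals(other.values.sort_index(axis=1))
            and self.tbsa.equals(other.tbsa)
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"CohortTable({self.n_rats} rats x {len(self._variables)} measurements)"


def _canonical_columns(variables: Iterable[VariableKey]) -> list[str]:
    order = {c: i for i, c in enumerate(COMPARTMENTS)}
    return [
        v.column
        for v in sorted(variables, key=lambda v: (v.analyte, order[v.compartment]))
    ]


def read_cohort(path) -> CohortTable:
    """Read a cohort CSV (``rat_id,tbsa,analyte@compartment,...``; empty = missing)."""
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    for required in ("rat_id", "tbsa"):
        if required not in raw.columns:
            raise CohortError(f"cohort file lacks required column {required!r}")
    raw = raw.set_index("rat_id")
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].tolist()
        raise CohortError(f"duplicate rat_id(s): {dups}")

    def to_float(col: pd.Series) -> pd.Series:
        # python's float() is correctly rounded (pandas' fast parser is not),
        # which keeps write -> read bit-identical for finite values
        def parse(cell: str, rat) -> float:
            if cell == "":
                return np.nan
            try:
                return float(cell)
            except ValueError:
                raise CohortError(
                    f"non-numeric cell {cell!r} in column {col.name!r}, rat {rat!r}"
                ) from None

        return pd.Series(
            [parse(c, r) for r, c in col.items()], index=col.index, name=col.name
        )

    tbsa = to_float(raw["tbsa"])
    values = raw.drop(columns="tbsa").apply(to_float)
    return CohortTable(values, tbsa)


def write_cohort(table: CohortTable, path) -> None:
    """Write a cohort CSV in the canonical column order (round-trips exactly)."""
    out = table.values[_canonical_columns(table.variables)].copy()
    out.insert(0, "tbsa", table.tbsa)
    out.index.name = "rat_id"
    out.to_csv(path)


# ---------------------------------------------------------------------------
# Group summary tables (per-variable median and IQR per burn group)
# ---------------------------------------------------------------------------

_SUMMARY_COLUMNS = (
    "analyte",
    "vessel",
    "paper_cluster",
    "median_sham",
    "iqr_sham",
    "median_20",
    "iqr_20",
    "median_40",
    "iqr_40",
)


class GroupSummaryTable:
    """One record per variable series: median and IQR per burn group.

    This mirrors the published summary table of the study (55 analytes in
    each of the three vessels), optionally with the cluster label the
    original analysis assigned to each series.
    """

    def __init__(self, records: pd.DataFrame, levels: Sequence[float] = STUDY_LEVELS):
        for col in _SUMMARY_COLUMNS:
            if col not in records.columns:
                raise SummaryParseError(f"summary lacks column {col!r}")
        keys = list(zip(records["analyte"], records["vessel"]))
        if len(set(keys)) != len(keys):
            raise SummaryParseError("duplicate (analyte, vessel) records")
        iqr_cols = ["iqr_sham", "iqr_20", "iqr_40"]
        if (records[iqr_cols].to_numpy(float) < 0).any():
            raise SummaryParseError("negative IQR in summary")
        self.records = records.reset_index(drop=True)
        self.levels = tuple(float(v) for v in levels)

    def __len__(self) -> int:
        return len(self.records)

    def keys(self) -> list[VariableKey]:
        return [
            VariableKey(a, v)
            for a, v in zip(self.records["analyte"], self.records["vessel"])
        ]

    def _row(self, key: VariableKey) -> pd.Series:
        m = (self.records["analyte"] == key.analyte) & (
            self.records["vessel"] == key.compartment
        )
        if not m.any():
            raise KeyError(key)
        return self.records[m].iloc[0]

    def medians(self, key: VariableKey) -> np.ndarray:
        r = self._row(key)
        return np.array([r["median_sham"], r["median_20"], r["median_40"]], float)

    def iqrs(self, key: VariableKey) -> np.ndarray:
        r = self._row(key)
        return np.array([r["iqr_sham"], r["iqr_20"], r["iqr_40"]], float)

    def paper_cluster(self, key: VariableKey) -> int | None:
        v = self._row(key)["paper_cluster"]
        return None if pd.isna(v) else int(v)

    def paper_assignment(self) -> dict[VariableKey, int]:
        """The published cluster label per series (only labelled records)."""
        out: dict[VariableKey, int] = {}
        for _, r in self.records.iterrows():
            if not pd.isna(r["paper_cluster"]):
                out[VariableKey(r["analyte"], r["vessel"])] = int(r["paper_cluster"])
        return out


def load_summary_fixture(path) -> GroupSummaryTable:
    """Load a group-summary CSV, reporting the offending line on any defect."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SummaryParseError(f"{path}: empty file") from None
        missing = [c for c in _SUMMARY_COLUMNS if c not in header]
        if missing:
            raise SummaryParseError(f"{path}: header lacks columns {missing}")
        idx = {c: header.index(c) for c in header}
        rows = []
        seen: set[tuple[str, str]] = set()
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c for c in row):
                continue
            if len(row) != len(header):
                raise SummaryParseError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}"
                )
            rec: dict[str, object] = {
                "analyte": row[idx["analyte"]],
                "vessel": row[idx["vessel"]],
            }
            if rec["vessel"] not in COMPARTMENTS:
                raise SummaryParseError(
                    f"{path}:{lineno}: unknown vessel {rec['vessel']!r}"
                )
            key = (row[idx["analyte"]], row[idx["vessel"]])
            if key in seen:
                raise SummaryParseError(f"{path}:{lineno}: duplicate key {key}")
            seen.add(key)
            for col in _SUMMARY_COLUMNS[2:]:
                cell = row[idx[col]]
                try:
                    val = float(cell) if cell != "" else np.nan
                except ValueError:
                    raise SummaryParseError(
                        f"{path}:{lineno}: non-numeric {col} value {cell!r}"
                    ) from None
                if col.startswith("iqr") and np.isfinite(val) and val < 0:
                    raise SummaryParseError(f"{path}:{lineno}: negative IQR {val}")
                rec[col] = val
            for extra in ("source_row", "printed_label"):
                if extra in idx:
                    rec[extra] = row[idx[extra]]
            rows.append(rec)
        if not rows:
            raise SummaryParseError(f"{path}: no records")
    return GroupSummaryTable(pd.DataFrame(rows))


def packaged_summary() -> GroupSummaryTable:
    """The packaged transcription of the study's printed summary table.

    165 series (55 analytes x 3 vessels) with per-group medians, IQRs and
    the published cluster labels.  Transcribed as printed; the one row whose
    printed enzyme label is ambiguous (the second aminotransferase row in HA)
    is keyed as AST, with the printed wording preserved in ``printed_label``.
    """
    with resources.as_file(
        resources.files("burndex.data") / "table1_summary.csv"
    ) as p:
        return load_summary_fixture(p)


def packaged_index_predictions() -> pd.DataFrame:
    """The published per-rat predictions of the final severity-index models.

    21 rats (7 sham, 7 at 20% TBSA, 7 at 40% TBSA) with the predicted %TBSA
    of the 2-, 3-, 4- and 5-variable neural-network indices trained on all
    data.  Used to validate the relative-absolute-error metric.
    """
    with resources.as_file(
        resources.files("burndex.data") / "table5_predictions.csv"
    ) as p:
        return pd.read_csv(p)
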