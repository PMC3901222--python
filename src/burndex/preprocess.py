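"""Preprocessing of per-rat cohorts and dose-response profile construction.

The pipeline order is fixed: outlier masking -> rat filtering -> group-median
imputation -> (optional) trans-liver flux derivation -> per-group profiles
normalized to [-1, 1].  Each destructive stage returns a report so the full
audit trail composes.

Quartiles use linear interpolation on the sorted sample (numpy's default,
"type 7"); the convention is configurable because the original analysis
environment did not document one.  With a zero IQR the outlier fence
collapses onto the median, so any value differing from the median is masked;
a warning is emitted for that edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .cohort_data import (
    CohortError,
    CohortTable,
    FluxInputs,
    GroupSummaryTable,
    VariableKey,
)

logger = logging.getLogger(__name__)

#: multiplier of the IQR on each side of the median defining the outlier fence
OUTLIER_FENCE_IQR = 2.0
#: rats with a missing fraction strictly above this are excluded
MAX_MISSING_FRACTION = 0.30


@dataclass
class DoseResponseProfile:
    """Per-group response of one variable, raw and normalized to [-1, 1]."""

    variable: VariableKey
    levels: tuple[float, ...]
    raw: np.ndarray
    normalized: np.ndarray


@dataclass
class PreprocessReport:
    """Audit trail of one preprocessing stage (or a composition of stages)."""

    masked: dict[str, dict[float, int]] = field(default_factory=dict)
    removed_rats: dict[str, float] = field(default_factory=dict)
    imputed: dict[str, int] = field(default_factory=dict)

    @property
    def n_masked(self) -> int:
        return sum(sum(g.values()) for g in self.masked.values())

    @property
    def n_imputed(self) -> int:
        return sum(self.imputed.values())

    def merge(self, other: "PreprocessReport") -> "PreprocessReport":
        out = PreprocessReport(
            {k: dict(v) for k, v in self.masked.items()},
            dict(self.removed_rats),
            dict(self.imputed),
        )
        for col, per_group in other.masked.items():
            tgt = out.masked.setdefault(col, {})
            for g, n in per_group.items():
                tgt[g] = tgt.get(g, 0) + n
        out.removed_rats.update(other.removed_rats)
        for col, n in other.imputed.items():
            out.imputed[col] = out.imputed.get(col, 0) + n
        return out

    def to_dict(self) -> dict:
        return {
            "masked": {c: {str(g): n for g, n in d.items()} for c, d in self.masked.items()},
            "removed_rats": self.removed_rats,
            "imputed": self.imputed,
            "n_masked": self.n_masked,
            "n_imputed": self.n_imputed,
        }


def _iqr(x: np.ndarray, method: str) -> tuple[float, float]:
    q1, q3 = np.percentile(x, [25, 75], method=method)
    return float(np.median(x)), float(q3 - q1)


def mask_outliers(
    table: CohortTable, quartile_method: str = "linear"
) -> tuple[CohortTable, PreprocessReport]:
    """Mask cells outside median +/- 2*IQR of their (variable, group).

    The median and IQR are computed on the pre-masking observed values, so
    the fence does not move as cells are removed.  Empty (variable, group)
    cells are left untouched with a warning.
    """
    values = table.values.copy()
    report = PreprocessReport()
    for col in values.columns:
        for level in table.levels:
            rats = table.group_rats(level)
            cell = values.loc[rats, col]
            obs = cell.dropna().to_numpy(float)
            if obs.size == 0:
                logger.warning("no observed values for %s in group %g", col, level)
                continue
            med, iqr = _iqr(obs, quartile_method)
            if iqr == 0 and (obs != med).any():
                logger.warning(
                    "zero IQR with varying values for %s in group %g: "
                    "fence collapses to the median",
                    col,
                    level,
                )
            lo, hi = med - OUTLIER_FENCE_IQR * iqr, med + OUTLIER_FENCE_IQR * iqr
            bad = cell.notna() & ((cell < lo) | (cell > hi))
            if bad.any():
                values.loc[cell.index[bad], col] = np.nan
                report.masked.setdefault(col, {})[level] = int(bad.sum())
    return CohortTable(values, table.tbsa.copy(), table.units), report


def filter_rats(
    table: CohortTable, max_missing_frac: float = MAX_MISSING_FRACTION
) -> tuple[CohortTable, PreprocessReport]:
    """Drop rats whose missing fraction exceeds ``max_missing_frac`` (strictly).

    The fraction is computed over the directly measured vessel-concentration
    columns only; derived flux columns do not count.  Survivor order is
    preserved.
    """
    cols = table.concentration_columns()
    if not cols:
        raise CohortError("cohort has no measurement columns")
    frac = table.missing_fraction(cols)
    drop = frac > max_missing_frac
    if drop.all():
        raise CohortError("empty cohort after filtering")
    report = PreprocessReport(
        removed_rats={r: float(frac[r]) for r in frac.index[drop]}
    )
    keep = frac.index[~drop]
    return (
        CohortTable(table.values.loc[keep], table.tbsa.loc[keep], table.units),
        report,
    )


def impute_group_median(table: CohortTable) -> tuple[CohortTable, PreprocessReport]:
    """Replace every missing cell by the median of its (variable, group).

    Errors if a (variable, group) is entirely missing.  Idempotent.
    """
    values = table.values.copy()
    report = PreprocessReport()
    for col in values.columns:
        if not values[col].isna().any():
            continue
        n_filled = 0
        for level in table.levels:
            rats = table.group_rats(level)
            cell = values.loc[rats, col]
            miss = cell.isna()
            if not miss.any():
                continue
            obs = cell.dropna()
            if obs.empty:
                raise CohortError(
                    f"cannot impute {col!r} in group {level:g}: no observed values"
                )
            values.loc[cell.index[miss], col] = float(obs.median())
            n_filled += int(miss.sum())
        report.imputed[col] = n_filled
    return CohortTable(values, table.tbsa.copy(), table.units), report


# ---------------------------------------------------------------------------
# Trans-liver flux
# ---------------------------------------------------------------------------

def compute_flux(conc_ha, conc_pv, conc_shvc, fx: FluxInputs):
    """Net trans-liver flux per gram of liver (positive = release by liver).

    Inflow is carried by the portal vein and hepatic artery, outflow by the
    hepatic veins; the outflow rate equals the summed inflow rates.  The flux
    is the concentration-weighted flow difference normalized by liver mass:

        ((Q_pv + Q_ha) * C_shvc - Q_pv * C_pv - Q_ha * C_ha) / W_liver
    """
    q_out = fx.flow_pv + fx.flow_ha
    return (
        np.asarray(conc_shvc) * q_out
        - np.asarray(conc_pv) * fx.flow_pv
        - np.asarray(conc_ha) * fx.flow_ha
    ) / fx.liver_weight


def derive_fluxes(
    table: CohortTable,
    liver_weights: pd.Series | float,
    flow_variable: str = "FlowRate",
) -> CohortTable:
    """Append a FLUX series for every analyte measured in all three vessels.

    Per-rat flow rates are taken from the cohort's own ``FlowRate@PV`` and
    ``FlowRate@HA`` columns; ``liver_weights`` is a per-rat Series or a
    scalar (g).  Must run on an imputed table so no flux is built from a
    missing concentration.
    """
    need = {f"{flow_variable}@PV", f"{flow_variable}@HA"}
    if not need <= set(table.values.columns):
        raise CohortError(f"cohort lacks flow columns {sorted(need)}")
    if np.isscalar(liver_weights):
        liver_weights = pd.Series(float(liver_weights), index=table.values.index)
    liver_weights = liver_weights.reindex(table.values.index)
    if liver_weights.isna().any() or (liver_weights <= 0).any():
        raise CohortError("liver weights must be strictly positive for every rat")
    q_pv = table.values[f"{flow_variable}@PV"]
    q_ha = table.values[f"{flow_variable}@HA"]
    values = table.values.copy()
    by_analyte: dict[str, set[str]] = {}
    for v in table.variables:
        if v.compartment != "FLUX":
            by_analyte.setdefault(v.analyte, set()).add(v.compartment)
    for analyte, comps in by_analyte.items():
        if analyte == flow_variable or comps != {"HA", "PV", "SHVC"}:
            continue
        flux = (
            values[f"{analyte}@SHVC"] * (q_pv + q_ha)
            - values[f"{analyte}@PV"] * q_pv
            - values[f"{analyte}@HA"] * q_ha
        ) / liver_weights
        values[VariableKey(analyte, "FLUX").column] = flux
    return CohortTable(values, table.tbsa.copy(), table.units)


# ---------------------------------------------------------------------------
# Dose-response profiles
# ---------------------------------------------------------------------------

def normalize_profile(raw: np.ndarray) -> np.ndarray:
    """Affine map of a profile onto [-1, 1] (min -> -1, max -> +1).

    A constant profile maps to all zeros.  Invariant under positive affine
    rescaling of the raw values, so profiles are unit-free.
    """
    raw = np.asarray(raw, float)
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return np.zeros_like(raw)
    return 2.0 * (raw - lo) / (hi - lo) - 1.0


def group_profiles(
    table: CohortTable,
    use_statistic: str | Callable[[np.ndarray], float] = "mean",
) -> list[DoseResponseProfile]:
    """Per-variable per-group statistic (default mean), normalized to [-1, 1].

    Requires an imputed table and at least two dose levels.  ``use_statistic``
    may be ``"mean"``, ``"median"`` or any callable reducing a 1-D array.
    """
    levels = table.levels
    if len(levels) < 2:
        raise CohortError("need at least two dose levels for a profile")
    if table.values.isna().any().any():
        raise CohortError("group_profiles requires an imputed (complete) table")
    if callable(use_statistic):
        stat = use_statistic
    elif use_statistic == "mean":
        stat = np.mean
    elif use_statistic == "median":
        stat = np.median
    else:
        raise ValueError(f"unknown statistic {use_statistic!r}")
    groups = {lv: table.group_rats(lv) for lv in levels}
    out = []
    for key in table.variables:
        raw = np.array(
            [stat(table.values.loc[groups[lv], key.column].to_numpy(float)) for lv in levels]
        )
        out.append(
            DoseResponseProfile(key, tuple(levels), raw, normalize_profile(raw))
        )
    return out


def profiles_from_summary(summary: GroupSummaryTable) -> list[DoseResponseProfile]:
    """Profiles built from a summary table's printed group medians.

    Stands in for the per-rat group averages when only the published
    median/IQR summary is available; deterministic.
    """
    out = []
    for key in summary.keys():
        raw = summary.medians(key)
        out.append(
            DoseResponseProfile(key, summary.levels, raw, normalize_profile(raw))
        )
    return out
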