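"""Synthetic per-rat cohorts with the statistical structure the analysis assumes.

The study's raw per-rat tables were never deposited; only per-group medians
and interquartile ranges are published.  This module fabricates cohorts that
are calibrated to such a summary: each (variable, group) cell is drawn from
Normal(median, IQR/1.349) -- the normal-theory IQR-to-sd conversion --
truncated at zero by rejection for non-negative quantities (concentrations,
flows; fluxes may be negative).  Missingness and gross outliers are then
injected at configurable rates so the downstream masking and rat-exclusion
filters are exercised; injected outliers are placed just beyond the
median +/- 2*IQR fence (plus ``outlier_scale`` further IQRs) on a random
side, so they are removable by construction.

A second generator plants the four canonical dose-response archetypes
(monotone rise, peak at the middle dose, dip at the middle dose with a late
spike, monotone fall) with known labels, for cluster-recovery experiments.

Single-day-snapshot design only: no longitudinal time courses are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort_data import CohortError, CohortTable, GroupSummaryTable, VariableKey

#: normal-theory conversion between interquartile range and standard deviation
IQR_TO_SD = 1.349

#: normalized dose-response archetypes over (sham, 20%, 40%)
DEFAULT_ARCHETYPES: dict[str, tuple[float, float, float]] = {
    "monotone_up": (-1.0, 0.6, 1.0),
    "peak_middle": (-0.3, 1.0, -1.0),
    "dip_middle": (0.0, -1.0, 1.0),
    "monotone_down": (1.0, -0.7, -1.0),
}


@dataclass
class SimulationSpec:
    """Study conditions for one synthetic cohort.

    Defaults mirror the study design: group sizes 12/12/13 rats at 0/20/40
    %TBSA.  Liver weight is a generator parameter (mean 10 g, sd 1 g --
    plausible for ~300 g rats; the source prints none).  ``latent_sd``
    optionally adds a shared within-cluster group-level shift emulating
    metabolite correlation; off by default.
    """

    summary: GroupSummaryTable
    group_sizes: Mapping[float, int] = field(
        default_factory=lambda: {0.0: 12, 20.0: 12, 40.0: 13}
    )
    missing_rate: float = 0.05
    outlier_rate: float = 0.02
    outlier_scale: float = 3.0
    nonneg: Mapping[str, bool] | bool = True
    liver_weight_mean: float = 10.0
    liver_weight_sd: float = 1.0
    latent_sd: float = 0.0
    family: str = "normal"  # or "lognormal" for heavier tails
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.missing_rate, self.outlier_rate):
            if not 0.0 <= r <= 1.0:
                raise CohortError(f"rate {r} outside [0, 1]")
        if any(n < 1 for n in self.group_sizes.values()):
            raise CohortError("group sizes must be >= 1")
        missing_levels = set(self.group_sizes) - set(self.summary.levels)
        if missing_levels:
            raise CohortError(
                f"summary lacks group level(s) {sorted(missing_levels)}"
            )

    def is_nonneg(self, key: VariableKey) -> bool:
        if isinstance(self.nonneg, bool):
            return self.nonneg and key.compartment != "FLUX"
        return bool(self.nonneg.get(key.analyte, key.compartment != "FLUX"))


@dataclass
class CohortTruth:
    """Generation ground truth: which cells were blanked or made outliers."""

    outlier_mask: pd.DataFrame
    missing_mask: pd.DataFrame
    liver_weights: pd.Series


def _draw_truncated(
    rng: np.random.Generator, median: float, sd: float, n: int, nonneg: bool, family: str
) -> np.ndarray:
    if sd == 0:
        return np.full(n, median)
    if family == "lognormal":
        # heavier-tailed option: lognormal matched to the median and spread
        if median <= 0:
            return np.full(n, median)
        sigma = np.log1p(sd / median)
        return median * rng.lognormal(0.0, sigma, size=n)
    draw = rng.normal(median, sd, size=n)
    if nonneg:
        for _ in range(1000):
            neg = draw < 0
            if not neg.any():
                break
            draw[neg] = rng.normal(median, sd, size=int(neg.sum()))
        else:  # pathological spec (median << 0 demanded non-negative); clip
            draw = np.clip(draw, 0.0, None)
    return draw


def _rat_ids(group_sizes: Mapping[float, int]) -> tuple[list[str], np.ndarray]:
    ids, tbsa = [], []
    for level in sorted(group_sizes):
        for i in range(group_sizes[level]):
            ids.append(f"tbsa{int(level):02d}_r{i + 1:02d}")
            tbsa.append(level)
    return ids, np.array(tbsa)


def gen_cohort(
    spec: SimulationSpec, with_truth: bool = False
) -> CohortTable | tuple[CohortTable, CohortTruth]:
    """Generate a per-rat cohort calibrated to a group-summary table.

    Deterministic under a fixed ``spec.seed``: the same spec yields an
    identical table.  With ``with_truth`` the injected-outlier and
    missingness masks and the simulated liver weights are returned too.
    """
    rng = np.random.default_rng(spec.seed)
    ids, tbsa = _rat_ids(spec.group_sizes)
    levels = sorted(spec.group_sizes)
    keys = spec.summary.keys()
    values = pd.DataFrame(
        np.nan, index=pd.Index(ids, name="rat_id"), columns=[k.column for k in keys]
    )
    outlier_mask = pd.DataFrame(False, index=values.index, columns=values.columns)
    missing_mask = pd.DataFrame(False, index=values.index, columns=values.columns)

    summary_levels = list(spec.summary.levels)
    for key in keys:
        medians = spec.summary.medians(key)
        iqrs = spec.summary.iqrs(key)
        nonneg = spec.is_nonneg(key)
        col = np.empty(len(ids))
        pos = 0
        latent = {
            lv: rng.normal(0.0, spec.latent_sd) if spec.latent_sd > 0 else 0.0
            for lv in levels
        }
        for level in levels:
            n = spec.group_sizes[level]
            li = summary_levels.index(level)
            med, iqr = float(medians[li]), float(iqrs[li])
            sd = iqr / IQR_TO_SD
            draw = _draw_truncated(rng, med, sd, n, nonneg, spec.family)
            draw = draw + latent[level] * sd

            # gross outliers: just beyond the 2*IQR fence, plus outlier_scale
            # more IQRs, on a random side (negative side skipped when it
            # would violate non-negativity)
            out = rng.random(n) < spec.outlier_rate
            if out.any():
                step = (2.0 + spec.outlier_scale) * iqr if iqr > 0 else max(
                    1.0, 0.5 * abs(med)
                )
                side = np.where(rng.random(int(out.sum())) < 0.5, -1.0, 1.0)
                if nonneg:
                    side[med - step < 0] = 1.0
                draw[out] = med + side * step * (1.0 + 1e-6)
            # missingness
            miss = rng.random(n) < spec.missing_rate
            draw[miss] = np.nan

            col[pos : pos + n] = draw
            rows = slice(pos, pos + n)
            outlier_mask.iloc[rows, outlier_mask.columns.get_loc(key.column)] = (
                out & ~miss
            )
            missing_mask.iloc[rows, missing_mask.columns.get_loc(key.column)] = miss
            pos += n

        values[key.column] = col

    liver = pd.Series(
        np.clip(
            rng.normal(spec.liver_weight_mean, spec.liver_weight_sd, len(ids)),
            1e-3,
            None,
        ),
        index=values.index,
        name="liver_weight_g",
    )
    table = CohortTable(values, pd.Series(tbsa, index=values.index, name="tbsa"))
    if with_truth:
        return table, CohortTruth(outlier_mask, missing_mask, liver)
    return table


def plant_signal(
    summary: GroupSummaryTable,
    signal_keys: Sequence[VariableKey],
    signal_iqr_frac: float | None = None,
) -> GroupSummaryTable:
    """A copy of ``summary`` in which only ``signal_keys`` keep a dose effect.

    Every other variable's three group medians are replaced by their mean,
    so its expected dose-response is flat while its noise level (IQR) stays
    realistic.  Cohorts generated from the result carry a known planted
    signal against summary-calibrated noise, for selection-recovery
    experiments.

    With ``signal_iqr_frac`` the signal rows' IQRs are set to that fraction
    of each group median's magnitude, giving a planted signal of controlled
    strength (e.g. 0.10 matches the printed relative precision of the
    study's headline indicator) independent of how tail-inflated the
    printed spread of the source row happens to be.
    """
    keep = {(k.analyte, k.compartment) for k in signal_keys}
    records = summary.records.copy()
    med_cols = ["median_sham", "median_20", "median_40"]
    iqr_cols = ["iqr_sham", "iqr_20", "iqr_40"]
    is_signal = records.apply(
        lambda r: (r["analyte"], r["vessel"]) in keep, axis=1
    )
    flat = ~is_signal
    flat_means = records.loc[flat, med_cols].mean(axis=1)
    for col in med_cols:
        records.loc[flat, col] = flat_means
    if signal_iqr_frac is not None:
        for med_col, iqr_col in zip(med_cols, iqr_cols):
            records.loc[is_signal, iqr_col] = (
                signal_iqr_frac * records.loc[is_signal, med_col].abs()
            )
    return GroupSummaryTable(records, summary.levels)


@dataclass
class ArchetypeSpec:
    """Planted dose-response archetypes with a known variable-to-pattern map."""

    patterns: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPES)
    )
    assignment: Mapping[VariableKey, str] = field(default_factory=dict)
    noise_sd: float = 0.1

    def __post_init__(self) -> None:
        for name, p in self.patterns.items():
            arr = np.asarray(p, float)
            if arr.shape != (3,) or (np.abs(arr) > 1).any():
                raise CohortError(f"pattern {name!r} must be a 3-vector in [-1, 1]")
        counts: dict[str, int] = {}
        for pat in self.assignment.values():
            if pat not in self.patterns:
                raise CohortError(f"assignment references unknown pattern {pat!r}")
            counts[pat] = counts.get(pat, 0) + 1
        thin = [p for p, n in counts.items() if n < 2]
        if thin:
            raise CohortError(
                f"pattern(s) {thin} have fewer than 2 variables; recovery undefined"
            )

    @classmethod
    def balanced(
        cls,
        n_per_pattern: int = 10,
        noise_sd: float = 0.1,
        patterns: Mapping[str, Sequence[float]] | None = None,
    ) -> "ArchetypeSpec":
        patterns = dict(patterns or DEFAULT_ARCHETYPES)
        assignment = {
            VariableKey(f"{pat}_{i + 1:02d}", "HA"): pat
            for pat in patterns
            for i in range(n_per_pattern)
        }
        return cls(patterns, assignment, noise_sd)


def gen_archetype_cohort(
    arch: ArchetypeSpec,
    n_per_group: int = 7,
    effect_scale: float = 1.0,
    seed: int = 0,
    levels: Sequence[float] = (0.0, 20.0, 40.0),
) -> tuple[CohortTable, dict[VariableKey, str]]:
    """Cohort whose per-group means follow the assigned archetype patterns.

    Each variable's group mean is its pattern scaled by ``effect_scale``;
    per-rat values add Normal(0, noise_sd) noise.  Returns the table and the
    ground-truth pattern labels for recovery tests.
    """
    if not arch.assignment:
        raise CohortError("archetype spec assigns no variables")
    rng = np.random.default_rng(seed)
    group_sizes = {float(lv): n_per_group for lv in levels}
    ids, tbsa = _rat_ids(group_sizes)
    values = {}
    for key, pat in arch.assignment.items():
        mean_by_level = dict(zip(levels, np.asarray(arch.patterns[pat], float) * effect_scale))
        values[key.column] = np.concatenate(
            [
                mean_by_level[lv] + rng.normal(0.0, arch.noise_sd, n_per_group)
                for lv in sorted(group_sizes)
            ]
        )
    frame = pd.DataFrame(values, index=pd.Index(ids, name="rat_id"))
    table = CohortTable(frame, pd.Series(tbsa, index=frame.index, name="tbsa"))
    return table, dict(arch.assignment)
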