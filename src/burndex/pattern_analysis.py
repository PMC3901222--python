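"""Counting independent dose-response patterns and cluster-membership analysis.

Each cluster is summarized as the per-injury-level median of its members'
normalized profiles; the columns form the centroid matrix (3 levels x k
clusters).  Its singular values measure how many genuinely independent
patterns the clusters carry: near-duplicate or marginal singular values are
artifacts of measurement error and of the clustering itself, so the count
keeps only distinct non-zero values (> ``tol``, merged when within ``tol``
of each other) and stops once the remaining squared singular-value mass
falls below ``residual_energy_tol`` -- patterns explainable within that
margin of error are not counted as independent.  The resulting count is the
variable budget of the downstream severity-index regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort_data import COMPARTMENTS, VariableKey
from .preprocess import DoseResponseProfile

logger = logging.getLogger(__name__)


@dataclass
class CentroidMatrix:
    """Levels x clusters matrix of per-level cluster medians."""

    matrix: np.ndarray  # shape (n_levels, k)
    cluster_ids: tuple[int, ...]
    levels: tuple[float, ...]

    @property
    def k(self) -> int:
        return self.matrix.shape[1]


@dataclass
class PatternAnalysisResult:
    singular_values: np.ndarray  # descending
    n_independent: int
    cluster_ids: tuple[int, ...]
    right_vectors: np.ndarray  # V^T of the decomposition, rows match singular values

    def explained_fraction_by(self, n: int) -> float:
        """Share of squared singular-value mass carried by the top n values."""
        e = self.singular_values**2
        total = e.sum()
        if total == 0:
            return 1.0
        return float(e[:n].sum() / total)

    @property
    def dominant_clusters(self) -> tuple[int, ...]:
        """Per leading singular vector, the cluster carrying the largest weight."""
        out: list[int] = []
        for row in np.abs(self.right_vectors[: self.n_independent]):
            for i in np.argsort(-row):
                if self.cluster_ids[i] not in out:
                    out.append(self.cluster_ids[i])
                    break
        return tuple(out)


def centroid_matrix(
    profiles: Sequence[DoseResponseProfile],
    assignment: Mapping[VariableKey, int],
) -> CentroidMatrix:
    """Per-cluster, per-level median of member normalized profiles."""
    by_key = {p.variable: p for p in profiles}
    clusters = sorted(set(assignment.values()))
    levels = next(iter(by_key.values())).levels
    cols = []
    for c in clusters:
        members = [by_key[k].normalized for k, cc in assignment.items() if cc == c and k in by_key]
        if not members:
            raise ValueError(f"cluster {c} has no member profiles")
        cols.append(np.median(np.vstack(members), axis=0))
    return CentroidMatrix(np.column_stack(cols), tuple(clusters), tuple(levels))


def _count_distinct_nonzero(s: np.ndarray, tol: float) -> int:
    """Distinct (merged greedily top-down when within tol) values above tol."""
    count = 0
    current = None
    for v in s:
        if v <= tol:
            break
        if current is None or current - v > tol:
            count += 1
            current = v
    return count


def svd_patterns(
    cm: CentroidMatrix,
    tol: float = 1e-2,
    residual_energy_tol: float = 0.02,
) -> PatternAnalysisResult:
    """Singular value decomposition of the centroid matrix (no centering).

    ``n_independent`` is the number of distinct non-zero singular values,
    truncated at the smallest count that already leaves a residual
    squared-energy share below ``residual_energy_tol``.
    """
    if not np.isfinite(cm.matrix).all():
        raise ValueError("centroid matrix must be finite")
    _, s, vt = np.linalg.svd(cm.matrix)
    n_distinct = _count_distinct_nonzero(s, tol)
    energy = s**2
    total = energy.sum()
    n = n_distinct
    if total > 0:
        cumulative = np.cumsum(energy) / total
        for m in range(1, n_distinct + 1):
            if 1.0 - cumulative[m - 1] < residual_energy_tol:
                n = m
                break
    return PatternAnalysisResult(s, n, cm.cluster_ids, vt)


def cross_vessel_membership(
    assignment: Mapping[VariableKey, int],
) -> list[tuple[str, int, int]]:
    """Analytes whose two liver-inlet clusters agree but whose outlet differs.

    Returns (analyte, inlet cluster, outlet cluster) for every analyte with
    HA and PV assigned to the same cluster and SHVC to a different one --
    the signature of the liver altering that analyte in the injury response.
    Analytes lacking any of the three vessels are skipped with a warning.
    """
    per_analyte: dict[str, dict[str, int]] = {}
    for key, c in assignment.items():
        if key.compartment in ("HA", "PV", "SHVC"):
            per_analyte.setdefault(key.analyte, {})[key.compartment] = c
    out = []
    for analyte in sorted(per_analyte):
        got = per_analyte[analyte]
        if set(got) != {"HA", "PV", "SHVC"}:
            logger.warning("analyte %s lacks a vessel assignment; skipped", analyte)
            continue
        if got["HA"] == got["PV"] != got["SHVC"]:
            out.append((analyte, got["HA"], got["SHVC"]))
    return out


def membership_census(assignment: Mapping[VariableKey, int]) -> pd.DataFrame:
    """Contingency counts of cluster membership per compartment, with totals."""
    rows = [
        {"cluster": c, "compartment": key.compartment}
        for key, c in assignment.items()
    ]
    df = pd.DataFrame(rows)
    compartments = [c for c in COMPARTMENTS if c in set(df["compartment"])]
    census = pd.crosstab(df["cluster"], df["compartment"]).reindex(
        columns=compartments, fill_value=0
    )
    census["Total"] = census.sum(axis=1)
    census.loc["Total"] = census.sum(axis=0)
    return census
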