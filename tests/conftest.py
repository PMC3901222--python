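import numpy as np
import pandas as pd
import pytest

import burndex as bx


@pytest.fixture(scope="session")
def summary() -> bx.GroupSummaryTable:
    return bx.packaged_summary()


@pytest.fixture(scope="session")
def fixture_profiles(summary):
    return bx.profiles_from_summary(summary)


@pytest.fixture(scope="session")
def paper_assignment(summary):
    return summary.paper_assignment()


def make_cohort(columns: dict[str, list], tbsa: list, rat_ids: list | None = None) -> bx.CohortTable:
    """Small literal cohorts for unit tests; column names are analyte@vessel."""
    n = len(tbsa)
    rat_ids = rat_ids or [f"r{i + 1}" for i in range(n)]
    values = pd.DataFrame(columns, index=pd.Index(rat_ids, name="rat_id"), dtype=float)
    return bx.CohortTable(values, pd.Series(tbsa, index=values.index, name="tbsa", dtype=float))


def make_summary(rows: list[tuple]) -> bx.GroupSummaryTable:
    """rows: (analyte, vessel, cluster, m0, i0, m20, i20, m40, i40)."""
    cols = ["analyte", "vessel", "paper_cluster", "median_sham", "iqr_sham",
            "median_20", "iqr_20", "median_40", "iqr_40"]
    return bx.GroupSummaryTable(pd.DataFrame(rows, columns=cols))
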