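"""Group-comparison table for the PCHD cohort (HT vs non-HT).

Reproduces the conventions of a clinical baseline table: categorical
variables as n (%) compared by the uncorrected Pearson chi-square test,
normally distributed continuous variables as mean +/- SD compared by the
Welch t-test, and skewed continuous variables as median (IQR) compared by
the Mann-Whitney U test with a tie-corrected Z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import (
    BinaryCovariate,
    CategoricalCovariate,
    MedianIqrCovariate,
    NormalCovariate,
    PatientRecord,
    default_covariate_specs,
)
from .diagnostics import (
    HT,
    ContingencyTable2x2,
    mann_whitney,
    pearson_chi2,
    welch_t,
)
from .errors import InputError

__all__ = ["GroupComparisonRow", "table_one", "table_one_frame"]


@dataclass
class GroupComparisonRow:
    """One variable's summaries in both groups plus its test."""

    variable: str
    overall: str
    group1: str  # HT
    group2: str  # non-HT (CE)
    statistic: float
    test: str  # chi2 | t | mannwhitney | missing
    p_value: float


def _pct(k: int, n: int) -> str:
    return f"{k} ({100.0 * k / n:.2f})" if n else f"{k} (-)"


def _binary_row(name: str, g1: list, g2: list) -> GroupComparisonRow:
    k1 = sum(bool(v) for v in g1)
    k2 = sum(bool(v) for v in g2)
    n1, n2 = len(g1), len(g2)
    t = ContingencyTable2x2(k1, n1 - k1, k2, n2 - k2)
    try:
        chi2, p = pearson_chi2(t, correction=False)
    except Exception:
        chi2, p = math.nan, math.nan
    return GroupComparisonRow(
        variable=name,
        overall=_pct(k1 + k2, n1 + n2),
        group1=_pct(k1, n1),
        group2=_pct(k2, n2),
        statistic=chi2,
        test="chi2",
        p_value=p,
    )


def _normal_row(name: str, g1: list, g2: list) -> GroupComparisonRow:
    a1, a2 = np.asarray(g1, dtype=float), np.asarray(g2, dtype=float)
    both = np.concatenate([a1, a2])
    tstat, p = welch_t(a1, a2)
    fmt = lambda a: f"{a.mean():.2f} +/- {a.std(ddof=1):.2f}"
    return GroupComparisonRow(
        variable=name, overall=fmt(both), group1=fmt(a1), group2=fmt(a2),
        statistic=tstat, test="t", p_value=p,
    )


def _median_row(name: str, g1: list, g2: list) -> GroupComparisonRow:
    a1, a2 = np.asarray(g1, dtype=float), np.asarray(g2, dtype=float)
    both = np.concatenate([a1, a2])
    _, z, p = mann_whitney(a1, a2)
    fmt = lambda a: (
        f"{np.median(a):.0f} ({np.percentile(a, 25):.0f}-{np.percentile(a, 75):.0f})"
    )
    return GroupComparisonRow(
        variable=name, overall=fmt(both), group1=fmt(a1), group2=fmt(a2),
        statistic=z, test="mannwhitney", p_value=p,
    )


def _missing_row(name: str) -> GroupComparisonRow:
    return GroupComparisonRow(
        variable=name, overall="-", group1="-", group2="-",
        statistic=math.nan, test="missing", p_value=math.nan,
    )


def table_one(
    records: list[PatientRecord],
    grouping: str = "true_outcome",
    covariate_specs: Optional[dict] = None,
    predictions: Optional[dict] = None,
) -> list[GroupComparisonRow]:
    """Build the HT vs non-HT comparison table from patient records.

    ``records`` should be the PCHD analysis set (every record must have a
    group label under ``grouping``).  When ``predictions`` maps patient id
    to a predicted "HT"/"CE" label, an ``rmdv_gt1`` row is appended,
    treating a predicted HT as test-positive.  Variables absent from all
    records are reported as missing, not fatal.
    """
    if not records:
        raise InputError("no records to tabulate")
    specs = covariate_specs if covariate_specs is not None else default_covariate_specs()
    g1 = [r for r in records if getattr(r, grouping) == HT]
    g2 = [r for r in records if getattr(r, grouping) != HT]
    if not g1 or not g2:
        raise InputError("both outcome groups must be nonempty")

    rows: list[GroupComparisonRow] = []
    for name, spec in specs.items():
        v1 = [r.covariates[name] for r in g1 if name in r.covariates]
        v2 = [r.covariates[name] for r in g2 if name in r.covariates]
        if not v1 or not v2:
            rows.append(_missing_row(name))
            continue
        if isinstance(spec, BinaryCovariate):
            rows.append(_binary_row(name, v1, v2))
        elif isinstance(spec, CategoricalCovariate):
            for level in spec.levels:
                rows.append(
                    _binary_row(
                        f"{name}={level}",
                        [v == level for v in v1],
                        [v == level for v in v2],
                    )
                )
        elif isinstance(spec, NormalCovariate):
            rows.append(_normal_row(name, v1, v2))
        elif isinstance(spec, MedianIqrCovariate):
            rows.append(_median_row(name, v1, v2))

    if predictions is not None:
        p1 = [predictions.get(r.patient_id) == HT for r in g1]
        p2 = [predictions.get(r.patient_id) == HT for r in g2]
        rows.append(_binary_row("rmdv_gt1", p1, p2))
    return rows


def table_one_frame(rows: list[GroupComparisonRow]) -> pd.DataFrame:
    """Render the comparison rows as a DataFrame (CSV-ready)."""
    return pd.DataFrame(
        {
            "variable": [r.variable for r in rows],
            "overall": [r.overall for r in rows],
            "ht_group": [r.group1 for r in rows],
            "non_ht_group": [r.group2 for r in rows],
            "statistic": [round(r.statistic, 3) if math.isfinite(r.statistic) else r.statistic for r in rows],
            "test": [r.test for r in rows],
            "p_value": [round(r.p_value, 4) if math.isfinite(r.p_value) else r.p_value for r in rows],
        }
    )
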