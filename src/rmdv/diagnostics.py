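"""Diagnostic-accuracy statistics for the RMDV > 1 test.

Everything downstream of the 2x2 table lives here: sensitivity,
specificity, predictive values, the Youden index, the single-threshold ROC
area with a Hanley-McNeil confidence interval, the uncorrected Pearson
chi-square test, and the two group-comparison tests (Welch t, Mann-Whitney
U) used for the cohort table.

For a single-cutoff test the ROC has three points, (0,0), (1-Sp, Se) and
(1,1), so the trapezoidal AUC is exactly (Se + Sp) / 2.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Sequence, Union

import numpy as np
from scipy import stats

from .errors import DegenerateTableError, InputError

__all__ = [
    "ContingencyTable2x2",
    "DiagnosticReport",
    "build_table",
    "diagnostic_summary",
    "binary_auc",
    "hanley_mcneil_ci",
    "pearson_chi2",
    "welch_t",
    "mann_whitney",
]

HT = "HT"
CE = "CE"


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Prediction x outcome counts: a=TP, b=FN, c=FP, d=TN.

    Rows are the true outcome (HT / CE), columns the RMDV prediction
    (positive / negative): a and b split the HT patients, c and d the CE
    patients.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise InputError("2x2 counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_ht(self) -> int:
        return self.a + self.b

    @property
    def n_ce(self) -> int:
        return self.c + self.d

    @property
    def n_pos(self) -> int:
        return self.a + self.c

    @property
    def n_neg(self) -> int:
        return self.b + self.d

    def require_margins(self, *, predictive: bool = True) -> None:
        bad = []
        if self.n_ht == 0:
            bad.append("sensitivity (no HT cases)")
        if self.n_ce == 0:
            bad.append("specificity (no CE cases)")
        if predictive and self.n_pos == 0:
            bad.append("PPV (no positive predictions)")
        if predictive and self.n_neg == 0:
            bad.append("NPV (no negative predictions)")
        if bad:
            raise DegenerateTableError(
                "degenerate 2x2 table: undefined " + ", ".join(bad)
            )


@dataclass
class DiagnosticReport:
    """Terminal product of the pipeline: the test's accuracy profile."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    youden: float
    auc: float
    auc_ci: tuple[float, float]
    chi2: float
    p_value: float
    ci_method: str = "hanley-mcneil"
    table: tuple[int, int, int, int] = (0, 0, 0, 0)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["auc_ci"] = list(self.auc_ci)
        d["table"] = {"a": self.table[0], "b": self.table[1],
                      "c": self.table[2], "d": self.table[3]}
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def build_table(
    predictions: Union[dict, Sequence[str]],
    outcomes: Union[dict, Sequence[str]],
) -> ContingencyTable2x2:
    """Cross-tabulate per-patient predictions against outcomes.

    Accepts either two dicts keyed by patient id (keys must coincide) or
    two aligned sequences of "HT"/"CE" labels.
    """
    if isinstance(predictions, dict) != isinstance(outcomes, dict):
        raise InputError("predictions and outcomes must both be dicts or both sequences")
    if isinstance(predictions, dict):
        if set(predictions) != set(outcomes):
            missing = set(predictions) ^ set(outcomes)
            raise InputError(f"patient ids do not align: {sorted(missing)[:5]}")
        keys = sorted(predictions)
        pred = [predictions[k] for k in keys]
        outc = [outcomes[k] for k in keys]
    else:
        if len(predictions) != len(outcomes):
            raise InputError("predictions and outcomes differ in length")
        pred, outc = list(predictions), list(outcomes)
    if not pred:
        raise InputError("empty input: nothing to tabulate")
    for lab in (*pred, *outc):
        if lab not in (HT, CE):
            raise InputError(f"label {lab!r} is not HT or CE")
    a = sum(1 for p, o in zip(pred, outc) if p == HT and o == HT)
    b = sum(1 for p, o in zip(pred, outc) if p == CE and o == HT)
    c = sum(1 for p, o in zip(pred, outc) if p == HT and o == CE)
    d = sum(1 for p, o in zip(pred, outc) if p == CE and o == CE)
    return ContingencyTable2x2(a, b, c, d)


def hanley_mcneil_ci(
    auc: float, n_pos: int, n_neg: int, level: float = 0.95
) -> tuple[float, float]:
    """Wald interval for the AUC with the Hanley-McNeil standard error."""
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    se = float(np.sqrt(max(var, 0.0)))
    z = stats.norm.ppf(0.5 + level / 2.0)
    return (max(0.0, auc - z * se), min(1.0, auc + z * se))


def binary_auc(
    t: ContingencyTable2x2, level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """AUC of the single-threshold ROC, with a Hanley-McNeil CI.

    The ROC through (0,0), (1-Sp, Se), (1,1) has trapezoidal area
    (Se + Sp) / 2 exactly.
    """
    t.require_margins(predictive=False)
    se = t.a / t.n_ht
    sp = t.d / t.n_ce
    auc = (se + sp) / 2.0
    return auc, hanley_mcneil_ci(auc, t.n_ht, t.n_ce, level=level)


def pearson_chi2(
    t: ContingencyTable2x2, correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square test of association on the 2x2 table.

    Uncorrected by default: chi2 = n (ad - bc)^2 / (r1 r2 c1 c2).  The
    Yates continuity correction is available behind ``correction``.
    """
    if t.n == 0:
        raise InputError("empty table")
    if min(t.n_ht, t.n_ce, t.n_pos, t.n_neg) == 0:
        raise DegenerateTableError("chi-square undefined: a margin is zero")
    a, b, c, d = (float(x) for x in (t.a, t.b, t.c, t.d))
    n = a + b + c + d
    num = abs(a * d - b * c)
    if correction:
        num = max(num - n / 2.0, 0.0)
    chi2 = n * num**2 / (t.n_ht * t.n_ce * t.n_pos * t.n_neg)
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def diagnostic_summary(t: ContingencyTable2x2, level: float = 0.95) -> DiagnosticReport:
    """Full accuracy profile of the 2x2 table.

    Zero margins raise :class:`DegenerateTableError` naming the undefined
    quantity rather than returning NaN.
    """
    t.require_margins(predictive=True)
    sens = t.a / t.n_ht
    spec = t.d / t.n_ce
    ppv = t.a / t.n_pos
    npv = t.d / t.n_neg
    auc, ci = binary_auc(t, level=level)
    chi2, p = pearson_chi2(t, correction=False)
    return DiagnosticReport(
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        youden=sens + spec - 1.0,
        auc=auc,
        auc_ci=ci,
        chi2=chi2,
        p_value=p,
        table=(t.a, t.b, t.c, t.d),
    )


def roc_points(t: ContingencyTable2x2) -> list[tuple[float, float]]:
    """The three ROC points (FPR, TPR) of a single-cutoff test."""
    t.require_margins(predictive=False)
    return [(0.0, 0.0), (1.0 - t.d / t.n_ce, t.a / t.n_ht), (1.0, 1.0)]


def welch_t(
    group1: Union[Sequence[float], tuple[float, float, int]],
    group2: Union[Sequence[float], tuple[float, float, int]],
) -> tuple[float, float]:
    """Two-sided Welch t-test; accepts raw values or (mean, sd, n).

    Sign convention: t has the sign of mean(group2) - mean(group1).
    """

    def summarize(g) -> tuple[float, float, int]:
        if isinstance(g, tuple) and len(g) == 3 and np.isscalar(g[0]):
            mean, sd, n = g
        else:
            arr = np.asarray(g, dtype=float)
            n = arr.size
            if n < 2:
                raise InputError("each group needs at least 2 observations")
            mean, sd = arr.mean(), arr.std(ddof=1)
        if n < 2:
            raise InputError("each group needs at least 2 observations")
        if sd <= 0:
            raise InputError("group standard deviation must be positive")
        return float(mean), float(sd), int(n)

    m1, s1, n1 = summarize(group1)
    m2, s2, n2 = summarize(group2)
    v1, v2 = s1**2 / n1, s2**2 / n2
    se = np.sqrt(v1 + v2)
    tstat = (m2 - m1) / se
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = float(2.0 * stats.t.sf(abs(tstat), df))
    return float(tstat), p


def mann_whitney(
    group1: Sequence[float], group2: Sequence[float]
) -> tuple[float, float, float]:
    """Mann-Whitney U with tie-corrected normal Z and two-sided p.

    Reports min(U1, U2).  The p-value uses exact enumeration for small
    tie-free samples (n1 * n2 <= 400) and the tie-corrected normal
    approximation otherwise.  Z carries the sign of U1 - n1 n2 / 2, so two
    stochastically equal groups give Z near 0.
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("both groups must be nonempty")
    n1, n2 = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    u2 = n1 * n2 - u1

    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = np.any(tie_counts > 1)
    n = n1 + n2
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    z = 0.0 if var <= 0 else float((u1 - n1 * n2 / 2.0) / np.sqrt(var))

    if not has_ties and n1 * n2 <= 400:
        p = float(
            stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        )
    else:
        p = float(2.0 * stats.norm.sf(abs(z)))
    return float(min(u1, u2)), z, min(p, 1.0)
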