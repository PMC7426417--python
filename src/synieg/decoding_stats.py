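"""Filter and logic-gate characterization with the study's hypothesis tests.

Comparisons between conditions use two-sided Student t-tests (equal-variance
unpaired by default, Welch optionally, paired where measurements are matched
within clones).  The AND-gate classifier is a package-defined operational
rule, reported as such in its output: a circuit is called AND-like when the
synergy S = mean AUC(A+B) - mean AUC(A) - mean AUC(B) is positive, the
combined response is significantly above each single input (p < 0.05), and
each single-input fold-change stays below a weak-response threshold tau
(default 1.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import AnalysisError, ValidationError

__all__ = [
    "TTestResult",
    "GateReport",
    "ttest",
    "duration_filter_index",
    "gate_analysis",
    "significance_stars",
]


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    paired: bool
    welch: bool = False


@dataclass
class GateReport:
    """Per-condition AUC summaries and the operational gate classification."""

    mean_auc: dict[str, float]
    synergy: float
    single_input_folds: dict[str, float]
    p_values: dict[str, float]
    classification: str
    tau: float
    note: str = (
        "classification rule is an operational definition of this package: "
        "AND-like requires S > 0, p < 0.05 for AB vs each single input, and "
        "single-input folds < tau"
    )


def ttest(group_a: Sequence[float], group_b: Sequence[float],
          paired: bool = False, welch: bool = False) -> TTestResult:
    """Two-sided two-sample t-test (Student's equal-variance by default).

    Zero variance in both groups with equal means returns t=0, p=1 by
    convention (scipy yields NaN for the 0/0 statistic).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs at least two observations")
    if paired:
        if len(a) != len(b):
            raise ValidationError("paired test requires equal group sizes")
        if welch:
            raise ValidationError("welch applies to unpaired tests only")
        res = sps.ttest_rel(a, b)
        df = float(len(a) - 1)
    else:
        res = sps.ttest_ind(a, b, equal_var=not welch)
        df = float(res.df)
    t, p = float(res.statistic), float(res.pvalue)
    if np.isnan(t):  # zero variance, zero mean difference
        t, p = 0.0, 1.0
    return TTestResult(t=t, df=df, p=p, paired=paired, welch=welch)


def duration_filter_index(fold_sustained: Sequence[float],
                          fold_transient: Sequence[float],
                          welch: bool = False) -> dict[str, float | bool]:
    """Sustained-over-transient selectivity of baseline-subtracted fold-changes.

    ratio = mean(fold_sustained - 1) / mean(fold_transient - 1); a ratio > 1
    with a significant unpaired t-test on the folds indicates a
    sustained-selective (duration-filtering) circuit.  A transient mean fold
    of exactly 1 makes the ratio infinite and is flagged.
    """
    fs = np.asarray(fold_sustained, dtype=float)
    ft = np.asarray(fold_transient, dtype=float)
    if len(fs) == 0 or len(ft) == 0:
        raise ValidationError("both groups must be nonempty")
    num = float((fs - 1.0).mean())
    den = float((ft - 1.0).mean())
    undefined = den == 0.0
    ratio = float("inf") if undefined else num / den
    test = ttest(fs, ft, welch=welch) if len(fs) >= 2 and len(ft) >= 2 else None
    return {
        "ratio": ratio,
        "p_value": test.p if test else float("nan"),
        "t": test.t if test else float("nan"),
        "sustained_selective": (not undefined) and ratio > 1.0,
        "ratio_undefined": undefined,
    }


_REQUIRED_CONDITIONS = ("starve", "A", "B", "AB")


def gate_analysis(auc_by_condition: dict[str, Sequence[float]],
                  fold_by_condition: dict[str, Sequence[float]] | None = None,
                  tau: float = 1.5, welch: bool = False) -> GateReport:
    """Score a two-input gate from per-cell AUCs of the four conditions.

    ``auc_by_condition`` must hold 'starve', 'A', 'B' and 'AB' (here A =
    serum, B = doxorubicin).  All stated comparisons are computed: starve
    vs each stimulated condition, and each single input vs the combination.
    Single-input folds come from ``fold_by_condition`` when given, else from
    AUC means normalized by the starve AUC spread (AUC-only fallback flagged
    by NaN folds when starve AUC is degenerate).
    """
    for cond in _REQUIRED_CONDITIONS:
        if cond not in auc_by_condition:
            raise ValidationError(f"missing condition {cond!r}")
        if len(auc_by_condition[cond]) < 3:
            raise ValidationError(f"condition {cond!r} needs >= 3 cells for testing")
    aucs = {c: np.asarray(v, dtype=float) for c, v in auc_by_condition.items()}
    mean_auc = {c: float(v.mean()) for c, v in aucs.items()}
    synergy = mean_auc["AB"] - mean_auc["A"] - mean_auc["B"]

    p_values = {}
    for cond in ("A", "B", "AB"):
        p_values[f"starve_vs_{cond}"] = ttest(aucs["starve"], aucs[cond], welch=welch).p
    for cond in ("A", "B"):
        p_values[f"{cond}_vs_AB"] = ttest(aucs[cond], aucs["AB"], welch=welch).p

    if fold_by_condition is not None:
        folds = {c: float(np.mean(fold_by_condition[c])) for c in ("A", "B")}
    else:
        folds = {c: float("nan") for c in ("A", "B")}

    singles_weak = all(f < tau for f in folds.values()) if fold_by_condition else True
    additive_tol = 0.10 * max(abs(mean_auc["AB"]), 1e-12)
    if abs(synergy) <= additive_tol:
        cls = "additive"
    elif (synergy > 0
          and p_values["A_vs_AB"] < 0.05
          and p_values["B_vs_AB"] < 0.05
          and singles_weak):
        cls = "AND-like"
    else:
        cls = "single-input-driven"
    return GateReport(
        mean_auc=mean_auc,
        synergy=float(synergy),
        single_input_folds=folds,
        p_values=p_values,
        classification=cls,
        tau=tau,
    )


def significance_stars(p: float) -> str:
    """Conventional star notation: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
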