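"""Group comparisons of ROI parameter values between tissue classes.

Wilcoxon-Mann-Whitney rank-sum tests, two-sided, at a fixed 0.05 threshold:
exact when both samples are small and tie-free, otherwise the normal
approximation with tie and continuity corrections. Comparison design: all
pairwise cancer-grade tests, pooled cancers versus pooled normal tissue, and
peripheral versus transitional zone — per parameter, with no multiplicity
adjustment driving the significance flag (a Holm-adjusted column is emitted
alongside for transparency).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupSample",
    "ComparisonResult",
    "rank_sum_test",
    "run_comparisons",
    "comparisons_to_frame",
]

ALPHA = 0.05
EXACT_MAX_N = 12  # exact enumeration path when n_a + n_b <= this and no ties

CANCER_CLASSES = ("G3+3", "G3+4", "G4+3")
NORMAL_CLASSES = ("PZ", "TZ")
PARAMETERS = ("MD", "MK_I", "MK_A")


@dataclass(frozen=True)
class GroupSample:
    """Per-ROI parameter values of one tissue class."""

    label: str
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.size < 1:
            raise ValueError(f"group {self.label!r} is empty")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"group {self.label!r} contains non-finite values")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class ComparisonResult:
    """One two-sided rank-sum comparison."""

    parameter: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    statistic: float  # Mann-Whitney U of group_a
    p: float
    median_diff: float  # median(a) - median(b), sign reported as-is
    significant: bool
    method: str = "exact"
    degenerate: bool = False
    computable: bool = True
    p_holm: float = float("nan")

    def __post_init__(self):
        if self.computable and not (0.0 <= self.p <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def _has_ties(pooled: np.ndarray) -> bool:
    return np.unique(pooled).size < pooled.size


def rank_sum_test(a: GroupSample, b: GroupSample, parameter: str = "") -> ComparisonResult:
    """Two-sided Wilcoxon-Mann-Whitney test of two tissue-class samples.

    Exact null distribution when ``n_a + n_b <= 12`` and the pooled sample is
    tie-free; otherwise the normal approximation with mid-ranks, tie-corrected
    variance and continuity correction. Completely degenerate data (every
    value identical in both groups) yields p = 1 with a warning flag.
    """
    med_diff = float(np.median(a.values) - np.median(b.values))
    pooled = np.concatenate([a.values, b.values])
    if np.unique(pooled).size == 1:
        u = a.n * b.n / 2.0
        return ComparisonResult(
            parameter, a.label, b.label, a.n, b.n, u, 1.0, med_diff,
            significant=False, method="degenerate", degenerate=True,
        )
    exact = (a.n + b.n <= EXACT_MAX_N) and not _has_ties(pooled)
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(
        a.values, b.values, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    p = float(min(res.pvalue, 1.0))
    return ComparisonResult(
        parameter, a.label, b.label, a.n, b.n, float(res.statistic), p,
        med_diff, significant=p < ALPHA, method=method,
    )


def _not_computable(parameter, ga, gb, reason="class absent") -> ComparisonResult:
    return ComparisonResult(
        parameter, ga, gb, 0, 0, float("nan"), float("nan"), float("nan"),
        significant=False, method=reason, computable=False,
    )


def run_comparisons(roi_table: pd.DataFrame, parameters=PARAMETERS) -> list[ComparisonResult]:
    """All study comparisons from a tidy ROI table.

    Per parameter: every pairwise cancer-grade comparison, pooled cancers
    versus pooled normal (PZ + TZ), and PZ versus TZ — five tests per
    parameter when all classes are present. Missing classes make the affected
    comparisons not-computable without touching the rest. The ``significant``
    flag uses the raw p at 0.05; Holm-adjusted p-values over all computed
    tests are attached in ``p_holm``.
    """
    required = {"class", "parameter", "value"}
    if not required <= set(roi_table.columns):
        raise ValueError(f"ROI table must have columns {sorted(required)}")
    results: list[ComparisonResult] = []

    def sample(classes, label, parameter):
        sel = roi_table[
            roi_table["class"].isin(classes) & (roi_table["parameter"] == parameter)
        ]["value"].dropna()
        if sel.empty:
            return None
        return GroupSample(label, sel.to_numpy())

    pairs = [
        (CANCER_CLASSES[i], CANCER_CLASSES[j])
        for i in range(len(CANCER_CLASSES))
        for j in range(i + 1, len(CANCER_CLASSES))
    ]
    for parameter in parameters:
        for ca, cb in pairs:
            sa, sb = sample([ca], ca, parameter), sample([cb], cb, parameter)
            results.append(
                rank_sum_test(sa, sb, parameter)
                if sa is not None and sb is not None
                else _not_computable(parameter, ca, cb)
            )
        sc = sample(CANCER_CLASSES, "cancer", parameter)
        sn = sample(NORMAL_CLASSES, "normal", parameter)
        results.append(
            rank_sum_test(sc, sn, parameter)
            if sc is not None and sn is not None
            else _not_computable(parameter, "cancer", "normal")
        )
        sp_, st_ = sample(["PZ"], "PZ", parameter), sample(["TZ"], "TZ", parameter)
        results.append(
            rank_sum_test(sp_, st_, parameter)
            if sp_ is not None and st_ is not None
            else _not_computable(parameter, "PZ", "TZ")
        )

    # Holm column across all computed tests (transparency only)
    idx = [i for i, r in enumerate(results) if r.computable and not r.degenerate]
    if idx:
        _, p_holm, _, _ = multipletests([results[i].p for i in idx], method="holm")
        for i, ph in zip(idx, p_holm):
            r = results[i]
            results[i] = ComparisonResult(
                r.parameter, r.group_a, r.group_b, r.n_a, r.n_b, r.statistic,
                r.p, r.median_diff, r.significant, r.method, r.degenerate,
                r.computable, float(ph),
            )
    return results


def comparisons_to_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    """Tidy export: one row per comparison."""
    return pd.DataFrame(
        [
            {
                "parameter": r.parameter,
                "group_a": r.group_a,
                "group_b": r.group_b,
                "n_a": r.n_a,
                "n_b": r.n_b,
                "statistic": r.statistic,
                "p": r.p,
                "median_diff": r.median_diff,
                "significant": r.significant,
                "p_holm": r.p_holm,
                "method": r.method,
            }
            for r in results
        ]
    )


def summarize(results: list[ComparisonResult]) -> str:
    """Human-readable comparison log."""
    lines = []
    for r in results:
        if not r.computable:
            lines.append(f"{r.parameter:5s} {r.group_a} vs {r.group_b}: not computable ({r.method})")
            continue
        flag = "*" if r.significant else " "
        lines.append(
            f"{r.parameter:5s} {r.group_a:>6s} vs {r.group_b:<6s} "
            f"n=({r.n_a},{r.n_b}) U={r.statistic:7.1f} p={r.p:.4g}{flag} "
            f"median diff={r.median_diff:+.4g}"
        )
    return "\n".join(lines)
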