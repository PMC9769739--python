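"""Pairwise condition comparison with FDR control.

Analyte levels are compared between growth conditions with two-sided
t tests on replicate values — Welch's unequal-variance variant by
default, since measured SDs differ widely between conditions — and the
raw p-values of all condition pairs are adjusted with the
Benjamini-Hochberg step-up procedure. The adjustment family defaults to
the pairs within one analyte; a global family across analytes is
available.

The t test is delegated to scipy and the BH adjustment to statsmodels;
both are cross-checked against first-principles implementations in the
test suite.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .composition_io import ConditionDataset

__all__ = ["TestResult", "StatsError", "welch_t", "pooled_t", "bh_adjust", "pairwise_compare", "results_frame"]


class StatsError(ValueError):
    """Raised for inputs the test contract rejects (e.g. n < 2)."""


@dataclass(frozen=True)
class TestResult:
    """One pairwise comparison of an analyte between two conditions."""

    analyte: str
    condition_a: str
    condition_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    t_statistic: float
    degrees_of_freedom: float
    p_raw: float
    p_adjusted: float
    significant: bool


def _check_groups(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatsError(f"each group needs >= 2 values (got {a.size} and {b.size})")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise StatsError("non-finite values in input groups")
    return a, b


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's two-sided t test: (t, Welch–Satterthwaite df, p).

    With zero variance in both groups and equal means the comparison is
    degenerate; it is reported as t = 0, p = 1 (no evidence of a
    difference) with df = n_a + n_b − 2.
    """
    a, b = _check_groups(a, b)
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        raise StatsError("zero variance in both groups with unequal means: t undefined")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def pooled_t(a, b) -> tuple[float, float, float]:
    """Student's pooled-variance two-sided t test: (t, df, p)."""
    a, b = _check_groups(a, b)
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        raise StatsError("zero variance in both groups with unequal means: t undefined")
    res = sps.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(a.size + b.size - 2), float(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values, in the input order.

    Step-up rule on the sorted scale: p(i) → min_{j>=i} min(1, p(j)·m/j),
    mapped back to the original order. Idempotent.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise StatsError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pairwise_compare(
    ds: ConditionDataset,
    analyte: str | None = None,
    *,
    family: str = "analyte",
    alpha: float = 0.05,
    variant: str = "welch",
    log_transform: bool = False,
) -> list[TestResult]:
    """Test all unordered condition pairs for one analyte (or all analytes).

    Parameters
    ----------
    analyte:
        Analyte to compare; ``None`` compares every analyte in the dataset.
    family:
        BH correction family: ``"analyte"`` adjusts within each analyte's
        pairs, ``"global"`` across all (analyte, pair) tests at once.
    alpha:
        Significance threshold applied to the adjusted p-value.
    variant:
        ``"welch"`` (unequal variances, default) or ``"pooled"``.
    log_transform:
        Compare natural-log values instead of raw values (all values must
        be positive).
    """
    if family not in {"analyte", "global"}:
        raise ValueError(f"unknown family {family!r}")
    test = {"welch": welch_t, "pooled": pooled_t}.get(variant)
    if test is None:
        raise ValueError(f"unknown t-test variant {variant!r}")
    analytes = [analyte] if analyte is not None else ds.analytes

    raw: list[TestResult] = []
    for an in analytes:
        groups = {
            cond: np.asarray(ds.values(cond, an), dtype=float)
            for cond in ds.conditions
            if len(ds.values(cond, an)) >= 2
        }
        if len(groups) < 2:
            raise StatsError(f"analyte {an!r}: fewer than 2 conditions with >= 2 replicates")
        for ca, cb in itertools.combinations(sorted(groups), 2):
            a, b = groups[ca], groups[cb]
            if log_transform:
                if np.any(a <= 0) or np.any(b <= 0):
                    raise StatsError(f"analyte {an!r}: non-positive values, log transform impossible")
                a, b = np.log(a), np.log(b)
            t, df, p = test(a, b)
            raw.append(
                TestResult(
                    analyte=an, condition_a=ca, condition_b=cb,
                    n_a=a.size, n_b=b.size,
                    mean_a=float(np.asarray(ds.values(ca, an)).mean()),
                    mean_b=float(np.asarray(ds.values(cb, an)).mean()),
                    t_statistic=t, degrees_of_freedom=df, p_raw=p,
                    p_adjusted=np.nan, significant=False,
                )
            )

    adjusted: list[TestResult] = []
    if family == "global":
        families = {None: raw}
    else:
        families = {}
        for r in raw:
            families.setdefault(r.analyte, []).append(r)
    for members in families.values():
        p_adj = bh_adjust([r.p_raw for r in members])
        for r, q in zip(members, p_adj):
            adjusted.append(
                TestResult(**{**r.__dict__, "p_adjusted": float(q), "significant": bool(q < alpha)})
            )
    order = {(r.analyte, r.condition_a, r.condition_b): i for i, r in enumerate(raw)}
    adjusted.sort(key=lambda r: order[(r.analyte, r.condition_a, r.condition_b)])
    return adjusted


def results_frame(results: list[TestResult]) -> pd.DataFrame:
    """Flatten a list of :class:`TestResult` into a tidy DataFrame."""
    return pd.DataFrame([r.__dict__ for r in results])
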