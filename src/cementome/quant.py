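"""Quantitation normalization and time-course differential representation.

Global normalization follows the Total Area Sums (TAS) convention: every
run (column) is rescaled so its summed abundance equals the grand mean of
the raw run totals, which preserves within-run proportions and makes run
totals identical.  Differential representation between the feeding stages
T1/T2/T3 is assessed per protein with a two-sided Student's t-test
(pooled variance) on the three pairwise comparisons T1vT2, T2vT3, T1vT3
at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import QuantMatrix, ValidationError

__all__ = [
    "COMPARISONS",
    "DifferentialResult",
    "tas_normalize",
    "differential_test",
    "differential_table",
    "anova_oneway",
]

#: the three pairwise time comparisons, (earlier, later)
COMPARISONS = {"T1vT2": ("T1", "T2"), "T2vT3": ("T2", "T3"), "T1vT3": ("T1", "T3")}


@dataclass
class DifferentialResult:
    """One protein × one pairwise time comparison."""

    protein: str
    comparison: str
    mean_a: float
    mean_b: float
    direction: str  # up | down | flat (later relative to earlier)
    t_statistic: float
    p_value: float
    significant: bool
    testable: bool = True


def tas_normalize(matrix: QuantMatrix) -> QuantMatrix:
    """Rescale each run so its total equals the grand mean of raw run totals.

    Idempotent; raises for any all-zero run (that run's scale is undefined).
    """
    totals = matrix.values.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValidationError(f"all-zero run(s): {list(zero)}")
    target = float(totals.mean())
    scaled = matrix.values * (target / totals)
    return QuantMatrix(scaled, matrix.runs.copy())


def _pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided pooled-variance (Student's) t-test.

    Returns (t, p); identical constant groups give t = 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return np.inf if a.mean() > b.mean() else -np.inf, 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def differential_test(
    matrix: QuantMatrix,
    comparisons: dict[str, tuple[str, str]] | None = None,
    alpha: float = 0.05,
    replicate_unit: str = "run",
    fdr: bool = False,
) -> list[DifferentialResult]:
    """Per-protein pairwise time comparisons on a normalized matrix.

    ``replicate_unit='run'`` uses every biological × technical run as an
    observation (n = 6 per time point under the study design);
    ``'bio_rep_mean'`` first averages technical replicates within each
    biological replicate.  Proteins with fewer than two observations in
    either group of a comparison are flagged untestable rather than
    silently dropped.  The reported direction is that of the later time
    point relative to the earlier one.

    ``fdr=True`` gates significance on Benjamini–Hochberg-adjusted
    p-values (per comparison, across proteins) instead of raw p < alpha;
    the raw convention is the default.
    """
    if replicate_unit not in ("run", "bio_rep_mean"):
        raise ValueError(f"unknown replicate_unit: {replicate_unit!r}")
    comparisons = comparisons or COMPARISONS
    runs = matrix.runs
    results: list[DifferentialResult] = []

    groups: dict[str, np.ndarray] = {}
    for tp in set(t for pair in comparisons.values() for t in pair):
        cols = runs.index[runs["time"] == tp]
        block = matrix.values[cols]
        if replicate_unit == "bio_rep_mean" and len(cols):
            block = block.T.groupby(runs.loc[cols, "bio_rep"]).mean().T
        groups[tp] = block.to_numpy(dtype=float)

    t_arr = {}
    for name, (ta, tb) in comparisons.items():
        a, b = groups[ta], groups[tb]
        t_arr[name] = (a, b)

    for i, protein in enumerate(matrix.proteins):
        for name, (ta, tb) in comparisons.items():
            a = t_arr[name][0][i]
            b = t_arr[name][1][i]
            if a.size < 2 or b.size < 2:
                results.append(
                    DifferentialResult(protein, name, float("nan"), float("nan"),
                                       "flat", float("nan"), float("nan"),
                                       False, testable=False)
                )
                continue
            t, p = _pooled_t(a, b)
            mean_a, mean_b = float(a.mean()), float(b.mean())
            sig = bool(p < alpha)
            if not sig or mean_a == mean_b:
                direction = "flat"
            else:
                direction = "up" if mean_b > mean_a else "down"
            results.append(
                DifferentialResult(protein, name, mean_a, mean_b, direction, t, p, sig)
            )
    if fdr:
        _apply_bh(results, alpha)
    return results


def _apply_bh(results: list[DifferentialResult], alpha: float) -> None:
    """Re-gate significance on Benjamini–Hochberg-adjusted p-values,
    per comparison across proteins (in place)."""
    by_comp: dict[str, list[DifferentialResult]] = {}
    for r in results:
        if r.testable:
            by_comp.setdefault(r.comparison, []).append(r)
    for recs in by_comp.values():
        order = sorted(range(len(recs)), key=lambda i: recs[i].p_value)
        m = len(recs)
        adj = [0.0] * m
        running = 1.0
        for rank_from_end, i in enumerate(reversed(order)):
            rank = m - rank_from_end
            running = min(running, recs[i].p_value * m / rank)
            adj[i] = running
        for i, r in enumerate(recs):
            r.significant = bool(adj[i] < alpha)
            if not r.significant:
                r.direction = "flat"


def differential_table(results: list[DifferentialResult]) -> pd.DataFrame:
    """Flatten results to a tidy frame (one row per protein × comparison)."""
    return pd.DataFrame(
        [
            {
                "protein": r.protein,
                "comparison": r.comparison,
                "mean_a": r.mean_a,
                "mean_b": r.mean_b,
                "direction": r.direction,
                "t": r.t_statistic,
                "p": r.p_value,
                "significant": r.significant,
                "testable": r.testable,
            }
            for r in results
        ]
    )


def anova_oneway(groups: list[list[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA.

    Degenerate input (all groups constant with zero within-group variance)
    is reported as F = 0, p = 1 when the means are equal, which is the
    documented convention for "no evidence of difference"; unequal constant
    means give F = inf, p = 0.
    """
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValidationError("one-way ANOVA needs >=2 groups with >=2 values each")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if all(a.var(ddof=1) == 0 for a in arrs):
        means = {float(a.mean()) for a in arrs}
        if len(means) == 1:
            return 0.0, 1.0
        return float("inf"), 0.0
    f, p = stats.f_oneway(*arrs)
    return float(f), float(p)
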