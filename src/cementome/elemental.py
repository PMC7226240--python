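"""SEM–EDS elemental statistics and alpha-Gal ELISA quantitation.

Elemental composition (atomic %) is summarized per element, tissue and
feeding stage, classed by mean abundance (high > 10 atomic %, low < 1
atomic %, mid in between, rare = present in too few samples to analyze),
and compared across stages with one-way ANOVA.  Element abundances are
correlated with protein-group atomic composition by Spearman rank
correlation.  The alpha-Gal assay is quantified against a BSA–alpha-Gal
standard curve (OLS on blank-corrected standards over the 0.0–1.0 ng
working range) and compared between groups with Welch's t-test or one-way
ANOVA, matching the assay's statistical treatment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quant import anova_oneway
from .io import ValidationError

__all__ = [
    "ElisaPlate",
    "CalibrationFit",
    "summarize_elements",
    "correlate_composition",
    "fit_calibration",
    "calibration_from_plate",
    "quantify_alpha_gal",
    "compare_groups",
]


@dataclass
class ElisaPlate:
    """OD450 well readings: standards (known ng), blanks, and samples."""

    wells: pd.DataFrame  # columns: well, role, sample_id, ng, replicate, od
    coated_ng_per_well: float = 100.0

    def standards(self) -> pd.DataFrame:
        return self.wells[self.wells["role"] == "standard"]

    def blanks(self) -> pd.DataFrame:
        return self.wells[self.wells["role"] == "blank"]

    def samples(self) -> pd.DataFrame:
        return self.wells[self.wells["role"] == "sample"]


def _abundance_class(mean_pct: float) -> str:
    if mean_pct > 10.0:
        return "high"
    if mean_pct < 1.0:
        return "low"
    return "mid"


def summarize_elements(eds: pd.DataFrame, rare_min_samples: int = 2) -> pd.DataFrame:
    """Per (tissue, element): stage means, abundance class, ANOVA across stages.

    An element detected (atomic % > 0) in fewer than ``rare_min_samples``
    samples of a tissue is excluded as rare and reported with class
    ``rare`` and no test — the treatment applied to sporadic trace
    elements such as Br and Zn.
    """
    rows = []
    for (tissue, element), grp in eds.groupby(["tissue", "element"], sort=True):
        per_sample = grp.groupby(["sample_id"])["atomic_percent"].mean()
        n_detected = int((per_sample > 0).sum())
        if n_detected < rare_min_samples:
            rows.append({
                "tissue": tissue, "element": element, "class": "rare",
                "n_scans": len(grp), "mean_percent": float(grp["atomic_percent"].mean()),
                "mean_T1": float("nan"), "mean_T2": float("nan"),
                "mean_T3": float("nan"),
                "anova_F": float("nan"), "anova_p": float("nan"),
                "significant": False, "excluded": True,
            })
            continue
        by_time = {tp: g["atomic_percent"].to_list()
                   for tp, g in grp.groupby("time")}
        groups = [v for v in by_time.values() if len(v) >= 2]
        if len(groups) >= 2:
            f, p = anova_oneway(groups)
        else:
            f, p = float("nan"), float("nan")
        mean_pct = float(grp["atomic_percent"].mean())
        rows.append({
            "tissue": tissue, "element": element,
            "class": _abundance_class(mean_pct),
            "n_scans": len(grp), "mean_percent": mean_pct,
            "mean_T1": float(np.mean(by_time.get("T1", [np.nan]))),
            "mean_T2": float(np.mean(by_time.get("T2", [np.nan]))),
            "mean_T3": float(np.mean(by_time.get("T3", [np.nan]))),
            "anova_F": f, "anova_p": p,
            "significant": bool(p == p and p < 0.05), "excluded": False,
        })
    return pd.DataFrame(rows)


def correlate_composition(
    protein_atomic_percent: Mapping[str, float],
    eds_mean_percent: Mapping[str, float],
    elements: Sequence[str] = ("C", "N", "O", "S"),
) -> tuple[float, float]:
    """Spearman rank correlation between protein-group atomic composition
    and the stage-averaged EDS composition over the shared element list.

    Average ranks are used for ties.  Rank-concordant vectors give
    rho = 1; fully opposed vectors give -1.
    """
    if len(elements) < 3:
        raise ValidationError("need at least 3 elements for a rank correlation")
    missing = [e for e in elements
               if e not in protein_atomic_percent or e not in eds_mean_percent]
    if missing:
        raise ValidationError(f"element(s) missing from a composition vector: {missing}")
    a = [float(protein_atomic_percent[e]) for e in elements]
    b = [float(eds_mean_percent[e]) for e in elements]
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)


@dataclass
class CalibrationFit:
    """OLS line OD = intercept + slope * ng over the standard working range."""

    slope: float
    intercept: float
    r_squared: float
    working_range: tuple[float, float]

    def od_to_ng(self, od: float) -> float:
        return (od - self.intercept) / self.slope


def fit_calibration(standards: Sequence[tuple[float, float]]) -> CalibrationFit:
    """Ordinary least squares on (ng, OD) pairs; requires >= 3 standards
    spanning 0 ng; a flat OD response is a degenerate fit."""
    if len(standards) < 3:
        raise ValidationError("need at least 3 calibration standards")
    ng = np.array([s[0] for s in standards], dtype=float)
    od = np.array([s[1] for s in standards], dtype=float)
    if ng.min() > 0:
        raise ValidationError("calibration standards must include 0 ng")
    if np.allclose(od, od[0]):
        raise ValidationError("degenerate calibration: all OD readings equal")
    res = stats.linregress(ng, od)
    return CalibrationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
        working_range=(float(ng.min()), float(ng.max())),
    )


def calibration_from_plate(plate: ElisaPlate) -> CalibrationFit:
    """Fit the standard curve on blank-corrected standard ODs.

    The mean blank OD is subtracted from every standard reading before the
    fit, matching the assay protocol (blank subtraction from all reads);
    the resulting intercept absorbs any residual background.
    """
    blanks = plate.blanks()
    if blanks.empty:
        raise ValidationError("plate has no blank wells")
    blank_mean = float(blanks["od"].mean())
    stds = plate.standards()
    pairs = [(float(r["ng"]), float(r["od"]) - blank_mean) for _, r in stds.iterrows()]
    return fit_calibration(pairs)


def quantify_alpha_gal(plate: ElisaPlate, fit: CalibrationFit) -> pd.DataFrame:
    """ng alpha-Gal per 1 ug coated protein, per sample.

    Per sample: replicate ODs are averaged, the mean blank OD subtracted,
    the fitted line inverted (ng per well), and the result scaled to per
    microgram of coated protein (100 ng coated per well => x10).  Values
    driven negative by noise are floored at 0 and flagged.
    """
    blanks = plate.blanks()
    if blanks.empty:
        raise ValidationError("plate has no blank wells")
    blank_mean = float(blanks["od"].mean())
    scale = 1000.0 / plate.coated_ng_per_well
    rows = []
    for sid, grp in plate.samples().groupby("sample_id", sort=True):
        mean_od = float(grp["od"].mean())
        corrected = mean_od - blank_mean
        ng_per_well = fit.od_to_ng(corrected)
        floored = ng_per_well < 0
        ng_per_well = max(0.0, ng_per_well)
        rows.append({
            "sample_id": sid,
            "n_replicates": len(grp),
            "mean_od": mean_od,
            "blank_corrected_od": corrected,
            "ng_per_well": ng_per_well,
            "ng_per_ug_protein": ng_per_well * scale,
            "floored": bool(floored),
        })
    return pd.DataFrame(rows).set_index("sample_id")


def compare_groups(
    values_by_group: Mapping[str, Sequence[float]],
    mode: str = "welch_t",
) -> pd.DataFrame:
    """Group comparisons of quantified values.

    ``welch_t``: all pairwise two-sided t-tests with unequal variance
    (Welch–Satterthwaite df).  ``anova``: a single one-way ANOVA across
    all groups (e.g. across T1–T3).
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise ValidationError("need >= 2 groups with >= 2 values each")
    if mode == "anova":
        f, p = anova_oneway([list(v) for v in groups.values()])
        return pd.DataFrame([{
            "comparison": " vs ".join(groups), "statistic": f, "p": p,
            "test": "anova", "significant": bool(p < 0.05),
        }])
    if mode != "welch_t":
        raise ValueError(f"unknown mode: {mode!r}")
    names = list(groups)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = groups[names[i]], groups[names[j]]
            if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_ind(a, b, equal_var=False)
            rows.append({
                "comparison": f"{names[i]} vs {names[j]}",
                "statistic": float(t), "p": float(p), "test": "welch_t",
                "significant": bool(p < 0.05),
            })
    return pd.DataFrame(rows)
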