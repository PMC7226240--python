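"""Assignment of proteins to developmental-process categories.

A protein that is differentially represented (significant in at least one
pairwise comparison between feeding stages) is assigned to a category by
matching its significance/direction triple over (T1vT2, T2vT3, T1vT3)
against a template table; a protein with no significant comparison is
assigned to housekeeping functions.

The shipped default table (``data/profile_templates.json``) is a documented
reconstruction of the published profile shapes, which exist only as
figures: secondary cement production I peaks at T2, II rises by T2 and
stays high, cement maintenance holds through T2 then drops, molting is
T1-high, feeding rises monotonically, feeding-and-oogenesis rises late, and
detachment dips at T2 relative to T1 and T3.  The table is total: any
attainable triple resolves to exactly one category, either explicitly or
via the Hamming-nearest signature with a fixed priority order for ties.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .quant import COMPARISONS, DifferentialResult

__all__ = [
    "ProfileTemplates",
    "ProfileAssignment",
    "load_templates",
    "default_templates",
    "classify",
    "classify_matrix",
    "category_summary",
]

_STATES = ("up", "down", "ns")


@dataclass
class ProfileTemplates:
    """Total mapping from significance/direction triples to categories."""

    categories: dict[str, dict]
    priority: list[str]
    comparisons: list[str] = field(default_factory=lambda: list(COMPARISONS))

    def __post_init__(self) -> None:
        self._explicit: dict[tuple[str, ...], str] = {}
        for cat, spec in self.categories.items():
            pats = [tuple(spec["signature"])] + [
                tuple(p) for p in spec.get("extra_patterns", [])
            ]
            for pat in pats:
                if len(pat) != len(self.comparisons):
                    raise ValueError(f"pattern {pat} has wrong arity for {cat}")
                if any(s not in _STATES for s in pat):
                    raise ValueError(f"unknown state in pattern {pat}")
                if pat in self._explicit and self._explicit[pat] != cat:
                    raise ValueError(
                        f"pattern {pat} claimed by both {self._explicit[pat]} and {cat}"
                    )
                self._explicit[pat] = cat
        missing = [c for c in self.priority if c not in self.categories]
        if missing:
            raise ValueError(f"priority lists unknown categories: {missing}")

    def signature(self, category: str) -> tuple[str, ...]:
        return tuple(self.categories[category]["signature"])

    def trajectory(self, category: str) -> list[float]:
        return list(self.categories[category]["trajectory"])

    @property
    def category_names(self) -> list[str]:
        return list(self.categories)

    def match(self, pattern: tuple[str, ...]) -> str:
        """Resolve a triple to its category.

        Explicit entries win; otherwise the nearest template signature
        under a flip-type-aware edit cost, with the priority order breaking
        ties.  The cost reflects how a true profile could read as the
        observed triple: a template "ns" observed as significant is a
        type-I event (cost 1, probability ~alpha); a template effect
        observed as "ns" is a missed detection (cost 4, rare at the design
        power); an inverted sign is costlier still (cost 16).  The
        housekeeping gate (no significant comparison) is applied by the
        caller, so the fallback never returns housekeeping.
        """
        if pattern in self._explicit:
            return self._explicit[pattern]

        def flip_cost(template_state: str, observed: str) -> int:
            if template_state == observed or template_state == "any":
                return 0
            if template_state == "ns":
                return 1
            if observed == "ns":
                return 4
            return 16

        best_cat, best_d = None, float("inf")
        for cat in self.priority:
            spec = self.categories[cat]
            pats = [tuple(spec["signature"])] + [
                tuple(p) for p in spec.get("extra_patterns", [])
            ]
            d = min(sum(flip_cost(a, b) for a, b in zip(p, pattern)) for p in pats)
            if d < best_d:
                best_cat, best_d = cat, d
        if best_cat is None:
            raise ValueError(f"pattern triple not covered by templates: {pattern}")
        return best_cat


def load_templates(path: str | Path) -> ProfileTemplates:
    with open(path) as fh:
        raw = json.load(fh)
    return ProfileTemplates(
        categories=raw["categories"],
        priority=raw["priority"],
        comparisons=raw.get("comparisons", list(COMPARISONS)),
    )


def default_templates() -> ProfileTemplates:
    raw = json.loads(
        resources.files("cementome.data").joinpath("profile_templates.json").read_text()
    )
    return ProfileTemplates(
        categories=raw["categories"],
        priority=raw["priority"],
        comparisons=raw.get("comparisons", list(COMPARISONS)),
    )


@dataclass
class ProfileAssignment:
    protein: str
    category: str
    pattern: tuple[str, ...]
    evidence: list[DifferentialResult]


def _state(result: DifferentialResult) -> str:
    if not result.testable:
        return "ns"  # untestable comparisons carry no evidence of change
    return result.direction if result.significant else "ns"


def classify(
    results: list[DifferentialResult],
    templates: ProfileTemplates | None = None,
) -> list[ProfileAssignment]:
    """Assign every protein present in ``results`` to exactly one category.

    Deterministic given the template table; proteins with zero significant
    comparisons go to housekeeping.
    """
    templates = templates or default_templates()
    by_protein: dict[str, dict[str, DifferentialResult]] = {}
    for r in results:
        by_protein.setdefault(r.protein, {})[r.comparison] = r
    assignments = []
    for protein, comp_map in by_protein.items():
        missing = [c for c in templates.comparisons if c not in comp_map]
        if missing:
            raise ValueError(f"protein {protein} missing comparison(s): {missing}")
        evidence = [comp_map[c] for c in templates.comparisons]
        pattern = tuple(_state(r) for r in evidence)
        if all(s == "ns" for s in pattern):
            category = "housekeeping"
        else:
            category = templates.match(pattern)
        assignments.append(ProfileAssignment(protein, category, pattern, evidence))
    return assignments


def classify_matrix(matrix, templates: ProfileTemplates | None = None,
                    alpha: float = 0.05, replicate_unit: str = "run"):
    """Convenience wrapper: normalize, test, classify one tissue's matrix."""
    from .quant import differential_test, tas_normalize

    normalized = tas_normalize(matrix)
    results = differential_test(normalized, alpha=alpha, replicate_unit=replicate_unit)
    return classify(results, templates)


def classify_per_sample_type(
    matrix,
    templates: ProfileTemplates | None = None,
    alpha: float = 0.05,
    replicate_unit: str = "run",
    min_detect_fraction: float = 0.5,
) -> dict[tuple[str, str], list[ProfileAssignment]]:
    """Classify each (tissue, extraction) sample type separately.

    Within a sample type only proteins detected there (nonzero in more
    than ``min_detect_fraction`` of its runs) are tested; absences are
    true zeros, not noise, so they carry no profile information.
    """
    out: dict[tuple[str, str], list[ProfileAssignment]] = {}
    for (tissue, extraction), meta in matrix.runs.groupby(
            ["tissue", "extraction"], sort=True):
        mask = matrix.runs["tissue"].eq(tissue) & matrix.runs["extraction"].eq(extraction)
        sub = matrix.subset_runs(mask)
        detected = sub.values.index[(sub.values > 0).mean(axis=1) > min_detect_fraction]
        if not len(detected):
            continue
        sub = sub.subset_proteins(detected)
        out[(tissue, extraction)] = classify_matrix(
            sub, templates, alpha=alpha, replicate_unit=replicate_unit)
    return out


#: order in which a protein's assignments are merged across sample types
_SAMPLE_TYPE_PRIORITY = (
    ("salivary_gland", "native"), ("cement", "SDS"), ("cement", "urea"))


def consensus_assignments(
    per_sample_type: dict[tuple[str, str], list[ProfileAssignment]],
) -> dict[str, ProfileAssignment]:
    """One assignment per protein: the first available sample type in the
    fixed priority order (salivary gland, then SDS cement, then urea)."""
    merged: dict[str, ProfileAssignment] = {}
    keys = [k for k in _SAMPLE_TYPE_PRIORITY if k in per_sample_type]
    keys += [k for k in per_sample_type if k not in keys]
    for key in keys:
        for a in per_sample_type[key]:
            merged.setdefault(a.protein, a)
    return merged


def category_summary(
    assignments: list[ProfileAssignment],
    origins: pd.Series | dict,
    tissue: str | None = None,
) -> pd.DataFrame:
    """Percent of proteins per category, per origin (tick/host).

    Empty origin groups yield no rows rather than a division error;
    percentages within each origin sum to 100 up to rounding.
    """
    origins = pd.Series(origins)
    rows = []
    frame = pd.DataFrame(
        {
            "protein": [a.protein for a in assignments],
            "category": [a.category for a in assignments],
        }
    )
    frame["origin"] = frame["protein"].map(origins)
    for origin, grp in frame.groupby("origin"):
        counts = grp["category"].value_counts()
        for category, n in counts.items():
            rows.append(
                {
                    "tissue": tissue,
                    "origin": origin,
                    "category": category,
                    "n": int(n),
                    "percent": 100.0 * n / len(grp),
                }
            )
    return pd.DataFrame(rows, columns=["tissue", "origin", "category", "n", "percent"])
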