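"""Origin/tissue/extraction set algebra and key-protein selection.

The partition model reproduces the identification arithmetic of the
study design: the cementome is the unique-accession union of the SDS and
urea cement extractions, and every protein is placed in one cell of
(origin in {tick, host}) x (sialome-only, cementome-only, shared).
Accessions are opaque strings; "unique non-redundant entries" means exact
accession equality.

Key proteins are scored by four criteria: (a) identified in both sialome
and cementome; (b) among the top-2 mean normalized abundances within a
(non-housekeeping) profile category; (c) annotated to a GO biological
process holding over 4% of the annotations in the analyzed set; and
(d) high co-occurrence network centrality (BNC above a configurable
quantile — the operational reading of "after network analysis").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .io import ValidationError
from .profiles import ProfileAssignment

__all__ = [
    "PartitionSummary",
    "SelectionParams",
    "build_partition",
    "select_key_proteins",
    "go_process_shares",
    "top_n_with_other",
    "example_identification_sets",
]


def example_identification_sets() -> tuple[dict, dict]:
    """Synthetic accession sets reproducing the published identification
    arithmetic of the *R. microplus* sialome/cementome study design.

    Returns ``(identifications, origins)`` such that: the sialome holds
    1936 tick and 61 host proteins; the cementome is the union of disjoint
    SDS (388) and urea (266) extraction sets, 654 unique accessions; 13
    tick and 49 host proteins are shared between sialome and cementome
    (62 total); and 68 tick proteins are cementome-only, so the tick
    cementome totals 81.  Accessions are placeholders — only the set
    arithmetic is meaningful.
    """
    tick_shared = [f"TS{i}" for i in range(13)]
    host_shared = [f"HS{i}" for i in range(49)]
    tick_cem_only = [f"TC{i}" for i in range(68)]
    tick_sial_only = [f"T{i}" for i in range(1936 - 13)]
    host_sial_only = [f"H{i}" for i in range(61 - 49)]
    # remaining cementome identifications are host-derived (the study read
    # most of these as contaminants from host tissue on the cement cone)
    host_cem_only = [f"HC{i}" for i in range(654 - 13 - 49 - 68)]

    cementome = tick_shared + host_shared + tick_cem_only + host_cem_only
    identifications = {
        ("salivary_gland", "native"):
            tick_sial_only + host_sial_only + tick_shared + host_shared,
        ("cement", "SDS"): cementome[:388],
        ("cement", "urea"): cementome[388:],
    }
    origins = {}
    for accs in identifications.values():
        for acc in accs:
            origins[acc] = "host" if acc[0] == "H" else "tick"
    return identifications, origins


@dataclass
class PartitionSummary:
    """Venn counts per origin plus extraction identification sets."""

    sialome: set[str]
    cementome: set[str]
    extraction_sets: dict[str, set[str]]  # e.g. {"SDS": ..., "urea": ...}
    origins: dict[str, str]

    @property
    def shared(self) -> set[str]:
        return self.sialome & self.cementome

    def counts(self) -> pd.DataFrame:
        rows = []
        for origin in ("tick", "host"):
            members = {a for a, o in self.origins.items() if o == origin}
            sial = self.sialome & members
            cem = self.cementome & members
            shared = sial & cem
            rows.append({
                "origin": origin,
                "sialome_total": len(sial),
                "cementome_total": len(cem),
                "sialome_only": len(sial - cem),
                "cementome_only": len(cem - sial),
                "shared": len(shared),
            })
        return pd.DataFrame(rows).set_index("origin")

    def summary(self) -> dict:
        counts = self.counts()
        return {
            "sialome_total": len(self.sialome),
            "cementome_total": len(self.cementome),
            "shared_total": len(self.shared),
            "extraction_counts": {k: len(v) for k, v in self.extraction_sets.items()},
            "extraction_union": len(set().union(*self.extraction_sets.values()))
            if self.extraction_sets else 0,
            "per_origin": counts.to_dict(orient="index"),
        }


def build_partition(
    identifications: Mapping[tuple[str, str], Iterable[str]],
    annotations: pd.DataFrame | Mapping[str, str],
) -> PartitionSummary:
    """Build the partition from per-(tissue, extraction) accession sets.

    ``identifications`` maps (tissue, extraction) — e.g.
    ("salivary_gland", "native"), ("cement", "SDS"), ("cement", "urea") —
    to iterables of accessions.  Counts are invariant to input ordering
    and duplication.  Every accession must carry an origin annotation.
    """
    if isinstance(annotations, pd.DataFrame):
        origins = annotations["origin"].to_dict()
    else:
        origins = dict(annotations)
    sialome: set[str] = set()
    extraction_sets: dict[str, set[str]] = {}
    for (tissue, extraction), accs in identifications.items():
        accs = set(accs)
        if tissue == "salivary_gland":
            sialome |= accs
        elif tissue == "cement":
            extraction_sets.setdefault(extraction, set()).update(accs)
        else:
            raise ValidationError(f"unknown tissue: {tissue!r}")
    cementome = set().union(*extraction_sets.values()) if extraction_sets else set()
    unannotated = sorted((sialome | cementome) - set(origins))
    if unannotated:
        raise ValidationError(f"unannotated accession(s): {unannotated}")
    return PartitionSummary(
        sialome=sialome,
        cementome=cementome,
        extraction_sets=extraction_sets,
        origins={a: origins[a] for a in sialome | cementome},
    )


def go_process_shares(
    annotations: pd.DataFrame,
    protein_set: Iterable[str] | None = None,
    denominator: str = "annotations",
) -> pd.Series:
    """Share of each GO biological process within the analyzed set.

    Default denominator is the number of (protein, process) annotation
    pairs (a pie-chart reading); ``denominator='proteins'`` divides each
    process's protein count by the number of annotated proteins instead
    (shares then need not sum to 1).  Shares are sorted descending.
    """
    if protein_set is not None:
        protein_set = set(protein_set)
        ann = annotations.loc[[a for a in annotations.index if a in protein_set]]
    else:
        ann = annotations
    pairs: list[tuple[str, str]] = []
    for acc, row in ann.iterrows():
        for term in row.get("go_terms", []) or []:
            pairs.append((acc, term))
    if not pairs:
        return pd.Series(dtype=float)
    frame = pd.DataFrame(pairs, columns=["accession", "process"])
    counts = frame["process"].value_counts()
    if denominator == "annotations":
        shares = counts / counts.sum()
    elif denominator == "proteins":
        shares = counts / frame["accession"].nunique()
    else:
        raise ValueError(f"unknown denominator: {denominator!r}")
    return shares.sort_values(ascending=False)


def top_n_with_other(shares: pd.Series, n: int = 10) -> pd.Series:
    """Keep the n largest shares and bucket the remainder as 'Other'."""
    if len(shares) <= n:
        return shares.copy()
    top = shares.iloc[:n].copy()
    top.loc["Other"] = float(shares.iloc[n:].sum())
    return top


@dataclass
class SelectionParams:
    top_k: int = 2
    go_share_threshold: float = 0.04
    centrality_quantile: float = 0.9


@dataclass
class SelectionScore:
    protein: str
    shared_sialome_cementome: bool
    top2_in_profile_category: bool
    go_process_share_gt_threshold: bool
    high_network_centrality: bool
    criteria_met: int
    centrality_available: bool = True


def select_key_proteins(
    assignments: list[ProfileAssignment],
    partition: PartitionSummary,
    annotations: pd.DataFrame,
    mean_abundance: Mapping[str, float],
    centrality: Mapping[str, float] | None = None,
    params: SelectionParams | None = None,
) -> pd.DataFrame:
    """Score each assigned protein on the four selection criteria.

    ``mean_abundance`` is the mean normalized TAS per protein (used to
    rank within categories; ties at the top-k boundary keep all tied
    proteins).  A missing centrality table skips that criterion with a
    warning flag rather than scoring it false.
    """
    params = params or SelectionParams()
    by_cat: dict[str, list[str]] = {}
    for a in assignments:
        if a.category != "housekeeping":
            by_cat.setdefault(a.category, []).append(a.protein)

    top_flags: set[str] = set()
    for cat, prots in by_cat.items():
        ranked = sorted(prots, key=lambda p: (-float(mean_abundance.get(p, 0.0)), p))
        if len(ranked) <= params.top_k:
            top_flags.update(ranked)
            continue
        # keep the top k plus anything tied with the k-th value
        cutoff = float(mean_abundance.get(ranked[params.top_k - 1], 0.0))
        top_flags.update(p for p in ranked
                         if float(mean_abundance.get(p, 0.0)) >= cutoff)

    shares = go_process_shares(annotations, [a.protein for a in assignments])
    hot_processes = set(shares.index[shares > params.go_share_threshold])

    central_cut = None
    if centrality is not None and len(centrality):
        vals = pd.Series(dict(centrality), dtype=float)
        central_cut = float(vals.quantile(params.centrality_quantile))

    rows = []
    for a in assignments:
        p = a.protein
        go_terms = annotations.loc[p, "go_terms"] if p in annotations.index else []
        go_flag = any(t in hot_processes for t in (go_terms or []))
        if centrality is None:
            central_flag, available = False, False
        else:
            bnc = float(dict(centrality).get(p, 0.0))
            central_flag = bool(len(centrality) and bnc >= central_cut and bnc > 0)
            available = True
        flags = {
            "shared_sialome_cementome": p in partition.shared,
            "top2_in_profile_category": p in top_flags,
            "go_process_share_gt_threshold": bool(go_flag),
            "high_network_centrality": central_flag,
        }
        rows.append({
            "protein": p,
            "category": a.category,
            **flags,
            "criteria_met": int(sum(flags.values())),
            "centrality_available": available,
        })
    return pd.DataFrame(rows).set_index("protein").sort_values(
        ["criteria_met", "protein"], ascending=[False, True])
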