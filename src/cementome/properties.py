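"""Sequence-derived physicochemical panel and the amino-acid ratio screen.

Implements the calculators the ExPASy ProtParam tool reports for a protein
sequence: amino-acid mole composition, theoretical isoelectric point
(Bjellqvist pKa set, Henderson–Hasselbalch charge model solved by
bisection), GRAVY (mean Kyte–Doolittle hydropathy), the Guruprasad
instability index (dipeptide DIWV weights, instability threshold 40), the
Ikai aliphatic index, and the molecular atomic composition (C, H, N, O, S).

Ambiguous residues (X) are excluded from all mole-percent denominators and
counted per sequence.  Two published constant tables are vendored under
``data/``: the DIWV dipeptide weights (Guruprasad, Reddy & Pandit 1990,
Protein Eng. 4:155–161) and the Bjellqvist pKa set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "AMINO_ACIDS",
    "KYTE_DOOLITTLE",
    "RESIDUE_FORMULAS",
    "PhysicoChemProfile",
    "aa_composition",
    "gravy",
    "isoelectric_point",
    "instability_index",
    "aliphatic_index",
    "atomic_composition",
    "physchem_profile",
    "profile_table",
    "ratio_screen",
    "group_property_summary",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Kyte & Doolittle (1982) hydropathy values
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: atoms (C, H, N, O, S) per free amino acid; peptide bonds remove one
#: water per bond
RESIDUE_FORMULAS = {
    "A": (3, 7, 1, 2, 0), "R": (6, 14, 4, 2, 0), "N": (4, 8, 2, 3, 0),
    "D": (4, 7, 1, 4, 0), "C": (3, 7, 1, 2, 1), "Q": (5, 10, 2, 3, 0),
    "E": (5, 9, 1, 4, 0), "G": (2, 5, 1, 2, 0), "H": (6, 9, 3, 2, 0),
    "I": (6, 13, 1, 2, 0), "L": (6, 13, 1, 2, 0), "K": (6, 14, 2, 2, 0),
    "M": (5, 11, 1, 2, 1), "F": (9, 11, 1, 2, 0), "P": (5, 9, 1, 2, 0),
    "S": (3, 7, 1, 3, 0), "T": (4, 9, 1, 3, 0), "W": (11, 12, 2, 2, 0),
    "Y": (9, 11, 1, 3, 0), "V": (5, 11, 1, 2, 0),
}

_ELEMENTS = ("C", "H", "N", "O", "S")


def _load_json(name: str):
    return json.loads(resources.files("cementome.data").joinpath(name).read_text())


_DIWV: dict[str, dict[str, float]] | None = None
_PKA_SETS: dict[str, dict] = {}


def _diwv() -> dict[str, dict[str, float]]:
    global _DIWV
    if _DIWV is None:
        _DIWV = _load_json("diwv.json")
    return _DIWV


def _pka(name: str = "bjellqvist") -> dict:
    if name not in _PKA_SETS:
        _PKA_SETS[name] = _load_json(f"pka_{name}.json")
    return _PKA_SETS[name]


def _clean(sequence: str) -> tuple[str, int]:
    """Upper-case, drop X; return (defined residues, count of X dropped)."""
    seq = sequence.upper()
    n_x = seq.count("X")
    defined = "".join(ch for ch in seq if ch != "X")
    bad = set(defined) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"non-standard residue(s): {sorted(bad)}")
    return defined, n_x


def aa_composition(sequence: str) -> dict[str, float]:
    """Mole percent of each of the 20 residues (sums to 100).

    X residues are excluded from the denominator.
    """
    defined, _ = _clean(sequence)
    if not defined:
        raise ValueError("empty sequence (or all-ambiguous)")
    n = len(defined)
    return {aa: 100.0 * defined.count(aa) / n for aa in AMINO_ACIDS}


def gravy(sequence: str) -> float:
    """Grand average of hydropathicity over the defined residues."""
    defined, _ = _clean(sequence)
    if not defined:
        raise ValueError("empty sequence")
    return sum(KYTE_DOOLITTLE[aa] for aa in defined) / len(defined)


def _charge_at(ph: float, counts: Mapping[str, int], pos_pk: dict,
               neg_pk: dict) -> float:
    pos = sum(
        n / (1.0 + 10.0 ** (ph - pos_pk[grp]))
        for grp, n in counts.items()
        if grp in pos_pk
    )
    neg = sum(
        n / (1.0 + 10.0 ** (neg_pk[grp] - ph))
        for grp, n in counts.items()
        if grp in neg_pk
    )
    return pos - neg


def isoelectric_point(sequence: str, pka_set: str = "bjellqvist",
                      tol: float = 1e-4) -> float:
    """Theoretical pI: the pH in [0, 14] where net charge crosses zero.

    Charge is the Henderson–Hasselbalch sum over the termini and the
    D, E, C, Y, H, K, R side chains, with residue-specific terminal pKa
    overrides where the model defines them; the root is found by
    bisection.
    """
    defined, _ = _clean(sequence)
    if not defined:
        raise ValueError("empty sequence")
    pka = _pka(pka_set)
    pos_pk = dict(pka["positive"])
    neg_pk = dict(pka["negative"])
    pos_pk["Nterm"] = pka.get("nterm_by_residue", {}).get(defined[0],
                                                          pos_pk["Nterm"])
    neg_pk["Cterm"] = pka.get("cterm_by_residue", {}).get(defined[-1],
                                                          neg_pk["Cterm"])
    counts: dict[str, int] = {"Nterm": 1, "Cterm": 1}
    for grp in ("K", "R", "H", "D", "E", "C", "Y"):
        counts[grp] = defined.count(grp)
    lo, hi = 0.0, 14.0
    # net charge is monotone decreasing in pH: positive at 0, negative at 14
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if _charge_at(mid, counts, pos_pk, neg_pk) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def instability_index(sequence: str) -> float:
    """Guruprasad instability index: (10/L) * sum of DIWV dipeptide weights.

    Values above 40 predict an unstable protein in vitro.  Order matters:
    the index is generally not invariant under sequence reversal.
    """
    defined, _ = _clean(sequence)
    if len(defined) < 2:
        raise ValueError("instability index needs at least 2 defined residues")
    diwv = _diwv()
    total = sum(diwv[a][b] for a, b in zip(defined, defined[1:]))
    return 10.0 / len(defined) * total


def aliphatic_index(sequence: str) -> float:
    """Ikai aliphatic index: X(Ala) + 2.9 X(Val) + 3.9 (X(Ile) + X(Leu)),
    with X the mole percent of each residue."""
    comp = aa_composition(sequence)
    return comp["A"] + 2.9 * comp["V"] + 3.9 * (comp["I"] + comp["L"])


def atomic_composition(sequence: str) -> tuple[dict[str, int], dict[str, float]]:
    """Atom counts and atomic percent (C, H, N, O, S) of the polypeptide.

    The molecular formula is the sum of free-residue formulas minus
    (L - 1) waters for the peptide bonds.
    """
    defined, _ = _clean(sequence)
    if not defined:
        raise ValueError("empty sequence")
    totals = np.zeros(5, dtype=int)
    for aa in defined:
        totals += np.array(RESIDUE_FORMULAS[aa])
    n_bonds = len(defined) - 1
    totals[1] -= 2 * n_bonds  # H2O per bond
    totals[3] -= n_bonds
    counts = dict(zip(_ELEMENTS, (int(x) for x in totals)))
    total_atoms = int(totals.sum())
    percent = {el: 100.0 * counts[el] / total_atoms for el in _ELEMENTS}
    return counts, percent


@dataclass
class PhysicoChemProfile:
    """Per-sequence physicochemical panel (ProtParam-equivalent)."""

    accession: str
    length: int
    n_ambiguous: int
    aa_percent: dict[str, float]
    pi: float
    gravy: float
    instability_index: float
    unstable: bool
    aliphatic_index: float
    atomic_counts: dict[str, int]
    atomic_percent: dict[str, float]


def physchem_profile(accession: str, sequence: str,
                     pka_set: str = "bjellqvist") -> PhysicoChemProfile:
    defined, n_x = _clean(sequence)
    counts, percent = atomic_composition(sequence)
    ii = instability_index(sequence) if len(defined) >= 2 else float("nan")
    return PhysicoChemProfile(
        accession=accession,
        length=len(defined),
        n_ambiguous=n_x,
        aa_percent=aa_composition(sequence),
        pi=isoelectric_point(sequence, pka_set),
        gravy=gravy(sequence),
        instability_index=ii,
        unstable=bool(ii > 40.0),
        aliphatic_index=aliphatic_index(sequence),
        atomic_counts=counts,
        atomic_percent=percent,
    )


def profile_table(sequences: Mapping[str, str]) -> pd.DataFrame:
    """One row per protein with the scalar panel plus aa/atomic percents."""
    rows = []
    for acc, seq in sequences.items():
        p = physchem_profile(acc, seq)
        row = {
            "accession": acc,
            "length": p.length,
            "n_ambiguous": p.n_ambiguous,
            "pI": p.pi,
            "gravy": p.gravy,
            "instability_index": p.instability_index,
            "unstable": p.unstable,
            "aliphatic_index": p.aliphatic_index,
        }
        row.update({f"aa_{aa}": p.aa_percent[aa] for aa in AMINO_ACIDS})
        row.update({f"atom_{el}": p.atomic_percent[el] for el in _ELEMENTS})
        rows.append(row)
    return pd.DataFrame(rows).set_index("accession")


def ratio_screen(
    group_a_percent: Mapping[str, float],
    group_b_percent: Mapping[str, float],
    low: float = 0.5,
    high: float = 1.5,
) -> pd.DataFrame:
    """Flag residues whose mole-percent ratio a/b lies in either tail.

    A residue is flagged iff ratio <= ``low`` or ratio >= ``high``
    (boundaries inclusive).  A zero denominator with a nonzero numerator
    reports an infinite ratio and is flagged; 0/0 is reported as NaN and
    not flagged.
    """
    rows = []
    for aa in AMINO_ACIDS:
        a = float(group_a_percent.get(aa, 0.0))
        b = float(group_b_percent.get(aa, 0.0))
        if b == 0.0:
            ratio = float("nan") if a == 0.0 else float("inf")
        else:
            ratio = a / b
        flagged = bool(ratio <= low or ratio >= high) if ratio == ratio else False
        rows.append({"residue": aa, "percent_a": a, "percent_b": b,
                     "ratio": ratio, "flagged": flagged})
    return pd.DataFrame(rows).set_index("residue")


def group_property_summary(
    groups: Mapping[str, Mapping[str, str]],
    subsample: Mapping[str, int] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean physicochemical profile per protein group.

    ``groups`` maps a group name (e.g. host, tick, host_cement,
    tick_cement) to its accession → sequence mapping.  ``subsample``
    optionally caps a group at n randomly chosen proteins (fixed seed, as
    for the 100-protein tick subsample); groups at or under the cap are
    kept whole.  Empty groups yield no row.
    """
    subsample = subsample or {}
    rng = np.random.default_rng(seed)
    rows = []
    for name, seqs in groups.items():
        accs = sorted(seqs)
        cap = subsample.get(name)
        if cap is not None and len(accs) > cap:
            accs = sorted(rng.choice(accs, size=cap, replace=False))
        if not accs:
            continue
        table = profile_table({a: seqs[a] for a in accs})
        mean = table.drop(columns=["unstable"]).mean(numeric_only=True)
        row = {"group": name, "n_proteins": len(accs)}
        row.update(mean.to_dict())
        rows.append(row)
    return pd.DataFrame(rows).set_index("group") if rows else pd.DataFrame()
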