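"""Synthetic data with known ground truth for the whole pipeline.

The generator emulates the study design this package analyzes: three adult
female feeding stages (T1, T2, T3), two biological replicates, three
technical replicates, and three sample types — salivary-gland lysate
("native" extraction) plus SDS- and urea-extracted cement — for 54 LC–MS
runs in total.  Protein abundances are log-normal around category-specific
mean trajectories taken from the same profile-template table the
classifier uses, so classification recovery is a closed loop with known
truth.  Sequences, origin labels, GO-process annotations, SEM–EDS
elemental tables and ELISA plates are generated to match.

The abundance model is multiplicative: biological and technical
coefficients of variation act as independent log-normal noise layers
(sigma = sqrt(log(1 + cv^2))).  Positive, right-skewed label-free
intensities motivate the choice; no distributional claim from real data is
encoded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .elemental import ElisaPlate
from .io import QuantMatrix, TIME_POINTS
from .profiles import ProfileTemplates, default_templates
from .properties import AMINO_ACIDS, atomic_composition

__all__ = [
    "ParameterError",
    "SyntheticConfig",
    "TruthRecord",
    "GroundTruth",
    "generate_dataset",
    "generate_eds_table",
    "ElisaPlate",
    "generate_elisa_plate",
    "DEFAULT_GO_PROCESSES",
]


class ParameterError(ValueError):
    """An invalid generator parameter, named in the message."""


#: GO biological-process vocabulary used for synthetic annotations,
#: drawn from processes typical of sialome/cementome datasets
DEFAULT_GO_PROCESSES = (
    "translation",
    "cytoskeleton organization",
    "proteolysis",
    "immune response",
    "catalytic activity",
    "carbohydrate metabolism",
    "protein processing and transport",
    "blood circulation and coagulation",
    "oxidation-reduction process",
    "lipid metabolism",
    "ion transport",
    "signal transduction",
    "chitin metabolism",
    "cell adhesion",
)

_MEMBERSHIPS = ("sialome_only", "cementome_only", "shared")


def _sample_type_members(key: tuple) -> list[str]:
    """Which run types (SG, SDS cement, urea cement) a cell contributes to."""
    _origin, membership, ext = key
    types = []
    if membership in ("sialome_only", "shared"):
        types.append("SG")
    if membership in ("cementome_only", "shared"):
        if "SDS" in ext:
            types.append("SDS")
        if "urea" in ext:
            types.append("urea")
    return types


def _solve_cell_weights(
    cell_mass: Mapping[tuple, float],
    host_weights: Mapping[str, float],
    templates: ProfileTemplates,
    effect_size: float,
) -> dict[tuple, dict[str, float]]:
    """Category mass-share targets per cell making every run type's total
    abundance stage-stable.

    Global TAS normalization assumes run totals reflect sample loading, not
    biology; the emulated proteome therefore balances up- against
    down-regulated mass within every run type (salivary gland, SDS cement,
    urea cement).  Host cells keep the configured (unbalanced) host
    category tilt, so the tick cells must compensate: this solver finds,
    per tick cell, the category distribution closest to uniform such that
    each run type's realized mixture is stage-balanced at the configured
    effect size, given the realized cell masses.
    """
    from scipy.optimize import minimize

    cats = list(templates.category_names)
    n_cat = len(cats)
    v = np.array([[effect_size ** m for m in templates.trajectory(c)] for c in cats])
    a_vecs = (v[:, 0] - v[:, 1], v[:, 1] - v[:, 2])
    h = np.array([float(host_weights.get(c, 0.0)) for c in cats])

    tick_cells = sorted(k for k in cell_mass if k[0] == "tick")
    host_cells = [k for k in cell_mass if k[0] == "host"]
    if not tick_cells:
        return {k: {c: float(x) for c, x in zip(cats, h)} for k in host_cells}

    def unpack(x):
        return {k: x[i * n_cat:(i + 1) * n_cat] for i, k in enumerate(tick_cells)}

    def type_mix(x, run_type):
        w = unpack(x)
        mix = np.zeros(n_cat)
        for k in tick_cells:
            if run_type in _sample_type_members(k):
                mix = mix + cell_mass[k] * w[k]
        for k in host_cells:
            if run_type in _sample_type_members(k):
                mix = mix + cell_mass[k] * h
        return mix

    run_types = sorted({t for k in cell_mass for t in _sample_type_members(k)})
    cons = []
    for i in range(len(tick_cells)):
        cons.append({"type": "eq",
                     "fun": lambda x, i=i: x[i * n_cat:(i + 1) * n_cat].sum() - 1.0})
    total_mass = sum(cell_mass.values())

    # balance enters as a heavy penalty, not a hard constraint: realized
    # masses can make exact balance infeasible, and the continuous
    # per-protein rebalancing downstream removes any small residual
    def objective(x):
        dist = np.sum((x - 1.0 / n_cat) ** 2)
        pen = 0.0
        for rt in run_types:
            mix = type_mix(x, rt)
            for a in a_vecs:
                pen += (mix @ a / total_mass) ** 2
        return dist + 1e4 * pen

    x0 = np.full(len(tick_cells) * n_cat, 1.0 / n_cat)
    res = minimize(objective, x0, constraints=cons,
                   bounds=[(0.0, 1.0)] * len(x0),
                   method="SLSQP", options={"maxiter": 500, "ftol": 1e-14})
    w = unpack(np.clip(res.x, 0.0, None))
    out = {k: {c: float(x / w[k].sum()) for c, x in zip(cats, w[k])}
           for k in tick_cells}
    for k in host_cells:
        out[k] = {c: float(x) for c, x in zip(cats, h)}
    return out


def _default_host_category_weights() -> dict[str, float]:
    # host proteins concentrate (86%) in feeding-and-oogenesis and the two
    # secondary cement production templates, mirroring the partition the
    # pipeline reports for host-derived proteins
    return {
        "feeding_and_oogenesis": 0.43,
        "secondary_cement_production_I": 0.215,
        "secondary_cement_production_II": 0.215,
        "housekeeping": 0.05,
        "feeding": 0.03,
        "molting": 0.02,
        "cement_maintenance": 0.02,
        "detachment": 0.02,
    }


@dataclass
class SyntheticConfig:
    """All tunable generator parameters (fixed seed => byte-identical output)."""

    n_proteins: int = 200
    fraction_host: float = 0.2
    #: None => compositionally balanced weights (see _solve_cell_weights)
    category_weights: dict[str, float] | None = None
    host_category_weights: dict[str, float] = field(
        default_factory=_default_host_category_weights
    )
    mean_log_abundance: float = 11.5  # log TAS units, exp(11.5) ~ 1e5
    log_abundance_sd: float = 1.0  # protein-to-protein spread, log units
    cv_technical: float = 0.1
    cv_biological: float = 0.2
    effect_size: float = 4.0  # fold change per trajectory step, > 1
    n_bio_reps: int = 2
    n_tech_reps: int = 3
    seed: int = 0
    gly_rich_fraction: float = 0.3  # of tick proteins
    gly_percent_range: tuple[float, float] = (30.0, 45.0)
    sequence_length_range: tuple[int, int] = (80, 300)
    #: membership probabilities (sialome_only, cementome_only, shared) per origin
    tick_membership: tuple[float, float, float] = (0.70, 0.25, 0.05)
    host_membership: tuple[float, float, float] = (0.10, 0.50, 0.40)

    def validate(self) -> None:
        if self.n_proteins < 0:
            raise ParameterError("n_proteins must be >= 0")
        for name in ("fraction_host", "cv_technical", "cv_biological",
                     "gly_rich_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1]")
        for name in ("category_weights", "host_category_weights"):
            w = getattr(self, name)
            if w is None:
                continue
            if abs(sum(w.values()) - 1.0) > 1e-9:
                raise ParameterError(f"{name} must sum to 1")
            if any(v < 0 for v in w.values()):
                raise ParameterError(f"{name} has negative weight(s)")
        if self.effect_size < 1.0:
            raise ParameterError("effect_size must be >= 1")
        if self.n_bio_reps < 1 or self.n_tech_reps < 1:
            raise ParameterError("n_bio_reps and n_tech_reps must be >= 1")
        lo, hi = self.sequence_length_range
        if lo < 2 or hi < lo:
            raise ParameterError("sequence_length_range must satisfy 2 <= min <= max")
        for name in ("tick_membership", "host_membership"):
            m = getattr(self, name)
            if len(m) != 3 or abs(sum(m) - 1.0) > 1e-9 or any(v < 0 for v in m):
                raise ParameterError(f"{name} must be 3 non-negative values summing to 1")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = json.load(fh)
        cfg = cls(**raw)
        for name in ("sequence_length_range", "tick_membership", "host_membership",
                     "gly_percent_range"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg


@dataclass
class TruthRecord:
    origin: str  # tick | host
    category: str
    membership: str  # sialome_only | cementome_only | shared
    extractions: tuple[str, ...]  # cement extraction(s) the protein appears in
    sequence_class: str  # gly_rich | background
    gly_percent: float


@dataclass
class GroundTruth:
    records: dict[str, TruthRecord]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({k: asdict(v) for k, v in sorted(self.records.items())},
                      fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            raw = json.load(fh)
        return cls({
            k: TruthRecord(**{**v, "extractions": tuple(v["extractions"])})
            for k, v in raw.items()
        })

    def categories(self) -> dict[str, str]:
        return {k: v.category for k, v in self.records.items()}

    def origins(self) -> dict[str, str]:
        return {k: v.origin for k, v in self.records.items()}


def _run_frame(config: SyntheticConfig) -> pd.DataFrame:
    """54 runs under the default design: 3 sample types x 3 times x bio x tech."""
    rows = []
    sample_types = [("salivary_gland", "native"), ("cement", "SDS"), ("cement", "urea")]
    for tissue, extraction in sample_types:
        tag = "SG" if tissue == "salivary_gland" else f"CEM{extraction}"
        for tp in TIME_POINTS:
            for b in range(1, config.n_bio_reps + 1):
                for t in range(1, config.n_tech_reps + 1):
                    rows.append({
                        "run": f"{tag}_{tp}_b{b}_r{t}",
                        "tissue": tissue,
                        "extraction": extraction,
                        "time": tp,
                        "bio_rep": b,
                        "tech_rep": t,
                    })
    return pd.DataFrame(rows).set_index("run")


def _draw_sequence(rng: np.random.Generator, length: int,
                   gly_rich: bool, gly_range: tuple[float, float]) -> tuple[str, float]:
    aas = np.array(list(AMINO_ACIDS))
    if gly_rich:
        g = rng.uniform(gly_range[0] / 100.0, gly_range[1] / 100.0)
        probs = np.full(len(aas), (1.0 - g) / (len(aas) - 1))
        probs[list(AMINO_ACIDS).index("G")] = g
    else:
        g = 1.0 / len(aas)
        probs = np.full(len(aas), 1.0 / len(aas))
    seq = "".join(rng.choice(aas, size=length, p=probs))
    return seq, 100.0 * g


def generate_dataset(
    config: SyntheticConfig,
    templates: ProfileTemplates | None = None,
) -> tuple[QuantMatrix, pd.DataFrame, dict[str, str], GroundTruth]:
    """Generate (QuantMatrix, annotation table, sequences, ground truth).

    Abundance for protein p in a run at time t is
    ``exp(base_p + traj[t] * log(effect_size) + eps_bio + eps_tech)`` in the
    tissues/extractions the protein belongs to, and exactly 0 elsewhere
    (true zeros: absence, not censoring).
    """
    config.validate()
    templates = templates or default_templates()
    rng = np.random.default_rng(config.seed)
    runs = _run_frame(config)
    n = config.n_proteins
    if n == 0:
        values = pd.DataFrame(np.zeros((0, len(runs))),
                              index=pd.Index([], name="protein"),
                              columns=runs.index)
        ann = pd.DataFrame(columns=["origin", "go_terms"],
                           index=pd.Index([], name="accession"))
        return QuantMatrix(values, runs), ann, {}, GroundTruth({})

    accs = [f"P{i:05d}" for i in range(n)]
    origins = np.where(rng.random(n) < config.fraction_host, "host", "tick")

    memberships = np.empty(n, dtype=object)
    for i in range(n):
        probs = config.host_membership if origins[i] == "host" else config.tick_membership
        memberships[i] = rng.choice(_MEMBERSHIPS, p=np.array(probs))

    # cement extraction membership for cement-containing proteins
    extractions: list[tuple[str, ...]] = []
    for i in range(n):
        if memberships[i] == "sialome_only":
            extractions.append(())
        else:
            u = rng.random()
            if u < 0.5:
                extractions.append(("SDS", "urea"))
            elif u < 0.75:
                extractions.append(("SDS",))
            else:
                extractions.append(("urea",))

    base = config.mean_log_abundance + rng.normal(0.0, config.log_abundance_sd, size=n)

    # Categories are assigned by stratified (mass-quota) randomization: within
    # each origin x membership x extraction cell, proteins are walked in
    # descending base abundance and each is drawn into a category with
    # probability proportional to that category's remaining MASS deficit
    # (target share of the cell's cumulative abundance minus mass assigned so
    # far).  The targets come from a per-dataset balance solve over the
    # realized cell masses (see _solve_cell_weights), keeping the REALIZED
    # total abundance of every run type stage-stable — not just its
    # expectation — which is the condition under which global total-sum
    # normalization reflects loading rather than biology.  Category labels
    # remain random; only their aggregate mass shares are controlled.
    cats = np.empty(n, dtype=object)
    cells: dict[tuple, list[int]] = {}
    for i in range(n):
        cells.setdefault((origins[i], memberships[i], extractions[i]), []).append(i)
    cell_mass = {key: float(np.sum(np.exp(base[idx] - config.mean_log_abundance)))
                 for key, idx in cells.items()}
    if config.category_weights is not None:
        cell_weights = {key: dict(config.category_weights) if key[0] == "tick"
                        else dict(config.host_category_weights) for key in cells}
    else:
        cell_weights = _solve_cell_weights(
            cell_mass, config.host_category_weights, templates, config.effect_size)
    for key, idx in sorted(cells.items()):
        idx.sort(key=lambda i: -base[i])
        w = cell_weights[key]
        names = list(w)
        targets = np.array([w[c] for c in names], dtype=float)
        assigned_mass = np.zeros(len(names))
        cum_mass = 0.0
        for i in idx:
            mass = float(np.exp(base[i] - config.mean_log_abundance))
            cum_mass += mass
            deficit = np.clip(targets * cum_mass - assigned_mass, 0.0, None)
            if deficit.sum() == 0:
                deficit = targets.copy()
            j = int(rng.choice(len(names), p=deficit / deficit.sum()))
            assigned_mass[j] += mass
            cats[i] = names[j]

    # Continuous rebalancing: minimum-norm per-protein log-abundance tweaks
    # that zero the remaining stage drift of every run type exactly (the
    # discrete quota above cannot split a dominant protein's mass across
    # categories).  Typically |delta| << the protein-to-protein spread.
    v_all = np.array(
        [[config.effect_size ** x for x in templates.trajectory(c)] for c in cats])
    pres_mask = {
        "SG": np.array([_sample_type_members((origins[i], memberships[i],
                                              extractions[i])).count("SG") > 0
                        for i in range(n)]),
        "SDS": np.array(["SDS" in _sample_type_members((origins[i], memberships[i],
                                                        extractions[i]))
                         for i in range(n)]),
        "urea": np.array(["urea" in _sample_type_members((origins[i], memberships[i],
                                                          extractions[i]))
                          for i in range(n)]),
    }
    rows = []
    for rt, pres in pres_mask.items():
        if pres.any():
            rows.append(pres * (v_all[:, 0] - v_all[:, 1]))
            rows.append(pres * (v_all[:, 1] - v_all[:, 2]))
    if rows:
        u_mat = np.array(rows)
        mass = np.exp(base - config.mean_log_abundance)
        delta = np.zeros(n)
        for _ in range(20):
            m_eff = mass * np.exp(delta)
            g = u_mat @ m_eff
            if np.max(np.abs(g)) < 1e-9 * m_eff.sum():
                break
            jac = u_mat * m_eff
            gram = jac @ jac.T
            delta -= jac.T @ np.linalg.solve(gram + 1e-12 * np.eye(len(g)), g)
        base = base + delta

    log_effect = float(np.log(config.effect_size))
    sigma_bio = float(np.sqrt(np.log1p(config.cv_biological ** 2)))
    sigma_tech = float(np.sqrt(np.log1p(config.cv_technical ** 2)))
    traj = np.array([templates.trajectory(c) for c in cats], dtype=float)  # n x 3

    time_index = {tp: k for k, tp in enumerate(TIME_POINTS)}
    values = np.zeros((n, len(runs)))
    run_meta = runs.reset_index()

    in_sialome = np.isin(memberships, ["sialome_only", "shared"])
    in_cement = np.isin(memberships, ["cementome_only", "shared"])
    in_sds = np.array([("SDS" in e) for e in extractions])
    in_urea = np.array([("urea" in e) for e in extractions])

    # biological noise per (protein, tissue, time, bio_rep)
    bio_eps = rng.normal(
        0.0, sigma_bio,
        size=(n, 2, len(TIME_POINTS), config.n_bio_reps),
    )
    tissue_index = {"salivary_gland": 0, "cement": 1}

    for j, row in run_meta.iterrows():
        t_idx = time_index[row["time"]]
        ti = tissue_index[row["tissue"]]
        if row["tissue"] == "salivary_gland":
            present = in_sialome
        elif row["extraction"] == "SDS":
            present = in_cement & in_sds
        else:
            present = in_cement & in_urea
        mu = base + traj[:, t_idx] * log_effect
        eps_b = bio_eps[:, ti, t_idx, row["bio_rep"] - 1]
        eps_t = rng.normal(0.0, sigma_tech, size=n)
        col = np.exp(mu + eps_b + eps_t)
        values[:, j] = np.where(present, col, 0.0)

    matrix = QuantMatrix(
        pd.DataFrame(values, index=pd.Index(accs, name="protein"), columns=runs.index),
        runs,
    )

    sequences: dict[str, str] = {}
    records: dict[str, TruthRecord] = {}
    go_weights = 1.0 / np.arange(1, len(DEFAULT_GO_PROCESSES) + 1)
    go_weights /= go_weights.sum()
    ann_rows = []
    for i, acc in enumerate(accs):
        gly_rich = bool(origins[i] == "tick" and rng.random() < config.gly_rich_fraction)
        length = int(rng.integers(config.sequence_length_range[0],
                                  config.sequence_length_range[1] + 1))
        seq, gly_pct = _draw_sequence(rng, length, gly_rich, config.gly_percent_range)
        sequences[acc] = seq
        n_terms = int(rng.integers(1, 4))
        terms = sorted(rng.choice(DEFAULT_GO_PROCESSES, size=n_terms,
                                  replace=False, p=go_weights))
        ann_rows.append({"accession": acc, "origin": origins[i], "go_terms": terms})
        records[acc] = TruthRecord(
            origin=str(origins[i]),
            category=str(cats[i]),
            membership=str(memberships[i]),
            extractions=extractions[i],
            sequence_class="gly_rich" if gly_rich else "background",
            gly_percent=gly_pct,
        )
    annotation = pd.DataFrame(ann_rows).set_index("accession")
    return matrix, annotation, sequences, GroundTruth(records)


EDS_ELEMENTS = ("C", "N", "O", "S")


def generate_eds_table(
    matrix: QuantMatrix,
    sequences: Mapping[str, str],
    noise_sd: float = 0.5,
    n_scans: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """SEM–EDS elemental tables derived from protein atomic composition.

    Per (tissue, time) sample, the C/N/O/S atomic percentages are the
    abundance-weighted mean of the member proteins' atomic composition
    (H is not reported: EDS does not quantify hydrogen), renormalized to
    100%, with Gaussian noise per scan (``noise_sd`` in atomic-% units;
    noisy scans are clipped at 0 and renormalized, so each scan sums to
    exactly 100 over the retained elements).
    """
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    comp = {}
    for acc in matrix.proteins:
        counts, _ = atomic_composition(sequences[acc])
        vec = np.array([counts[el] for el in EDS_ELEMENTS], dtype=float)
        comp[acc] = vec
    comp_mat = np.array([comp[a] for a in matrix.proteins])  # n x 4 atom counts

    rows = []
    for (tissue, tp), grp in matrix.runs.groupby(["tissue", "time"], sort=True):
        weights = matrix.values[grp.index].mean(axis=1).to_numpy()
        if weights.sum() == 0:
            continue
        atoms = weights @ comp_mat
        pct = 100.0 * atoms / atoms.sum()
        sample_id = f"{tissue}_{tp}"
        for scan in range(1, n_scans + 1):
            noisy = pct + rng.normal(0.0, noise_sd, size=len(pct))
            noisy = np.clip(noisy, 0.0, None)
            noisy = 100.0 * noisy / noisy.sum()
            for el, v in zip(EDS_ELEMENTS, noisy):
                rows.append({
                    "sample_id": sample_id, "tissue": tissue, "time": tp,
                    "scan": scan, "element": el, "atomic_percent": float(v),
                })
    return pd.DataFrame(rows, columns=["sample_id", "tissue", "time", "scan",
                                       "element", "atomic_percent"])


def generate_elisa_plate(
    slope: float,
    intercept: float,
    noise_sd: float,
    standards: list[float],
    n_blanks: int = 3,
    samples: Mapping[str, float] | None = None,
    n_replicates: int = 3,
    coated_ng_per_well: float = 100.0,
    seed: int = 0,
) -> ElisaPlate:
    """Simulate a plate: OD = intercept + slope * ng + Gaussian noise.

    ``standards`` are BSA–alpha-Gal amounts in ng (the working range spans
    0.0–1.0 ng); blanks are uncoated wells (ng = 0); ``samples`` maps
    sample ids to their true alpha-Gal ng per well.  The intercept models
    the shared assay background, which the blank wells also read.
    """
    if not standards:
        raise ParameterError("standards must be a non-empty list of ng values")
    if n_blanks < 1:
        raise ParameterError("n_blanks must be >= 1")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    w = 0

    def od_for(ng: float) -> float:
        return max(0.0, intercept + slope * ng + rng.normal(0.0, noise_sd))

    for ng in standards:
        w += 1
        rows.append({"well": f"W{w:03d}", "role": "standard", "sample_id": "",
                     "ng": float(ng), "replicate": 1, "od": od_for(ng)})
    for b in range(1, n_blanks + 1):
        w += 1
        rows.append({"well": f"W{w:03d}", "role": "blank", "sample_id": "",
                     "ng": 0.0, "replicate": b, "od": od_for(0.0)})
    for sid, ng in (samples or {}).items():
        for r in range(1, n_replicates + 1):
            w += 1
            rows.append({"well": f"W{w:03d}", "role": "sample", "sample_id": sid,
                         "ng": float("nan"), "replicate": r, "od": od_for(ng)})
    return ElisaPlate(pd.DataFrame(rows), coated_ng_per_well=coated_ng_per_well)
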