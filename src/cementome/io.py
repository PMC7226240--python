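"""Readers and writers for every external artifact of the pipeline.

Tabular artifacts are TSV with a header; sequences are FASTA; networks are
GraphML or edge-list TSV; configuration and result bundles are JSON.

The canonical quantitation layout is "long metadata, wide values": a run
metadata block (one row per LC–MS run) plus a protein × run abundance block
in Total Area Sums (TAS) units.  Run metadata columns are fixed by
:data:`RUN_METADATA_COLUMNS`; time labels are the adult female feeding
stages T1 (14–17 dpi), T2 (18–20 dpi) and T3 (21–25 dpi).

Readers reject malformed values instead of coercing them; writers are
deterministic given identical input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd
from Bio import SeqIO

__all__ = [
    "QuantMatrix",
    "FormatError",
    "ValidationError",
    "RUN_METADATA_COLUMNS",
    "TIME_POINTS",
    "TISSUES",
    "read_quant_matrix",
    "write_quant_matrix",
    "read_annotation",
    "write_annotation",
    "read_fasta",
    "write_fasta",
    "read_eds_table",
    "write_eds_table",
    "read_elisa_plate",
    "write_elisa_plate",
    "export_network",
    "read_network",
    "read_json",
    "write_json",
]


class FormatError(ValueError):
    """A file does not conform to the documented schema."""


class ValidationError(ValueError):
    """Contents parse but violate a domain invariant."""


RUN_METADATA_COLUMNS = ("tissue", "extraction", "time", "bio_rep", "tech_rep")
TIME_POINTS = ("T1", "T2", "T3")
TISSUES = ("salivary_gland", "cement")

#: residues accepted in sequence input; X is tolerated (unknown residue)
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class QuantMatrix:
    """Protein × run abundance table with per-run metadata.

    ``values`` is indexed by protein accession with one column per run id;
    ``runs`` is indexed by run id with columns :data:`RUN_METADATA_COLUMNS`.
    Abundances are Total Area Sums (TAS) units, non-negative.
    """

    values: pd.DataFrame
    runs: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        missing = [c for c in RUN_METADATA_COLUMNS if c not in self.runs.columns]
        if missing:
            raise FormatError(f"run metadata missing column(s): {missing}")
        if list(self.values.columns) != list(self.runs.index):
            raise ValidationError("value columns and run metadata rows disagree")
        if self.values.columns.duplicated().any():
            dup = list(self.values.columns[self.values.columns.duplicated()])
            raise FormatError(f"duplicated run column(s): {dup}")
        if self.values.index.duplicated().any():
            dup = list(self.values.index[self.values.index.duplicated()])
            raise ValidationError(f"duplicated protein accession(s): {dup}")
        if (self.values.values < 0).any():
            raise ValidationError("negative abundance value(s) present")
        bad_time = set(self.runs["time"]) - set(TIME_POINTS)
        if bad_time:
            raise ValidationError(f"unknown time label(s): {sorted(bad_time)}")
        if self.runs[list(RUN_METADATA_COLUMNS)].isna().any().any():
            raise ValidationError("incomplete run metadata")

    @property
    def proteins(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_runs(self) -> int:
        return self.values.shape[1]

    def subset_runs(self, mask: pd.Series) -> "QuantMatrix":
        """Restrict to runs where ``mask`` (indexed like ``runs``) is true."""
        keep = self.runs.index[mask.reindex(self.runs.index).fillna(False)]
        return QuantMatrix(self.values[keep].copy(), self.runs.loc[keep].copy())

    def subset_proteins(self, accessions: Iterable[str]) -> "QuantMatrix":
        keep = [a for a in accessions if a in self.values.index]
        return QuantMatrix(self.values.loc[keep].copy(), self.runs.copy())

    def equals(self, other: "QuantMatrix") -> bool:
        return self.values.equals(other.values) and self.runs.equals(other.runs)


def write_quant_matrix(matrix: QuantMatrix, path: str | Path) -> None:
    """Serialize as TSV: metadata rows ``#tissue`` … then the value block."""
    path = Path(path)
    with open(path, "w") as fh:
        header = ["protein"] + list(matrix.values.columns)
        for col in RUN_METADATA_COLUMNS:
            row = [f"#{col}"] + [str(matrix.runs.loc[r, col]) for r in matrix.values.columns]
            fh.write("\t".join(row) + "\n")
        fh.write("\t".join(header) + "\n")
        for acc, row in matrix.values.iterrows():
            fh.write("\t".join([str(acc)] + [repr(float(v)) for v in row]) + "\n")


def read_quant_matrix(path: str | Path) -> QuantMatrix:
    path = Path(path)
    meta_rows: dict[str, list[str]] = {}
    header: list[str] | None = None
    data: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts[0].startswith("#"):
                meta_rows[parts[0][1:]] = parts[1:]
            elif header is None:
                header = parts
            else:
                data.append(parts)
    if header is None or header[0] != "protein":
        raise FormatError("missing 'protein' header line")
    missing = [c for c in RUN_METADATA_COLUMNS if c not in meta_rows]
    if missing:
        raise FormatError(f"run metadata missing column(s): {missing}")
    run_ids = header[1:]
    runs = pd.DataFrame(
        {col: meta_rows[col] for col in RUN_METADATA_COLUMNS}, index=pd.Index(run_ids, name="run")
    )
    runs["bio_rep"] = runs["bio_rep"].astype(int)
    runs["tech_rep"] = runs["tech_rep"].astype(int)
    accs = [row[0] for row in data]
    try:
        vals = [[float(x) for x in row[1:]] for row in data]
    except ValueError as exc:
        raise FormatError(f"non-numeric abundance value: {exc}") from exc
    values = pd.DataFrame(vals, index=pd.Index(accs, name="protein"), columns=run_ids)
    return QuantMatrix(values, runs)


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    """Annotation table: accession (index), origin ∈ {tick, host}, go_terms.

    GO biological-process terms are serialized ``;``-joined in one column.
    """
    out = annotation.copy()
    if "go_terms" in out.columns:
        out["go_terms"] = out["go_terms"].map(
            lambda t: ";".join(t) if isinstance(t, (list, tuple)) else (t or "")
        )
    out.to_csv(path, sep="\t", index_label="accession")


def read_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", index_col="accession", keep_default_na=False)
    if "origin" not in ann.columns:
        raise FormatError("annotation table missing 'origin' column")
    bad = set(ann["origin"]) - {"tick", "host"}
    if bad:
        raise ValidationError(f"unknown origin value(s): {sorted(bad)}")
    if "go_terms" in ann.columns:
        ann["go_terms"] = ann["go_terms"].map(
            lambda s: [t for t in str(s).split(";") if t] if s else []
        )
    return ann


def read_fasta(path: str | Path) -> dict[str, str]:
    """Parse FASTA into {accession: upper-cased sequence}.

    The accession is the first whitespace token of the header.  Any residue
    outside the 20 standard amino acids other than X is rejected with its
    position.
    """
    mapping: dict[str, str] = {}
    allowed = set(AMINO_ACIDS + "X")
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        for pos, ch in enumerate(seq):
            if ch not in allowed:
                raise ValidationError(
                    f"non-residue character {ch!r} in {record.id} at position {pos + 1}"
                )
        mapping[record.id] = seq
    return mapping


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for acc in sequences:
            fh.write(f">{acc}\n")
            seq = sequences[acc]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


EDS_COLUMNS = ("sample_id", "tissue", "time", "scan", "element", "atomic_percent")


def write_eds_table(eds: pd.DataFrame, path: str | Path) -> None:
    eds.to_csv(path, sep="\t", index=False, columns=list(EDS_COLUMNS))


def read_eds_table(path: str | Path) -> pd.DataFrame:
    eds = pd.read_csv(path, sep="\t")
    missing = [c for c in EDS_COLUMNS if c not in eds.columns]
    if missing:
        raise FormatError(f"EDS table missing column(s): {missing}")
    pct = eds["atomic_percent"]
    if ((pct < 0) | (pct > 100)).any():
        raise ValidationError("atomic percent outside [0, 100]")
    sums = eds.groupby(["sample_id", "scan"])["atomic_percent"].sum()
    if (sums > 100 + 1e-6).any():
        raise ValidationError("per-scan element percentages exceed 100")
    return eds


ELISA_COLUMNS = ("well", "role", "sample_id", "ng", "replicate", "od")


def write_elisa_plate(plate: "object", path: str | Path) -> None:
    wells = plate.wells if hasattr(plate, "wells") else plate
    with open(path, "w") as fh:
        coated = getattr(plate, "coated_ng_per_well", "")
        fh.write(f"#coated_ng_per_well\t{coated}\n")
        wells.to_csv(fh, sep="\t", index=False, columns=list(ELISA_COLUMNS))


def read_elisa_plate(path: str | Path):
    from .elemental import ElisaPlate  # deferred to avoid a cycle

    coated = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#coated_ng_per_well"):
            coated = float(first.split("\t")[1])
            wells = pd.read_csv(fh, sep="\t", keep_default_na=False)
        else:
            fh.seek(0)
            wells = pd.read_csv(fh, sep="\t", keep_default_na=False)
    missing = [c for c in ELISA_COLUMNS if c not in wells.columns]
    if missing:
        raise FormatError(f"ELISA table missing column(s): {missing}")
    wells["od"] = wells["od"].astype(float)
    wells["ng"] = pd.to_numeric(wells["ng"], errors="coerce")
    if (wells["od"] < 0).any():
        raise ValidationError("negative OD reading")
    return ElisaPlate(wells=wells, coated_ng_per_well=coated if coated is not None else 100.0)


def export_network(graph: nx.Graph, path: str | Path, fmt: str = "graphml") -> None:
    """Write a co-occurrence network; nodes carry BNC/category attributes,
    edges carry the SparCC correlation ``weight``."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(graph, str(path))
    elif fmt == "edgelist":
        rows = [
            {"source": u, "target": v, "weight": d.get("weight", 1.0)}
            for u, v, d in graph.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError(f"unknown network format: {fmt!r}")


def read_network(path: str | Path) -> nx.Graph:
    g = nx.read_graphml(str(path))
    return g


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
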