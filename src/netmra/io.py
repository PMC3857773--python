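"""Readers and writers for every external format the pipeline touches.

Canonical tabular dialect: tab-separated UTF-8 with "." decimal. All
reader/writer pairs round-trip losslessly on valid input (exact for text
and integers, <=1e-12 relative for reals). Readers validate and fail loudly
rather than silently dropping records.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO

from .core import ExpressionMatrix, GeneSet, MotifModel, SurvivalTable, ValidationError

logger = logging.getLogger("netmra")

_FLOAT_FMT = "%.17g"  # enough digits for exact float64 round-trips


# ---------------------------------------------------------------- expression

def read_expression_matrix(
    path: str | Path, sep: str = "\t", duplicate_policy: str = "error"
) -> ExpressionMatrix:
    """Read a genes x samples TSV (header = sample ids, first column = gene ids).

    ``duplicate_policy``: "error" (default) rejects duplicated gene ids;
    "mean" collapses duplicates by averaging their rows (logged).
    """
    df = pd.read_csv(path, sep=sep, index_col=0, header=0, dtype={0: str},
                     float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.columns.duplicated().any():
        raise ValidationError(f"duplicate sample id in {path}")
    if df.index.duplicated().any():
        if duplicate_policy == "mean":
            n_dup = int(df.index.duplicated().sum())
            logger.warning("collapsing %d duplicate gene ids by mean in %s", n_dup, path)
            df = df.groupby(level=0, sort=False).mean()
        else:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene id in {path}: {dups[:5]}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric expression cell in {path}: {exc}") from None
    if values.size and not np.all(np.isfinite(values)):
        raise ValidationError(f"NaN or infinite expression value in {path}")
    return ExpressionMatrix(list(df.index), list(df.columns), values)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path, sep: str = "\t") -> None:
    matrix.to_frame().to_csv(path, sep=sep, float_format=_FLOAT_FMT, index_label="gene")


# ----------------------------------------------------------------------- GMT

def read_gene_sets_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT file: name TAB description TAB member... (one set per line)."""
    sets: list[GeneSet] = []
    names: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 member"
                )
            name, desc, members = fields[0], fields[1], fields[2:]
            if name in names:
                raise ValidationError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            names.add(name)
            sets.append(GeneSet(name, desc, members))
    return sets


def write_gene_sets_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in sets:
            if not gs.members:
                raise ValidationError(f"gene set {gs.name!r} has no members")
            fh.write("\t".join([gs.name, gs.description, *gs.members]) + "\n")


# ---------------------------------------------------------------- JASPAR PFM

def read_pfm_jaspar(path: str | Path) -> MotifModel:
    """Read a JASPAR-style PFM: optional ">id name" header, then 4 rows A/C/G/T.

    Both the raw 4-row layout and the bracketed JASPAR layout
    (``A [ 4 19 0 ... ]``) are accepted. The motif id comes from the header
    when present, else from the file stem.
    """
    path = Path(path)
    motif_id = path.stem
    rows: list[list[float]] = []
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                motif_id = line[1:].split()[0]
                continue
            tokens = line.replace("[", " ").replace("]", " ").split()
            if tokens and tokens[0].upper() in ("A", "C", "G", "T"):
                tokens = tokens[1:]
            try:
                rows.append([float(t) for t in tokens])
            except ValueError:
                raise ValidationError(f"non-numeric PFM entry in {path}: {line!r}") from None
    if len(rows) != 4:
        raise ValidationError(f"{path}: expected 4 PFM rows (A,C,G,T), found {len(rows)}")
    if len({len(r) for r in rows}) != 1:
        raise ValidationError(f"{path}: PFM rows have unequal lengths")
    return MotifModel(motif_id, np.array(rows, dtype=float))


def write_pfm_jaspar(motif: MotifModel, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f">{motif.motif_id}\n")
        for row in motif.counts:
            fh.write(" ".join(_FLOAT_FMT % v for v in row) + "\n")


# --------------------------------------------------------------------- FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into {id: sequence}. Sequences are uppercased (soft masking
    is ignored, logged); only A, C, G, T and N are accepted."""
    sequences: dict[str, str] = {}
    n_lower = 0
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq)
        if seq != seq.upper():
            n_lower += 1
            seq = seq.upper()
        if set(seq) - set("ACGTN"):
            bad = sorted(set(seq) - set("ACGTN"))
            raise ValidationError(f"{path}: sequence {record.id!r} has non-ACGTN characters {bad}")
        if record.id in sequences:
            raise ValidationError(f"{path}: duplicate sequence id {record.id!r}")
        sequences[record.id] = seq
    if n_lower:
        logger.warning("uppercased %d soft-masked sequences in %s", n_lower, path)
    return sequences


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ------------------------------------------------------------------ survival

def read_survival_table(path: str | Path, sep: str = "\t") -> SurvivalTable:
    """Read a survival TSV with columns: sample, time, event, covariate."""
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    required = ["sample", "time", "event", "covariate"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing survival columns {missing}")
    return SurvivalTable(
        list(df["sample"].astype(str)),
        df["time"].to_numpy(dtype=float),
        df["event"].to_numpy(),
        df["covariate"].to_numpy(dtype=float),
    )


def write_survival_table(table: SurvivalTable, path: str | Path, sep: str = "\t") -> None:
    pd.DataFrame(
        {
            "sample": table.sample_ids,
            "time": table.time,
            "event": table.event,
            "covariate": table.covariate,
        }
    ).to_csv(path, sep=sep, index=False, float_format=_FLOAT_FMT)


# ----------------------------------------------------------------- gene list

def read_gene_list(path: str | Path) -> list[str]:
    """Plain-text gene list, one id per line (blank lines ignored)."""
    with open(path, encoding="utf-8") as fh:
        genes = [line.strip() for line in fh if line.strip()]
    if len(set(genes)) != len(genes):
        raise ValidationError(f"duplicate ids in gene list {path}")
    return genes


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            fh.write(f"{g}\n")


# ----------------------------------------------------------------- edge list

def write_edge_list(network, path: str | Path, sep: str = "\t") -> None:
    """Write a network's edges as TSV: tf, target, mi, p, p_adj, sign."""
    rows = [
        {"tf": e.tf, "target": e.target, "mi": e.mi, "p": e.p, "p_adj": e.p_adj, "sign": e.sign}
        for e in network.edges
    ]
    pd.DataFrame(rows, columns=["tf", "target", "mi", "p", "p_adj", "sign"]).to_csv(
        path, sep=sep, index=False, float_format=_FLOAT_FMT
    )


def read_edge_list(path: str | Path, sep: str = "\t"):
    """Read an edge-list TSV back into a RegulatoryNetwork (params empty)."""
    from .network import Edge, RegulatoryNetwork

    df = pd.read_csv(path, sep=sep, dtype={"tf": str, "target": str},
                     float_precision="round_trip")
    edges = [
        Edge(
            tf=row.tf,
            target=row.target,
            mi=float(row.mi),
            p=float(row.p),
            p_adj=float(row.p_adj),
            sign=int(row.sign),
        )
        for row in df.itertuples(index=False)
    ]
    tfs = sorted({e.tf for e in edges})
    return RegulatoryNetwork(tf_list=tfs, edges=edges, params={})
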