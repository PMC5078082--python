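"""Readers and writers for the plain-text formats the pipeline exchanges.

All tables are tab-separated with a header row. Matrices are genes x samples
log2 intensities; labels map sample ids to {case, control}; annotations are
GMT; edges are two-column TSV with an optional evidence-source column.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .synth import CASE, CONTROL, ExpressionExperiment, TruthLedger

log = logging.getLogger(__name__)


def read_experiment(
    matrix_path: str | Path,
    labels_path: str | Path,
    experiment_id: str | None = None,
) -> ExpressionExperiment:
    """Read one experiment; rejects NaN values and duplicate gene ids."""
    matrix_path, labels_path = Path(matrix_path), Path(labels_path)
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    labels_df = pd.read_csv(labels_path, sep="\t", index_col=0)
    labels = labels_df.iloc[:, 0].astype(str)
    if experiment_id is None:
        experiment_id = matrix_path.stem.removesuffix("_matrix")
    missing = [s for s in matrix.columns if s not in labels.index]
    if missing:
        raise ValueError(f"{experiment_id}: samples without labels: {missing}")
    labels = labels.loc[list(matrix.columns)]
    return ExpressionExperiment(experiment_id, matrix, labels)


def write_call_set(table: pd.DataFrame, path: str | Path) -> Path:
    """Write per-gene calls (columns d, call, q) to TSV."""
    path = Path(path)
    out = table.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.8g")
    return path


def read_call_set(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col=0)
    required = {"d", "call", "q"}
    if not required <= set(table.columns):
        raise ValueError(f"{path}: call table must have columns {sorted(required)}")
    return table


def read_universe(path: str | Path) -> list[str]:
    genes = [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
    if len(set(genes)) != len(genes):
        raise ValueError(f"{path}: duplicate gene ids in universe")
    return genes


def read_truth(path: str | Path, universe: Sequence[str] | None = None) -> TruthLedger:
    table = pd.read_csv(path, sep="\t", index_col=0)
    return TruthLedger(table, list(universe) if universe is not None else [])


def read_positions(path: str | Path) -> pd.DataFrame:
    """BED-like gene positions: gene_id, chrom, start (0-based; only the
    start is used). Extra columns are ignored."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: need at least 3 columns (gene, chrom, start)")
    df = df.iloc[:, :3]
    df.columns = ["gene_id", "chrom", "start"]
    if not np.issubdtype(df["start"].dtype, np.number):
        raise ValueError(f"{path}: start column is not numeric")
    return df


def read_gmt(path: str | Path, namespace: str = "pathway") -> dict[str, set[str]]:
    """GMT: term <tab> description <tab> gene1 <tab> gene2 ... Empty terms
    are rejected."""
    terms: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line has no genes")
        term, genes = parts[0], {g for g in parts[2:] if g}
        if not genes:
            raise ValueError(f"{path}:{lineno}: term {term!r} is empty")
        terms[term] = genes
    return terms


def write_gmt(terms: dict[str, set[str]], path: str | Path, description: str = "na") -> Path:
    path = Path(path)
    lines = [
        "\t".join([term, description, *sorted(genes)])
        for term, genes in sorted(terms.items())
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_edges(path: str | Path) -> pd.DataFrame:
    """Edge TSV: gene_a <tab> gene_b [<tab> source]. Malformed rows are
    logged, skipped and counted."""
    rows, skipped = [], 0
    lines = Path(path).read_text().splitlines()
    start = 1 if lines and lines[0].lower().startswith(("gene_a", "genea", "#")) else 0
    for lineno, line in enumerate(lines[start:], start + 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
            log.warning("%s:%d: malformed edge row skipped: %r", path, lineno, line)
            skipped += 1
            continue
        rows.append((parts[0].strip(), parts[1].strip(), parts[2].strip() if len(parts) > 2 else ""))
    if skipped:
        log.warning("%s: skipped %d malformed edge rows", path, skipped)
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "source"])
    df.attrs["n_skipped"] = skipped
    return df


def read_score_table(path: str | Path):
    """IHC score CSV: first column group label, remaining columns ordered
    grade counts (-, +, ++, +++)."""
    from .ihc import ScoreTable

    df = pd.read_csv(path, index_col=0)
    return ScoreTable(
        groups=df.index.astype(str).tolist(),
        grades=df.columns.astype(str).tolist(),
        counts=df.to_numpy(),
    )
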