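"""Readers and writers for the pipeline's tab-separated artifacts.

All tabular formats are TSV with a header row; gene lists are
newline-delimited id files; networks are exchanged as edge TSVs
(``regulator, target, weight``) plus an optional SIF export for
Cytoscape.  Every writer/reader pair round-trips its artifact
bit-exactly (floats are written with ``repr`` precision).
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import pandas as pd
import yaml

from ._errors import DataError
from .expression import ExpressionMatrix
from .grn_inference import EdgeList
from .network_validation import GoldStandard

FLOAT_FMT = "%.17g"


def _read_tsv(path, **kw) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"input file not found: {path}")
    try:
        return pd.read_csv(path, sep="\t", float_precision="round_trip", **kw)
    except pd.errors.ParserError as exc:
        raise DataError(f"malformed TSV {path}: {exc}") from exc


def write_expression(expr: ExpressionMatrix, expr_path, metadata_path=None) -> None:
    expr.values.to_csv(expr_path, sep="\t", float_format=FLOAT_FMT)
    if metadata_path is not None:
        if expr.metadata is None:
            raise DataError("expression matrix has no metadata to write")
        expr.metadata.to_csv(metadata_path, sep="\t")


def read_expression(expr_path, metadata_path=None) -> ExpressionMatrix:
    values = _read_tsv(expr_path, index_col=0)
    if values.isna().any().any():
        raise DataError(f"missing values in expression TSV {expr_path}")
    metadata = None
    if metadata_path is not None:
        metadata = _read_tsv(metadata_path, index_col=0)
    return ExpressionMatrix(values, metadata)


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=index)


def read_table(path, index_col=None) -> pd.DataFrame:
    return _read_tsv(path, index_col=index_col)


def write_gene_list(genes, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(set(genes))))


def read_gene_list(path) -> list[str]:
    path = Path(path)
    if not path.exists():
        raise DataError(f"gene list not found: {path}")
    return [line.strip() for line in path.read_text().splitlines() if line.strip()]


def write_edges(edges: EdgeList, path, top_k: int | None = None) -> None:
    df = edges.edges if top_k is None else edges.edges.head(top_k)
    write_table(df, path)


def read_edges(path) -> EdgeList:
    df = _read_tsv(path)
    required = {"regulator", "target", "weight"}
    if not required <= set(df.columns):
        raise DataError(f"edge TSV {path} must have columns {sorted(required)}")
    return EdgeList(df[["regulator", "target", "weight"]])


def write_gold_standard(gold: GoldStandard, path) -> None:
    rows = [
        {
            "tf": tf,
            "target": t,
            "dataset": gold.dataset_labels.get((tf, t), "validated"),
        }
        for tf, t in sorted(gold.validated_edges)
    ]
    write_table(pd.DataFrame(rows, columns=["tf", "target", "dataset"]), path)


def read_gold_standard(path, assayed_tfs=None, assayed_universe=None) -> GoldStandard:
    df = _read_tsv(path)
    if not {"tf", "target"} <= set(df.columns):
        raise DataError(f"gold-standard TSV {path} must have columns tf, target")
    edges = set(zip(df["tf"], df["target"]))
    labels = {}
    if "dataset" in df.columns:
        labels = {(r.tf, r.target): r.dataset for r in df.itertuples()}
    tfs = set(assayed_tfs) if assayed_tfs is not None else set(df["tf"])
    return GoldStandard(
        validated_edges=edges,
        assayed_tfs=tfs,
        assayed_universe=assayed_universe,
        dataset_labels=labels,
    )


def write_sif(edges_df: pd.DataFrame, path, interaction: str = "regulates") -> None:
    """Cytoscape SIF export: ``source <tab> interaction <tab> target``."""
    with open(path, "w") as fh:
        for row in edges_df.itertuples():
            fh.write(f"{row.regulator}\t{interaction}\t{row.target}\n")


def read_annotation(path) -> dict[str, set]:
    """Flat term->gene annotation from a two-column (term, gene) TSV."""
    df = _read_tsv(path)
    if not {"term", "gene"} <= set(df.columns):
        raise DataError(f"annotation TSV {path} must have columns term, gene")
    ann: dict[str, set] = {}
    for row in df.itertuples():
        ann.setdefault(row.term, set()).add(row.gene)
    return ann


def load_config(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise DataError(f"config file not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise DataError(f"config {path} must be a mapping")
    return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def append_manifest(
    out_dir, stage: str, config: dict, seed, inputs: list, outputs: list
) -> None:
    """Append a JSON-lines manifest entry capturing a stage execution."""
    entry = {
        "stage": stage,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": seed,
        "inputs": {str(p): _sha256(p) for p in inputs if Path(p).exists()},
        "outputs": {str(p): _sha256(p) for p in outputs if Path(p).exists()},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    manifest = Path(out_dir) / "manifest.jsonl"
    with open(manifest, "a") as fh:
        fh.write(json.dumps(entry, sort_keys=True) + "\n")
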