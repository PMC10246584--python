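"""Readers, writers and the run manifest.

Counts are accepted as dense CSV/TSV (cells x genes, or transposed via a
flag) or as MatrixMarket ``.mtx`` with 10x-style sidecar files
(``genes.tsv`` row names, ``barcodes.tsv`` column names; the 10x layout is
genes x cells and is transposed on read).  Results are written as a
deterministic directory layout: labels CSV, embeddings CSV, training-log
CSV and a YAML run manifest that round-trips losslessly.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp
import yaml

from .preprocess import CountMatrix

__all__ = [
    "RunManifest",
    "read_counts",
    "read_labels",
    "write_counts_mtx",
    "write_labels",
    "write_processed",
    "write_results",
]


@dataclass
class RunManifest:
    """Everything needed to reproduce a run."""

    config: dict
    seed: int
    versions: dict
    input_checksum: str
    pretrain_epochs: int
    finetune_epochs: int
    stop_reasons: dict

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunManifest":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _versions() -> dict:
    import sklearn

    import scgpcl

    return {"scgpcl": scgpcl.__version__, "numpy": np.__version__,
            "pandas": pd.__version__, "sklearn": sklearn.__version__}


def counts_checksum(counts: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(counts).tobytes()).hexdigest()


def _validate_int_counts(values: np.ndarray, cell_ids, gene_ids) -> np.ndarray:
    bad = ~np.isfinite(values) | (values != np.floor(values))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-integer count at cell {cell_ids[i]!r} / gene {gene_ids[j]!r}")
    neg = values < 0
    if neg.any():
        i, j = np.argwhere(neg)[0]
        raise ValueError(
            f"negative count at cell {cell_ids[i]!r} / gene {gene_ids[j]!r}")
    return values.astype(np.int64)


def read_counts(path, fmt: str | None = None,
                transpose: bool = False) -> CountMatrix:
    """Read a raw count matrix.

    ``fmt`` is inferred from the extension when omitted ('csv', 'tsv',
    'mtx').  ``transpose=True`` flips the on-disk orientation (for dense
    files stored genes x cells; for MTX it cancels the default 10x
    transposition).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt in ("csv", "tsv"):
        df = pd.read_csv(path, index_col=0,
                         sep="," if fmt == "csv" else "\t")
        if transpose:
            df = df.T
        values = df.to_numpy(dtype=float)
        cell_ids = [str(c) for c in df.index]
        gene_ids = [str(g) for g in df.columns]
    elif fmt == "mtx":
        mat = sio.mmread(path)
        mat = sp.coo_matrix(mat).toarray().astype(float)
        genes = _read_names(path.parent / "genes.tsv")
        cells = _read_names(path.parent / "barcodes.tsv")
        if not transpose:  # 10x layout: rows are genes, columns are cells
            mat = mat.T
        if mat.shape != (len(cells), len(genes)):
            raise ValueError(
                f"sidecar name files do not match matrix shape {mat.shape}")
        values, cell_ids, gene_ids = mat, cells, genes
    else:
        raise ValueError(f"unknown format {fmt!r}: expected csv, tsv or mtx")
    counts = _validate_int_counts(values, cell_ids, gene_ids)
    return CountMatrix(counts=counts, cell_ids=cell_ids, gene_ids=gene_ids)


def _read_names(path: Path) -> list[str]:
    if not path.exists():
        raise FileNotFoundError(f"missing sidecar name file {path}")
    return [line.split("\t")[0].strip()
            for line in path.read_text().splitlines() if line.strip()]


def write_counts_mtx(outdir, counts, cell_ids, gene_ids,
                     labels=None) -> dict[str, Path]:
    """Write counts as 10x-style triplet (matrix.mtx genes x cells plus
    barcodes.tsv / genes.tsv), optionally with a truth-label CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts = np.asarray(counts)
    paths = {
        "matrix": outdir / "matrix.mtx",
        "barcodes": outdir / "barcodes.tsv",
        "genes": outdir / "genes.tsv",
    }
    sio.mmwrite(paths["matrix"], sp.coo_matrix(counts.T), field="integer")
    paths["barcodes"].write_text("\n".join(map(str, cell_ids)) + "\n")
    paths["genes"].write_text("\n".join(map(str, gene_ids)) + "\n")
    if labels is not None:
        paths["labels"] = outdir / "labels.csv"
        pd.DataFrame({"cell_id": list(cell_ids),
                      "cluster": np.asarray(labels)}).to_csv(
            paths["labels"], index=False)
    return paths


def write_processed(outdir, cm, graph) -> dict[str, Path]:
    """Write the preprocessed features and a graph manifest.

    Layout: ``features.csv`` (cells x genes scaled features, with ids),
    ``size_factors.csv`` and ``graph.yaml`` (node/edge counts, gene-feature
    dimension, raw-count checksum).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"features": outdir / "features.csv",
             "size_factors": outdir / "size_factors.csv",
             "graph": outdir / "graph.yaml"}
    feats = pd.DataFrame(graph.Xc, index=cm.cell_ids, columns=cm.gene_ids)
    feats.to_csv(paths["features"])
    pd.DataFrame({"cell_id": cm.cell_ids,
                  "library_size": cm.library_sizes,
                  "size_factor": cm.size_factors}).to_csv(
        paths["size_factors"], index=False)
    manifest = {"n_cells": int(graph.n_cells), "n_genes": int(graph.n_genes),
                "n_edges": int(graph.n_edges),
                "gene_feature_dim": int(graph.Xg.shape[1]),
                "counts_checksum": counts_checksum(cm.counts)}
    paths["graph"].write_text(yaml.safe_dump(manifest, sort_keys=True))
    return paths


def write_labels(path, cell_ids, labels) -> None:
    pd.DataFrame({"cell_id": list(cell_ids),
                  "cluster": np.asarray(labels)}).to_csv(path, index=False)


def read_labels(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.shape[1] == 1:  # headerless single column of labels
        df = pd.DataFrame({"cell_id": np.arange(len(df)),
                           "cluster": df.iloc[:, 0]})
    if "cluster" not in df.columns:
        # take last column as the label column
        df = df.rename(columns={df.columns[-1]: "cluster"})
    return df


def write_results(outdir, result, cell_ids, input_counts,
                  force: bool = False) -> dict[str, Path]:
    """Write labels, embeddings, training log and manifest for a fit run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "labels": outdir / "labels.csv",
        "embeddings": outdir / "embeddings.csv",
        "log": outdir / "training_log.csv",
        "manifest": outdir / "manifest.yaml",
    }
    clash = [p for p in paths.values() if p.exists()]
    if clash and not force:
        raise FileExistsError(
            f"output files exist (use force=True / --force): {clash[0]}")
    write_labels(paths["labels"], cell_ids, result.labels)
    emb = pd.DataFrame(result.embeddings,
                       columns=[f"dim{i}" for i in
                                range(result.embeddings.shape[1])])
    emb.insert(0, "cell_id", list(cell_ids))
    emb.to_csv(paths["embeddings"], index=False)
    pd.DataFrame(result.pretrain_log + result.finetune_log).to_csv(
        paths["log"], index=False)
    manifest = RunManifest(
        config=result.config.to_dict(),
        seed=result.config.seed,
        versions=_versions(),
        input_checksum=counts_checksum(input_counts),
        pretrain_epochs=len(result.pretrain_log),
        finetune_epochs=len(result.finetune_log),
        stop_reasons=dict(result.stop_reasons),
    )
    manifest.to_yaml(paths["manifest"])
    return paths
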