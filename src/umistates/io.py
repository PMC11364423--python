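"""Readers and writers for the standard on-disk formats.

Count matrices come in as Matrix Market coordinate files (1-based indices,
integer entries) with ``genes.tsv``/``barcodes.tsv`` sidecars, or as dense
TSV/CSV with a header row; results go out as plain TSV/JSON so they can be
inspected with standard tools.  Every run writes a manifest sufficient to
reproduce it bit-identically (tool version, config echo, seed, input
checksum, final likelihood).
"""

from __future__ import annotations

import datetime
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from pydantic import BaseModel

from .data import CountMatrix, DataError, DirichletPrior, Partition
from .optimize import RunResult

logger = logging.getLogger(__name__)

TOOL_VERSION = "0.1.0"


class RunManifest(BaseModel):
    """Provenance record of one optimizer run (JSON-serialisable)."""

    tool_version: str
    timestamp: str
    seed: int
    config: dict
    input_checksum: str
    n_cells: int
    n_genes: int
    n_cellstates: int
    theta: float
    log_likelihood: float
    log_likelihood_note: str = (
        "log-likelihood is reported up to a partition-independent data "
        "constant (per-cell multinomial coefficients are dropped)"
    )


def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".mtx":
        return "mtx"
    if suffix in (".tsv", ".txt"):
        return "tsv"
    if suffix == ".csv":
        return "csv"
    raise DataError(f"cannot detect format of {path}; pass format explicitly")


def read_counts(path, format: str | None = None,
                orientation: str = "genes-by-cells") -> CountMatrix:
    """Load a validated :class:`CountMatrix`.

    ``format`` is ``"mtx"`` (with ``genes.tsv`` and ``barcodes.tsv`` sidecars
    next to the matrix file), ``"tsv"`` or ``"csv"`` (dense, first column =
    gene ids, header = cell ids); autodetected from the suffix if omitted.
    ``orientation`` is ``"genes-by-cells"`` (default) or ``"cells-by-genes"``
    for transposed files.  Zero-total genes are dropped with a warning;
    zero-total cells are an error.
    """
    path = Path(path)
    fmt = format or _detect_format(path)
    if orientation not in ("genes-by-cells", "cells-by-genes"):
        raise DataError(f"unknown orientation {orientation!r}")

    if fmt == "mtx":
        mat = scipy.io.mmread(path)
        mat = sp.coo_matrix(mat)
        if mat.data.size and not np.all(mat.data == np.floor(mat.data)):
            bad = np.flatnonzero(mat.data != np.floor(mat.data))[0]
            raise DataError(
                f"matrix has real-valued entry {mat.data[bad]} at "
                f"(row {mat.row[bad] + 1}, col {mat.col[bad] + 1})"
            )
        mat = sp.csc_matrix(mat.astype(np.int64))
        row_ids = _read_sidecar(path.parent / "genes.tsv")
        col_ids = _read_sidecar(path.parent / "barcodes.tsv")
        if orientation == "cells-by-genes":
            mat = sp.csc_matrix(mat.T)
            row_ids, col_ids = col_ids, row_ids
        if row_ids is not None and len(row_ids) != mat.shape[0]:
            raise DataError(
                f"genes sidecar has {len(row_ids)} entries for "
                f"{mat.shape[0]} matrix rows"
            )
        if col_ids is not None and len(col_ids) != mat.shape[1]:
            raise DataError(
                f"barcodes sidecar has {len(col_ids)} entries for "
                f"{mat.shape[1]} matrix columns"
            )
        return CountMatrix(mat, gene_ids=row_ids, cell_ids=col_ids)

    sep = "\t" if fmt == "tsv" else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if orientation == "cells-by-genes":
        df = df.T
    values = df.to_numpy()
    if values.dtype.kind == "f" and not np.all(values == np.floor(values)):
        r, c = np.argwhere(values != np.floor(values))[0]
        raise DataError(
            f"non-integer entry {values[r, c]} at gene {df.index[r]!r}, "
            f"cell {df.columns[c]!r}"
        )
    return CountMatrix(values, gene_ids=list(df.index.astype(str)),
                       cell_ids=list(df.columns.astype(str)))


def _read_sidecar(path: Path):
    if not path.exists():
        logger.warning("sidecar %s not found; using default identifiers", path)
        return None
    ids = pd.read_csv(path, sep="\t", header=None)[0].astype(str).tolist()
    return ids


def write_counts(matrix: CountMatrix, path, format: str | None = None) -> None:
    """Inverse of :func:`read_counts` (lossless round trip)."""
    path = Path(path)
    fmt = format or _detect_format(path)
    if fmt == "mtx":
        scipy.io.mmwrite(path, matrix.counts, field="integer")
        pd.Series(matrix.gene_ids).to_csv(
            path.parent / "genes.tsv", sep="\t", index=False, header=False
        )
        pd.Series(matrix.cell_ids).to_csv(
            path.parent / "barcodes.tsv", sep="\t", index=False, header=False
        )
        return
    sep = "\t" if fmt == "tsv" else ","
    pd.DataFrame(
        matrix.dense(), index=matrix.gene_ids, columns=matrix.cell_ids
    ).to_csv(path, sep=sep)


def write_results(result: RunResult, outdir, config_echo: dict | None = None
                  ) -> RunManifest:
    """Write a run's outputs: assignment TSV, manifest JSON, GES TSV, log.

    ``cell_states.tsv`` has one row per cell (cell_id, cellstate_id);
    ``ges.tsv`` holds the posterior-mean transcription quotients of every
    cellstate; ``manifest.json`` is the validated :class:`RunManifest`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    part = result.partition
    matrix = part.matrix

    pd.DataFrame(
        {
            "cell_id": matrix.cell_ids,
            "cellstate_id": [part.labels[k] for k in part.assignment],
        }
    ).to_csv(outdir / "cell_states.tsv", sep="\t", index=False)

    ges = np.vstack(
        [part.ges(k, result.prior).quotients for k in range(part.n_clusters)]
    )
    pd.DataFrame(ges, index=[str(l) for l in part.labels],
                 columns=matrix.gene_ids).rename_axis("cellstate").to_csv(
        outdir / "ges.tsv", sep="\t"
    )

    manifest = RunManifest(
        tool_version=TOOL_VERSION,
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        seed=result.seed,
        config=config_echo or {},
        input_checksum=matrix.checksum(),
        n_cells=matrix.n_cells,
        n_genes=matrix.n_genes,
        n_cellstates=part.n_clusters,
        theta=result.prior.strength,
        log_likelihood=result.log_likelihood,
    )
    (outdir / "manifest.json").write_text(manifest.model_dump_json(indent=2))
    with open(outdir / "run.log", "a") as fh:
        fh.write(
            f"{manifest.timestamp}\tseed={result.seed}\t"
            f"loglik={result.log_likelihood:.6f}\t"
            f"n_cellstates={part.n_clusters}\ttheta={result.prior.strength:.6g}\n"
        )
    return manifest


def read_manifest(path) -> RunManifest:
    return RunManifest.model_validate_json(Path(path).read_text())


def read_assignment(path) -> pd.Series:
    """Read a cell_states.tsv back as a cell_id -> cellstate_id series."""
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str})
    return df.set_index("cell_id")["cellstate_id"]
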