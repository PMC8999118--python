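"""Readers and writers for gene × cell count matrices and cell-label files.

Two on-disk layouts are supported:

* ``dense_tsv`` — a dense table (TSV, or CSV for ``.csv`` paths) with genes
  in rows and cells in columns; the header row carries cell IDs and the
  first column carries gene IDs.
* ``mtx_triplet`` — a MatrixMarket coordinate file (1-based indices on
  disk, as the format requires) accompanied by ``genes.tsv`` and
  ``barcodes.tsv`` sidecars, one ID per line.

In memory the orientation is fixed: rows are genes, columns are cells
(0-based indices), matching the m × n model input downstream.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse

__all__ = [
    "CountMatrix",
    "MatrixIOError",
    "read_counts",
    "read_labels",
    "write_counts",
    "write_labels",
]


class MatrixIOError(ValueError):
    """Malformed or inconsistent count-matrix / label input."""


@dataclass
class CountMatrix:
    """Raw integer read counts, genes × cells, with identifiers.

    Invariants enforced at construction: counts are non-negative integers,
    gene and cell IDs are unique and match the matrix dimensions, and
    labels (when present) align one-to-one with cells.
    """

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise MatrixIOError(f"counts must be 2-D, got shape {counts.shape}")
        if not np.issubdtype(counts.dtype, np.integer):
            bad = ~np.isfinite(counts) | (counts % 1 != 0)
            if bad.any():
                g, c = map(int, np.argwhere(bad)[0])
                raise MatrixIOError(
                    f"non-integer count at gene row {g}, cell column {c}: "
                    f"{counts[g, c]!r}"
                )
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            g, c = map(int, np.argwhere(counts < 0)[0])
            raise MatrixIOError(
                f"negative count at gene row {g}, cell column {c}: {counts[g, c]}"
            )
        self.counts = counts
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if len(self.gene_ids) != counts.shape[0]:
            raise MatrixIOError(
                f"{len(self.gene_ids)} gene IDs for {counts.shape[0]} gene rows"
            )
        if len(self.cell_ids) != counts.shape[1]:
            raise MatrixIOError(
                f"{len(self.cell_ids)} cell IDs for {counts.shape[1]} cell columns"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise MatrixIOError("duplicate gene IDs")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise MatrixIOError("duplicate cell IDs")
        if self.labels is not None:
            self.labels = [str(l) for l in self.labels]
            if len(self.labels) != counts.shape[1]:
                raise MatrixIOError(
                    f"{len(self.labels)} labels for {counts.shape[1]} cells"
                )

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]


def _read_id_file(path: Path) -> list[str]:
    """Read one ID per line; for multi-column sidecars keep the first field."""
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return ids


def _mtx_paths(path: str | os.PathLike) -> tuple[Path, Path, Path]:
    p = Path(path)
    d = p if p.is_dir() else p.parent
    mtx = p if p.suffix == ".mtx" else d / "matrix.mtx"
    return mtx, d / "genes.tsv", d / "barcodes.tsv"


def read_counts(path: str | os.PathLike, format: str = "dense_tsv") -> CountMatrix:
    """Read a count matrix from disk.

    ``format='dense_tsv'`` expects genes in rows / cells in columns;
    ``format='mtx_triplet'`` expects a ``.mtx`` file (or a directory
    containing ``matrix.mtx``) plus ``genes.tsv`` / ``barcodes.tsv``
    sidecars in the same directory. Entries absent from the sparse file
    are zero.
    """
    if format == "dense_tsv":
        return _read_dense(Path(path))
    if format == "mtx_triplet":
        return _read_mtx(path)
    raise MatrixIOError(f"unknown format {format!r}")


def _read_dense(path: Path) -> CountMatrix:
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise MatrixIOError(f"{path}: line 1: empty header")
        cell_ids = header.split(sep)
        # a leading corner label over the gene-ID column is tolerated
        if cell_ids and cell_ids[0] in ("", "gene", "gene_id", "genes"):
            cell_ids = cell_ids[1:]
        else:
            # no corner field: header may hold exactly the cell IDs; decide
            # from the first data line's field count
            pos = fh.tell()
            first = fh.readline().rstrip("\n")
            fh.seek(pos)
            if first and len(first.split(sep)) == len(cell_ids):
                cell_ids = cell_ids[1:]
        if not cell_ids:
            raise MatrixIOError(f"{path}: line 1: header has no cell IDs")
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split(sep)
            if len(fields) != len(cell_ids) + 1:
                raise MatrixIOError(
                    f"{path}: line {lineno}: expected {len(cell_ids) + 1} "
                    f"fields, found {len(fields)}"
                )
            gene_ids.append(fields[0])
            try:
                rows.append([float(v) for v in fields[1:]])
            except ValueError as err:
                raise MatrixIOError(f"{path}: line {lineno}: {err}") from err
    if not rows:
        raise MatrixIOError(f"{path}: no data rows")
    return CountMatrix(np.array(rows), gene_ids, cell_ids)


def _read_mtx(path: str | os.PathLike) -> CountMatrix:
    mtx, genes_f, barcodes_f = _mtx_paths(path)
    for f in (mtx, genes_f, barcodes_f):
        if not f.exists():
            raise MatrixIOError(f"missing file: {f}")
    try:
        mat = scipy.io.mmread(mtx)
    except Exception as err:  # scipy raises plain ValueError on bad headers
        raise MatrixIOError(f"{mtx}: malformed MatrixMarket file: {err}") from err
    mat = scipy.sparse.coo_matrix(mat)
    gene_ids = _read_id_file(genes_f)
    cell_ids = _read_id_file(barcodes_f)
    if mat.shape != (len(gene_ids), len(cell_ids)):
        raise MatrixIOError(
            f"{mtx}: matrix is {mat.shape[0]}×{mat.shape[1]} but sidecars "
            f"list {len(gene_ids)} genes and {len(cell_ids)} cells"
        )
    return CountMatrix(mat.toarray(), gene_ids, cell_ids)


def write_counts(
    m: CountMatrix, path: str | os.PathLike, format: str = "dense_tsv"
) -> None:
    """Write a count matrix; ``read_counts`` round-trips it exactly."""
    if m.n_genes == 0 or m.n_cells == 0:
        raise MatrixIOError(
            f"refusing to write empty matrix ({m.n_genes} genes × {m.n_cells} cells)"
        )
    if format == "dense_tsv":
        p = Path(path)
        sep = "," if p.suffix.lower() == ".csv" else "\t"
        with open(p, "w") as fh:
            fh.write("gene" + sep + sep.join(m.cell_ids) + "\n")
            for g, row in zip(m.gene_ids, m.counts):
                fh.write(g + sep + sep.join(str(int(v)) for v in row) + "\n")
    elif format == "mtx_triplet":
        d = Path(path)
        d.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(
            d / "matrix.mtx", scipy.sparse.coo_matrix(m.counts), field="integer"
        )
        (d / "genes.tsv").write_text("".join(g + "\n" for g in m.gene_ids))
        (d / "barcodes.tsv").write_text("".join(c + "\n" for c in m.cell_ids))
    else:
        raise MatrixIOError(f"unknown format {format!r}")


def read_labels(
    path: str | os.PathLike, cell_ids: list[str] | None = None
) -> list[str]:
    """Read cell labels: one label per line, or two-column (cell_id, label) TSV.

    The two-column form is reordered to match ``cell_ids`` when given.
    Duplicate or missing cell IDs raise :class:`MatrixIOError`.
    """
    lines = [
        line.rstrip("\n") for line in open(path) if line.rstrip("\n") != ""
    ]
    if not lines:
        raise MatrixIOError(f"{path}: empty label file")
    two_col = "\t" in lines[0]
    if not two_col:
        if cell_ids is not None and len(lines) != len(cell_ids):
            raise MatrixIOError(
                f"{path}: {len(lines)} labels for {len(cell_ids)} cells"
            )
        return lines
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(lines, start=1):
        fields = line.split("\t")
        if len(fields) != 2:
            raise MatrixIOError(f"{path}: line {lineno}: expected 2 fields")
        cid, lab = fields
        if cid in mapping:
            raise MatrixIOError(f"{path}: duplicate cell ID {cid!r}")
        mapping[cid] = lab
    if cell_ids is None:
        return [mapping[line.split("\t")[0]] for line in lines]
    missing = [c for c in cell_ids if c not in mapping]
    if missing:
        raise MatrixIOError(f"{path}: no label for cell ID {missing[0]!r}")
    return [mapping[c] for c in cell_ids]


def write_labels(
    labels: list[str], path: str | os.PathLike, cell_ids: list[str] | None = None
) -> None:
    with open(path, "w") as fh:
        if cell_ids is None:
            fh.writelines(l + "\n" for l in labels)
        else:
            if len(cell_ids) != len(labels):
                raise MatrixIOError("cell_ids and labels differ in length")
            fh.writelines(f"{c}\t{l}\n" for c, l in zip(cell_ids, labels))
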