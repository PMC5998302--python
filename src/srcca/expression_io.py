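"""Expression-matrix containers, file dialects, TPM normalisation and QC.

The central container is :class:`ExpressionMatrix`, a dense gene-by-cell
matrix with a unit tag (``counts``, ``tpm`` or ``log2tpm1``).  Matrices are
read and written either as Matrix Market triplets with one-id-per-line
gene/cell sidecar files (the dominant single-cell convention: 1-based
indices, genes as rows) or as dense TSV/CSV with gene rows and a cell-id
header.

TPM (transcripts per million) divides each gene's count by its effective
length, then rescales every cell to one million::

    rate_g  = count_g / length_g
    tpm_g   = 1e6 * rate_g / sum_g(rate_g)

Quality control is two explicit per-cell thresholds (minimum library size,
minimum genes detected) recorded in a :class:`QCReport`, standing in for
external QC tooling while keeping the stage auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import (
    EmptyResultError,
    FormatError,
    UnitError,
    UsageError,
    ValidationError,
)

UNITS = ("counts", "tpm", "log2tpm1")
_TPM_TOTAL = 1e6
_TPM_RTOL = 1e-6


def _duplicates(ids: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for i in ids:
        if i in seen and i not in dups:
            dups.append(i)
        seen.add(i)
    return dups


@dataclass
class ExpressionMatrix:
    """Dense gene-by-cell expression matrix with identifier sidecars.

    Parameters
    ----------
    values
        2-D float array, genes as rows, cells as columns; finite, >= 0.
    gene_ids, cell_ids
        Unique identifiers matching the array dimensions.
    unit
        One of ``counts``, ``tpm``, ``log2tpm1``.  A ``tpm`` matrix must
        have every cell column summing to 1e6 (relative tolerance 1e-6).
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    unit: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.unit not in UNITS:
            raise UsageError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D gene-by-cell array")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} gene ids x {len(self.cell_ids)} cell ids"
            )
        for label, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            dups = _duplicates(ids)
            if dups:
                raise ValidationError(f"duplicate {label} ids: {dups}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("values must be finite")
        if np.any(self.values < 0):
            raise ValidationError("values must be non-negative")
        if self.unit == "tpm" and self.n_cells:
            sums = self.values.sum(axis=0)
            if not np.allclose(sums, _TPM_TOTAL, rtol=_TPM_RTOL, atol=0):
                bad = [self.cell_ids[i] for i in np.flatnonzero(
                    ~np.isclose(sums, _TPM_TOTAL, rtol=_TPM_RTOL, atol=0))]
                raise ValidationError(f"TPM columns not summing to 1e6: {bad[:5]}")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    # -- convenience ------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_row(self, gene: str) -> np.ndarray:
        from .errors import GeneLookupError

        try:
            return self.values[self._gene_index[gene]]
        except KeyError:
            close = [g for g in self.gene_ids if gene.upper() in g.upper()][:5]
            raise GeneLookupError(gene, close) from None

    def has_gene(self, gene: str) -> bool:
        return gene in self._gene_index

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)

    def subset_cells(self, keep: Iterable[str]) -> "ExpressionMatrix":
        keep = list(keep)
        idx = {c: i for i, c in enumerate(self.cell_ids)}
        cols = [idx[c] for c in keep]
        return ExpressionMatrix(self.values[:, cols], list(self.gene_ids), keep, self.unit)


@dataclass
class GeneLengthTable:
    """Effective transcript lengths in bases, keyed by gene id."""

    lengths: dict[str, float]

    def __post_init__(self) -> None:
        self.lengths = {str(g): float(v) for g, v in self.lengths.items()}
        bad = [g for g, v in self.lengths.items() if not (v > 0 and math.isfinite(v))]
        if bad:
            raise ValidationError(f"non-positive gene lengths: {bad[:5]}")

    def __getitem__(self, gene: str) -> float:
        return self.lengths[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self.lengths

    @classmethod
    def read_tsv(cls, path: str | Path) -> "GeneLengthTable":
        df = pd.read_csv(path, sep="\t", header=None, names=["gene", "length"])
        return cls(dict(zip(df["gene"].astype(str), df["length"])))


@dataclass
class QCReport:
    """Per-cell QC metrics and the thresholds that produced the verdicts."""

    cell_ids: list[str]
    library_size: np.ndarray
    genes_detected: np.ndarray
    passed: np.ndarray
    min_library: float
    min_genes_detected: int

    @property
    def n_pass(self) -> int:
        return int(self.passed.sum())

    @property
    def n_fail(self) -> int:
        return len(self.cell_ids) - self.n_pass

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "library_size": self.library_size,
                "genes_detected": self.genes_detected,
                "pass": self.passed,
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# file dialects


def _read_ids(path: Path, what: str) -> list[str]:
    if not path.exists():
        raise FormatError(f"missing {what} sidecar file: {path}")
    ids = [line.strip() for line in path.read_text().splitlines() if line.strip()]
    dups = _duplicates(ids)
    if dups:
        raise ValidationError(f"duplicate ids in {path}: {dups}")
    return ids


def _mtx_paths(path: Path) -> tuple[Path, Path, Path]:
    if path.is_dir():
        return path / "matrix.mtx", path / "genes.txt", path / "cells.txt"
    stem = path.with_suffix("")
    return path, Path(f"{stem}.genes.txt"), Path(f"{stem}.cells.txt")


def read_matrix(path: str | Path, format: str = "mtx_triplet",
                unit: str = "counts") -> ExpressionMatrix:
    """Read an expression matrix in one of the supported dialects.

    ``mtx_triplet`` expects the .mtx file plus ``<stem>.genes.txt`` /
    ``<stem>.cells.txt`` sidecars (or ``matrix.mtx``/``genes.txt``/
    ``cells.txt`` when given a directory).  ``dense_tsv``/``dense_csv``
    expect gene rows, a header row of cell ids and a first column of
    gene ids.
    """
    path = Path(path)
    if format == "mtx_triplet":
        mtx, genes_p, cells_p = _mtx_paths(path)
        if not mtx.exists():
            raise FormatError(f"matrix file not found: {mtx}")
        genes = _read_ids(genes_p, "gene")
        cells = _read_ids(cells_p, "cell")
        try:
            mat = scipy.io.mmread(mtx)
        except Exception as exc:  # malformed header/triplets
            raise FormatError(f"cannot parse Matrix Market file {mtx}: {exc}") from exc
        mat = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
        if mat.shape != (len(genes), len(cells)):
            raise FormatError(
                f"{mtx}: matrix is {mat.shape[0]}x{mat.shape[1]} but sidecars list "
                f"{len(genes)} genes ({genes_p.name}) and {len(cells)} cells ({cells_p.name})"
            )
        return ExpressionMatrix(mat, genes, cells, unit)
    if format in ("dense_tsv", "dense_csv"):
        sep = "\t" if format == "dense_tsv" else ","
        if not path.exists():
            raise FormatError(f"matrix file not found: {path}")
        df = pd.read_csv(path, sep=sep, index_col=0)
        return ExpressionMatrix(df.to_numpy(dtype=float),
                                [str(g) for g in df.index],
                                [str(c) for c in df.columns], unit)
    raise UsageError(f"unknown format {format!r}")


def write_matrix(m: ExpressionMatrix, path: str | Path,
                 format: str = "mtx_triplet") -> None:
    """Write a matrix in the dialect `read_matrix` can read back."""
    path = Path(path)
    if format == "mtx_triplet":
        mtx, genes_p, cells_p = _mtx_paths(path)
        mtx.parent.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(mtx), scipy.sparse.coo_matrix(m.values))
        genes_p.write_text("".join(f"{g}\n" for g in m.gene_ids))
        cells_p.write_text("".join(f"{c}\n" for c in m.cell_ids))
        return
    if format in ("dense_tsv", "dense_csv"):
        sep = "\t" if format == "dense_tsv" else ","
        path.parent.mkdir(parents=True, exist_ok=True)
        m.to_frame().to_csv(path, sep=sep)
        return
    raise UsageError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# normalisation and QC


def tpm_normalize(m: ExpressionMatrix,
                  lengths: GeneLengthTable | Mapping[str, float]) -> ExpressionMatrix:
    """Length-normalise a counts matrix to TPM (columns sum to 1e6)."""
    if m.unit != "counts":
        raise UnitError(f"tpm_normalize expects counts, got {m.unit!r}")
    if not isinstance(lengths, GeneLengthTable):
        lengths = GeneLengthTable(dict(lengths))
    missing = [g for g in m.gene_ids if g not in lengths]
    if missing:
        raise ValidationError(f"genes without lengths: {missing[:10]}")
    lvec = np.array([lengths[g] for g in m.gene_ids])
    rates = m.values / lvec[:, None]
    totals = rates.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValidationError(
            "cells with zero total counts cannot be TPM-normalised: "
            f"{[m.cell_ids[i] for i in zero]}"
        )
    tpm = rates / totals * _TPM_TOTAL
    return ExpressionMatrix(tpm, list(m.gene_ids), list(m.cell_ids), "tpm")


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2(TPM + 1)."""
    if m.unit != "tpm":
        raise UnitError(f"log_transform expects tpm, got {m.unit!r}")
    return ExpressionMatrix(np.log2(m.values + 1.0), list(m.gene_ids),
                            list(m.cell_ids), "log2tpm1")


def qc_filter(m: ExpressionMatrix, min_library: float = 0,
              min_genes_detected: int = 0) -> tuple[ExpressionMatrix, QCReport]:
    """Drop cells below the library-size / genes-detected thresholds."""
    if min_library < 0 or min_genes_detected < 0:
        raise UsageError("QC thresholds must be >= 0")
    library = m.values.sum(axis=0)
    detected = (m.values > 0).sum(axis=0)
    passed = (library >= min_library) & (detected >= min_genes_detected)
    report = QCReport(list(m.cell_ids), library, detected, passed,
                      float(min_library), int(min_genes_detected))
    if not passed.any():
        raise EmptyResultError(
            f"all {m.n_cells} cells fail QC (min_library={min_library}, "
            f"min_genes_detected={min_genes_detected})"
        )
    keep = [c for c, ok in zip(m.cell_ids, passed) if ok]
    return m.subset_cells(keep), report
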