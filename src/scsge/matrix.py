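"""Expression matrices, time-course assembly, and log(1+x) normalization.

A time course is an ordered collection of gene-by-cell expression matrices
over a shared gene universe, one matrix per sampled time point.  All
downstream network and entropy computations treat the cells of a single
time point as the statistical ensemble, so cells are never mixed across
time points here.

Supported on-disk formats:

* dense delimited text (TSV/CSV): first column gene id, header row cell ids;
* Matrix Market (``.mtx``) with one-column gene-id and cell-id sidecar files;
* cell metadata: two-column TSV with header ``cell_id`` and ``time_label``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

#: Minimum cells per time point: the box statistic uses windows of
#: round(0.1 * N) cells, which needs N >= 10 to be non-degenerate.
MIN_CELLS = 10


@dataclass
class ExpressionMatrix:
    """A genes-by-cells matrix of non-negative expression values.

    Parameters
    ----------
    values
        Array of shape ``(M, N)`` with ``M`` genes in rows and ``N`` cells
        in columns.  Entries must be finite and non-negative.
    gene_ids, cell_ids
        Unique identifiers for rows and columns.
    normalized
        ``True`` once ``log(1+x)`` normalization has been applied.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D array")
        m, n = self.values.shape
        if m != len(self.gene_ids) or n != len(self.cell_ids):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} gene ids x {len(self.cell_ids)} cell ids"
            )
        if m < 2:
            raise ValidationError(f"need at least 2 genes, got {m}")
        if n < MIN_CELLS:
            raise ValidationError(
                f"need at least {MIN_CELLS} cells per time point, got {n}"
            )
        for name, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise ValidationError(f"duplicate {name} id {dup!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values contain non-finite entries")
        if np.any(self.values < 0):
            i, k = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative expression value at gene {self.gene_ids[i]!r}, "
                f"cell {self.cell_ids[k]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise ValidationError(f"unknown gene id {gene!r}") from None

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Return a new matrix restricted to ``genes``, in the given order."""
        idx = [self.gene_index(g) for g in genes]
        return ExpressionMatrix(
            self.values[idx, :], list(genes), list(self.cell_ids), self.normalized
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


def _first_duplicate(ids: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


def log_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Apply the elementwise ``log(1+x)`` transform (natural logarithm).

    The transform is monotone within every gene row, so it preserves the
    rank order of cells per gene and hence all box structures downstream.
    Raises :class:`ValidationError` if ``m`` is already normalized, to
    prevent an accidental double transform.
    """
    if m.normalized:
        raise ValidationError("matrix is already log(1+x)-normalized")
    return ExpressionMatrix(
        np.log1p(m.values), list(m.gene_ids), list(m.cell_ids), normalized=True
    )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _infer_sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(
    path: str | Path,
    format: str = "auto",
    gene_file: str | Path | None = None,
    cell_file: str | Path | None = None,
    transpose: bool = False,
) -> ExpressionMatrix:
    """Read an expression matrix from disk.

    ``format`` is one of ``"dense"``, ``"mtx"`` or ``"auto"`` (by suffix).
    Dense files carry gene ids in the first column and cell ids in the
    header row; Matrix Market files require the two sidecar id files.
    ``transpose`` flips a cells-in-rows dialect into the canonical
    genes-in-rows orientation.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    if format == "auto":
        format = "mtx" if path.suffix.lower() == ".mtx" else "dense"

    if format == "mtx":
        if gene_file is None or cell_file is None:
            raise ValidationError(
                "matrix-market input requires gene_file and cell_file sidecars"
            )
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:  # scipy raises bare ValueError on bad headers
            raise ParseError(f"cannot parse Matrix Market file {path}: {exc}") from exc
        values = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float
        )
        gene_ids = _read_id_column(gene_file)
        cell_ids = _read_id_column(cell_file)
    elif format == "dense":
        try:
            df = pd.read_csv(
                path,
                sep=_infer_sep(path),
                index_col=0,
                header=0,
                float_precision="round_trip",
            )
        except Exception as exc:
            raise ParseError(f"cannot parse {path}: {exc}") from exc
        non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
        if non_numeric:
            raise ParseError(
                f"{path}: non-numeric values in column(s) {non_numeric[:3]}"
            )
        values = df.to_numpy(dtype=float)
        gene_ids = [str(g) for g in df.index]
        cell_ids = [str(c) for c in df.columns]
    else:
        raise ValidationError(f"unknown format {format!r}")

    if transpose:
        values = values.T
        gene_ids, cell_ids = cell_ids, gene_ids
    return ExpressionMatrix(values, gene_ids, cell_ids, normalized=False)


def _read_id_column(path: str | Path) -> list[str]:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such sidecar file: {path}")
    with open(path) as fh:
        ids = [line.strip().split("\t")[0] for line in fh if line.strip()]
    if not ids:
        raise ParseError(f"empty identifier file: {path}")
    return ids


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    """Write a dense delimited matrix (separator chosen from the suffix).

    ``write_expression`` followed by :func:`read_expression` round-trips
    bit-identically: floats are printed with 17 significant digits.
    """
    path = Path(path)
    m.to_dataframe().to_csv(
        path, sep=_infer_sep(path), float_format=lambda v: format(float(v), ".17g")
    )


def read_time_metadata(path: str | Path) -> pd.DataFrame:
    """Read the two-column cell metadata table (``cell_id``, ``time_label``)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ParseError(f"cannot parse metadata {path}: {exc}") from exc
    missing = {"cell_id", "time_label"} - set(df.columns)
    if missing:
        raise ParseError(
            f"{path}: metadata must have columns cell_id and time_label; "
            f"missing {sorted(missing)}"
        )
    df["cell_id"] = df["cell_id"].astype(str)
    df["time_label"] = pd.to_numeric(df["time_label"], errors="raise")
    dup = _first_duplicate(list(df["cell_id"]))
    if dup is not None:
        raise ValidationError(f"duplicate cell id {dup!r} in metadata")
    return df


def split_by_time(
    m: ExpressionMatrix, metadata: pd.DataFrame
) -> tuple[list[ExpressionMatrix], list[float]]:
    """Split one combined matrix into per-time-point matrices.

    Every cell in ``m`` must be assigned a time label in ``metadata``.
    Returns matrices ordered by ascending time label, preserving the
    original cell order within each time point.
    """
    assignment = dict(zip(metadata["cell_id"], metadata["time_label"]))
    missing = [c for c in m.cell_ids if c not in assignment]
    if missing:
        raise ValidationError(
            f"{len(missing)} cells missing from metadata (first: {missing[0]!r})"
        )
    labels = sorted({float(assignment[c]) for c in m.cell_ids})
    matrices = []
    for t in labels:
        cols = [k for k, c in enumerate(m.cell_ids) if float(assignment[c]) == t]
        matrices.append(
            ExpressionMatrix(
                m.values[:, cols],
                list(m.gene_ids),
                [m.cell_ids[k] for k in cols],
                m.normalized,
            )
        )
    return matrices, labels


# ---------------------------------------------------------------------------
# time course
# ---------------------------------------------------------------------------


@dataclass
class TimeCourse:
    """An ordered set of per-time-point expression matrices.

    All matrices share an identical, identically ordered gene universe;
    ``time_labels`` are strictly increasing.  Tipping-point detection needs
    at least three time points; shorter courses are allowed (a warning is
    issued at assembly) so that entropy outputs can still be computed.
    """

    matrices: list[ExpressionMatrix]
    time_labels: list[float]
    time_unit: str = ""
    dropped_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.matrices) != len(self.time_labels):
            raise ValidationError("one time label per matrix required")
        if not self.matrices:
            raise ValidationError("empty time course")
        labels = [float(t) for t in self.time_labels]
        if any(b <= a for a, b in zip(labels, labels[1:])):
            raise ValidationError(
                f"time labels must be strictly increasing, got {labels}"
            )
        self.time_labels = labels
        ref = self.matrices[0].gene_ids
        for t, m in zip(labels, self.matrices):
            if m.gene_ids != ref:
                raise ValidationError(
                    f"matrix at time {t} does not share the gene universe"
                )

    @property
    def n_timepoints(self) -> int:
        return len(self.matrices)

    @property
    def gene_ids(self) -> list[str]:
        return self.matrices[0].gene_ids

    @property
    def normalized(self) -> bool:
        return all(m.normalized for m in self.matrices)

    def log_normalize(self) -> "TimeCourse":
        return TimeCourse(
            [log_normalize(m) for m in self.matrices],
            list(self.time_labels),
            self.time_unit,
            list(self.dropped_genes),
        )


def assemble_timecourse(
    matrices: Sequence[ExpressionMatrix],
    time_labels: Sequence[float],
    time_unit: str = "",
    drop_silent: bool = True,
    top_variable: int | None = None,
) -> TimeCourse:
    """Assemble per-time-point matrices into a validated :class:`TimeCourse`.

    Gene universes are intersected (order taken from the first matrix) and a
    report of dropped genes is logged.  With ``drop_silent`` (default), genes
    with zero expression in every cell of some time point are removed: such
    genes carry no rank structure there and can only form tie-break boxes.
    ``top_variable`` optionally retains only the ``V`` genes with largest
    pooled variance, for tractability on large matrices.
    """
    if len(matrices) != len(time_labels):
        raise ValidationError("matrices and time_labels must have equal length")
    labels = [float(t) for t in time_labels]
    if any(b <= a for a, b in zip(labels, labels[1:])):
        raise ValidationError(f"time labels must be strictly increasing, got {labels}")
    if len(matrices) < 3:
        warnings.warn(
            "fewer than 3 time points: tipping-point detection is disabled",
            stacklevel=2,
        )

    shared = [g for g in matrices[0].gene_ids if all(g in m.gene_ids for m in matrices)]
    dropped = sorted(
        {g for m in matrices for g in m.gene_ids if g not in set(shared)}
    )
    if not shared:
        raise ValidationError("gene universes have an empty intersection")
    if dropped:
        logger.info(
            "assemble_timecourse: dropped %d genes absent from some time point",
            len(dropped),
        )
    mats = [m.subset_genes(shared) for m in matrices]

    if drop_silent:
        silent = np.zeros(len(shared), dtype=bool)
        for m in mats:
            silent |= ~np.any(m.values > 0, axis=1)
        if silent.any():
            kept = [g for g, s in zip(shared, silent) if not s]
            gone = [g for g, s in zip(shared, silent) if s]
            logger.info(
                "assemble_timecourse: dropped %d silent genes", len(gone)
            )
            dropped = sorted(set(dropped) | set(gone))
            if len(kept) < 2:
                raise ValidationError("fewer than 2 genes left after filtering")
            mats = [m.subset_genes(kept) for m in mats]
            shared = kept

    if top_variable is not None and top_variable < len(shared):
        pooled = np.concatenate([m.values for m in mats], axis=1)
        var = pooled.var(axis=1)
        order = sorted(range(len(shared)), key=lambda i: (-var[i], shared[i]))
        keep = sorted(order[:top_variable])
        shared = [shared[i] for i in keep]
        mats = [m.subset_genes(shared) for m in mats]
        logger.info("assemble_timecourse: kept top %d variable genes", len(shared))

    return TimeCourse(mats, labels, time_unit, dropped)
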