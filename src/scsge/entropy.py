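"""Single-cell graph entropy (SGE) at local, cell, and time-point scale.

For gene ``g_i`` in cell ``C_k``, the local network ``LN_i(k)`` is the star
of ``g_i`` and its ``S`` first-order neighbors in the cell-specific
network.  Each neighbor ``g_j`` receives probability mass

    p_ij(k) = r_ij(k) * E_j(k) / sum_j r_ij(k) * E_j(k)

(the dependency weight times the neighbor's normalized expression), and
the local SGE is the normalized Shannon entropy

    H_i(k) = -(1 / log S) * sum_j p_ij(k) * log p_ij(k)  in  [0, 1].

Conventions: ``0 * log 0 = 0``; ``H_i(k) = 0`` when ``S <= 1`` (no
distributional uncertainty) or when all neighbor masses vanish.  Natural
logarithms are used throughout; the ``log S`` normalizer makes ``H``
base-invariant.

A cell's SGE ``H(k)`` sums the top ``T = ceil(0.05 * M)`` local values,
and the time-point SGE ``H_t`` is the mean of ``H(k)`` over the cells of
the time point.  An abrupt rise of ``H_t`` is the early-warning signal
read out by the tipping-point detector.

Alternative neighbor weightings (``r_only``: ``m_j = r_ij``;
``expr_only``: ``m_j = E_j``) are provided for sensitivity comparison;
``product`` is the method's definition and the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .matrix import ExpressionMatrix
from .network import BoxSpec, CellNetwork, _cell_r_matrix

WEIGHT_MODES = ("product", "r_only", "expr_only")


def local_network(net: CellNetwork, gene: str) -> tuple[list[str], np.ndarray]:
    """Neighbors and order-aligned edge weights of ``gene`` in ``net``."""
    return net.neighbors(gene)


def local_sge(
    weights: Sequence[float],
    expr_of_neighbors: Sequence[float],
    weight_mode: str = "product",
) -> float:
    """Normalized entropy of one local network (scalar reference version)."""
    if weight_mode not in WEIGHT_MODES:
        raise ValidationError(f"unknown weight_mode {weight_mode!r}")
    w = np.asarray(weights, dtype=float)
    e = np.asarray(expr_of_neighbors, dtype=float)
    if w.shape != e.shape:
        raise ValidationError("weights and expressions must be equal length")
    if w.size and w.min() <= 0:
        raise ValidationError("edge weights must be strictly positive")
    if e.size and e.min() < 0:
        raise ValidationError("expression values must be non-negative")
    s = w.size
    if s <= 1:
        return 0.0
    if weight_mode == "product":
        m = w * e
    elif weight_mode == "r_only":
        m = w
    else:
        m = e
    total = m.sum()
    if total <= 0:
        return 0.0
    p = m / total
    nz = p[p > 0]
    h = -float((nz * np.log(nz)).sum()) / math.log(s)
    return min(max(h, 0.0), 1.0)


def _entropy_rows(w: np.ndarray, expr: np.ndarray, weight_mode: str) -> np.ndarray:
    """Vectorized local SGE for all genes of one cell.

    ``w`` is the dense (M, M) non-negative weight matrix (zero where no
    edge), ``expr`` the cell's normalized expression vector.
    """
    mask = w > 0
    s = mask.sum(axis=1)
    if weight_mode == "product":
        m = w * expr[np.newaxis, :]
    elif weight_mode == "r_only":
        m = np.where(mask, w, 0.0)
    elif weight_mode == "expr_only":
        m = np.where(mask, expr[np.newaxis, :], 0.0)
    else:
        raise ValidationError(f"unknown weight_mode {weight_mode!r}")
    m = np.where(mask, m, 0.0)
    total = m.sum(axis=1)
    ok = (s >= 2) & (total > 0)
    h = np.zeros(w.shape[0])
    if ok.any():
        p = m[ok] / total[ok, np.newaxis]
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log(p), 0.0)
        h[ok] = -plogp.sum(axis=1) / np.log(s[ok])
    return np.clip(h, 0.0, 1.0)


@dataclass
class LocalEntropyMatrix:
    """Gene-by-cell matrix of local SGE values (all entries in [0, 1])."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    weight_mode: str = "product"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError("entropy matrix shape mismatch")
        if self.weight_mode not in WEIGHT_MODES:
            raise ValidationError(f"unknown weight_mode {self.weight_mode!r}")
        if self.values.size and (
            self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9
        ):
            raise ValidationError("local SGE values must lie in [0, 1]")
        self.values = np.clip(self.values, 0.0, 1.0)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def gene_means(self) -> np.ndarray:
        return self.values.mean(axis=1)

    def gene_row(self, gene: str) -> np.ndarray:
        try:
            i = self.gene_ids.index(gene)
        except ValueError:
            raise ValidationError(f"unknown gene id {gene!r}") from None
        return self.values[i, :]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


def local_entropy_matrix(
    networks: Sequence[CellNetwork],
    matrix: ExpressionMatrix,
    weight_mode: str = "product",
) -> LocalEntropyMatrix:
    """Local SGE for every (gene, cell) from prebuilt cell networks.

    ``networks`` must be aligned with the columns of ``matrix`` (one
    network per cell, same gene universe).  This is the contract path
    used for moderate sizes and validation;
    :func:`entropy_from_expression` fuses network construction and
    entropy for the pipeline.
    """
    if len(networks) != matrix.n_cells:
        raise ValidationError("one network per cell required")
    for net, cid in zip(networks, matrix.cell_ids):
        if net.gene_ids != matrix.gene_ids:
            raise ValidationError("network and matrix gene universes differ")
        if net.cell_id != cid:
            raise ValidationError(
                f"network order mismatch: {net.cell_id!r} vs cell {cid!r}"
            )
    out = np.zeros((matrix.n_genes, matrix.n_cells))
    for k, net in enumerate(networks):
        w = net.adjacency.toarray()
        out[:, k] = _entropy_rows(w, matrix.values[:, k], weight_mode)
    return LocalEntropyMatrix(
        out, list(matrix.gene_ids), list(matrix.cell_ids), weight_mode
    )


def entropy_from_expression(
    matrix: ExpressionMatrix,
    spec: BoxSpec = BoxSpec(),
    weight_mode: str = "product",
    return_mean_degrees: bool = False,
):
    """Fused box-statistic + entropy computation for one time point.

    Equivalent to building every cell's network and calling
    :func:`local_entropy_matrix`, but never materializes the networks;
    this is the pipeline's fast path.  Optionally also returns the mean
    degree of each cell's (implicit) network.
    """
    if not matrix.normalized:
        raise ValidationError("entropy_from_expression requires a normalized matrix")
    m, n = matrix.values.shape
    out = np.zeros((m, n))
    mean_deg = np.zeros(n)
    for k in range(n):
        r = _cell_r_matrix(matrix.values, k, spec)
        w = np.where(r > 0, r, 0.0)
        out[:, k] = _entropy_rows(w, matrix.values[:, k], weight_mode)
        mean_deg[k] = (w > 0).sum() / m
    lem = LocalEntropyMatrix(
        out, list(matrix.gene_ids), list(matrix.cell_ids), weight_mode
    )
    if return_mean_degrees:
        return lem, mean_deg
    return lem


# ---------------------------------------------------------------------------
# cell- and time-point-level aggregation
# ---------------------------------------------------------------------------


def cell_sge(
    local_column: np.ndarray, t_fraction: float = 0.05
) -> tuple[float, int]:
    """Sum of the ``T = ceil(t_fraction * M)`` largest local SGE values.

    Returns ``(H_k, T_used)``.  The sum is invariant to how ties at the
    cutoff are resolved; gene identity under ties is handled by the
    signaling-gene ranking, which breaks ties lexically.
    """
    col = np.asarray(local_column, dtype=float)
    if col.ndim != 1 or col.size < 1:
        raise ValidationError("local_column must be a non-empty vector")
    if not 0.0 < t_fraction <= 1.0:
        raise ValidationError(f"t_fraction must be in (0, 1], got {t_fraction}")
    t_used = math.ceil(t_fraction * col.size)
    top = np.partition(col, col.size - t_used)[col.size - t_used :]
    return float(top.sum()), t_used


def timepoint_sge(per_cell_values: Sequence[float]) -> float:
    """Mean cell SGE over a time point's cell population."""
    vals = np.asarray(per_cell_values, dtype=float)
    if vals.size == 0:
        raise ValidationError("timepoint_sge needs at least one cell")
    return float(vals.mean())


def timepoint_summary(per_cell_values: Sequence[float]) -> dict[str, float]:
    """Mean with median and quartiles, for the box-plot robustness view."""
    vals = np.asarray(per_cell_values, dtype=float)
    if vals.size == 0:
        raise ValidationError("timepoint_summary needs at least one cell")
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    return {
        "mean": float(vals.mean()),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "n": int(vals.size),
    }


@dataclass
class TimepointEntropy:
    """Per-cell and mean SGE for one time point."""

    time_label: float
    h_t: float
    per_cell: np.ndarray
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.per_cell = np.asarray(self.per_cell, dtype=float)
        if len(self.cell_ids) != self.per_cell.size:
            raise ValidationError("cell ids and values must align")
        if not math.isclose(self.h_t, float(self.per_cell.mean()), rel_tol=1e-9):
            raise ValidationError("h_t must equal the mean of its per-cell values")


@dataclass
class EntropySeries:
    """The SGE time series: per-cell H(k) grouped by time point."""

    per_timepoint: list[TimepointEntropy]
    t_used: int
    t_fraction: float

    @property
    def time_labels(self) -> list[float]:
        return [tp.time_label for tp in self.per_timepoint]

    @property
    def h_t(self) -> list[float]:
        return [tp.h_t for tp in self.per_timepoint]

    @property
    def per_cell(self) -> dict[str, float]:
        return {
            c: float(v)
            for tp in self.per_timepoint
            for c, v in zip(tp.cell_ids, tp.per_cell)
        }

    def to_dataframe(self) -> pd.DataFrame:
        """Long table: one row per cell (cell_id, time_label, cell_sge)."""
        rows = [
            (c, tp.time_label, float(v))
            for tp in self.per_timepoint
            for c, v in zip(tp.cell_ids, tp.per_cell)
        ]
        return pd.DataFrame(rows, columns=["cell_id", "time_label", "cell_sge"])

    def summary_dataframe(self) -> pd.DataFrame:
        rows = []
        for tp in self.per_timepoint:
            d = timepoint_summary(tp.per_cell)
            d["time_label"] = tp.time_label
            d["h_t"] = tp.h_t
            rows.append(d)
        return pd.DataFrame(rows)[
            ["time_label", "h_t", "n", "median", "q1", "q3", "mean"]
        ]


def build_entropy_series(
    lems: Sequence[LocalEntropyMatrix],
    time_labels: Sequence[float],
    t_fraction: float = 0.05,
) -> EntropySeries:
    """Aggregate per-time-point local entropy matrices into the SGE series."""
    if len(lems) != len(time_labels):
        raise ValidationError("one time label per entropy matrix required")
    if not lems:
        raise ValidationError("empty entropy series")
    t_used = math.ceil(t_fraction * lems[0].n_genes)
    points = []
    for t, lem in zip(time_labels, lems):
        vals = np.array(
            [cell_sge(lem.values[:, k], t_fraction)[0] for k in range(len(lem.cell_ids))]
        )
        points.append(
            TimepointEntropy(float(t), timepoint_sge(vals), vals, list(lem.cell_ids))
        )
    return EntropySeries(points, t_used, t_fraction)


def series_from_dataframe(df: pd.DataFrame, t_used: int = 0, t_fraction: float = 0.05) -> EntropySeries:
    """Rebuild an :class:`EntropySeries` from its long-table export."""
    required = {"cell_id", "time_label", "cell_sge"}
    if not required <= set(df.columns):
        raise ValidationError(f"series table must have columns {sorted(required)}")
    points = []
    for t in sorted(df["time_label"].unique()):
        sub = df[df["time_label"] == t]
        vals = sub["cell_sge"].to_numpy(dtype=float)
        points.append(
            TimepointEntropy(float(t), float(vals.mean()), vals, list(sub["cell_id"]))
        )
    return EntropySeries(points, t_used, t_fraction)


def lem_by_time(
    lems: Sequence[LocalEntropyMatrix], time_labels: Sequence[float]
) -> Mapping[float, LocalEntropyMatrix]:
    return {float(t): lem for t, lem in zip(time_labels, lems)}
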