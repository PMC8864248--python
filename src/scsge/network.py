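"""Cell-specific gene association networks from box-counting statistics.

For one cell ``k`` and one gene pair ``(g_i, g_j)``, picture the scatter
plot of the two genes' expression over all ``N`` cells of the time point.
Around the point for cell ``k`` lie two axis-aligned boxes, each holding
the ``b = round(0.1 * N)`` cells whose expression is nearest to cell
``k``'s value on that axis.  The dependency index is

    r_ij(k) = n_k(E_i, E_j) / N - (n_k(E_i) / N) * (n_k(E_j) / N)

where ``n_k(E_i, E_j)`` counts cells in both boxes and ``n_k(E_i) =
n_k(E_j) = b``.  Under independence the expected overlap is ``b^2 / N``,
so ``r > 0`` marks a positive local association: the cell-specific
network draws an edge with weight ``r_ij(k)`` exactly when ``r_ij(k) > 0``.

Boxes are deterministic: the ``b`` cells with smallest ``|value - value_k|``,
ties broken by smaller cell index.  With exact-size boxes the statistic is
bounded in ``[-f^2, f - f^2]`` for box fraction ``f``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import scipy.sparse

from .errors import ValidationError
from .matrix import ExpressionMatrix, TimeCourse

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BoxSpec:
    """Box parameters: ``fraction`` of the ensemble per box (default 0.1)."""

    fraction: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction <= 1.0:
            raise ValidationError(f"box fraction must be in (0, 1], got {self.fraction}")

    def box_size(self, n_cells: int) -> int:
        """Number of cells per box: ``round(fraction * N)``, half-up, >= 1."""
        return max(1, math.floor(self.fraction * n_cells + 0.5))


def box_membership(
    values: np.ndarray, k: int, spec: BoxSpec = BoxSpec()
) -> np.ndarray:
    """Indices of the box around cell ``k`` for one gene's expression vector.

    Returns the ``b`` cells whose values are nearest to ``values[k]``
    (ties by smaller index), as a sorted index array.  Cell ``k`` itself is
    a member unless more than ``b`` lower-index cells tie at its exact
    value (the zero-inflation tie case, where the box degenerates to the
    ``b`` smallest-index tied cells).
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValidationError("box_membership needs at least 2 cells")
    if not 0 <= k < n:
        raise ValidationError(f"cell index {k} out of range for {n} cells")
    b = spec.box_size(n)
    order = np.argsort(np.abs(values - values[k]), kind="stable")
    return np.sort(order[:b])


def dependency_index(
    box_i: Iterable[int], box_j: Iterable[int], n_cells: int
) -> float:
    """The box-overlap dependency statistic for one gene pair and cell."""
    si, sj = set(box_i), set(box_j)
    return len(si & sj) / n_cells - (len(si) / n_cells) * (len(sj) / n_cells)


def _membership_matrix(values: np.ndarray, k: int, b: int) -> np.ndarray:
    """Boolean (M, N) box membership for every gene, centered at cell ``k``.

    Row ``i`` flags the ``b`` cells nearest in value to ``values[i, k]``
    within gene ``i``'s expression row; stable argsort realizes the
    (|delta|, index) tie rule.
    """
    dist = np.abs(values - values[:, [k]])
    order = np.argsort(dist, axis=1, kind="stable")[:, :b]
    member = np.zeros(values.shape, dtype=bool)
    np.put_along_axis(member, order, True, axis=1)
    return member


def _cell_r_matrix(values: np.ndarray, k: int, spec: BoxSpec) -> np.ndarray:
    """Dense (M, M) dependency-index matrix for cell ``k``.

    The diagonal is set to ``-1`` so that self-pairs can never pass the
    ``r > 0`` edge rule.
    """
    m, n = values.shape
    b = spec.box_size(n)
    member = _membership_matrix(values, k, b).astype(np.float32)
    counts = member @ member.T
    r = counts.astype(float) / n - (b / n) ** 2
    np.fill_diagonal(r, -1.0)
    return r


@dataclass
class CellNetwork:
    """Weighted undirected gene-gene graph for a single cell.

    ``adjacency`` is a symmetric sparse matrix over the shared gene
    universe holding only the strictly positive dependency weights; the
    diagonal is empty (no self-loops).
    """

    cell_id: str
    gene_ids: list[str]
    adjacency: scipy.sparse.csr_matrix

    def __post_init__(self) -> None:
        a = scipy.sparse.csr_matrix(self.adjacency)
        if a.shape != (len(self.gene_ids), len(self.gene_ids)):
            raise ValidationError("adjacency shape does not match gene universe")
        a.eliminate_zeros()
        if a.nnz and a.data.min() <= 0:
            raise ValidationError("stored edge weights must be strictly positive")
        if a.diagonal().any():
            raise ValidationError("self-loops are not allowed")
        if (abs(a - a.T) > 1e-12).nnz:
            raise ValidationError("adjacency must be symmetric")
        self.adjacency = a

    @classmethod
    def from_r_matrix(
        cls, cell_id: str, gene_ids: Sequence[str], r: np.ndarray
    ) -> "CellNetwork":
        """Build from a dense dependency matrix, keeping only ``r > 0``."""
        pos = np.where(r > 0, r, 0.0)
        np.fill_diagonal(pos, 0.0)
        return cls(cell_id, list(gene_ids), scipy.sparse.csr_matrix(pos))

    @classmethod
    def from_edges(
        cls,
        cell_id: str,
        gene_ids: Sequence[str],
        edges: Iterable[tuple[str, str, float]],
    ) -> "CellNetwork":
        idx = {g: i for i, g in enumerate(gene_ids)}
        m = len(idx)
        a = scipy.sparse.lil_matrix((m, m))
        for gi, gj, w in edges:
            a[idx[gi], idx[gj]] = w
            a[idx[gj], idx[gi]] = w
        return cls(cell_id, list(gene_ids), scipy.sparse.csr_matrix(a))

    @property
    def n_edges(self) -> int:
        return self.adjacency.nnz // 2

    @property
    def mean_degree(self) -> float:
        return 2.0 * self.n_edges / len(self.gene_ids)

    def degrees(self) -> np.ndarray:
        return np.asarray((self.adjacency > 0).sum(axis=1)).ravel()

    def neighbors(self, gene: str) -> tuple[list[str], np.ndarray]:
        """First-order neighbors of ``gene`` and their edge weights."""
        try:
            i = self.gene_ids.index(gene)
        except ValueError:
            raise ValidationError(f"unknown gene id {gene!r}") from None
        row = self.adjacency.getrow(i)
        return [self.gene_ids[j] for j in row.indices], row.data.astype(float)

    def edges(self) -> Iterator[tuple[str, str, float]]:
        coo = scipy.sparse.triu(self.adjacency, k=1).tocoo()
        for i, j, w in zip(coo.row, coo.col, coo.data):
            yield self.gene_ids[i], self.gene_ids[j], float(w)

    def to_networkx(self):
        """Export as a :class:`networkx.Graph` (isolated genes included)."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.gene_ids)
        g.add_weighted_edges_from(self.edges())
        return g


def build_cell_network(
    matrix: ExpressionMatrix, k: int, spec: BoxSpec = BoxSpec()
) -> CellNetwork:
    """Build the cell-specific network for cell ``k`` of one time point.

    The statistical ensemble is exactly the cells of ``matrix``; the input
    must be log-normalized first.
    """
    if not matrix.normalized:
        raise ValidationError("build_cell_network requires a normalized matrix")
    r = _cell_r_matrix(matrix.values, k, spec)
    return CellNetwork.from_r_matrix(matrix.cell_ids[k], matrix.gene_ids, r)


def build_all_networks(
    tc: TimeCourse, spec: BoxSpec = BoxSpec(), pool_timepoints: bool = False
) -> list[list[CellNetwork]]:
    """Build one network per cell, grouped by time point.

    By default each time point's cells form their own ensemble.  With
    ``pool_timepoints`` all cells of the course are pooled into a single
    ensemble (a robustness switch; the per-time-point default matches the
    per-time-point normalization).
    """
    if not tc.normalized:
        raise ValidationError("build_all_networks requires a normalized time course")
    out: list[list[CellNetwork]] = []
    if pool_timepoints:
        values = np.concatenate([m.values for m in tc.matrices], axis=1)
        cell_ids = [c for m in tc.matrices for c in m.cell_ids]
        pooled = ExpressionMatrix(values, tc.gene_ids, cell_ids, normalized=True)
        nets = [build_cell_network(pooled, k, spec) for k in range(len(cell_ids))]
        start = 0
        for m in tc.matrices:
            out.append(nets[start : start + m.n_cells])
            start += m.n_cells
    else:
        for t, m in zip(tc.time_labels, tc.matrices):
            nets = [build_cell_network(m, k, spec) for k in range(m.n_cells)]
            logger.info(
                "time %g: %d networks, %d edges total",
                t,
                len(nets),
                sum(n.n_edges for n in nets),
            )
            out.append(nets)
    return out


# ---------------------------------------------------------------------------
# degree statistics
# ---------------------------------------------------------------------------


@dataclass
class DegreeReport:
    """Degree statistics pooled over a collection of cell networks.

    ``powerlaw_slope``/``powerlaw_r2`` come from a least-squares fit of
    ``log(count)`` on ``log(degree)`` over the pooled histogram (degrees
    >= 1 with nonzero counts); a network is flagged scale-free when its
    own fit reaches R^2 >= 0.8.  The flag is informational only.
    """

    per_cell_mean_degree: dict[str, float]
    degree_histogram: dict[int, int]
    powerlaw_slope: float
    powerlaw_r2: float
    per_cell_scale_free: dict[str, bool] = field(default_factory=dict)

    @property
    def scale_free_fraction(self) -> float:
        if not self.per_cell_scale_free:
            return 0.0
        return sum(self.per_cell_scale_free.values()) / len(self.per_cell_scale_free)


def _loglog_fit(hist: dict[int, int]) -> tuple[float, float]:
    pts = [(d, c) for d, c in hist.items() if d >= 1 and c > 0]
    if len(pts) < 2:
        return 0.0, 0.0
    x = np.log([d for d, _ in pts])
    y = np.log([c for _, c in pts])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - float((resid**2).sum()) / ss_tot
    return float(slope), float(r2)


def degree_report(
    networks: Sequence[CellNetwork], scale_free_r2: float = 0.8
) -> DegreeReport:
    """Summarize degrees over networks (a flat sequence, any time points)."""
    if not networks:
        raise ValidationError("degree_report needs at least one network")
    mean_deg: dict[str, float] = {}
    flags: dict[str, bool] = {}
    pooled: dict[int, int] = {}
    for net in networks:
        mean_deg[net.cell_id] = net.mean_degree
        degs = net.degrees()
        own: dict[int, int] = {}
        for d in degs[degs >= 1]:
            pooled[int(d)] = pooled.get(int(d), 0) + 1
            own[int(d)] = own.get(int(d), 0) + 1
        _, r2 = _loglog_fit(own)
        flags[net.cell_id] = bool(own) and r2 >= scale_free_r2
    slope, r2 = _loglog_fit(pooled)
    return DegreeReport(mean_deg, dict(sorted(pooled.items())), slope, r2, flags)


def export_edge_lists(
    networks: Sequence[CellNetwork], path, long_format: bool = True
) -> None:
    """Write networks as TSV edge lists.

    ``long_format`` writes a single file with columns
    ``cell_id, gene_i, gene_j, weight``; otherwise one three-column file
    per cell is written into the directory ``path``.
    """
    import pandas as pd
    from pathlib import Path

    rows = [
        (net.cell_id, gi, gj, w) for net in networks for gi, gj, w in net.edges()
    ]
    df = pd.DataFrame(rows, columns=["cell_id", "gene_i", "gene_j", "weight"])
    if long_format:
        df.to_csv(path, sep="\t", index=False)
    else:
        outdir = Path(path)
        outdir.mkdir(parents=True, exist_ok=True)
        for cell_id, sub in df.groupby("cell_id"):
            sub[["gene_i", "gene_j", "weight"]].to_csv(
                outdir / f"{cell_id}.tsv", sep="\t", index=False
            )
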