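"""Signaling genes at the tipping point, and dark-gene classification.

Signaling genes are the top 5% of genes ranked by mean local SGE over the
cells of the detected critical time point; they behave as a dynamical
network biomarker whose entropy rises collectively near the transition.

A *dark gene* is significantly different in local SGE between the
critical time point and the non-critical time points, while its
expression level is not: per gene, a two-sided Welch t-test compares the
per-cell local SGE at the critical time against all other times pooled
(and likewise for normalized expression), and

    is_dark  <=>  sge_p < alpha  and  expr_p >= alpha.

Welch's unequal-variance form is used because per-time-point cell counts
and variances differ.  Raw P values are reported at ``alpha = 0.05``
without multiple-testing correction, mirroring the method's usage;
Benjamini-Hochberg q-values are additionally attached for reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.stats

from .entropy import LocalEntropyMatrix
from .errors import ValidationError
from .matrix import ExpressionMatrix


def signaling_genes(
    lem: LocalEntropyMatrix,
    fraction: float = 0.05,
    direction: str = "highest",
) -> list[str]:
    """Top (or bottom) ``ceil(fraction * M)`` genes by mean local SGE.

    ``lem`` is the local entropy matrix restricted to the cells of the
    tipping time point.  Ties are broken by lexical gene id.
    """
    if direction not in ("highest", "lowest"):
        raise ValidationError(f"direction must be 'highest' or 'lowest', got {direction!r}")
    if not 0.0 < fraction <= 1.0:
        raise ValidationError(f"fraction must be in (0, 1], got {fraction}")
    means = lem.gene_means()
    n = math.ceil(fraction * lem.n_genes)
    sign = -1.0 if direction == "highest" else 1.0
    order = sorted(range(lem.n_genes), key=lambda i: (sign * means[i], lem.gene_ids[i]))
    return [lem.gene_ids[i] for i in order[:n]]


@dataclass
class DarkGeneRecord:
    """Per-gene SGE-level and expression-level test results."""

    gene_id: str
    sge_p: float
    expr_p: float
    mean_sge_critical: float
    mean_sge_other: float
    mean_expr_critical: float
    mean_expr_other: float
    is_dark: bool
    testable: bool = True
    sge_q: float | None = None
    expr_q: float | None = None

    def to_dict(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "sge_p": self.sge_p,
            "expr_p": self.expr_p,
            "mean_sge_critical": self.mean_sge_critical,
            "mean_sge_other": self.mean_sge_other,
            "mean_expr_critical": self.mean_expr_critical,
            "mean_expr_other": self.mean_expr_other,
            "is_dark": self.is_dark,
            "testable": self.testable,
            "sge_q": self.sge_q,
            "expr_q": self.expr_q,
        }


def _welch(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Welch t-test P value with degenerate-variance conventions."""
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    res = scipy.stats.ttest_ind(a, b, equal_var=False)
    p = float(res.pvalue)
    return 1.0 if math.isnan(p) else p


def dark_gene_scan(
    genes: Sequence[str],
    lem_by_time: Mapping[float, LocalEntropyMatrix],
    expr_by_time: Mapping[float, ExpressionMatrix],
    critical: float,
    alpha: float = 0.05,
    noncritical: str = "pooled",
) -> list[DarkGeneRecord]:
    """Classify ``genes`` as dark or not, given the critical time point.

    ``lem_by_time`` and ``expr_by_time`` map each time label to that time
    point's local entropy matrix and normalized expression matrix.  The
    comparison group is all non-critical time points pooled (default) or
    only the time points adjacent to the critical one
    (``noncritical="adjacent"``).  Pooling is order-free, so the result
    is invariant under relabeling of the non-critical time points.
    """
    critical = float(critical)
    if critical not in {float(t) for t in lem_by_time}:
        raise ValidationError(f"critical time {critical} not among time labels")
    if noncritical not in ("pooled", "adjacent"):
        raise ValidationError(f"noncritical must be 'pooled' or 'adjacent'")
    labels = sorted(float(t) for t in lem_by_time)
    if set(labels) != {float(t) for t in expr_by_time}:
        raise ValidationError("lem_by_time and expr_by_time must share time labels")
    others = [t for t in labels if t != critical]
    if noncritical == "adjacent":
        i = labels.index(critical)
        others = [labels[j] for j in (i - 1, i + 1) if 0 <= j < len(labels)]
    if not others:
        raise ValidationError("no non-critical time points to compare against")

    lem_c = lem_by_time[critical]
    expr_c = expr_by_time[critical]
    records: list[DarkGeneRecord] = []
    for gene in genes:
        present = all(
            gene in lem_by_time[t].gene_ids and gene in expr_by_time[t].gene_ids
            for t in [critical, *others]
        )
        if not present:
            records.append(
                DarkGeneRecord(gene, math.nan, math.nan, math.nan, math.nan,
                               math.nan, math.nan, False, testable=False)
            )
            continue
        sge_crit = lem_c.gene_row(gene)
        sge_other = np.concatenate([lem_by_time[t].gene_row(gene) for t in others])
        gi = expr_c.gene_index(gene)
        expr_crit = expr_c.values[gi, :]
        expr_other = np.concatenate(
            [expr_by_time[t].values[expr_by_time[t].gene_index(gene), :] for t in others]
        )
        sge_p = _welch(sge_crit, sge_other)
        expr_p = _welch(expr_crit, expr_other)
        records.append(
            DarkGeneRecord(
                gene,
                sge_p,
                expr_p,
                float(sge_crit.mean()),
                float(sge_other.mean()),
                float(expr_crit.mean()),
                float(expr_other.mean()),
                is_dark=(sge_p < alpha) and (expr_p >= alpha),
            )
        )

    testable = [r for r in records if r.testable]
    if testable:
        sge_q = scipy.stats.false_discovery_control([r.sge_p for r in testable])
        expr_q = scipy.stats.false_discovery_control([r.expr_p for r in testable])
        for r, qs, qe in zip(testable, sge_q, expr_q):
            r.sge_q = float(qs)
            r.expr_q = float(qe)
    return records


def common_signaling_genes(gene_lists: Sequence[Sequence[str]]) -> list[str]:
    """Intersection of signaling/dark gene lists, in lexical order."""
    if len(gene_lists) < 2:
        raise ValidationError("common_signaling_genes needs at least 2 lists")
    common = set(gene_lists[0])
    for lst in gene_lists[1:]:
        common &= set(lst)
    return sorted(common)
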