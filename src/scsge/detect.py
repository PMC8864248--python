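"""Tipping-point detection on the SGE time series.

A time point ``t`` (from the second point on) is flagged as the critical
point when

1. the population SGE increases: ``H_t > H_{t-1}``, and
2. ``H_t`` differs significantly (two-sided one-sample t-test,
   ``P < alpha``) from the prior information ``X``.

The t statistic is ``S = (mean(X) - H_t) / (sd(X) / sqrt(n))`` with the
sample standard deviation (``n - 1`` denominator) and ``n - 1`` degrees
of freedom.  "Prior information" is configurable:

* ``pooled_cells`` (default): ``X`` pools the per-cell SGE values of all
  time points strictly before ``t``;
* ``prior_means``: ``X`` is the vector of earlier time-point means
  ``(H_1, ..., H_{t-1})``, a conservative small-n alternative that
  becomes testable from the third time point on.

The earliest qualifying time point is reported as the detection; all
qualifying points are kept, since real courses show sustained elevation
after the transition.  No multiple-testing correction is applied across
time points.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.stats

from .entropy import EntropySeries
from .errors import ValidationError

logger = logging.getLogger(__name__)

PRIOR_MODES = ("pooled_cells", "prior_means")


def one_sample_t(X: Sequence[float], x: float) -> tuple[float, float]:
    """One-sample t statistic and two-sided P value of ``mean(X)`` vs ``x``.

    Degenerate samples (zero standard deviation) follow the convention:
    mean equal to ``x`` gives ``(0, 1)``; mean different from ``x`` gives
    a signed-infinity statistic with ``P = 0``.  Both cases are logged.
    """
    vals = np.asarray(X, dtype=float)
    if vals.size < 2:
        raise ValidationError("one_sample_t needs at least 2 observations")
    s = float(vals.std(ddof=1))
    mean = float(vals.mean())
    if s == 0.0:
        if mean == x:
            logger.warning("one_sample_t: zero-variance sample with mean == x")
            return 0.0, 1.0
        logger.warning("one_sample_t: zero-variance sample with mean != x")
        return math.copysign(math.inf, mean - x), 0.0
    res = scipy.stats.ttest_1samp(vals, popmean=x)
    return float(res.statistic), float(res.pvalue)


@dataclass
class CandidateRow:
    """Test record for one candidate time point (the 2nd point onward)."""

    time_label: float
    h_t: float
    h_prev: float
    increase: bool
    t_statistic: float | None
    p_value: float | None
    n_prior: int
    testable: bool

    def to_dict(self) -> dict:
        return {
            "time_label": self.time_label,
            "h_t": self.h_t,
            "h_prev": self.h_prev,
            "increase": self.increase,
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "n_prior": self.n_prior,
            "testable": self.testable,
        }


@dataclass
class TippingResult:
    """Outcome of the detection scan over an SGE series."""

    candidate_table: list[CandidateRow]
    detected: float | None
    all_detected: list[float]
    alpha: float
    prior_mode: str
    parameters: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "detected": self.detected,
            "all_detected": list(self.all_detected),
            "alpha": self.alpha,
            "prior_mode": self.prior_mode,
            "parameters": dict(self.parameters),
            "candidate_table": [row.to_dict() for row in self.candidate_table],
        }


def detect_tipping(
    series: EntropySeries,
    alpha: float = 0.05,
    prior_mode: str = "pooled_cells",
) -> TippingResult:
    """Scan an SGE series for the critical transition.

    Requires at least three time points.  Time points whose prior sample
    has fewer than two observations are marked untestable and can never
    be detected.
    """
    if prior_mode not in PRIOR_MODES:
        raise ValidationError(f"unknown prior_mode {prior_mode!r}")
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    points = series.per_timepoint
    if len(points) < 3:
        raise ValidationError(
            "tipping detection needs at least 3 time points "
            f"(got {len(points)})"
        )

    rows: list[CandidateRow] = []
    detected: list[float] = []
    for t in range(1, len(points)):
        h_t = points[t].h_t
        h_prev = points[t - 1].h_t
        increase = h_t > h_prev
        if prior_mode == "pooled_cells":
            prior = np.concatenate([points[u].per_cell for u in range(t)])
        else:
            prior = np.array([points[u].h_t for u in range(t)])
        testable = prior.size >= 2
        stat: float | None = None
        pval: float | None = None
        if testable:
            stat, pval = one_sample_t(prior, h_t)
            if increase and pval < alpha:
                detected.append(points[t].time_label)
        rows.append(
            CandidateRow(
                points[t].time_label,
                h_t,
                h_prev,
                increase,
                stat,
                pval,
                int(prior.size),
                testable,
            )
        )
    return TippingResult(
        candidate_table=rows,
        detected=detected[0] if detected else None,
        all_detected=detected,
        alpha=alpha,
        prior_mode=prior_mode,
        parameters={"t_fraction": series.t_fraction, "t_used": series.t_used},
    )
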