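"""Synthetic time-course generator with a planted critical transition.

The generator emulates the three-stage picture of a differentiation
course: a stable before-transition stage, a critical stage at one
designated time point, and an after-transition stage.  Cells are drawn
independently per time point as the exponential of a latent Gaussian:

* a planted module of ``dnb_size`` genes is equicorrelated at
  ``rho_before`` normally; at the critical time its correlation jumps to
  ``rho_critical`` and its latent variance is multiplied by
  ``var_boost`` (the collective-fluctuation signature of a dynamical
  network biomarker);
* ``dark_channel_size`` genes keep identical marginal distributions at
  every time point but join the correlated module only at the critical
  time, so their expression is non-differential while their local
  association structure shifts;
* ``deg_channel_size`` genes have their mean expression multiplied by
  ``deg_fold`` from the critical time onward (ordinary differentially
  expressed genes);
* all remaining genes are independent log-normals with the baseline
  location/scale;
* finally each entry is zeroed independently with probability
  ``dropout_rate``.

This is a stylized model, chosen so the planted correlation structure is
exact on the latent scale; it makes no attempt to match real library-size
or zero-inflation statistics.  Truth labels are returned alongside the
course so tests never re-derive them.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .matrix import ExpressionMatrix, TimeCourse


@dataclass
class SyntheticSpec:
    """Generator parameters; defaults define the standard study conditions."""

    n_genes: int = 200
    n_cells_per_time: int = 100
    n_times: int = 6
    critical_index: int = 4  # 1-based time-point index of the planted transition
    dnb_size: int = 20
    rho_before: float = 0.1
    rho_critical: float = 0.7
    var_boost: float = 3.0
    dark_channel_size: int = 10
    deg_channel_size: int = 10
    deg_fold: float = 2.0
    baseline_loc: float = 1.0
    baseline_scale: float = 0.5
    dropout_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dnb_size + self.dark_channel_size + self.deg_channel_size > self.n_genes:
            raise ValidationError("planted channels exceed the gene count")
        if not 2 <= self.critical_index <= self.n_times:
            raise ValidationError(
                f"critical_index must be in [2, n_times], got {self.critical_index}"
            )
        for name in ("rho_before", "rho_critical"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValidationError(f"{name} must be in [0, 1), got {v}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValidationError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if self.n_genes < 2 or self.n_cells_per_time < 10 or self.n_times < 2:
            raise ValidationError("need n_genes >= 2, n_cells_per_time >= 10, n_times >= 2")
        if self.var_boost <= 0 or self.deg_fold <= 0 or self.baseline_scale <= 0:
            raise ValidationError("var_boost, deg_fold and baseline_scale must be positive")
        if self.dnb_size < 2:
            raise ValidationError("dnb_size must be at least 2")


@dataclass
class SyntheticTruth:
    """Ground-truth labels shipped with a generated course."""

    dnb_genes: list[str]
    dark_genes: list[str]
    deg_genes: list[str]
    critical_index: int  # 1-based
    critical_time_label: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


def _gene_ids(spec: SyntheticSpec) -> list[str]:
    width = max(4, len(str(spec.n_genes)))
    return [f"G{i:0{width}d}" for i in range(spec.n_genes)]


def _equicorrelated(
    rng: np.random.Generator, n_cells: int, sds: np.ndarray, rho: float, loc: float
) -> np.ndarray:
    """Latent equicorrelated Gaussian block via a shared factor per cell.

    ``z_i = loc + sd_i * (sqrt(rho) * g + sqrt(1 - rho) * eps_i)`` gives
    pairwise correlation exactly ``rho`` for every gene pair in the block.
    """
    g = rng.standard_normal(n_cells)
    eps = rng.standard_normal((sds.size, n_cells))
    return loc + sds[:, None] * (math.sqrt(rho) * g[None, :] + math.sqrt(1.0 - rho) * eps)


def _sample_timepoint(
    spec: SyntheticSpec, rng: np.random.Generator, t_index: int, planted: bool
) -> np.ndarray:
    """Expression matrix for one time point (``t_index`` is 1-based)."""
    m, n = spec.n_genes, spec.n_cells_per_time
    sd = spec.baseline_scale
    latent = np.empty((m, n))
    dnb = slice(0, spec.dnb_size)
    dark = slice(spec.dnb_size, spec.dnb_size + spec.dark_channel_size)
    deg = slice(dark.stop, dark.stop + spec.deg_channel_size)

    critical = planted and t_index == spec.critical_index
    if critical:
        # dark genes join the module; their latent sd stays at baseline so
        # their marginal distribution is unchanged.
        sds = np.concatenate(
            [
                np.full(spec.dnb_size, sd * math.sqrt(spec.var_boost)),
                np.full(spec.dark_channel_size, sd),
            ]
        )
        block = _equicorrelated(rng, n, sds, spec.rho_critical, spec.baseline_loc)
        latent[dnb] = block[: spec.dnb_size]
        latent[dark] = block[spec.dnb_size :]
    else:
        latent[dnb] = _equicorrelated(
            rng, n, np.full(spec.dnb_size, sd), spec.rho_before, spec.baseline_loc
        )
        latent[dark] = spec.baseline_loc + sd * rng.standard_normal(
            (spec.dark_channel_size, n)
        )

    deg_loc = spec.baseline_loc
    if planted and t_index >= spec.critical_index:
        deg_loc += math.log(spec.deg_fold)
    latent[deg] = deg_loc + sd * rng.standard_normal((spec.deg_channel_size, n))

    rest = slice(deg.stop, m)
    latent[rest] = spec.baseline_loc + sd * rng.standard_normal((m - deg.stop, n))

    expr = np.exp(latent)
    if spec.dropout_rate > 0:
        expr[rng.random((m, n)) < spec.dropout_rate] = 0.0
    return expr


def _build_course(spec: SyntheticSpec, planted: bool) -> TimeCourse:
    rng = np.random.default_rng(spec.seed)
    genes = _gene_ids(spec)
    matrices = []
    for t in range(1, spec.n_times + 1):
        values = _sample_timepoint(spec, rng, t, planted)
        cells = [f"t{t - 1}_c{k:03d}" for k in range(spec.n_cells_per_time)]
        matrices.append(ExpressionMatrix(values, genes, cells, normalized=False))
    return TimeCourse(matrices, [float(t) for t in range(spec.n_times)], time_unit="day")


def generate(spec: SyntheticSpec) -> tuple[TimeCourse, SyntheticTruth]:
    """A course with the planted transition, plus its truth labels."""
    tc = _build_course(spec, planted=True)
    genes = tc.gene_ids
    truth = SyntheticTruth(
        dnb_genes=genes[: spec.dnb_size],
        dark_genes=genes[spec.dnb_size : spec.dnb_size + spec.dark_channel_size],
        deg_genes=genes[
            spec.dnb_size
            + spec.dark_channel_size : spec.dnb_size
            + spec.dark_channel_size
            + spec.deg_channel_size
        ],
        critical_index=spec.critical_index,
        critical_time_label=tc.time_labels[spec.critical_index - 1],
    )
    return tc, truth


def null_generate(spec: SyntheticSpec) -> TimeCourse:
    """A course with no critical time: every time point at baseline."""
    return _build_course(spec, planted=False)


# ---------------------------------------------------------------------------
# on-disk round trip (the same dense-TSV + metadata format io reads)
# ---------------------------------------------------------------------------


def write_dataset(
    tc: TimeCourse,
    outdir: str | Path,
    truth: SyntheticTruth | None = None,
    stem: str = "synthetic",
) -> dict[str, Path]:
    """Write a course as combined dense TSV + metadata (+ truth JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    values = np.concatenate([m.values for m in tc.matrices], axis=1)
    cells = [c for m in tc.matrices for c in m.cell_ids]
    matrix_path = outdir / f"{stem}_matrix.tsv"
    pd.DataFrame(values, index=tc.gene_ids, columns=cells).to_csv(
        matrix_path, sep="\t", float_format=lambda v: format(float(v), ".17g")
    )
    meta_rows = [
        (c, t) for m, t in zip(tc.matrices, tc.time_labels) for c in m.cell_ids
    ]
    meta_path = outdir / f"{stem}_metadata.tsv"
    pd.DataFrame(meta_rows, columns=["cell_id", "time_label"]).to_csv(
        meta_path, sep="\t", index=False
    )
    paths = {"matrix": matrix_path, "metadata": meta_path}
    if truth is not None:
        truth_path = outdir / f"{stem}_truth.json"
        truth.to_json(truth_path)
        paths["truth"] = truth_path
    return paths
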