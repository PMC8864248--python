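"""End-to-end pipeline: normalize, networks, entropy, detection, genes.

:func:`analyze_timecourse` is the in-memory engine; :func:`run_pipeline`
wraps it with file IO, artifact writing, and a run manifest for
provenance.  Outputs are deterministic given identical inputs and
configuration (no timestamps are embedded), so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .detect import PRIOR_MODES, TippingResult, detect_tipping
from .entropy import (
    EntropySeries,
    LocalEntropyMatrix,
    WEIGHT_MODES,
    build_entropy_series,
    entropy_from_expression,
)
from .errors import PipelineError, ScsgeError, ValidationError
from .genes import DarkGeneRecord, dark_gene_scan, signaling_genes
from .matrix import (
    TimeCourse,
    assemble_timecourse,
    read_expression,
    read_time_metadata,
    split_by_time,
)
from .network import BoxSpec, build_all_networks, export_edge_lists

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All tunable constants of the method, with their standard defaults.

    ``box_fraction`` sizes the statistical boxes (0.1 of the ensemble),
    ``t_fraction`` the share of top-entropy genes summed into the cell
    SGE (5%), ``signaling_fraction`` the share of genes reported as
    signaling genes at the tipping point (5%), and ``alpha`` the
    significance level of the detection and dark-gene tests (0.05).
    """

    box_fraction: float = 0.1
    t_fraction: float = 0.05
    weight_mode: str = "product"
    alpha: float = 0.05
    prior_mode: str = "pooled_cells"
    signaling_fraction: float = 0.05
    noncritical: str = "pooled"
    force_time: float | None = None  # analyze this time point if detection is off/empty
    export_networks: bool = False
    transpose: bool = False
    seed: int = 0
    matrix_path: str | None = None
    metadata_path: str | None = None
    format: str = "auto"
    gene_file: str | None = None
    cell_file: str | None = None
    outdir: str | None = None

    def __post_init__(self) -> None:
        for name in ("box_fraction", "t_fraction", "signaling_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValidationError(f"{name} must be in (0, 1], got {v}")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.weight_mode not in WEIGHT_MODES:
            raise ValidationError(f"unknown weight_mode {self.weight_mode!r}")
        if self.prior_mode not in PRIOR_MODES:
            raise ValidationError(f"unknown prior_mode {self.prior_mode!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    """In-memory results of a full analysis run."""

    timecourse: TimeCourse  # normalized
    local_entropy: list[LocalEntropyMatrix]
    mean_degrees: list  # one array of per-cell mean degrees per time point
    series: EntropySeries
    tipping: TippingResult | None
    critical_time: float | None
    signaling: list[str] | None
    signaling_low: list[str] | None
    dark_records: list[DarkGeneRecord] | None

    @property
    def lem_by_time(self) -> dict[float, LocalEntropyMatrix]:
        return {
            float(t): lem
            for t, lem in zip(self.timecourse.time_labels, self.local_entropy)
        }


def analyze_timecourse(tc: TimeCourse, config: RunConfig = RunConfig()) -> PipelineResult:
    """Run the full method on an assembled (raw or normalized) time course."""
    if not tc.normalized:
        tc = tc.log_normalize()
    spec = BoxSpec(config.box_fraction)

    lems = []
    degs = []
    for t, m in zip(tc.time_labels, tc.matrices):
        lem, md = entropy_from_expression(
            m, spec, config.weight_mode, return_mean_degrees=True
        )
        logger.info("time %g: mean degree %.2f", t, float(md.mean()))
        lems.append(lem)
        degs.append(md)

    series = build_entropy_series(lems, tc.time_labels, config.t_fraction)

    tipping: TippingResult | None = None
    if tc.n_timepoints >= 3:
        tipping = detect_tipping(series, config.alpha, config.prior_mode)
    else:
        warnings.warn("fewer than 3 time points: detection disabled", stacklevel=2)

    critical = config.force_time
    if critical is None and tipping is not None:
        critical = tipping.detected

    signaling = signaling_low = None
    dark = None
    if critical is not None:
        critical = float(critical)
        if critical not in tc.time_labels:
            raise ValidationError(f"time {critical} is not a time label of the course")
        lem_c = lems[tc.time_labels.index(critical)]
        signaling = signaling_genes(lem_c, config.signaling_fraction, "highest")
        signaling_low = signaling_genes(lem_c, config.signaling_fraction, "lowest")
        if tc.n_timepoints >= 2:
            dark = dark_gene_scan(
                signaling,
                {float(t): lem for t, lem in zip(tc.time_labels, lems)},
                {float(t): m for t, m in zip(tc.time_labels, tc.matrices)},
                critical,
                config.alpha,
                config.noncritical,
            )
    return PipelineResult(
        timecourse=tc,
        local_entropy=lems,
        mean_degrees=degs,
        series=series,
        tipping=tipping,
        critical_time=critical,
        signaling=signaling,
        signaling_low=signaling_low,
        dark_records=dark,
    )


# ---------------------------------------------------------------------------
# file-level driver
# ---------------------------------------------------------------------------


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def load_timecourse(config: RunConfig) -> TimeCourse:
    """Read matrix + metadata files and assemble the time course."""
    if config.matrix_path is None or config.metadata_path is None:
        raise ValidationError("matrix_path and metadata_path are required")
    matrix = read_expression(
        config.matrix_path,
        config.format,
        config.gene_file,
        config.cell_file,
        config.transpose,
    )
    metadata = read_time_metadata(config.metadata_path)
    matrices, labels = split_by_time(matrix, metadata)
    return assemble_timecourse(matrices, labels)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """File-in, files-out run; artifacts land in ``config.outdir``.

    Writes, in order: the normalized matrix, optional edge lists, the
    local SGE matrix (the drop-in feature table for external clustering),
    the entropy series (per-cell and summary), the tipping JSON, the
    signaling gene lists, the dark-gene report, and a manifest capturing
    configuration, package version, and input checksums.  Any stage
    error aborts with a message naming the stage.
    """
    if config.outdir is None:
        raise ValidationError("outdir is required")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except ScsgeError:
            raise
        except Exception as exc:
            raise PipelineError(f"[{name}] {exc}") from exc

    tc = stage("ingest", load_timecourse, config)
    result = stage("analyze", analyze_timecourse, tc, config)
    tc_norm = result.timecourse

    import pandas as pd

    combined = pd.concat([m.to_dataframe() for m in tc_norm.matrices], axis=1)
    combined.to_csv(outdir / "normalized_matrix.tsv", sep="\t")

    if config.export_networks:
        nets = stage(
            "networks", build_all_networks, tc_norm, BoxSpec(config.box_fraction)
        )
        export_edge_lists(
            [n for group in nets for n in group], outdir / "edge_lists.tsv"
        )

    lem_combined = pd.concat([lem.to_dataframe() for lem in result.local_entropy], axis=1)
    lem_combined.to_csv(outdir / "local_sge_matrix.tsv", sep="\t")
    result.series.to_dataframe().to_csv(outdir / "entropy_series.tsv", sep="\t", index=False)
    result.series.summary_dataframe().to_csv(
        outdir / "entropy_summary.tsv", sep="\t", index=False
    )

    if result.tipping is not None:
        (outdir / "tipping.json").write_text(
            json.dumps(
                {
                    **result.tipping.to_dict(),
                    "parameters": {
                        "alpha": config.alpha,
                        "prior_mode": config.prior_mode,
                        "t_fraction": config.t_fraction,
                        "box_fraction": config.box_fraction,
                        "weight_mode": config.weight_mode,
                    },
                },
                indent=2,
            )
            + "\n"
        )
    if result.signaling is not None:
        (outdir / "signaling_genes.txt").write_text("\n".join(result.signaling) + "\n")
        (outdir / "signaling_genes_low.txt").write_text(
            "\n".join(result.signaling_low) + "\n"
        )
    if result.dark_records is not None:
        pd.DataFrame([r.to_dict() for r in result.dark_records]).to_csv(
            outdir / "dark_genes.tsv", sep="\t", index=False
        )
        (outdir / "dark_genes_summary.json").write_text(
            json.dumps(
                {
                    "critical_time": result.critical_time,
                    "n_scanned": len(result.dark_records),
                    "n_dark": sum(r.is_dark for r in result.dark_records),
                },
                indent=2,
            )
            + "\n"
        )

    manifest = {
        "package": "scsge",
        "version": __version__,
        "config": config.to_dict(),
        "inputs": {
            "matrix": _sha256(config.matrix_path),
            "metadata": _sha256(config.metadata_path),
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return result
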