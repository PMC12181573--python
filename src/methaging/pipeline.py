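"""End-to-end orchestration: QC -> biomarkers -> outliers -> residuals -> contrasts.

The stage order is fixed and logged.  Outlier removal strictly precedes the
reference-model fit, so fence positions are computed on the raw biomarker
values of the full cohort.  Every run writes a manifest (config hash,
package and library versions) sufficient to reproduce the outputs, and all
stages are deterministic given the input files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .clocks import assemble_biomarker_table
from .compare import build_residual_table, correlate_biomarkers, remove_outliers, run_contrasts
from .errors import ConfigError, MethagingError, PipelineError
from .io import (
    load_beta_matrix,
    load_cell_reference,
    load_clock_definition,
    load_composite_definition,
    load_detection_p_matrix,
    load_sample_sheet,
    qc_filter,
)

logger = logging.getLogger(__name__)

STAGES = (
    "config-validation",
    "qc",
    "biomarkers",
    "outlier-removal",
    "reference-fit",
    "residuals",
    "contrasts",
    "correlations",
)


@dataclass
class PipelineConfig:
    """Validated description of one pipeline run (usually parsed from YAML)."""

    beta_path: str
    sheet_path: str
    reference_group: str
    contrasts: list[tuple[str, str]]
    clock_paths: list[str] = field(default_factory=list)
    composite_paths: list[str] = field(default_factory=list)
    cell_reference_path: str | None = None
    detp_path: str | None = None
    dialect: str = "plain"
    alpha: float = 0.05
    sample_mean_thresh: float = 0.05
    probe_fail_thresh: float = 0.01
    iqr_factor: float = 1.5
    welch: bool = False
    per_group_fences: bool = False
    bh_correction: bool = False
    missing_policy: str = "impute-cohort-mean"
    seed: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError("pipeline config must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown pipeline config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.contrasts = [tuple(pair) for pair in cfg.contrasts]
        return cfg

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if not self.contrasts:
            raise ConfigError("at least one contrast pair is required")
        for pair in self.contrasts:
            if len(pair) != 2:
                raise ConfigError(f"contrast {pair!r} is not a pair of group labels")
        if not self.clock_paths and self.cell_reference_path is None:
            raise ConfigError("no biomarkers configured: supply clocks or a cell reference")

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class PipelineResult:
    biomarkers: pd.DataFrame
    residuals: pd.DataFrame
    contrasts: pd.DataFrame
    correlations: pd.DataFrame
    outlier_log: pd.DataFrame
    reference_models: pd.DataFrame
    qc_report: object
    manifest: dict
    output_files: dict[str, Path]


def _models_frame(models: dict) -> pd.DataFrame:
    rows = [vars(m).copy() for m in models.values()]
    return pd.DataFrame(rows)


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> PipelineResult:
    """Execute the full analysis and write tidy result CSVs plus a manifest.

    Any stage failure aborts with the stage name; partially written outputs
    are removed so a result directory is either complete or absent.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = STAGES[0]
    try:
        logger.info("stage %s", stage)
        cfg.validate()
        sheet = load_sample_sheet(cfg.sheet_path)
        present = set(sheet.groups)
        if cfg.reference_group not in present:
            raise ConfigError(
                f"reference group {cfg.reference_group!r} absent from the sample "
                f"sheet (groups: {sorted(present)})"
            )
        for pair in cfg.contrasts:
            for g in pair:
                if g not in present:
                    raise ConfigError(f"contrast group {g!r} absent from the sample sheet")

        stage = "qc"
        logger.info("stage %s", stage)
        beta = load_beta_matrix(cfg.beta_path, dialect=cfg.dialect)
        detp = (load_detection_p_matrix(cfg.detp_path, dialect=cfg.dialect)
                if cfg.detp_path else None)
        beta, qc_report = qc_filter(beta, detp, cfg.sample_mean_thresh, cfg.probe_fail_thresh)
        kept = [s for s in sheet.sample_ids if s in set(beta.sample_ids)]
        sheet = sheet.subset(kept)

        stage = "biomarkers"
        logger.info("stage %s", stage)
        clocks = [load_clock_definition(p) for p in cfg.clock_paths]
        composites = [load_composite_definition(p) for p in cfg.composite_paths]
        cell_ref = (load_cell_reference(cfg.cell_reference_path)
                    if cfg.cell_reference_path else None)
        table = assemble_biomarker_table(
            beta, sheet, clocks, composites, cell_ref, cfg.missing_policy
        )

        stage = "outlier-removal"
        logger.info("stage %s", stage)
        table, outlier_log = remove_outliers(
            table, factor=cfg.iqr_factor,
            per_group=cfg.per_group_fences,
            sheet=sheet if cfg.per_group_fences else None,
        )

        stage = "reference-fit"
        logger.info("stage %s (reference group %s)", stage, cfg.reference_group)
        residuals, models = build_residual_table(table, sheet, cfg.reference_group)

        stage = "contrasts"
        logger.info("stage %s", stage)
        contrasts = run_contrasts(
            residuals, sheet, cfg.contrasts,
            alpha=cfg.alpha, welch=cfg.welch, bh_correction=cfg.bh_correction,
        )

        stage = "correlations"
        logger.info("stage %s", stage)
        correlations = correlate_biomarkers(residuals)

        manifest = {
            "package": "methaging",
            "version": __version__,
            "config_sha256": cfg.content_hash(),
            "config": asdict(cfg),
            "seed": cfg.seed,
            "stages": list(STAGES),
            "counts": {
                "samples_in": qc_report.n_samples_in,
                "samples_removed_qc": qc_report.n_samples_removed,
                "probes_in": qc_report.n_probes_in,
                "probes_removed_qc": qc_report.n_probes_removed,
                "outlier_cells_removed": int(len(outlier_log)),
                "biomarkers": int(table.shape[1]),
            },
            "library_versions": _library_versions(),
        }

        files = {
            "biomarkers": out / "biomarker_table.csv",
            "residuals": out / "residual_table.csv",
            "contrasts": out / "contrasts.csv",
            "correlations": out / "correlations.csv",
            "outlier_log": out / "outlier_log.csv",
            "reference_models": out / "reference_models.csv",
            "qc_samples": out / "qc_removed_samples.csv",
            "qc_probes": out / "qc_removed_probes.csv",
            "manifest": out / "manifest.json",
        }
        models_df = _models_frame(models)
        for key, frame in (
            ("biomarkers", table), ("residuals", residuals),
        ):
            frame.to_csv(files[key], index_label="sample_id")
            written.append(files[key])
        for key, frame in (
            ("contrasts", contrasts), ("correlations", correlations),
            ("outlier_log", outlier_log), ("reference_models", models_df),
            ("qc_samples", qc_report.sample_frame()),
            ("qc_probes", qc_report.probe_frame()),
        ):
            frame.to_csv(files[key], index=False)
            written.append(files[key])
        files["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
        written.append(files["manifest"])
    except MethagingError as exc:
        for path in written:
            path.unlink(missing_ok=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc

    return PipelineResult(
        biomarkers=table, residuals=residuals, contrasts=contrasts,
        correlations=correlations, outlier_log=outlier_log,
        reference_models=models_df, qc_report=qc_report,
        manifest=manifest, output_files=files,
    )


def _library_versions() -> dict[str, str]:
    import numpy
    import scipy

    return {"numpy": numpy.__version__, "scipy": scipy.__version__,
            "pandas": pd.__version__}


def summarize_contrasts(contrasts: pd.DataFrame, alpha: float = 0.05) -> str:
    """Human-readable digest of a contrast table (used by the report command)."""
    lines = []
    total = len(contrasts)
    sig = contrasts[contrasts["p"] < alpha]
    lines.append(f"{total} contrasts tested; {len(sig)} significant at alpha={alpha:g}")
    for _, row in sig.sort_values("p").iterrows():
        lines.append(
            f"  {row['biomarker']}: {row['group_a']} vs {row['group_b']} "
            f"diff={row['mean_difference']:+.3f} t={row['t']:.3f} "
            f"df={row['df']:.0f} p={row['p']:.4g}"
        )
    return "\n".join(lines)
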