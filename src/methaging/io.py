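"""Reading, validation and QC of methylation matrices, sample sheets and clock files.

The two matrix containers (:class:`BetaMatrix`, :class:`DetectionPMatrix`)
wrap a probe-by-sample :class:`pandas.DataFrame` and enforce the invariants
that the rest of the pipeline relies on: unique axes, numeric values, and a
[0, 1] range.  Out-of-range beta values are treated as hard errors rather
than clamped, so upstream preprocessing faults surface immediately.

Matrix files are wide TSV/CSV with probes as rows and samples as columns.
A GEO series-matrix-like dialect is supported in which metadata lines are
prefixed with ``!`` and ignored.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import QCError, ValidationError

logger = logging.getLogger(__name__)

REQUIRED_SHEET_COLUMNS = ("sample_id", "group", "age", "sex")
DEFAULT_SEX_CODING = {"F": 0, "M": 1}


def _check_axes(df: pd.DataFrame, what: str) -> None:
    dup_rows = df.index[df.index.duplicated()].unique()
    if len(dup_rows):
        raise ValidationError(f"{what}: duplicate probe id(s): {list(dup_rows)[:5]}")
    dup_cols = df.columns[df.columns.duplicated()].unique()
    if len(dup_cols):
        raise ValidationError(f"{what}: duplicate sample id(s): {list(dup_cols)[:5]}")


def _check_unit_interval(df: pd.DataFrame, what: str) -> None:
    values = df.to_numpy(dtype=float)
    bad = (values < 0) | (values > 1)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"{what}: value {values[i, j]!r} out of [0, 1] at "
            f"probe {df.index[i]!r}, sample {df.columns[j]!r}"
        )


@dataclass(frozen=True)
class BetaMatrix:
    """Probe x sample matrix of methylation fractions in [0, 1]; NaN = missing."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_axes(self.data, "BetaMatrix")
        _check_unit_interval(self.data, "BetaMatrix")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass(frozen=True)
class DetectionPMatrix:
    """Probe x sample matrix of detection p-values; axes must match the betas."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_axes(self.data, "DetectionPMatrix")
        _check_unit_interval(self.data, "DetectionPMatrix")

    def check_companion(self, beta: BetaMatrix) -> None:
        if list(self.data.index) != beta.probe_ids or list(self.data.columns) != beta.sample_ids:
            raise ValidationError("detection-p matrix axes do not match the beta matrix")


@dataclass(frozen=True)
class SampleSheet:
    """Per-sample phenotype annotations indexed by unique sample id.

    Columns: ``group`` (categorical label), ``age`` (years, > 0), ``sex``
    (0/1; default file coding F=0, M=1) plus arbitrary numeric covariates.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        dup = df.index[df.index.duplicated()].unique()
        if len(dup):
            raise ValidationError(f"SampleSheet: duplicate sample id(s): {list(dup)[:5]}")
        for col in ("group", "age", "sex"):
            if col not in df.columns:
                raise ValidationError(f"SampleSheet: missing required column {col!r}")
        age = df["age"].to_numpy(dtype=float)
        if not np.all(np.isfinite(age)) or np.any(age <= 0):
            bad = df.index[~(np.isfinite(age) & (age > 0))][0]
            raise ValidationError(f"SampleSheet: non-positive or non-finite age for sample {bad!r}")
        sex = df["sex"].to_numpy()
        if not np.isin(sex, [0, 1]).all():
            bad = df.index[~np.isin(sex, [0, 1])][0]
            raise ValidationError(f"SampleSheet: sex must be coded 0/1; offending sample {bad!r}")
        if (df["group"].astype(str).str.len() == 0).any():
            raise ValidationError("SampleSheet: empty group label")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def groups(self) -> list[str]:
        return sorted(self.data["group"].unique())

    def group_of(self) -> pd.Series:
        return self.data["group"]

    def subset(self, sample_ids: Sequence[str]) -> "SampleSheet":
        return SampleSheet(self.data.loc[list(sample_ids)].copy())


@dataclass
class QCReport:
    """Audit trail of the sample-then-probe QC funnel."""

    sample_mean_thresh: float
    probe_fail_thresh: float
    removed_samples: list[tuple[str, float]] = field(default_factory=list)
    removed_probes: list[tuple[str, str, float]] = field(default_factory=list)
    n_samples_in: int = 0
    n_probes_in: int = 0
    skipped: bool = False

    @property
    def n_samples_removed(self) -> int:
        return len(self.removed_samples)

    @property
    def n_probes_removed(self) -> int:
        return len(self.removed_probes)

    def sample_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.removed_samples, columns=["sample_id", "mean_detection_p"])

    def probe_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.removed_probes, columns=["probe_id", "failing_sample", "detection_p"]
        )


# ---------------------------------------------------------------------------
# matrix file parsing


def _infer_sep(path: Path) -> str:
    if path.suffix.lower() in (".tsv", ".txt"):
        return "\t"
    if path.suffix.lower() == ".csv":
        return ","
    with open(path) as fh:
        for line in fh:
            if not line.startswith("!"):
                return "\t" if "\t" in line else ","
    return "\t"


def _read_wide_matrix(path: str | Path, dialect: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect not in ("plain", "series-matrix"):
        raise ValueError(f"unknown dialect {dialect!r}; use 'plain' or 'series-matrix'")
    comment = "!" if dialect == "series-matrix" else None
    raw = pd.read_csv(path, sep=_infer_sep(path), index_col=0, comment=comment, dtype=str)
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    out = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            probe = raw.index[bad.to_numpy().nonzero()[0][0]]
            raise ValidationError(
                f"non-numeric cell {raw.loc[probe, col]!r} at probe {probe!r}, sample {col!r}"
            )
        out[col] = converted
    return out


def load_beta_matrix(path: str | Path, dialect: str = "plain") -> BetaMatrix:
    """Load a wide probe x sample beta matrix.

    ``dialect='series-matrix'`` tolerates ``!``-prefixed metadata lines; the
    payload parses identically to the plain dialect.
    """
    return BetaMatrix(_read_wide_matrix(path, dialect))


def load_detection_p_matrix(path: str | Path, dialect: str = "plain") -> DetectionPMatrix:
    return DetectionPMatrix(_read_wide_matrix(path, dialect))


def write_beta_matrix(beta: BetaMatrix, path: str | Path) -> None:
    """Write as TSV/CSV (by extension) at full float precision for round-trips."""
    path = Path(path)
    beta.data.to_csv(path, sep=_infer_sep(path), index_label="probe_id")


def write_detection_p_matrix(detp: DetectionPMatrix, path: str | Path) -> None:
    path = Path(path)
    detp.data.to_csv(path, sep=_infer_sep(path), index_label="probe_id")


# ---------------------------------------------------------------------------
# QC


def qc_filter(
    beta: BetaMatrix,
    detp: DetectionPMatrix | None,
    sample_mean_thresh: float = 0.05,
    probe_fail_thresh: float = 0.01,
) -> tuple[BetaMatrix, QCReport]:
    """Detection-p based QC: drop low-quality samples first, then failing probes.

    A sample is removed when its mean detection p-value is strictly above
    ``sample_mean_thresh``; afterwards a probe is removed when its detection
    p-value is strictly above ``probe_fail_thresh`` in at least one of the
    *remaining* samples.  The order matters: a probe failing only in an
    already-removed sample is kept.

    When ``detp`` is None the step is skipped with a warning (QC is assumed
    to have happened upstream, as for deposited processed matrices).
    """
    report = QCReport(sample_mean_thresh, probe_fail_thresh)
    report.n_samples_in = len(beta.sample_ids)
    report.n_probes_in = len(beta.probe_ids)
    if detp is None:
        logger.warning("no detection-p matrix supplied; QC filtering skipped")
        report.skipped = True
        return beta, report
    detp.check_companion(beta)

    p = detp.data
    sample_means = p.mean(axis=0, skipna=True)
    keep_samples = sample_means.index[~(sample_means > sample_mean_thresh)]
    for sid in sample_means.index[sample_means > sample_mean_thresh]:
        report.removed_samples.append((sid, float(sample_means[sid])))
    if len(keep_samples) == 0:
        raise QCError("QC removed every sample (all mean detection p-values above threshold)")

    p_kept = p[keep_samples]
    fail_mask = p_kept > probe_fail_thresh
    failing = fail_mask.any(axis=1)
    for pid in p_kept.index[failing]:
        row = p_kept.loc[pid]
        worst = row.idxmax()
        report.removed_probes.append((pid, worst, float(row[worst])))
    keep_probes = p_kept.index[~failing]
    if len(keep_probes) == 0:
        raise QCError("QC removed every probe")

    filtered = BetaMatrix(beta.data.loc[keep_probes, keep_samples].copy())
    logger.info(
        "QC: removed %d/%d samples and %d/%d probes",
        report.n_samples_removed, report.n_samples_in,
        report.n_probes_removed, report.n_probes_in,
    )
    return filtered, report


# ---------------------------------------------------------------------------
# sample sheet


def load_sample_sheet(
    path: str | Path,
    sex_coding: Mapping[str, int] = DEFAULT_SEX_CODING,
) -> SampleSheet:
    """Load the per-sample CSV (columns sample_id, group, age, sex, covariates...).

    ``sex_coding`` maps file labels to the 0/1 indicator used downstream;
    already-numeric 0/1 entries pass through.  Unrecognized columns are kept
    as covariates (e.g. diabetes duration in years).
    """
    df = pd.read_csv(path)
    for col in REQUIRED_SHEET_COLUMNS:
        if col not in df.columns:
            raise ValidationError(f"sample sheet missing required column {col!r}")
    df["sample_id"] = df["sample_id"].astype(str)

    def map_sex(v):
        if isinstance(v, str):
            key = v.strip()
            if key in sex_coding:
                return sex_coding[key]
            try:
                v = float(key)
            except ValueError:
                raise ValidationError(f"unmappable sex value {key!r}") from None
        if v in (0, 1, 0.0, 1.0):
            return int(v)
        raise ValidationError(f"unmappable sex value {v!r}")

    df["sex"] = df["sex"].map(map_sex)
    df["age"] = pd.to_numeric(df["age"], errors="raise")
    if (df["age"] <= 0).any():
        bad = df.loc[df["age"] <= 0, "sample_id"].iloc[0]
        raise ValidationError(f"negative or zero age for sample {bad!r}")
    return SampleSheet(df.set_index("sample_id"))


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.data.to_csv(path, index_label="sample_id")


# ---------------------------------------------------------------------------
# clock definition files (CSV of weights + JSON sidecar with metadata)


def load_clock_definition(csv_path: str | Path, sidecar: str | Path | None = None):
    """Load a linear clock: CSV with columns (cpg, weight) + JSON sidecar.

    The sidecar holds ``{name, intercept, transform, adult_age, units}`` and
    defaults to the CSV path with a ``.json`` extension.
    """
    from .clocks import ClockDefinition  # deferred to avoid a cycle

    csv_path = Path(csv_path)
    sidecar = Path(sidecar) if sidecar is not None else csv_path.with_suffix(".json")
    weights_df = pd.read_csv(csv_path)
    for col in ("cpg", "weight"):
        if col not in weights_df.columns:
            raise ValidationError(f"clock CSV missing required column {col!r}")
    if weights_df["cpg"].duplicated().any():
        dup = weights_df.loc[weights_df["cpg"].duplicated(), "cpg"].iloc[0]
        raise ValidationError(f"clock CSV: duplicate CpG id {dup!r}")
    meta = json.loads(sidecar.read_text())
    return ClockDefinition(
        name=meta["name"],
        intercept=float(meta["intercept"]),
        weights=dict(zip(weights_df["cpg"].astype(str), weights_df["weight"].astype(float))),
        transform=meta.get("transform", "identity"),
        adult_age=float(meta.get("adult_age", 20.0)),
        units=meta.get("units", "years"),
    )


def write_clock_definition(clock, csv_path: str | Path, sidecar: str | Path | None = None) -> None:
    csv_path = Path(csv_path)
    sidecar = Path(sidecar) if sidecar is not None else csv_path.with_suffix(".json")
    pd.DataFrame(
        {"cpg": list(clock.weights), "weight": list(clock.weights.values())}
    ).to_csv(csv_path, index=False)
    sidecar.write_text(json.dumps({
        "name": clock.name,
        "intercept": clock.intercept,
        "transform": clock.transform,
        "adult_age": clock.adult_age,
        "units": clock.units,
    }, indent=2))


def load_composite_definition(path: str | Path):
    """Load a composite clock (JSON: intercept + weights over sub-biomarkers, age, sex)."""
    from .clocks import CompositeClockDefinition

    meta = json.loads(Path(path).read_text())
    return CompositeClockDefinition(
        name=meta["name"],
        intercept=float(meta["intercept"]),
        component_weights={k: float(v) for k, v in meta["component_weights"].items()},
        age_weight=float(meta.get("age_weight", 0.0)),
        sex_weight=float(meta.get("sex_weight", 0.0)),
    )


def load_cell_reference(path: str | Path):
    """Load a cell-type methylation reference (wide CSV, probes x cell types)."""
    from .clocks import CellReferenceMatrix

    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    return CellReferenceMatrix(df.astype(float))
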