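"""Epigenetic clock engine: linear clocks, composite clocks, cell deconvolution.

A clock here is a linear predictor over CpG beta values,
``score_s = g(intercept + sum_j w_j * beta_{j,s})``, where ``g`` is either
the identity or the piecewise anti-log transform used by the Horvath family
of age clocks.  PC-clocks (linear maps on principal components of the betas)
are represented pre-flattened: since projection followed by regression is a
single linear map, one :class:`ClockDefinition` suffices.

Composite clocks (GrimAge-style) combine previously computed sub-biomarkers
with chronological age and sex.  Cell-type fractions are estimated by
constrained projection onto a cell-type methylation reference (non-negative
least squares followed by renormalization onto the simplex).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .errors import ClockError, ValidationError
from .io import BetaMatrix, SampleSheet

logger = logging.getLogger(__name__)

TRANSFORMS = ("identity", "horvath-inverse")
MISSING_POLICIES = ("error", "impute-cohort-mean")


@dataclass(frozen=True)
class ClockDefinition:
    """A linear clock: CpG weights, an intercept, and an output transform.

    ``adult_age`` (years) only matters for the ``horvath-inverse`` transform,
    where it is the knot of the piecewise age calibration.
    """

    name: str
    intercept: float
    weights: Mapping[str, float]
    transform: str = "identity"
    adult_age: float = 20.0
    units: str = "years"

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValidationError(f"clock {self.name!r}: empty weight set")
        if self.transform not in TRANSFORMS:
            raise ValidationError(
                f"clock {self.name!r}: unknown transform {self.transform!r}"
            )
        if not self.adult_age > 0:
            raise ValidationError(f"clock {self.name!r}: adult_age must be > 0")


@dataclass(frozen=True)
class CompositeClockDefinition:
    """A clock that is a linear combination of sub-biomarkers plus age and sex."""

    name: str
    intercept: float
    component_weights: Mapping[str, float]
    age_weight: float = 0.0
    sex_weight: float = 0.0


@dataclass(frozen=True)
class CellReferenceMatrix:
    """Mean beta per probe per cell type (probes x cell types, values in [0,1])."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.shape[1] < 2:
            raise ValidationError("cell reference needs at least 2 cell types")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValidationError(f"cell reference: duplicate probe id {dup!r}")
        vals = self.data.to_numpy(dtype=float)
        if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
            raise ValidationError("cell reference values must lie in [0, 1]")

    @property
    def cell_types(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class LinearClockResult:
    """Per-sample clock values plus a match/imputation audit."""

    values: pd.Series
    n_weights: int
    n_matched: int
    n_imputed_cells: int


def horvath_inverse(x, adult_age: float = 20.0):
    """Anti-log age calibration: maps the linear predictor back to years.

    Continuous and strictly increasing:
    ``x < 0  -> (1 + adult_age) * exp(x) - 1``;
    ``x >= 0 -> (1 + adult_age) * x + adult_age``.
    """
    if not adult_age > 0:
        raise ValidationError("adult_age must be > 0")
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ClockError("horvath_inverse: non-finite input")
    out = np.where(arr < 0, (1.0 + adult_age) * np.exp(arr) - 1.0,
                   (1.0 + adult_age) * arr + adult_age)
    return out.item() if np.isscalar(x) or arr.ndim == 0 else out


def apply_linear_clock(
    beta: BetaMatrix,
    clock: ClockDefinition,
    missing_policy: str = "impute-cohort-mean",
) -> LinearClockResult:
    """Evaluate a linear clock on every sample of a beta matrix.

    Clock CpGs absent from the matrix are dropped (recorded in the result);
    at least one must match.  NaN cells among matched CpGs are handled per
    ``missing_policy``: imputed with the probe's cohort mean, or raised.
    """
    if missing_policy not in MISSING_POLICIES:
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    matched = [cpg for cpg in clock.weights if cpg in beta.data.index]
    if not matched:
        raise ClockError(f"clock {clock.name!r}: no clock CpGs present in the beta matrix")
    sub = beta.data.loc[matched]
    n_imputed = 0
    if sub.isna().any().any():
        if missing_policy == "error":
            raise ClockError(
                f"clock {clock.name!r}: missing beta values under missing_policy='error'"
            )
        n_imputed = int(sub.isna().to_numpy().sum())
        sub = sub.apply(lambda row: row.fillna(row.mean()), axis=1)
        logger.info("clock %s: imputed %d missing cells with cohort means",
                    clock.name, n_imputed)
    w = np.array([clock.weights[c] for c in matched])
    linear = clock.intercept + w @ sub.to_numpy(dtype=float)
    if clock.transform == "horvath-inverse":
        scores = horvath_inverse(linear, clock.adult_age)
    else:
        scores = linear
    if not np.all(np.isfinite(scores)):
        raise ClockError(f"clock {clock.name!r}: non-finite score")
    values = pd.Series(scores, index=beta.data.columns, name=clock.name)
    return LinearClockResult(values, len(clock.weights), len(matched), n_imputed)


def apply_composite_clock(
    table: pd.DataFrame,
    sheet: SampleSheet,
    comp: CompositeClockDefinition,
) -> pd.Series:
    """Evaluate a composite clock on a sample x biomarker table.

    Samples missing any referenced component get a missing output; an
    unknown component name is a hard error.
    """
    for name in comp.component_weights:
        if name not in table.columns:
            raise ClockError(
                f"composite {comp.name!r}: unknown component biomarker {name!r}"
            )
    samples = table.index
    ann = sheet.data.loc[samples]
    out = pd.Series(float(comp.intercept), index=samples, name=comp.name)
    for name, w in comp.component_weights.items():
        out = out + w * table[name]
    out = out + comp.age_weight * ann["age"].astype(float) + comp.sex_weight * ann["sex"].astype(float)
    return out


@dataclass
class DeconvolutionResult:
    fractions: pd.DataFrame       # samples x cell types, rows on the simplex
    raw_sums: pd.Series           # pre-normalization NNLS coefficient sums
    n_shared_probes: int = 0


def deconvolve_cell_fractions(beta: BetaMatrix, ref: CellReferenceMatrix) -> DeconvolutionResult:
    """Houseman-style constrained projection of each sample onto cell references.

    Per sample s, solves ``min ||R f - beta_s||^2 s.t. f >= 0`` over the
    shared probes (NNLS), then renormalizes f to sum to 1.  The
    pre-normalization sum is kept as a fit diagnostic.  Deterministic.
    """
    shared = [p for p in ref.data.index if p in beta.data.index]
    k = ref.data.shape[1]
    if len(shared) < k:
        raise ClockError(
            f"deconvolution needs at least {k} shared probes; got {len(shared)}"
        )
    R = ref.data.loc[shared].to_numpy(dtype=float)
    B = beta.data.loc[shared]
    fracs = np.empty((len(beta.sample_ids), k))
    sums = np.empty(len(beta.sample_ids))
    for i, sid in enumerate(beta.sample_ids):
        y = B[sid].to_numpy(dtype=float)
        ok = np.isfinite(y)
        if ok.sum() < k:
            raise ClockError(f"sample {sid!r}: too few non-missing shared probes")
        f, _ = nnls(R[ok], y[ok])
        total = f.sum()
        if total <= 0:
            raise ClockError(f"sample {sid!r}: degenerate deconvolution (all-zero fit)")
        fracs[i] = f / total
        sums[i] = total
    fractions = pd.DataFrame(fracs, index=beta.sample_ids, columns=ref.cell_types)
    return DeconvolutionResult(fractions, pd.Series(sums, index=beta.sample_ids), len(shared))


def assemble_biomarker_table(
    beta: BetaMatrix,
    sheet: SampleSheet,
    clocks: list[ClockDefinition] = (),
    composites: list[CompositeClockDefinition] = (),
    cell_reference: CellReferenceMatrix | None = None,
    missing_policy: str = "impute-cohort-mean",
) -> pd.DataFrame:
    """Build the sample x biomarker table from clocks, composites and cell fractions.

    Composites are evaluated after all linear clocks and cell fractions so
    they may reference either; cell-fraction biomarkers are named
    ``cellfrac_<type>``.
    """
    columns: dict[str, pd.Series] = {}
    for clock in clocks:
        res = apply_linear_clock(beta, clock, missing_policy)
        columns[clock.name] = res.values
    if cell_reference is not None:
        dec = deconvolve_cell_fractions(beta, cell_reference)
        for ct in dec.fractions.columns:
            columns[f"cellfrac_{ct}"] = dec.fractions[ct]
    table = pd.DataFrame(columns, index=pd.Index(beta.sample_ids, name="sample_id"))
    for comp in composites:
        table[comp.name] = apply_composite_clock(table, sheet, comp)
    if table.empty or table.shape[1] == 0:
        raise ClockError("no biomarkers produced; supply at least one clock")
    return table
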