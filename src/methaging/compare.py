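"""Group comparison on age-adjusted residuals.

Implements the two-stage residual-outcome approach: per biomarker, an
ordinary least squares model ``biomarker ~ age + sex`` is fitted on the
designated reference group only; residuals from that fit are computed for
every sample (including the reference group), and phenotype groups are then
compared on those residuals with equal-variance two-sided t-tests.  Tukey
fences (Q1 - 1.5 IQR, Q3 + 1.5 IQR) remove per-biomarker outliers before
any model fitting.

Quantiles use linear interpolation between closest order statistics (the
numpy default), which is documented here because the fence positions depend
on the convention.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import StatsError
from .io import SampleSheet

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# outlier removal


def tukey_fences(values, factor: float = 1.5) -> tuple[float, float]:
    """Tukey's outer bounds: (Q1 - factor*IQR, Q3 + factor*IQR).

    Requires >= 4 non-missing values (quartiles of fewer are unstable).
    Values strictly outside the fences are the ones to flag; points exactly
    on a fence are kept.
    """
    v = np.asarray(pd.Series(values).dropna(), dtype=float)
    if v.size < 4:
        raise StatsError(f"tukey_fences needs >= 4 non-missing values, got {v.size}")
    q1, q3 = np.quantile(v, [0.25, 0.75])  # linear interpolation
    iqr = q3 - q1
    return float(q1 - factor * iqr), float(q3 + factor * iqr)


def remove_outliers(
    table: pd.DataFrame,
    factor: float = 1.5,
    per_group: bool = False,
    sheet: SampleSheet | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mask Tukey-fence outliers per biomarker (single pass, all samples pooled).

    Flagged entries become NaN for that biomarker only; the sample stays in
    the table for its other biomarkers.  With ``per_group=True`` fences are
    computed within each phenotype group instead of pooled.  Exactly one
    pass is performed: the rule is not idempotent (re-fencing the trimmed
    data may flag additional points), so the fences of the *original* data
    define outliers.

    Returns the masked table and a log with one row per removed cell.
    """
    if table.empty:
        raise StatsError("remove_outliers: empty biomarker table")
    if per_group and sheet is None:
        raise ValueError("per_group fencing requires a sample sheet")
    out = table.copy()
    records = []
    for biomarker in table.columns:
        col = table[biomarker]
        if per_group:
            groups = sheet.data.loc[col.index, "group"]
            parts = [(g, col[groups == g]) for g in groups.unique()]
        else:
            parts = [(None, col)]
        for g, part in parts:
            lo, hi = tukey_fences(part, factor=factor)
            mask = (part < lo) | (part > hi)
            for sid in part.index[mask.fillna(False)]:
                records.append({
                    "sample_id": sid, "biomarker": biomarker, "group": g,
                    "value": float(part[sid]), "lower_fence": lo, "upper_fence": hi,
                })
                out.loc[sid, biomarker] = np.nan
    log = pd.DataFrame(
        records,
        columns=["sample_id", "biomarker", "group", "value", "lower_fence", "upper_fence"],
    )
    if len(log):
        logger.info("outlier removal: masked %d cells across %d biomarkers",
                    len(log), log["biomarker"].nunique())
    return out, log


# ---------------------------------------------------------------------------
# reference model and residuals


@dataclass(frozen=True)
class ReferenceModel:
    """OLS fit of a biomarker on (intercept, age, sex) within the reference group."""

    biomarker: str
    reference_group: str
    intercept: float
    age_slope: float         # biomarker units per year
    sex_effect: float        # biomarker units; 0.0 when sex was dropped
    sex_dropped: bool
    n_fit: int
    residual_sd: float

    def predict(self, age, sex) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        sex = np.asarray(sex, dtype=float)
        return self.intercept + self.age_slope * age + self.sex_effect * sex


def fit_reference_model(
    table: pd.DataFrame,
    sheet: SampleSheet,
    biomarker: str,
    reference_group: str,
) -> ReferenceModel:
    """Fit ``biomarker ~ age + sex`` by OLS using reference-group samples only.

    Requires >= 3 non-missing reference samples with non-constant age.  A
    single-sex reference group makes the sex column collinear with the
    intercept; sex is then dropped with a warning instead of failing.
    """
    if biomarker not in table.columns:
        raise StatsError(f"unknown biomarker {biomarker!r}")
    ann = sheet.data
    ref_ids = [s for s in table.index
               if s in ann.index and ann.loc[s, "group"] == reference_group]
    y = table.loc[ref_ids, biomarker].dropna()
    if len(y) < 3:
        raise StatsError(
            f"reference group {reference_group!r} has {len(y)} usable samples for "
            f"{biomarker!r}; need >= 3"
        )
    age = ann.loc[y.index, "age"].to_numpy(dtype=float)
    sex = ann.loc[y.index, "sex"].to_numpy(dtype=float)
    if np.ptp(age) == 0:
        if np.ptp(sex) == 0:
            raise StatsError(
                f"degenerate design for {biomarker!r}: column 'age' is constant "
                "(and so is 'sex')"
            )
        raise StatsError(f"degenerate design for {biomarker!r}: column 'age' is constant")
    sex_dropped = np.ptp(sex) == 0
    if sex_dropped:
        warnings.warn(
            f"reference group {reference_group!r} is single-sex; dropping the sex "
            f"covariate for {biomarker!r}",
            stacklevel=2,
        )
        X = np.column_stack([np.ones_like(age), age])
    else:
        X = np.column_stack([np.ones_like(age), age, sex])
    coef, _, rank, _ = np.linalg.lstsq(X, y.to_numpy(dtype=float), rcond=None)
    if rank < X.shape[1]:
        raise StatsError(f"rank-deficient design for {biomarker!r}")
    resid = y.to_numpy(dtype=float) - X @ coef
    dof = max(len(y) - X.shape[1], 1)
    return ReferenceModel(
        biomarker=biomarker,
        reference_group=reference_group,
        intercept=float(coef[0]),
        age_slope=float(coef[1]),
        sex_effect=0.0 if sex_dropped else float(coef[2]),
        sex_dropped=sex_dropped,
        n_fit=len(y),
        residual_sd=float(np.sqrt(resid @ resid / dof)),
    )


def compute_residuals(
    model: ReferenceModel,
    table: pd.DataFrame,
    sheet: SampleSheet,
) -> pd.Series:
    """Residuals (observed minus reference-model prediction) for every sample.

    Applied to all groups, reference included; samples lacking age or sex
    annotations get a missing residual.
    """
    col = table[model.biomarker]
    ann = sheet.data.reindex(col.index)
    age = pd.to_numeric(ann["age"], errors="coerce")
    sex = pd.to_numeric(ann["sex"], errors="coerce")
    missing_ann = age.isna() | sex.isna()
    if missing_ann.any():
        logger.warning("residuals for %s: %d samples lack age/sex annotation",
                       model.biomarker, int(missing_ann.sum()))
    pred = model.intercept + model.age_slope * age + model.sex_effect * sex
    res = col - pred
    res[missing_ann] = np.nan
    res.name = model.biomarker
    return res


def build_residual_table(
    table: pd.DataFrame,
    sheet: SampleSheet,
    reference_group: str,
) -> tuple[pd.DataFrame, dict[str, ReferenceModel]]:
    """Fit one reference model per biomarker and tabulate residuals for all samples."""
    models: dict[str, ReferenceModel] = {}
    cols = {}
    for biomarker in table.columns:
        model = fit_reference_model(table, sheet, biomarker, reference_group)
        models[biomarker] = model
        cols[biomarker] = compute_residuals(model, table, sheet)
    return pd.DataFrame(cols, index=table.index), models


# ---------------------------------------------------------------------------
# inference


@dataclass(frozen=True)
class ContrastResult:
    """Two-group comparison of residuals for one biomarker."""

    biomarker: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    mean_difference: float   # mean_a - mean_b
    t: float
    df: float
    p: float
    alpha: float
    significant: bool
    welch: bool


def contrast_groups(
    residuals: pd.Series,
    sheet: SampleSheet,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    welch: bool = False,
    biomarker: str | None = None,
) -> ContrastResult:
    """Two-sided Student's t-test on residuals between two phenotype groups.

    Pooled-variance by default (df = n_a + n_b - 2); Welch's unequal-variance
    variant behind a flag.  Degenerate zero-variance data: identical means
    give t = 0, p = 1; distinct means are an error (the test is undefined).
    """
    groups = sheet.data.reindex(residuals.index)["group"]
    a = residuals[groups == group_a].dropna().to_numpy(dtype=float)
    b = residuals[groups == group_b].dropna().to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise StatsError(
            f"need >= 2 non-missing residuals per group; got {len(a)} ({group_a!r}) "
            f"and {len(b)} ({group_b!r})"
        )
    name = biomarker or (residuals.name or "")
    var_a, var_b = a.var(ddof=1), b.var(ddof=1)
    if var_a == 0 and var_b == 0:
        if a.mean() == b.mean():
            t_stat, p, df = 0.0, 1.0, float(len(a) + len(b) - 2)
        else:
            raise StatsError(
                f"{name}: zero variance in both groups with unequal means; "
                "t-test undefined"
            )
    elif welch:
        t_stat, p = stats.ttest_ind(a, b, equal_var=False)
        se2_a, se2_b = var_a / len(a), var_b / len(b)
        df = (se2_a + se2_b) ** 2 / (
            se2_a ** 2 / (len(a) - 1) + se2_b ** 2 / (len(b) - 1)
        )
    else:
        t_stat, p = stats.ttest_ind(a, b, equal_var=True)
        df = float(len(a) + len(b) - 2)
    return ContrastResult(
        biomarker=name, group_a=group_a, group_b=group_b,
        n_a=len(a), n_b=len(b),
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        mean_difference=float(a.mean() - b.mean()),
        t=float(t_stat), df=float(df), p=float(p),
        alpha=alpha, significant=bool(p < alpha), welch=welch,
    )


def run_contrasts(
    residuals: pd.DataFrame,
    sheet: SampleSheet,
    contrasts: list[tuple[str, str]],
    alpha: float = 0.05,
    welch: bool = False,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Tidy table: one row per (biomarker, group pair).

    With ``bh_correction`` a Benjamini-Hochberg q-value is reported alongside
    the raw p (the significance flag stays on the raw p at alpha).
    """
    rows = []
    for biomarker in residuals.columns:
        for ga, gb in contrasts:
            r = contrast_groups(residuals[biomarker], sheet, ga, gb,
                                alpha=alpha, welch=welch, biomarker=biomarker)
            rows.append(vars(r).copy())
    out = pd.DataFrame(rows)
    if bh_correction and len(out):
        from statsmodels.stats.multitest import multipletests

        out["q_bh"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


def anova_oneway(sheet: SampleSheet, variable: str = "age") -> tuple[float, float]:
    """Classic one-way fixed-effects ANOVA of a sample-sheet variable across groups."""
    df = sheet.data
    if variable not in df.columns:
        raise StatsError(f"unknown sample-sheet variable {variable!r}")
    samples = [pd.to_numeric(sub[variable], errors="coerce").dropna().to_numpy()
               for _, sub in df.groupby("group")]
    if len(samples) < 2:
        raise StatsError("ANOVA needs >= 2 groups")
    for arr in samples:
        if len(arr) < 2:
            raise StatsError("ANOVA needs >= 2 samples in every group")
    f_stat, p = stats.f_oneway(*samples)
    if np.isnan(f_stat):  # all groups constant and equal
        f_stat, p = 0.0, 1.0
    return float(f_stat), float(p)


def pearson_correlation(x, y) -> tuple[float, float]:
    """Sample Pearson r with a two-sided p from the t-transformation.

    Pairs with a missing value on either side are dropped; needs >= 3
    complete pairs and non-zero variance on both sides.
    """
    xs = pd.Series(np.asarray(x, dtype=float))
    ys = pd.Series(np.asarray(y, dtype=float))
    ok = xs.notna() & ys.notna()
    xs, ys = xs[ok], ys[ok]
    if len(xs) < 3:
        raise StatsError(f"pearson_correlation needs >= 3 complete pairs, got {len(xs)}")
    if xs.std(ddof=1) == 0 or ys.std(ddof=1) == 0:
        raise StatsError("pearson_correlation: zero variance input")
    r, p = stats.pearsonr(xs, ys)
    return float(r), float(p)


def correlate_biomarkers(residuals: pd.DataFrame, min_pairs: int = 3) -> pd.DataFrame:
    """All pairwise Pearson correlations between biomarker residuals (tidy)."""
    cols = list(residuals.columns)
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            ok = residuals[a].notna() & residuals[b].notna()
            if ok.sum() < min_pairs:
                continue
            try:
                r, p = pearson_correlation(residuals.loc[ok, a], residuals.loc[ok, b])
            except StatsError:
                continue
            rows.append({"biomarker_a": a, "biomarker_b": b,
                         "n": int(ok.sum()), "r": r, "p": p})
    return pd.DataFrame(rows, columns=["biomarker_a", "biomarker_b", "n", "r", "p"])
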