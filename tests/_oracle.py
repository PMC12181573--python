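"""Flat, self-contained re-derivation of the analysis used only as a cross-check.

Everything here is written from first principles with plain numpy arrays:
quantiles by manual order-statistic interpolation, OLS by the normal
equations, the pooled t statistic, ANOVA sums of squares, and the Pearson r
by its covariance formula.  Only the scipy distribution CDFs are used for
p-values.  Nothing is imported from the package under test.
"""

import numpy as np
from scipy.stats import f as f_dist
from scipy.stats import t as t_dist


def quantile_linear(values, q):
    v = np.sort(np.asarray(values, dtype=float))
    h = (len(v) - 1) * q
    lo = int(np.floor(h))
    hi = min(lo + 1, len(v) - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def tukey_fences(values, factor=1.5):
    q1 = quantile_linear(values, 0.25)
    q3 = quantile_linear(values, 0.75)
    iqr = q3 - q1
    return q1 - factor * iqr, q3 + factor * iqr


def mask_outliers(values):
    """One pass: NaN out entries strictly outside the fences of the full vector."""
    v = np.asarray(values, dtype=float).copy()
    ok = ~np.isnan(v)
    lo, hi = tukey_fences(v[ok])
    with np.errstate(invalid="ignore"):
        v[ok & ((v < lo) | (v > hi))] = np.nan
    return v


def ols_fit(y, X):
    """Normal-equations solution (X'X)^-1 X'y."""
    XtX = X.T @ X
    return np.linalg.solve(XtX, X.T @ y)


def pooled_t_test(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    sa2 = ((a - a.mean()) ** 2).sum() / (na - 1)
    sb2 = ((b - b.mean()) ** 2).sum() / (nb - 1)
    sp2 = ((na - 1) * sa2 + (nb - 1) * sb2) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    df = na + nb - 2
    p = 2.0 * t_dist.sf(abs(t), df)
    return t, df, p


def anova_oneway(groups):
    """Classic fixed-effects ANOVA from the sum-of-squares decomposition."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    all_v = np.concatenate(groups)
    grand = all_v.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_v) - len(groups)
    F = (ss_between / df_b) / (ss_within / df_w)
    p = f_dist.sf(F, df_b, df_w)
    return F, p


def pearson(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    xc, yc = x - x.mean(), y - y.mean()
    r = (xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * t_dist.sf(abs(t), n - 2)
    return r, p


def analyze_cohort(beta, probe_ids, sample_ids, clocks, ages, sexes, groups,
                   ref_group, pairs):
    """Full flat pipeline: clocks -> outlier mask -> reference OLS -> residuals
    -> pooled t contrasts -> age ANOVA -> pairwise residual correlations.

    ``beta`` is probes x samples; ``clocks`` maps name -> (weights dict,
    intercept).  Returns a dict of plain arrays/tuples keyed by biomarker.
    """
    ages = np.asarray(ages, dtype=float)
    sexes = np.asarray(sexes, dtype=float)
    groups = np.asarray(groups)
    probe_index = {p: i for i, p in enumerate(probe_ids)}

    residuals = {}
    contrasts = {}
    for name, (weights, intercept) in clocks.items():
        score = np.full(len(sample_ids), float(intercept))
        for cpg, w in weights.items():
            if cpg in probe_index:
                score = score + w * beta[probe_index[cpg]]
        masked = mask_outliers(score)
        ok_ref = (groups == ref_group) & ~np.isnan(masked)
        X = np.column_stack([np.ones(ok_ref.sum()), ages[ok_ref], sexes[ok_ref]])
        coef = ols_fit(masked[ok_ref], X)
        pred = coef[0] + coef[1] * ages + coef[2] * sexes
        residuals[name] = masked - pred
        for ga, gb in pairs:
            a = residuals[name][(groups == ga) & ~np.isnan(residuals[name])]
            b = residuals[name][(groups == gb) & ~np.isnan(residuals[name])]
            contrasts[(name, ga, gb)] = pooled_t_test(a, b)

    anova = anova_oneway([ages[groups == g] for g in dict.fromkeys(groups)])

    correlations = {}
    names = list(clocks)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            ok = ~np.isnan(residuals[a]) & ~np.isnan(residuals[b])
            correlations[(a, b)] = pearson(residuals[a][ok], residuals[b][ok])

    return {"residuals": residuals, "contrasts": contrasts,
            "anova": anova, "correlations": correlations}
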