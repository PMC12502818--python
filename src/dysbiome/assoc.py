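"""Covariate-adjusted association machinery.

Four tools shared by many result sections:

* two-stage covariate-adjusted linear models with stepwise AIC selection and
  pairwise group contrasts (means and slopes),
* partial correlations (Pearson / Spearman / Kendall) via the precision-
  matrix formula,
* Brown's method for combining the dependent p-values of the three
  correlation tests (Kost-McDermott covariance polynomial),
* rank tests (Kruskal-Wallis, Wilcoxon rank-sum, paired t) for group and
  cluster characterisation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .coredata import CohortMetadata, DysbiomeError, NormalizedTable


# --------------------------------------------------------------------------
# adjusted linear models with stepwise AIC
# --------------------------------------------------------------------------

@dataclass
class AdjustedModelResult:
    terms: list[str]
    params: pd.Series
    bse: pd.Series
    contrasts: pd.DataFrame  # pairwise mean / slope differences + p, p_fdr
    aic_trace: list[tuple[str, float]]
    n_dropped: int
    model: object = field(repr=False, default=None)


def _residualize(y: pd.Series, meta: pd.DataFrame) -> pd.Series:
    """Stage 1: residuals of y ~ sex + scaled BMI + scaled age."""
    X = pd.DataFrame(index=meta.index)
    X["const"] = 1.0
    sex = pd.get_dummies(meta["sex"], drop_first=True)
    for c in sex.columns:
        X[f"sex_{c}"] = sex[c].astype(float)
    for c in ("bmi", "age"):
        v = meta[c].astype(float)
        X[c] = (v - v.mean()) / (v.std() if v.std() > 0 else 1.0)
    fit = sm.OLS(y.to_numpy(dtype=float), X.to_numpy()).fit()
    return pd.Series(fit.resid, index=y.index)

def _stage2_design(meta: pd.DataFrame, phenotype: str | None,
                   terms: set[str]) -> tuple[np.ndarray, list[str]]:
    dx = pd.Categorical(meta["diagnosis"])
    levels = list(dx.categories)
    cols: list[np.ndarray] = [np.ones(len(meta))]
    names = ["Intercept"]
    if "diagnosis" in terms:
        for lv in levels[1:]:
            cols.append((dx == lv).astype(float))
            names.append(f"diagnosis[{lv}]")
    if phenotype is not None and "phenotype" in terms:
        ph = meta[phenotype].to_numpy(dtype=float)
        cols.append(ph)
        names.append(phenotype)
        if "interaction" in terms:
            for lv in levels[1:]:
                cols.append(ph * (dx == lv).astype(float))
                names.append(f"diagnosis[{lv}]:{phenotype}")
    return np.column_stack(cols), names


def fit_adjusted_lm(
    response: pd.Series,
    metadata: CohortMetadata | pd.DataFrame,
    phenotype: str | None = None,
    stepwise: bool = True,
) -> AdjustedModelResult:
    """Two-stage adjusted model: residualise the response on sex + scaled
    BMI + scaled age, then model the residuals on diagnosis (x phenotype).

    Backward-forward stepwise selection on AIC respects model hierarchy
    (interaction only with both mains).  Pairwise diagnosis contrasts of
    means (and of slopes when the interaction is retained) are Wald tests
    with BH correction within each family.
    """
    meta = metadata.data if isinstance(metadata, CohortMetadata) else metadata
    meta = meta.reset_index(drop=True)
    y = pd.Series(np.asarray(response, dtype=float))
    needed = ["sex", "bmi", "age", "diagnosis"] + ([phenotype] if phenotype else [])
    mask = y.notna() & meta[needed].notna().all(axis=1)
    n_dropped = int((~mask).sum())
    meta = meta[mask].reset_index(drop=True)
    y = y[mask].reset_index(drop=True)

    resid = _residualize(y, meta)
    candidates = {"diagnosis"} | ({"phenotype", "interaction"} if phenotype else set())
    current = set(candidates)

    def model_aic(terms: set[str]) -> float:
        X, _ = _stage2_design(meta, phenotype, terms)
        return sm.OLS(resid.to_numpy(), X).fit().aic

    trace = [("+".join(sorted(current)) or "null", model_aic(current))]
    if stepwise:
        improved = True
        while improved:
            improved = False
            best_aic = trace[-1][1]
            best_move = None
            for t in sorted(current):
                trial = current - {t}
                if "interaction" in trial and not {"diagnosis", "phenotype"} <= trial:
                    continue
                a = model_aic(trial)
                if a < best_aic - 1e-9:
                    best_aic, best_move = a, ("-", t, trial)
            for t in sorted(candidates - current):
                trial = current | {t}
                if "interaction" in trial and not {"diagnosis", "phenotype"} <= trial:
                    continue
                a = model_aic(trial)
                if a < best_aic - 1e-9:
                    best_aic, best_move = a, ("+", t, trial)
            if best_move:
                current = best_move[2]
                trace.append(("+".join(sorted(current)) or "null", best_aic))
                improved = True

    X, names = _stage2_design(meta, phenotype, current)
    fit = sm.OLS(resid.to_numpy(), X).fit()
    params = pd.Series(fit.params, index=names)
    bse = pd.Series(fit.bse, index=names)

    dx = pd.Categorical(meta["diagnosis"])
    levels = list(dx.categories)
    counts = meta["diagnosis"].value_counts()
    rows = []
    for kind, prefix in (("mean", "diagnosis["), ("slope", None)):
        if kind == "mean" and "diagnosis" not in current:
            continue
        if kind == "slope" and "interaction" not in current:
            continue
        for a, b in itertools.combinations(levels, 2):
            if counts.get(a, 0) < 3 or counts.get(b, 0) < 3:
                warnings.warn(f"contrast {a}-{b} suppressed (<3 observations)")
                continue
            L = np.zeros(len(names))
            def coef_name(lv):
                return (f"diagnosis[{lv}]" if kind == "mean"
                        else f"diagnosis[{lv}]:{phenotype}")
            for lv, sign in ((a, 1.0), (b, -1.0)):
                nm = coef_name(lv)
                if nm in names:
                    L[names.index(nm)] += sign
            if not L.any():
                continue
            tt = fit.t_test(L)
            rows.append({
                "kind": kind, "comparison": f"{a}-{b}",
                "estimate": float(np.squeeze(tt.effect)),
                "p": float(np.squeeze(tt.pvalue)),
            })
    contrasts = pd.DataFrame(rows)
    if len(contrasts):
        contrasts["p_fdr"] = np.nan
        for kind in contrasts["kind"].unique():
            m = contrasts["kind"] == kind
            contrasts.loc[m, "p_fdr"] = multipletests(
                contrasts.loc[m, "p"], method="fdr_bh")[1]
    return AdjustedModelResult(sorted(current), params, bse, contrasts,
                               trace, n_dropped, model=fit)


# --------------------------------------------------------------------------
# partial correlation
# --------------------------------------------------------------------------

def partial_correlation(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    method: str = "pearson",
) -> tuple[float, float]:
    """Partial correlation of x and y given covariates.

    Uses the precision-matrix identity ``rho = -P_xy / sqrt(P_xx P_yy)`` on
    the chosen correlation matrix (data rank-transformed for Spearman;
    Kendall's tau matrix used directly, an approximation).  P-values use the
    t distribution at ``df = n - n_cov - 2`` (Pearson/Spearman) or the
    normal approximation of tau (Kendall).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if covariates is None:
        Z = np.empty((n, 0))
    else:
        Z = np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
    ncov = Z.shape[1]
    if n <= ncov + 2:
        raise DysbiomeError("too few observations for partial correlation")
    data = np.column_stack([x, y, Z])
    # degenerate but well-defined limit: x and y perfectly correlated
    r_xy = np.corrcoef(x, y)[0, 1]
    if abs(r_xy) >= 1.0 - 1e-12:
        return float(np.sign(r_xy)), 0.0
    if method in ("pearson", "spearman"):
        if method == "spearman":
            data = np.apply_along_axis(stats.rankdata, 0, data)
        R = np.corrcoef(data, rowvar=False)
    elif method == "kendall":
        k = data.shape[1]
        R = np.eye(k)
        for i in range(k):
            for j in range(i + 1, k):
                R[i, j] = R[j, i] = stats.kendalltau(data[:, i], data[:, j])[0]
    else:
        raise DysbiomeError(f"unknown correlation method {method!r}")
    try:
        P = np.linalg.inv(R)
    except np.linalg.LinAlgError as exc:
        raise DysbiomeError("singular correlation matrix") from exc
    rho = float(-P[0, 1] / np.sqrt(P[0, 0] * P[1, 1]))
    rho = float(np.clip(rho, -1.0, 1.0))
    df = n - ncov - 2
    if method == "kendall":
        denom = 2.0 * (2.0 * (n - ncov) + 5.0)
        z = rho * np.sqrt(9.0 * (n - ncov) * (n - 1 - ncov) / denom)
        p = 2.0 * stats.norm.sf(abs(z))
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt(df / (1.0 - rho ** 2))
            p = 2.0 * stats.t.sf(abs(t), df)
    return rho, float(p)


# --------------------------------------------------------------------------
# Brown's method
# --------------------------------------------------------------------------

def browns_combine(p_values: np.ndarray, correlations: np.ndarray | None = None) -> float:
    """Combine dependent p-values by Brown's extension of Fisher's method.

    ``X = -2 sum(ln p)`` is referred to a scaled chi-square with moments
    ``E[X] = 2k`` and ``Var[X] = 4k + 2 sum_{i<j} cov_ij`` where the
    covariance between two Fisher terms is approximated from their
    correlation ``rho`` by the Kost-McDermott polynomial
    ``3.263 rho + 0.710 rho^2 + 0.027 rho^3``.  With zero correlations this
    is exactly Fisher's method.
    """
    p = np.asarray(p_values, dtype=float)
    k = len(p)
    if (p <= 0).any():
        warnings.warn("p-values of 0 clamped to machine minimum")
        p = np.maximum(p, np.finfo(float).tiny)
    if (p > 1).any():
        raise DysbiomeError("p-values must be in (0, 1]")
    X = float(-2.0 * np.log(p).sum())
    mean = 2.0 * k
    var = 4.0 * k
    if correlations is not None:
        R = np.asarray(correlations, dtype=float)
        if R.shape != (k, k):
            raise DysbiomeError("correlation matrix shape mismatch")
        eigs = np.linalg.eigvalsh((R + R.T) / 2)
        if eigs.min() < -1e-8:
            raise DysbiomeError("correlation matrix not positive semidefinite")
        for i in range(k):
            for j in range(i + 1, k):
                r = R[i, j]
                var += 2.0 * (3.263 * r + 0.710 * r ** 2 + 0.027 * r ** 3)
    var = max(var, 1e-12)
    c = var / (2.0 * mean)  # scale
    df = 2.0 * mean ** 2 / var
    return float(stats.chi2.sf(X / c, df))


# --------------------------------------------------------------------------
# group tests
# --------------------------------------------------------------------------

def group_tests(
    values: pd.Series | np.ndarray,
    groups: pd.Series | np.ndarray,
    paired: np.ndarray | None = None,
) -> pd.DataFrame:
    """Rank tests for group differences.

    Unpaired: Kruskal-Wallis across all groups plus pairwise two-sided
    Wilcoxon rank-sum tests (BH-corrected).  Paired two-group designs use
    the paired t-test on the differences.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    levels = pd.unique(g)
    if any((g == lv).sum() == 0 for lv in levels) or len(levels) < 2:
        raise DysbiomeError("need at least 2 non-empty groups")
    rows = []
    if paired is not None:
        if len(levels) != 2:
            raise DysbiomeError("paired design requires exactly 2 groups")
        pairing = np.asarray(paired)
        a_ids = {p: val for p, val, lv in zip(pairing, v, g) if lv == levels[0]}
        b_ids = {p: val for p, val, lv in zip(pairing, v, g) if lv == levels[1]}
        common = sorted(set(a_ids) & set(b_ids))
        if len(common) < 2:
            raise DysbiomeError("pairing incomplete")
        t, p = stats.ttest_rel([a_ids[c] for c in common],
                               [b_ids[c] for c in common])
        rows.append({"test": "paired_t",
                     "comparison": f"{levels[0]}-{levels[1]}",
                     "statistic": float(t), "p": float(p)})
        df = pd.DataFrame(rows)
        df["p_fdr"] = df["p"]
        return df
    if len(levels) > 2:
        h, p = stats.kruskal(*[v[g == lv] for lv in levels])
        rows.append({"test": "kruskal", "comparison": "omnibus",
                     "statistic": float(h), "p": float(p)})
    for a, b in itertools.combinations(levels, 2):
        u, p = stats.mannwhitneyu(v[g == a], v[g == b], alternative="two-sided")
        rows.append({"test": "wilcoxon_ranksum", "comparison": f"{a}-{b}",
                     "statistic": float(u), "p": float(p)})
    df = pd.DataFrame(rows)
    pw = df["test"] == "wilcoxon_ranksum"
    df["p_fdr"] = df["p"]
    df.loc[pw, "p_fdr"] = multipletests(df.loc[pw, "p"], method="fdr_bh")[1]
    return df


# --------------------------------------------------------------------------
# taxon x phenotype combined-correlation scan
# --------------------------------------------------------------------------

def correlation_scan(
    clr_table: NormalizedTable,
    metadata: CohortMetadata,
    phenotypes: list[str],
    covariates: tuple[str, ...] = ("age", "sex", "bmi"),
    empirical_dependence: bool = True,
    fixed_correlation: np.ndarray | None = None,
) -> pd.DataFrame:
    """Partial-correlation scan of CLR taxon abundances against phenotypes.

    For every (taxon, phenotype) pair the Pearson, Spearman and Kendall
    partial correlations (adjusted for the covariates) are combined by
    Brown's method; the inter-test correlation is estimated empirically from
    the ``-2 ln p`` vectors across taxa of the same scan unless a fixed
    matrix is supplied.  Brown p-values are BH-corrected per phenotype.
    """
    meta = metadata.data.set_index("sample_id").loc[clr_table.sample_ids]
    cov_cols = []
    for c in covariates:
        col = meta[c]
        if col.dtype.kind in "OUb":
            cov_cols.append(pd.get_dummies(col, drop_first=True)
                            .to_numpy(dtype=float))
        else:
            cov_cols.append(col.to_numpy(dtype=float)[:, None])
    Z_full = np.column_stack(cov_cols)
    methods = ("pearson", "spearman", "kendall")
    out = []
    for pheno in phenotypes:
        yv = meta[pheno].to_numpy(dtype=float)
        ok = ~np.isnan(yv)
        pervals = {m: [] for m in methods}
        rows = []
        for taxon in clr_table.taxon_ids:
            xv = clr_table.data[taxon].to_numpy()[ok]
            rec = {"taxon_id": taxon, "phenotype": pheno}
            for m in methods:
                rho, p = partial_correlation(xv, yv[ok], Z_full[ok], method=m)
                rec[f"rho_{m}"] = rho
                rec[f"p_{m}"] = p
                pervals[m].append(p)
            rows.append(rec)
        if fixed_correlation is not None:
            R = fixed_correlation
        elif empirical_dependence and len(rows) >= 5:
            mat = np.column_stack([-2.0 * np.log(np.maximum(
                np.asarray(pervals[m]), np.finfo(float).tiny)) for m in methods])
            R = np.corrcoef(mat, rowvar=False)
        else:
            R = np.eye(3)
        for rec in rows:
            ps = np.array([rec[f"p_{m}"] for m in methods])
            rec["brown_p"] = browns_combine(ps, R)
        df = pd.DataFrame(rows)
        df["brown_p_fdr"] = multipletests(df["brown_p"], method="fdr_bh")[1]
        out.append(df)
    return pd.concat(out, ignore_index=True)
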