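"""Per-taxon negative-binomial Wald tests with covariates and FDR control.

Each taxon is modelled by a log-link NB2 GLM with ``log(size_factor)``
offsets and covariates (sex, scaled BMI, scaled age, optionally time point)
plus the group factor.  The per-taxon dispersion is estimated by maximising
the Cox-Reid adjusted profile likelihood and optionally shrunk on the log
scale toward a fitted mean-dispersion trend ``alpha(mu) = a / mu + b``.
Wald z-scores test the group coefficient; Benjamini-Hochberg corrects within
each contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .coredata import CohortMetadata, CountTable, DysbiomeError, prevalence_filter, robust_size_factors

DEFAULT_CONTRASTS = ("CD_vs_Control", "UC_vs_Control", "CD_vs_UC", "IBD_vs_Control")

_ALPHA_MIN, _ALPHA_MAX = 1e-8, 20.0


@dataclass
class NbFit:
    coef: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    alpha: float  # NB2 dispersion (variance = mu + alpha mu^2)
    converged: bool
    loglike: float
    mu_mean: float


def _glm_fit(y, X, offset, alpha):
    fam = sm.families.NegativeBinomial(alpha=max(alpha, _ALPHA_MIN))
    model = sm.GLM(y, X, family=fam, offset=offset)
    return model.fit(maxiter=500, tol=1e-8)


def _adjusted_profile_loglik(alpha, y, X, offset):
    """Cox-Reid adjusted profile log-likelihood of the NB dispersion."""
    try:
        res = _glm_fit(y, X, offset, alpha)
    except Exception:
        return -np.inf
    mu = res.fittedvalues
    w = mu / (1.0 + alpha * mu)  # GLM working weights at the log link
    xtwx = X.T @ (X * w[:, None])
    sign, logdet = np.linalg.slogdet(xtwx)
    if sign <= 0:
        return -np.inf
    r = 1.0 / alpha
    ll = float(np.sum(gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)
                      + r * np.log(r) + y * np.log(mu + 1e-300)
                      - (y + r) * np.log(r + mu)))
    return ll - 0.5 * logdet


def estimate_dispersion(y, X, offset) -> float:
    """Maximum adjusted-profile-likelihood NB dispersion for one taxon."""
    res = minimize_scalar(
        lambda la: -_adjusted_profile_loglik(np.exp(la), y, X, offset),
        bounds=(np.log(_ALPHA_MIN), np.log(_ALPHA_MAX)), method="bounded",
        options={"xatol": 1e-3},
    )
    return float(np.exp(res.x))


def fit_nb_glm(
    y: np.ndarray,
    X: np.ndarray,
    sf: np.ndarray,
    alpha: float | None = None,
) -> NbFit:
    """Fit one taxon's NB GLM; the dispersion is profiled out unless given."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DysbiomeError("design matrix is rank deficient (aliased terms)")
    offset = np.log(np.asarray(sf, dtype=float))
    if alpha is None:
        alpha = estimate_dispersion(y, X, offset)
    res = _glm_fit(y, X, offset, alpha)
    cov = np.asarray(res.cov_params())
    return NbFit(
        coef=np.asarray(res.params), se=np.asarray(res.bse), cov=cov,
        alpha=alpha, converged=bool(res.converged), loglike=float(res.llf),
        mu_mean=float(res.fittedvalues.mean()),
    )


def _shrink_dispersions(alphas: np.ndarray, mus: np.ndarray,
                        weight: float | None = None) -> np.ndarray:
    """Log-scale shrinkage toward the parametric trend ``a / mu + b``.

    The trend is fitted by least squares on the per-taxon estimates; the
    shrinkage weight defaults to the fraction of log-dispersion variance
    attributable to estimation noise (clipped to [0.2, 0.9])."""
    ok = (alphas > 2 * _ALPHA_MIN) & (mus > 0)
    if ok.sum() < 10:
        return alphas
    A = np.column_stack([1.0 / mus[ok], np.ones(ok.sum())])
    coef, *_ = np.linalg.lstsq(A, alphas[ok], rcond=None)
    a, b = max(coef[0], 0.0), max(coef[1], _ALPHA_MIN)
    trend = np.maximum(a / np.maximum(mus, 1e-6) + b, _ALPHA_MIN)
    resid = np.log(np.maximum(alphas, _ALPHA_MIN)) - np.log(trend)
    if weight is None:
        total_var = max(np.var(resid[ok]), 1e-6)
        sampling_var = 0.5  # rough sampling variance of a log NB dispersion
        weight = float(np.clip(sampling_var / total_var, 0.2, 0.9))
    shrunk = np.exp((1 - weight) * np.log(np.maximum(alphas, _ALPHA_MIN))
                    + weight * np.log(trend))
    return shrunk


def _design_matrix(meta: pd.DataFrame, group_dummy: np.ndarray,
                   covariate_cols: list[str]) -> tuple[np.ndarray, int]:
    """Intercept + covariates + the group dummy (last column)."""
    cols = [np.ones(len(meta))[:, None]]
    for c in covariate_cols:
        col = meta[c]
        if col.dtype.kind in "OUb" or isinstance(col.dtype, pd.CategoricalDtype):
            cols.append(pd.get_dummies(col, drop_first=True).to_numpy(dtype=float))
        else:
            x = col.to_numpy(dtype=float)
            cols.append(((x - x.mean()) / (x.std() if x.std() > 0 else 1.0))[:, None])
    cols.append(group_dummy.astype(float)[:, None])
    X = np.column_stack(cols)
    return X, X.shape[1] - 1


def run_diffabund(
    counts: CountTable,
    metadata: CohortMetadata,
    contrasts: tuple[str, ...] = DEFAULT_CONTRASTS,
    covariates: tuple[str, ...] = ("sex", "bmi", "age"),
    min_normalized_count: float = 5.0,
    min_sample_fraction: float = 0.01,
    shrink: bool = True,
) -> dict[str, pd.DataFrame]:
    """Prevalence-filter, fit every taxon per contrast and BH-adjust.

    Contrasts are ``LEVEL_vs_REFERENCE`` on the diagnosis column; ``IBD``
    pools CD and UC (uIBD is excluded throughout).  The log2 fold change is
    positive when the taxon is more abundant in LEVEL than in REFERENCE.
    """
    meta = metadata.data.set_index("sample_id").loc[counts.sample_ids]
    sf_all = robust_size_factors(counts)
    filtered = prevalence_filter(counts, min_normalized_count,
                                 min_sample_fraction, factors=sf_all)
    results: dict[str, pd.DataFrame] = {}
    for contrast in contrasts:
        level, ref = contrast.split("_vs_")
        dx = meta["diagnosis"]
        if level == "IBD":
            mask = dx.isin(["CD", "UC", ref])
            group = dx.where(~dx.isin(["CD", "UC"]), "IBD")[mask]
        else:
            for lv in (level, ref):
                if lv not in set(dx):
                    raise DysbiomeError(f"contrast level {lv!r} absent from data")
            mask = dx.isin([level, ref])
            group = dx[mask]
        sub_meta = meta[mask]
        sub_ids = list(sub_meta.index)
        sub_counts = filtered.subset_samples(sub_ids)
        sub_sf = sf_all.loc[sub_ids].to_numpy()
        # tested dummy: 1 for `level`, 0 for `ref`
        dummy = (group.to_numpy() == level)
        X, gcol = _design_matrix(sub_meta, dummy, list(covariates))

        mat = sub_counts.values()
        rows = []
        fits = []
        for j, taxon in enumerate(sub_counts.taxon_ids):
            y = mat[:, j].astype(float)
            try:
                fit = fit_nb_glm(y, X, sub_sf)
            except Exception as exc:  # non-convergence: flagged, excluded
                warnings.warn(f"taxon {taxon} failed to fit: {exc}")
                fit = None
            fits.append((taxon, y, fit))
        if shrink:
            ok = [(t, y, f) for t, y, f in fits if f is not None]
            if len(ok) >= 10:
                alphas = np.array([f.alpha for _, _, f in ok])
                mus = np.array([f.mu_mean for _, _, f in ok])
                shrunk = _shrink_dispersions(alphas, mus)
                refit = []
                for (t, y, _), a in zip(ok, shrunk):
                    try:
                        refit.append((t, y, fit_nb_glm(y, X, sub_sf, alpha=float(a))))
                    except Exception:
                        refit.append((t, y, None))
                fits = refit + [(t, y, f) for t, y, f in fits if f is None]
        for taxon, y, fit in fits:
            if fit is None or not fit.converged:
                continue
            beta = fit.coef[gcol]
            se = fit.se[gcol]
            z = beta / se if se > 0 else 0.0
            p = 2.0 * norm.sf(abs(z))
            rows.append({
                "taxon_id": taxon,
                "base_mean": float((y / sub_sf).mean()),
                "log2_fold_change": beta / np.log(2.0),
                "standard_error": se / np.log(2.0),
                "wald_stat": z,
                "p": p,
                "contrast_label": contrast,
                "alpha_dispersion": fit.alpha,
            })
        df = pd.DataFrame(rows)
        if len(df):
            df["p_fdr"] = multipletests(df["p"], method="fdr_bh")[1]
        else:
            df["p_fdr"] = []
        results[contrast] = df.reset_index(drop=True)
    return results
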