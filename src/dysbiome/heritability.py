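"""Pedigree-based kinship and variance-component heritability.

The additive relationship matrix ``A = 2 * Phi`` is built by the classical
recursive (tabular) kinship algorithm from reported parent links.  Narrow-
sense heritability of a quantitative phenotype (here CLR taxon abundances or
the dysbiosis index) is estimated under the single-random-effect linear
mixed model

    y = X beta + g + e,   g ~ N(0, sigma_g^2 A),   e ~ N(0, sigma_e^2 I)

by REML.  One eigendecomposition of ``A`` rotates the model to independent
observations, after which the profiled restricted likelihood is maximised
over the one-dimensional heritability ratio.  The "null" model carries no
fixed covariates beyond the intercept; the "full" model adjusts for age,
sex, BMI and IBD status, and the two are compared on maximum-likelihood AIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .coredata import DysbiomeError

FULL_MODEL_COVARIATES = ("age", "sex", "bmi", "diagnosis")


@dataclass
class Pedigree:
    """Subject table with optional father/mother links.

    Columns: ``subject_id``, ``father_id``, ``mother_id``, ``sex``,
    ``family_id``.  Absent parents (founders) are empty strings / NA.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        for col in ("subject_id", "father_id", "mother_id", "sex", "family_id"):
            if col not in df.columns:
                raise DysbiomeError(f"pedigree missing column {col!r}")
        df["subject_id"] = df["subject_id"].astype(str)
        for col in ("father_id", "mother_id"):
            df[col] = df[col].fillna("").astype(str)
        if df["subject_id"].duplicated().any():
            raise DysbiomeError("duplicate subject_id in pedigree")
        self.data = df.reset_index(drop=True)
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        parents = {
            r.subject_id: [p for p in (r.father_id, r.mother_id) if p]
            for r in self.data.itertuples()
        }
        state: dict[str, int] = {}

        def visit(node: str, stack: list[str]) -> None:
            state[node] = 1
            for p in parents.get(node, []):
                if state.get(p) == 1:
                    cycle = stack[stack.index(p):] + [p] if p in stack else [node, p]
                    raise DysbiomeError(f"pedigree cycle involving {' -> '.join(cycle)}")
                if state.get(p, 0) == 0:
                    visit(p, stack + [p])
            state[node] = 2

        for s in parents:
            if state.get(s, 0) == 0:
                visit(s, [s])

    @property
    def subject_ids(self) -> list[str]:
        return list(self.data["subject_id"])

    @property
    def founders(self) -> list[str]:
        d = self.data
        return list(d.loc[(d["father_id"] == "") & (d["mother_id"] == ""), "subject_id"])

    def topological_order(self) -> list[str]:
        """Subjects ordered so that parents precede children."""
        remaining = dict(zip(self.data["subject_id"],
                             zip(self.data["father_id"], self.data["mother_id"])))
        known = set()
        order: list[str] = []
        while remaining:
            progress = [
                s for s, (f, m) in remaining.items()
                if (not f or f in known) and (not m or m in known)
            ]
            if not progress:
                raise DysbiomeError("pedigree not topologically orderable")
            for s in progress:
                order.append(s)
                known.add(s)
                del remaining[s]
        return order

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "Pedigree":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        return cls(df)


@dataclass
class KinshipMatrix:
    """Additive relationship matrix ``A = 2 Phi`` with its subject ids."""

    values: np.ndarray
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.subject_ids)
        if self.values.shape != (n, n):
            raise DysbiomeError("kinship matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise DysbiomeError("kinship matrix not symmetric")

    def subset(self, subject_ids) -> "KinshipMatrix":
        idx = [self.subject_ids.index(s) for s in subject_ids]
        return KinshipMatrix(self.values[np.ix_(idx, idx)], list(subject_ids))

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.subject_ids,
                     columns=self.subject_ids).to_csv(path, sep="\t")


def kinship_matrix(ped: Pedigree) -> KinshipMatrix:
    """Recursive kinship coefficients Phi, returned as ``A = 2 Phi``.

    Founders are treated as unrelated and non-inbred.  Handles inbreeding
    through the standard recursion ``Phi(i,i) = 0.5 (1 + Phi(f_i, m_i))``.
    """
    order = ped.topological_order()
    index = {s: i for i, s in enumerate(order)}
    d = ped.data.set_index("subject_id")
    n = len(order)
    phi = np.zeros((n, n))
    for i, s in enumerate(order):
        f, m = d.loc[s, "father_id"], d.loc[s, "mother_id"]
        fi = index.get(f, -1) if f else -1
        mi = index.get(m, -1) if m else -1
        if fi >= 0 and mi >= 0:
            phi[i, i] = 0.5 * (1.0 + phi[fi, mi])
        else:
            phi[i, i] = 0.5
        for j in range(i):
            val = 0.0
            if fi >= 0:
                val += 0.5 * phi[fi, j]
            if mi >= 0:
                val += 0.5 * phi[mi, j]
            phi[i, j] = phi[j, i] = val
    # restore original pedigree order
    perm = [index[s] for s in ped.subject_ids]
    A = 2.0 * phi[np.ix_(perm, perm)]
    return KinshipMatrix(A, ped.subject_ids)


@dataclass
class H2Estimate:
    """REML heritability estimate for one phenotype under one fixed-effect
    model."""

    phenotype_id: str
    h2: float
    sigma_g2: float
    sigma_e2: float
    log_likelihood: float  # restricted log-likelihood at the optimum
    aic: float  # from the maximum-likelihood refit
    model: str
    n: int
    unidentifiable: bool = False
    boundary: bool = False


def _eigendecompose(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    vals, vecs = np.linalg.eigh(A)
    if vals.min() < -1e-6:
        raise DysbiomeError(
            f"kinship matrix not PSD (min eigenvalue {vals.min():.3g}); "
            "consider bending the matrix"
        )
    return np.clip(vals, 0.0, None), vecs


def _profiled_negloglik(h2: float, lam: np.ndarray, ystar: np.ndarray,
                        Xstar: np.ndarray, reml: bool) -> float:
    """Negative profiled (restricted) log-likelihood at heritability h2."""
    n, p = Xstar.shape
    gamma = h2 / (1.0 - h2)
    w = 1.0 / (gamma * lam + 1.0)  # proportional to precision
    Xw = Xstar * w[:, None]
    XtWX = Xstar.T @ Xw
    XtWy = Xw.T @ ystar
    beta = np.linalg.solve(XtWX, XtWy)
    resid = ystar - Xstar @ beta
    rss = float(resid @ (w * resid))
    logdet_v = float(np.sum(np.log(gamma * lam + 1.0)))
    if reml:
        dof = n - p
        sigma_e2 = rss / dof
        sign, logdet_x = np.linalg.slogdet(XtWX)
        ll = -0.5 * (dof * np.log(2 * np.pi * sigma_e2) + logdet_v
                     + logdet_x + dof)
    else:
        sigma_e2 = rss / n
        ll = -0.5 * (n * np.log(2 * np.pi * sigma_e2) + logdet_v + n)
    return -ll


def fit_h2(
    phenotype: np.ndarray | pd.Series,
    A: KinshipMatrix,
    covariates: pd.DataFrame | np.ndarray | None = None,
    phenotype_id: str = "phenotype",
    model: str | None = None,
    _eigen: tuple[np.ndarray, np.ndarray] | None = None,
) -> H2Estimate:
    """REML heritability under ``y = X beta + g + e`` with ``Var(g) =
    sigma_g^2 A``.

    The kinship eigendecomposition can be precomputed and passed via
    ``_eigen`` when fitting many phenotypes on the same subjects.
    """
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    if n != len(A.subject_ids):
        raise DysbiomeError("phenotype length does not match kinship matrix")
    if covariates is None:
        X = np.ones((n, 1))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        X = np.column_stack([np.ones(n), C])
    if n <= X.shape[1] + 2:
        raise DysbiomeError("too few observations for heritability fit")

    lam, U = _eigen if _eigen is not None else _eigendecompose(A.values)
    unident = bool(lam.max() - lam.min() < 1e-8)
    # standardise the phenotype so the optimisation (and hence h2) is
    # exactly invariant to its scale; variance components are scaled back
    y_sd = float(np.std(y))
    y_scale = y_sd if y_sd > 0 else 1.0
    ystar = U.T @ (y / y_scale)
    Xstar = U.T @ X

    if unident:
        # A proportional to I: sigma_g and sigma_e are confounded
        beta, *_ = np.linalg.lstsq(Xstar, ystar, rcond=None)
        resid = ystar - Xstar @ beta
        tot = float(resid @ resid) / max(n - X.shape[1], 1) * y_scale ** 2
        nll = _profiled_negloglik(1e-9, lam, ystar, Xstar, reml=True) \
            + (n - X.shape[1]) * np.log(y_scale)
        nll_ml = _profiled_negloglik(1e-9, lam, ystar, Xstar, reml=False) \
            + n * np.log(y_scale)
        return H2Estimate(phenotype_id, float("nan"), float("nan"), tot,
                          -nll, 2 * nll_ml + 2 * (X.shape[1] + 2),
                          model or ("full" if covariates is not None else "null"),
                          n, unidentifiable=True)

    upper = 1.0 - 1e-6
    res = minimize_scalar(
        _profiled_negloglik, bounds=(0.0, upper), method="bounded",
        args=(lam, ystar, Xstar, True), options={"xatol": 1e-10},
    )
    h2 = float(res.x)
    boundary = h2 < 1e-5 or h2 > upper - 1e-5
    if h2 < 1e-5:
        h2_rep = 0.0
    else:
        h2_rep = min(h2, 1.0)

    # recover variance components at the optimum
    gamma = h2 / (1.0 - h2)
    w = 1.0 / (gamma * lam + 1.0)
    Xw = Xstar * w[:, None]
    beta = np.linalg.solve(Xstar.T @ Xw, Xw.T @ ystar)
    resid = ystar - Xstar @ beta
    sigma_e2 = float(resid @ (w * resid)) / (n - X.shape[1]) * y_scale ** 2
    sigma_g2 = gamma * sigma_e2

    nll_ml = minimize_scalar(
        _profiled_negloglik, bounds=(0.0, upper), method="bounded",
        args=(lam, ystar, Xstar, False), options={"xatol": 1e-10},
    ).fun + n * np.log(y_scale)
    k_params = X.shape[1] + 2  # betas + two variance components
    aic = 2 * float(nll_ml) + 2 * k_params

    ll_reml = -float(res.fun) - (n - X.shape[1]) * np.log(y_scale)
    return H2Estimate(
        phenotype_id, h2_rep, sigma_g2, sigma_e2, ll_reml, aic,
        model or ("full" if covariates is not None else "null"), n,
        boundary=boundary,
    )


def compare_h2_models(
    phenotype: pd.Series | np.ndarray,
    covariates: pd.DataFrame,
    A: KinshipMatrix,
    phenotype_id: str = "phenotype",
) -> tuple[H2Estimate, H2Estimate, float]:
    """Fit the covariate-free ("null") and covariate-adjusted ("full")
    heritability models on the identical subject set and report
    ``delta_aic = AIC_null - AIC_full`` (positive favours the full model)."""
    y = pd.Series(np.asarray(phenotype, dtype=float))
    cov = covariates.reset_index(drop=True)
    mask = y.notna() & cov.notna().all(axis=1)
    if not mask.all():
        keep = [s for s, m in zip(A.subject_ids, mask) if m]
        A = A.subset(keep)
        y = y[mask]
        cov = cov[mask]
    X_full = _design_from_covariates(cov)
    lam_vecs = _eigendecompose(A.values)
    null = fit_h2(y.to_numpy(), A, None, phenotype_id, model="null",
                  _eigen=lam_vecs)
    full = fit_h2(y.to_numpy(), A, X_full, phenotype_id, model="full",
                  _eigen=lam_vecs)
    return null, full, null.aic - full.aic


def _design_from_covariates(cov: pd.DataFrame) -> np.ndarray:
    """Numeric design columns from a covariate frame; categoricals are
    dummy-coded dropping the first level, numerics standardised."""
    cols = []
    for name in cov.columns:
        col = cov[name]
        if col.dtype.kind in "OUb" or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=name, drop_first=True)
            cols.append(dummies.to_numpy(dtype=float))
        else:
            x = col.to_numpy(dtype=float)
            sd = x.std()
            cols.append(((x - x.mean()) / (sd if sd > 0 else 1.0))[:, None])
    return np.column_stack(cols) if cols else np.empty((len(cov), 0))


def h2_scan(
    clr_table: pd.DataFrame,
    counts_prevalence: pd.DataFrame,
    metadata: pd.DataFrame,
    A: KinshipMatrix,
    prevalence_cutoff: float = 0.10,
) -> pd.DataFrame:
    """Null/full heritability for every taxon passing the prevalence gate.

    ``clr_table`` holds CLR phenotypes (samples x taxa) aligned to the
    kinship subjects; ``counts_prevalence`` holds the raw counts used for the
    presence gate (a taxon must be present in at least ``prevalence_cutoff``
    of samples).
    """
    present = (counts_prevalence.to_numpy() > 0).mean(axis=0)
    taxa = [t for t, pr in zip(counts_prevalence.columns, present)
            if pr >= prevalence_cutoff]
    cov = metadata.loc[:, list(FULL_MODEL_COVARIATES)]
    rows = []
    for taxon in taxa:
        if taxon not in clr_table.columns:
            continue
        null, full, d_aic = compare_h2_models(
            clr_table[taxon].to_numpy(), cov, A, phenotype_id=taxon)
        rows.append({
            "taxon_id": taxon, "h2_null": null.h2, "h2_full": full.h2,
            "aic_null": null.aic, "aic_full": full.aic, "delta_aic": d_aic,
            "n": full.n,
        })
    if not rows:
        warnings.warn("no taxa pass the prevalence cutoff")
    return pd.DataFrame(rows)


def h2_scan_from_cohort(ped: Pedigree, counts, metadata,
                        prevalence_cutoff: float = 0.10) -> pd.DataFrame:
    """Convenience wrapper: align samples to pedigree subjects, CLR-transform
    and run the per-taxon null/full heritability scan."""
    from .coredata import clr_transform

    meta = metadata.data.set_index("sample_id")
    subjects = [s for s in ped.subject_ids if s in meta.index
                and s in counts.sample_ids]
    if not subjects:
        raise DysbiomeError("no overlap between pedigree and samples")
    A = kinship_matrix(ped).subset(subjects)
    sub = counts.subset_samples(subjects)
    clr = clr_transform(sub).data
    return h2_scan(clr, sub.data, meta.loc[subjects].reset_index(),
                   A, prevalence_cutoff)
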