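"""Microbial dysbiosis (MD) index and the dysbiosis-diversity curve.

The disease-up / health-up taxon sets come from baseline differential
abundance: taxa significantly more abundant in either CD or UC versus
controls define the numerator set, taxa significantly more abundant in
controls the denominator set.  The index for a sample is

    MD = log1p(sum of normalised abundance over disease-up taxa)
       / log1p(sum over health-up taxa)

so equal sums give exactly 1 and the score is non-negative wherever the
denominator sum is positive.  The relation between dysbiosis and alpha
diversity is summarised by the best of a linear, one-breakpoint segmented,
and quadratic fit under AIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coredata import CountTable, DysbiomeError, normalized_counts, relative_abundance


@dataclass
class MDTaxonSets:
    """Disjoint disease-up and health-up taxon id sets with provenance."""

    ibd_up: set[str]
    control_up: set[str]
    source: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = self.ibd_up & self.control_up
        if overlap:
            raise DysbiomeError(f"taxon sets overlap: {sorted(overlap)}")

    def to_tsv(self, path) -> None:
        rows = [(t, "ibd_up") for t in sorted(self.ibd_up)]
        rows += [(t, "control_up") for t in sorted(self.control_up)]
        pd.DataFrame(rows, columns=["taxon_id", "set"]).to_csv(
            path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "MDTaxonSets":
        df = pd.read_csv(path, sep="\t")
        return cls(set(df.loc[df["set"] == "ibd_up", "taxon_id"]),
                   set(df.loc[df["set"] == "control_up", "taxon_id"]))


@dataclass
class MDIndex:
    values: pd.Series  # per-sample score, NaN where the denominator sum is 0
    basis: str  # normalisation used for "abundance"
    n_missing: int = 0


def derive_md_taxa(
    results_cd: pd.DataFrame,
    results_uc: pd.DataFrame,
    alpha_fdr: float = 0.05,
) -> MDTaxonSets:
    """Combine CD-vs-control and UC-vs-control results into taxon sets.

    A taxon significant (``p_fdr <= alpha_fdr``) with positive log2FC in
    either contrast joins ``ibd_up``; significant with negative log2FC in
    either contrast joins ``control_up``.  Taxa pulled both ways are dropped
    with a warning to keep the sets disjoint.
    """
    frames = [f for f in (results_cd, results_uc) if f is not None and len(f)]
    if not frames:
        raise DysbiomeError("empty differential abundance results")
    up: set[str] = set()
    down: set[str] = set()
    for df in frames:
        sig = df[df["p_fdr"] <= alpha_fdr]
        up |= set(sig.loc[sig["log2_fold_change"] > 0, "taxon_id"])
        down |= set(sig.loc[sig["log2_fold_change"] < 0, "taxon_id"])
    conflict = up & down
    if conflict:
        warnings.warn(
            f"{len(conflict)} taxa significant in opposite directions "
            "across contrasts were dropped from both sets")
    return MDTaxonSets(
        up - conflict, down - conflict,
        source={"alpha_fdr": alpha_fdr,
                "contrasts": [str(f["contrast_label"].iloc[0]) for f in frames],
                "n_conflicts": len(conflict)},
    )


def md_index(
    counts: CountTable,
    sets: MDTaxonSets,
    basis: str = "normalized",
    factors: pd.Series | None = None,
) -> MDIndex:
    """Per-sample MD score on size-factor-normalised counts (default) or
    relative abundances (``basis='relative'``).  Precomputed size factors
    (e.g. from the full cohort) can be supplied via ``factors``."""
    if not sets.ibd_up or not sets.control_up:
        raise DysbiomeError("both taxon sets must be non-empty")
    missing = (sets.ibd_up | sets.control_up) - set(counts.taxon_ids)
    if missing:
        raise DysbiomeError(f"taxa absent from table: {sorted(missing)}")
    if basis == "normalized":
        table = normalized_counts(counts, factors)
    elif basis == "relative":
        table = relative_abundance(counts)
    else:
        raise DysbiomeError(f"unknown basis {basis!r}")
    df = table.data
    num = np.log1p(df[sorted(sets.ibd_up)].sum(axis=1).to_numpy())
    den = np.log1p(df[sorted(sets.control_up)].sum(axis=1).to_numpy())
    with np.errstate(divide="ignore", invalid="ignore"):
        md = np.where(den > 0, num / den, np.nan)
    n_missing = int(np.isnan(md).sum())
    if n_missing:
        warnings.warn(f"{n_missing} samples with zero health-up abundance "
                      "set to missing")
    return MDIndex(pd.Series(md, index=counts.sample_ids, name="MD"),
                   basis=basis, n_missing=n_missing)


# --------------------------------------------------------------------------
# dysbiosis-diversity curve
# --------------------------------------------------------------------------

@dataclass
class CurveFit:
    model: str  # linear | segmented | quadratic
    aic: dict[str, float]
    coefficients: dict[str, np.ndarray]
    breakpoint: float | None
    breakpoint_ci: tuple[float, float] | None
    r2: float
    n: int


def _ols_rss(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def _aic(rss: float, n: int, k: int) -> float:
    # Gaussian AIC; k counts regression coefficients + breakpoint + sigma
    return n * np.log(max(rss, 1e-300) / n) + 2 * k


def fit_dysbiosis_diversity_model(
    md: MDIndex | pd.Series,
    diversity: pd.Series,
    grid_size: int = 200,
) -> CurveFit:
    """AIC selection among linear, one-breakpoint segmented, and quadratic
    fits of diversity on the MD score.

    The segmented model profiles the breakpoint on a grid between the 5th
    and 95th percentile of MD with a continuity constraint (hinge basis
    ``(x - psi)_+``); its profile 95% CI collects grid points whose RSS stays
    within the chi-square(1) threshold of the minimum.
    """
    x = (md.values if isinstance(md, MDIndex) else md)
    paired = pd.concat([pd.Series(x), pd.Series(diversity.to_numpy(),
                                                index=pd.Series(x).index)],
                       axis=1, keys=["md", "div"]).dropna()
    if len(paired) < 10:
        raise DysbiomeError("need at least 10 paired observations")
    xv = paired["md"].to_numpy()
    yv = paired["div"].to_numpy()
    if np.ptp(xv) == 0:
        raise DysbiomeError("constant predictor")
    n = len(xv)

    X_lin = np.column_stack([np.ones(n), xv])
    beta_lin, rss_lin = _ols_rss(X_lin, yv)
    X_quad = np.column_stack([np.ones(n), xv, xv ** 2])
    beta_quad, rss_quad = _ols_rss(X_quad, yv)

    lo, hi = np.percentile(xv, [5, 95])
    grid = np.linspace(lo, hi, grid_size)
    rss_grid = np.empty(grid_size)
    betas = []
    for i, psi in enumerate(grid):
        Xs = np.column_stack([np.ones(n), xv, np.clip(xv - psi, 0.0, None)])
        b, r = _ols_rss(Xs, yv)
        rss_grid[i] = r
        betas.append(b)
    i_best = int(np.argmin(rss_grid))
    psi_hat = float(grid[i_best])
    rss_seg = float(rss_grid[i_best])
    beta_seg = betas[i_best]
    # profile CI: n log(RSS/RSS_min) <= chi2_{1,0.95}
    with np.errstate(divide="ignore"):
        stat = n * np.log(rss_grid / rss_seg)
    in_ci = grid[stat <= 3.841]
    ci = (float(in_ci.min()), float(in_ci.max())) if len(in_ci) else None

    aics = {
        "linear": _aic(rss_lin, n, 3),
        "segmented": _aic(rss_seg, n, 5),
        "quadratic": _aic(rss_quad, n, 4),
    }
    best = min(aics, key=aics.get)
    rss_best = {"linear": rss_lin, "segmented": rss_seg,
                "quadratic": rss_quad}[best]
    tss = float(((yv - yv.mean()) ** 2).sum())
    return CurveFit(
        model=best,
        aic=aics,
        coefficients={"linear": beta_lin, "segmented": beta_seg,
                      "quadratic": beta_quad},
        breakpoint=psi_hat if best == "segmented" else None,
        breakpoint_ci=ci if best == "segmented" else None,
        r2=1.0 - rss_best / tss if tss > 0 else 0.0,
        n=n,
    )
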