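"""Diversity estimators, dissimilarities, ordination, permutational
multivariate ANOVA and the multivariate dispersion test.

PERMANOVA follows the McArdle & Anderson partition of the Gower-centred
squared-distance matrix, with sequential (Type-I) sums of squares in the
order the terms are given.  Conditioning terms are projected out of both the
distance space and the design before the partition, and permutation is
applied to the conditioned residual matrix (a Freedman-Lane-style scheme).
The dispersion test embeds samples by principal coordinates (negative
eigenvalue axes enter with negative squared contributions, as in the
standard correction), measures each sample's distance to its group centroid,
and permutes group membership, recomputing the distances each time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from skbio.diversity.alpha import chao1 as _skbio_chao1
from sklearn.manifold import MDS

from .coredata import CountTable, DysbiomeError, NormalizedTable


@dataclass
class DistanceMatrix:
    """Symmetric, zero-diagonal dissimilarity matrix with sample ids."""

    values: np.ndarray
    ids: list[str]
    metric: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise DysbiomeError("distance matrix shape mismatch")
        if np.nanmax(np.abs(self.values - self.values.T)) > 1e-12:
            raise DysbiomeError("distance matrix not symmetric")
        np.fill_diagonal(self.values, 0.0)
        if np.nanmin(self.values) < 0:
            raise DysbiomeError("negative distances")

    def subset(self, ids) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(self.values[np.ix_(idx, idx)], list(ids), self.metric)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t")

    @classmethod
    def from_tsv(cls, path, metric: str = "unknown") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(), list(df.index.astype(str)), metric)


@dataclass
class PermanovaResult:
    terms: list[str]
    df: dict[str, int]
    sum_of_squares: dict[str, float]
    pseudo_F: dict[str, float]
    R2: dict[str, float]
    adj_R2: dict[str, float]
    p_perm: dict[str, float]
    n_perm: int
    ss_residual: float
    ss_total: float
    df_residual: int
    conditioned_on: list[str] = field(default_factory=list)
    label: str = "PERMANOVA (sequential SS)"


@dataclass
class DispersionResult:
    group_distances: pd.Series
    groups: pd.Series
    F: float
    p_perm: float
    n_perm: int


# --------------------------------------------------------------------------
# alpha diversity
# --------------------------------------------------------------------------

def alpha_diversity(counts: CountTable, metric: str = "chao1") -> pd.Series:
    """Per-sample alpha diversity.

    ``chao1`` is the bias-corrected estimator
    ``S_obs + f1 (f1 - 1) / (2 (f2 + 1))``; ``shannon_effective`` is the
    Shannon numbers equivalent ``exp(-sum p_i ln p_i)``.  Empty samples give
    NaN.
    """
    mat = counts.values()
    out = np.full(counts.n_samples, np.nan)
    for i, row in enumerate(mat):
        total = row.sum()
        if total == 0:
            continue
        if metric == "chao1":
            out[i] = _skbio_chao1(row.astype(int), bias_corrected=True)
        elif metric == "shannon_effective":
            p = row[row > 0] / total
            out[i] = float(np.exp(-(p * np.log(p)).sum()))
        else:
            raise DysbiomeError(f"unknown alpha metric {metric!r}")
    if np.isnan(out).any():
        warnings.warn("empty samples flagged as missing in alpha diversity")
    return pd.Series(out, index=counts.sample_ids, name=metric)


# --------------------------------------------------------------------------
# dissimilarity
# --------------------------------------------------------------------------

def dissimilarity(table: CountTable | NormalizedTable, metric: str = "bray_curtis") -> DistanceMatrix:
    """Bray-Curtis on abundances or Jaccard on presence/absence."""
    mat = table.values().astype(float)
    if mat.shape[0] < 2:
        raise DysbiomeError("need at least 2 samples")
    if metric == "bray_curtis":
        dm = squareform(pdist(mat, metric="braycurtis"))
    elif metric == "jaccard":
        dm = squareform(pdist(mat > 0, metric="jaccard"))
    else:
        raise DysbiomeError(f"unknown dissimilarity metric {metric!r}")
    if np.isnan(dm).any():
        warnings.warn("undefined pairs (two all-zero samples) flagged as NaN")
    return DistanceMatrix(dm, table.sample_ids, metric)


# --------------------------------------------------------------------------
# ordination
# --------------------------------------------------------------------------

def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d ** 2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def pcoa(d: DistanceMatrix, k: int | None = None, lingoes: bool = False):
    """Principal coordinates via Gower double-centering.

    Returns ``(coordinates DataFrame, eigenvalues)``.  Negative eigenvalues
    are reported; coordinate axes are built only from positive eigenvalues
    unless ``lingoes=True`` applies the additive constant correction first.
    """
    dmat = d.values
    if lingoes:
        g = _gower_center(dmat)
        evals = np.linalg.eigvalsh(g)
        c = max(0.0, -evals.min())
        if c > 0:
            dmat = np.sqrt(dmat ** 2 + 2 * c)
            np.fill_diagonal(dmat, 0.0)
    g = _gower_center(dmat)
    evals, evecs = np.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-10
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    if k is not None:
        if k >= len(d.ids):
            raise DysbiomeError("k must be smaller than the number of samples")
        coords = coords[:, :k]
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=d.ids, columns=cols), evals


def nmds(d: DistanceMatrix, k: int = 2, n_restarts: int = 20,
         max_iter: int = 300, tol: float = 1e-7, seed: int = 0):
    """Non-metric MDS by stress majorisation with monotone regression; the
    best of ``n_restarts`` random starts is kept and normalised stress
    (Kruskal stress-1) reported."""
    mds = MDS(n_components=k, metric=False, dissimilarity="precomputed",
              n_init=n_restarts, max_iter=max_iter, eps=tol,
              random_state=seed, normalized_stress=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        coords = mds.fit_transform(d.values)
    stress = float(mds.stress_)
    if stress > 0.2:
        warnings.warn(f"NMDS stress {stress:.3f} is high; interpret with care")
    cols = [f"NMDS{i + 1}" for i in range(k)]
    return pd.DataFrame(coords, index=d.ids, columns=cols), stress


def ordinate(d: DistanceMatrix, method: str = "pcoa", k: int = 2, **kwargs):
    if method == "pcoa":
        return pcoa(d, k=k, **kwargs)
    if method == "nmds":
        return nmds(d, k=k, **kwargs)
    raise DysbiomeError(f"unknown ordination method {method!r}")


# --------------------------------------------------------------------------
# PERMANOVA
# --------------------------------------------------------------------------

def _term_design(metadata: pd.DataFrame, term: str) -> np.ndarray:
    """Columns for one design term: categoricals dummy-coded (drop first),
    numerics as a single column, ``a:b`` as elementwise products."""
    if ":" in term:
        left, right = term.split(":", 1)
        a = _term_design(metadata, left)
        b = _term_design(metadata, right)
        return np.einsum("ij,ik->ijk", a, b).reshape(len(a), -1)
    col = metadata[term]
    if col.isna().any():
        raise DysbiomeError(f"metadata column {term!r} has missing values")
    if col.dtype.kind in "OUb" or isinstance(col.dtype, pd.CategoricalDtype):
        return pd.get_dummies(col, drop_first=True).to_numpy(dtype=float)
    x = col.to_numpy(dtype=float)
    return ((x - x.mean()) / (x.std() if x.std() > 0 else 1.0))[:, None]


def _hat(X: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(X)
    rank = np.sum(np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max()))
    q = q[:, :rank]
    return q @ q.T


def permanova(
    d: DistanceMatrix,
    metadata: pd.DataFrame,
    terms: list[str],
    condition: list[str] | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Distance-based permutation ANOVA with sequential SS.

    ``terms`` are metadata column names (categorical or numeric; ``a:b``
    denotes an interaction), fitted in the order given.  ``condition`` terms
    are removed from distances and design before partitioning, and
    permutations act on the conditioned residual matrix.
    """
    meta = metadata.set_index("sample_id").loc[d.ids] \
        if "sample_id" in metadata.columns else metadata.loc[d.ids]
    n = len(d.ids)
    G = _gower_center(d.values)

    rng = np.random.default_rng(seed)
    intercept = np.ones((n, 1))
    if condition:
        Xc = np.column_stack([intercept] + [_term_design(meta, t) for t in condition])
        Hc = _hat(Xc)
        R = np.eye(n) - Hc
        G = R @ G @ R
    else:
        Hc = _hat(intercept)
        R = np.eye(n) - Hc
        G = R @ G @ R  # centering (idempotent for Gower-centred G)

    blocks = []
    X_cum = intercept
    if condition:
        X_cum = np.column_stack([intercept] + [_term_design(meta, t) for t in condition])
    hats = [_hat(X_cum)]
    dfs = []
    for t in terms:
        B = _term_design(meta, t)
        if B.shape[1] == 0:
            raise DysbiomeError(f"term {t!r} has no contrast columns")
        X_new = np.column_stack([X_cum, B])
        H_new = _hat(X_new)
        df_t = int(round(np.trace(H_new) - np.trace(hats[-1])))
        if df_t == 0:
            raise DysbiomeError(f"term {t!r} aliased with earlier terms")
        hats.append(H_new)
        dfs.append(df_t)
        X_cum = X_new
        blocks.append(B)

    H_diffs = [hats[i + 1] - hats[i] for i in range(len(terms))]
    H_full = hats[-1]
    M_res = np.eye(n) - H_full
    df_res = n - int(round(np.trace(H_full)))
    if df_res <= 0:
        raise DysbiomeError("saturated design: no residual degrees of freedom")

    def stats_for(Gmat):
        ss_terms = np.array([float(np.sum(Hd * Gmat)) for Hd in H_diffs])
        ss_res = float(np.sum(M_res * Gmat))
        F = (ss_terms / np.array(dfs)) / (ss_res / df_res)
        return ss_terms, ss_res, F

    ss_terms, ss_res, F_obs = stats_for(G)
    ss_total = float(np.trace(G))

    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Gp = G[np.ix_(perm, perm)]
        _, _, F_p = stats_for(Gp)
        exceed += F_p >= F_obs - 1e-12
    p = (exceed + 1.0) / (n_perm + 1.0)

    R2 = ss_terms / ss_total if ss_total > 0 else np.zeros(len(terms))
    adj = {}
    for i, t in enumerate(terms):
        df_model = sum(dfs[: i + 1])
        r2_cum = ss_terms[: i + 1].sum() / ss_total if ss_total > 0 else 0.0
        adj[t] = 1.0 - (1.0 - r2_cum) * (n - 1) / (n - 1 - df_model)
    return PermanovaResult(
        terms=list(terms),
        df=dict(zip(terms, dfs)),
        sum_of_squares=dict(zip(terms, ss_terms)),
        pseudo_F=dict(zip(terms, F_obs)),
        R2=dict(zip(terms, R2)),
        adj_R2=adj,
        p_perm=dict(zip(terms, p)),
        n_perm=n_perm,
        ss_residual=ss_res,
        ss_total=ss_total,
        df_residual=df_res,
        conditioned_on=list(condition or []),
    )


# --------------------------------------------------------------------------
# multivariate dispersion
# --------------------------------------------------------------------------

def dispersion_test(
    d: DistanceMatrix,
    groups: pd.Series | np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> DispersionResult:
    """Homogeneity of multivariate dispersions around group centroids.

    Samples are embedded by PCoA keeping all non-null axes; squared distance
    to the own-group centroid is the positive-axis contribution minus the
    negative-axis (imaginary) contribution.  The one-way F on those distances
    is assessed by permuting group membership and recomputing the
    centroid distances under each permuted grouping.
    """
    g = pd.Series(np.asarray(groups), index=d.ids)
    sizes = g.value_counts()
    small = sizes[sizes < 2].index.tolist()
    if small:
        warnings.warn(f"groups of size 1 excluded: {small}")
        keep = [i for i in d.ids if g[i] not in small]
        d = d.subset(keep)
        g = g.loc[keep]
    if g.nunique() < 2:
        raise DysbiomeError("need at least 2 groups with >= 2 samples")

    G = _gower_center(d.values)
    evals, evecs = np.linalg.eigh(G)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep_ax = np.abs(evals) > 1e-10
    evals, evecs = evals[keep_ax], evecs[:, keep_ax]
    axes = evecs * np.sqrt(np.abs(evals))
    signs = np.sign(evals)

    labels = g.to_numpy()
    levels = pd.unique(labels)

    def distances_for(lab):
        zz = np.empty(len(lab))
        for level in levels:
            idx = np.where(lab == level)[0]
            centroid = axes[idx].mean(axis=0)
            sq = ((axes[idx] - centroid) ** 2 * signs).sum(axis=1)
            zz[idx] = np.sqrt(np.clip(sq, 0.0, None))
        return zz

    def anova_f(vals, lab):
        grand = vals.mean()
        ss_b = ss_w = 0.0
        df_b = -1
        for level in levels:
            v = vals[lab == level]
            ss_b += len(v) * (v.mean() - grand) ** 2
            ss_w += ((v - v.mean()) ** 2).sum()
            df_b += 1
        df_w = len(vals) - df_b - 1
        return (ss_b / df_b) / (ss_w / df_w)

    z = distances_for(labels)
    F_obs = anova_f(z, labels)
    # permute group membership and rerun the whole procedure (centroids and
    # distances recomputed under the permuted grouping)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        lab_p = labels[rng.permutation(len(labels))]
        z_p = distances_for(lab_p)
        if anova_f(z_p, lab_p) >= F_obs - 1e-12:
            exceed += 1
    p = (exceed + 1.0) / (n_perm + 1.0)
    return DispersionResult(
        group_distances=pd.Series(z, index=d.ids, name="dist_to_centroid"),
        groups=g, F=float(F_obs), p_perm=float(p), n_perm=n_perm)
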