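"""Core data containers and the normalisation / filtering primitives shared by
every analysis stage.

The central object is :class:`CountTable`, a samples x taxa matrix of
non-negative integer ASV counts with unique sample and taxon identifiers.
Normalisation follows standard amplicon practice: median-of-ratios size
factors for count-scale models, relative abundance for dissimilarities, and
the centered log-ratio (CLR) transform for correlation and network analyses.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DIAGNOSIS_LEVELS = ("Control", "CD", "UC", "uIBD")
TIME_POINTS = ("BL", "F1", "F2", "F3")
BIOMARKER_COLUMNS = (
    "ASCA_IgA",
    "ASCA_IgG",
    "GP2_IgA",
    "GP2_IgG",
    "calprotectin",
    "BSS",
)
PRS_COLUMNS = ("CD_PRS", "UC_PRS", "IBD_PRS")


class DysbiomeError(Exception):
    """Base error for invalid inputs or configurations."""


@dataclass
class CountTable:
    """Samples x taxa matrix of non-negative integer counts.

    Parameters
    ----------
    data:
        DataFrame with sample ids as the index and taxon ids as columns.
        Values must be non-negative integers.
    taxonomy:
        Optional map from taxon id to a rank-labelled lineage string.
    """

    data: pd.DataFrame
    taxonomy: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            raise DysbiomeError("CountTable.data must be a DataFrame")
        if self.data.index.has_duplicates:
            raise DysbiomeError("duplicate sample ids")
        if self.data.columns.has_duplicates:
            raise DysbiomeError("duplicate taxon ids")
        values = self.data.to_numpy()
        if values.size and values.min() < 0:
            raise DysbiomeError("counts must be non-negative")
        if not np.issubdtype(values.dtype, np.integer):
            if values.size and not np.allclose(values, np.round(values)):
                raise DysbiomeError("counts must be integers")
            self.data = self.data.astype(np.int64)
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset_samples(self, sample_ids) -> "CountTable":
        return CountTable(self.data.loc[list(sample_ids)].copy(), self.taxonomy)

    def subset_taxa(self, taxon_ids) -> "CountTable":
        tax = None
        if self.taxonomy is not None:
            tax = {t: self.taxonomy[t] for t in taxon_ids if t in self.taxonomy}
        return CountTable(self.data.loc[:, list(taxon_ids)].copy(), tax)

    # ------------------------------------------------------------------ I/O
    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, taxonomy: dict[str, str] | None = None) -> "CountTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index.name = None
        return cls(df, taxonomy)

    def to_biom_json(self, path) -> None:
        """Write as a minimal BIOM v1 (JSON, dense) table."""
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "dysbiome",
            "date": "",
            "matrix_type": "dense",
            "matrix_element_type": "int",
            "shape": [self.n_taxa, self.n_samples],
            "rows": [
                {"id": t, "metadata": ({"taxonomy": self.taxonomy[t]}
                                       if self.taxonomy and t in self.taxonomy else None)}
                for t in self.taxon_ids
            ],
            "columns": [{"id": s, "metadata": None} for s in self.sample_ids],
            "data": self.data.to_numpy().T.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_biom_json(cls, path) -> "CountTable":
        with open(path) as fh:
            doc = json.load(fh)
        taxa = [r["id"] for r in doc["rows"]]
        samples = [c["id"] for c in doc["columns"]]
        if doc["matrix_type"] == "dense":
            mat = np.asarray(doc["data"])
        else:  # sparse: [row, col, value] triplets
            mat = np.zeros((len(taxa), len(samples)))
            for r, c, v in doc["data"]:
                mat[int(r), int(c)] = v
        taxonomy = {}
        for r in doc["rows"]:
            md = r.get("metadata")
            if md and "taxonomy" in md:
                tx = md["taxonomy"]
                taxonomy[r["id"]] = tx if isinstance(tx, str) else "; ".join(tx)
        df = pd.DataFrame(mat.T, index=samples, columns=taxa)
        return cls(df, taxonomy or None)


@dataclass
class CohortMetadata:
    """Per-sample covariates: subject / family structure, diagnosis, time
    point, anthropometrics, inflammation biomarkers and optional polygenic
    risk scores."""

    data: pd.DataFrame

    REQUIRED = ("sample_id", "subject_id", "diagnosis")

    def __post_init__(self) -> None:
        df = self.data
        for col in self.REQUIRED:
            if col not in df.columns:
                raise DysbiomeError(f"metadata missing required column {col!r}")
        if df["sample_id"].duplicated().any():
            raise DysbiomeError("duplicate sample_id in metadata")
        bad = set(df["diagnosis"].dropna()) - set(DIAGNOSIS_LEVELS)
        if bad:
            raise DysbiomeError(f"unknown diagnosis levels: {sorted(bad)}")
        if "time_point" in df.columns:
            bad_tp = set(df["time_point"].dropna()) - set(TIME_POINTS)
            if bad_tp:
                raise DysbiomeError(f"unknown time points: {sorted(bad_tp)}")
        if "BSS" in df.columns:
            bss = df["BSS"].dropna()
            if len(bss) and ((bss < 1) | (bss > 7)).any():
                raise DysbiomeError("BSS values outside [1, 7]")
        self.data = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"].astype(str))

    def aligned_to(self, sample_ids) -> "CohortMetadata":
        df = self.data.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return CohortMetadata(df)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "CohortMetadata":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class NormalizedTable:
    """Normalised abundance matrix plus a record of how it was produced."""

    data: pd.DataFrame
    method: str
    size_factors: pd.Series | None = None
    pseudocount: float | None = None
    all_zero_samples: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    def values(self) -> np.ndarray:
        return self.data.to_numpy()


# --------------------------------------------------------------------------
# normalisation primitives
# --------------------------------------------------------------------------

def size_factors(counts: CountTable, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors.

    Taxa with a zero anywhere have zero geometric mean and drop out of the
    reference; the factor for sample ``j`` is the median over remaining taxa
    of ``count_ij / geomean_i``.  Factors are rescaled to geometric mean 1 so
    that normalised counts stay on the count scale.

    With ``pseudo_reference=True`` the geometric means are computed on
    counts + 1, which rescues tables where no taxon is positive everywhere.
    """
    mat = counts.values().astype(float)
    if mat.shape[0] == 0 or mat.shape[1] == 0:
        raise DysbiomeError("empty count table")
    if (mat.sum(axis=1) == 0).any():
        raise DysbiomeError("sample with all-zero counts; size factors undefined")
    if pseudo_reference:
        logs = np.log(mat + 1.0)
        log_geomean = logs.mean(axis=0)
        ref = np.ones(mat.shape[1], dtype=bool)
        ratios = np.log(mat + 1.0) - log_geomean
    else:
        with np.errstate(divide="ignore"):
            logs = np.log(mat)
        ref = np.isfinite(logs).all(axis=0)
        if not ref.any():
            raise DysbiomeError(
                "no taxon is positive in every sample; rerun with "
                "pseudo_reference=True to use a pseudo-count reference"
            )
        log_geomean = logs[:, ref].mean(axis=0)
        ratios = logs[:, ref] - log_geomean
        sf = np.exp(np.median(ratios, axis=1))
        sf = sf / np.exp(np.mean(np.log(sf)))
        return pd.Series(sf, index=counts.sample_ids, name="size_factor")
    sf = np.exp(np.median(ratios[:, ref], axis=1))
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=counts.sample_ids, name="size_factor")


def robust_size_factors(counts: CountTable) -> pd.Series:
    """Median-of-ratios factors with automatic pseudo-reference fallback for
    tables where no taxon is positive in every sample (common for sparse ASV
    data)."""
    try:
        return size_factors(counts)
    except DysbiomeError:
        return size_factors(counts, pseudo_reference=True)


def normalized_counts(counts: CountTable, factors: pd.Series | None = None) -> NormalizedTable:
    """Counts divided by their median-of-ratios size factor."""
    if factors is None:
        factors = robust_size_factors(counts)
    factors = factors.reindex(counts.sample_ids)
    mat = counts.values() / factors.to_numpy()[:, None]
    return NormalizedTable(
        pd.DataFrame(mat, index=counts.sample_ids, columns=counts.taxon_ids),
        method="median_of_ratios",
        size_factors=factors,
    )


def relative_abundance(counts: CountTable) -> NormalizedTable:
    """Per-sample proportions; all-zero samples are flagged and left at zero."""
    mat = counts.values().astype(float)
    totals = mat.sum(axis=1)
    zero = totals == 0
    safe = np.where(zero, 1.0, totals)
    props = mat / safe[:, None]
    flagged = [s for s, z in zip(counts.sample_ids, zero) if z]
    if flagged:
        warnings.warn(f"{len(flagged)} all-zero samples in relative abundance")
    return NormalizedTable(
        pd.DataFrame(props, index=counts.sample_ids, columns=counts.taxon_ids),
        method="relative_abundance",
        all_zero_samples=flagged,
    )


def clr_transform(table: CountTable | NormalizedTable, pseudocount: float = 0.5) -> NormalizedTable:
    """Centered log-ratio transform: ``ln(x_i + pc) - mean_k ln(x_k + pc)``.

    ``pseudocount`` must be positive whenever zeros are present; each output
    row sums to zero.
    """
    if isinstance(table, CountTable):
        mat = table.values().astype(float)
        sample_ids, taxon_ids = table.sample_ids, table.taxon_ids
    else:
        mat = table.values().astype(float)
        sample_ids, taxon_ids = table.sample_ids, table.taxon_ids
    if pseudocount < 0:
        raise DysbiomeError("pseudocount must be non-negative")
    if pseudocount == 0 and (mat == 0).any():
        raise DysbiomeError("zero counts require a positive pseudocount")
    logs = np.log(mat + pseudocount)
    clr = logs - logs.mean(axis=1, keepdims=True)
    return NormalizedTable(
        pd.DataFrame(clr, index=sample_ids, columns=taxon_ids),
        method="clr",
        pseudocount=pseudocount,
    )


def prevalence_filter(
    counts: CountTable,
    min_normalized_count: float = 5.0,
    min_sample_fraction: float = 0.01,
    factors: pd.Series | None = None,
) -> CountTable:
    """Retain taxa whose size-factor-normalised count reaches
    ``min_normalized_count`` in at least ``ceil(min_sample_fraction * n)``
    samples (boundary inclusive).  Defaults keep taxa with normalised counts
    of at least 5 in at least 1% of samples.
    """
    if min_normalized_count < 0 or min_sample_fraction < 0:
        raise DysbiomeError("filter thresholds must be non-negative")
    if factors is None:
        factors = robust_size_factors(counts)
    norm = normalized_counts(counts, factors)
    need = max(1, math.ceil(min_sample_fraction * counts.n_samples))
    hits = (norm.values() >= min_normalized_count).sum(axis=0)
    keep = [t for t, h in zip(counts.taxon_ids, hits) if h >= need]
    return counts.subset_taxa(keep)
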