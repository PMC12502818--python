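"""Synthetic family-cohort generator.

Emulates the statistical structure a family-based IBD 16S study presents to
the downstream analyses: nuclear-family pedigrees, negative-binomial ASV
counts around a compositional mean, disease-associated taxon shifts
(disease-up taxa such as Enterobacteriaceae and ectopic oral colonisers,
health-up short-chain-fatty-acid producers), inflated inter-individual
compositional noise in IBD samples (the "Anna Karenina" pattern), inflammation
biomarkers coupled to a latent dysbiosis score, kinship-correlated genetic
effects with target heritability, and optionally planted community clusters.

The per-sample generative model on the log-abundance scale is

    lambda_st = baseline_t + ln(2) * log2fc_t * IBD_s + g_st + eps_st

with ``g_t ~ MVN(0, sigma_g_t^2 A)`` (A the additive relationship matrix) and
``eps_st ~ N(0, (noise_sd * inflation_s)^2)``; counts are drawn Gamma-Poisson
(negative binomial) around ``library_size_s * softmax(lambda_s)``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coredata import CohortMetadata, CountTable, DysbiomeError
from .heritability import KinshipMatrix, Pedigree, kinship_matrix

_GENUS_POOL = [
    "Bacteroides", "Faecalibacterium", "Prevotella", "Alistipes", "Blautia",
    "Ruminococcus", "Oscillibacter", "Roseburia", "Clostridium_XlVa",
    "Klebsiella", "Escherichia_Shigella", "Veillonella", "Haemophilus",
    "Fusobacterium", "Rothia", "Granulicatella", "Dialister", "Enterococcus",
    "Akkermansia", "Barnesiella",
]


@dataclass
class ClusterSpec:
    """Planted community-type structure: ``n_clusters`` compositional modes
    whose centres sit at pairwise Aitchison distance ``separation``."""

    n_clusters: int = 3
    separation: float = 4.0
    weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise DysbiomeError("n_clusters must be >= 1")
        if self.weights is not None:
            if len(self.weights) != self.n_clusters:
                raise DysbiomeError("cluster weights length mismatch")
            if abs(sum(self.weights) - 1.0) > 1e-9:
                raise DysbiomeError("cluster weights must sum to 1")


@dataclass
class SimulationConfig:
    """All knobs of the cohort generator; every field has a documented
    default so ``SimulationConfig(seed=...)`` is a complete study design."""

    seed: int
    n_families: int = 150
    # probability of a nuclear family having 1, 2 or 3 children
    family_size_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.30, 2: 0.45, 3: 0.25})
    n_taxa: int = 120
    # log-normal library sizes (natural-log scale): median ~ 10k reads
    library_size_mean_log: float = 9.2
    library_size_sd_log: float = 0.35
    baseline_log_abundance: np.ndarray | None = None
    dispersion: np.ndarray | float = 1.0  # NB size parameter per taxon
    disease_log2fc: np.ndarray | None = None
    ibd_prevalence: float = 0.45
    sample_noise_sd: float = 0.8
    dispersion_inflation_ibd: float = 2.0
    heritable_taxa: dict[str, float] = field(default_factory=dict)
    biomarker_coupling: dict[str, float] = field(default_factory=lambda: {
        "ASCA_IgA": 0.8, "ASCA_IgG": 0.8, "GP2_IgA": 0.5, "GP2_IgG": 0.5,
        "calprotectin": 1.0, "BSS": 0.6,
    })
    include_prs: bool = True
    cluster_spec: ClusterSpec | None = None
    # planted co-abundance couplings: (taxon_idx_a, taxon_idx_b, rho) applied
    # to the per-sample log-abundance noise; the ``ibd_`` list only in IBD
    coupling_pairs: tuple[tuple[int, int, float], ...] = ()
    ibd_coupling_pairs: tuple[tuple[int, int, float], ...] = ()
    n_disease_up: int = 12
    n_control_up: int = 12
    effect_log2fc: float = 2.0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise DysbiomeError("n_families must be >= 1")
        if self.n_taxa < 2:
            raise DysbiomeError("n_taxa must be >= 2")
        if not self.family_size_distribution:
            raise DysbiomeError("family_size_distribution must be non-empty")
        if any(k < 0 for k in self.family_size_distribution):
            raise DysbiomeError("invalid family template: negative child count")
        total = sum(self.family_size_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise DysbiomeError("family size probabilities must sum to 1")
        if not 0.0 <= self.ibd_prevalence <= 1.0:
            raise DysbiomeError("ibd_prevalence must be in [0, 1]")
        if self.sample_noise_sd <= 0 or self.library_size_sd_log <= 0:
            raise DysbiomeError("noise parameters must be strictly positive")
        disp = np.atleast_1d(np.asarray(self.dispersion, dtype=float))
        if (disp <= 0).any():
            raise DysbiomeError("NB size parameters must be strictly positive")
        if self.dispersion_inflation_ibd < 1.0:
            raise DysbiomeError("dispersion_inflation_ibd must be >= 1")
        for taxon, h2 in self.heritable_taxa.items():
            if not 0.0 <= h2 <= 0.95:
                raise DysbiomeError(
                    f"target h2 for {taxon} outside [0, 0.95]: infeasible "
                    "given the sampling noise")

    def taxon_ids(self) -> list[str]:
        return [f"ASV-{i + 1:03d}" for i in range(self.n_taxa)]

    def resolved_baseline(self) -> np.ndarray:
        """Default baseline: a smooth rank-abundance gradient spanning about
        e^6 between the most and least abundant taxon."""
        if self.baseline_log_abundance is not None:
            b = np.asarray(self.baseline_log_abundance, dtype=float)
            if len(b) != self.n_taxa:
                raise DysbiomeError("baseline length != n_taxa")
            return b
        return np.linspace(3.0, -3.0, self.n_taxa)

    def resolved_log2fc(self) -> np.ndarray:
        """Default disease effects: ``n_control_up`` abundant health-
        associated taxa down in IBD and ``n_disease_up`` mid-rank
        disease-associated taxa up in IBD, at |log2FC| = ``effect_log2fc``."""
        if self.disease_log2fc is not None:
            fc = np.asarray(self.disease_log2fc, dtype=float)
            if len(fc) != self.n_taxa:
                raise DysbiomeError("disease_log2fc length != n_taxa")
            return fc
        fc = np.zeros(self.n_taxa)
        ctrl = np.arange(5, 5 + self.n_control_up)
        dis = np.arange(self.n_taxa // 4, self.n_taxa // 4 + self.n_disease_up)
        if self.n_control_up and ctrl[-1] >= self.n_taxa:
            raise DysbiomeError("too few taxa for default effect layout")
        if self.n_disease_up and dis[-1] >= self.n_taxa:
            raise DysbiomeError("too few taxa for default effect layout")
        fc[ctrl] = -self.effect_log2fc
        fc[dis] = self.effect_log2fc
        return fc

    def resolved_dispersion(self) -> np.ndarray:
        disp = np.atleast_1d(np.asarray(self.dispersion, dtype=float))
        if disp.size == 1:
            return np.full(self.n_taxa, float(disp[0]))
        if disp.size != self.n_taxa:
            raise DysbiomeError("dispersion length != n_taxa")
        return disp


@dataclass
class SyntheticCohort:
    """A simulated cohort together with its ground truth."""

    counts: CountTable
    metadata: CohortMetadata
    pedigree: Pedigree
    kinship: KinshipMatrix
    truth: dict

    def write(self, outdir) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        self.counts.to_tsv(os.path.join(outdir, "counts.tsv"))
        self.metadata.to_tsv(os.path.join(outdir, "metadata.tsv"))
        self.pedigree.to_tsv(os.path.join(outdir, "pedigree.tsv"))
        truth = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in self.truth.items()
        }
        with open(os.path.join(outdir, "truth.json"), "w") as fh:
            json.dump(truth, fh, indent=1)


def simulate_dmm_counts(
    alpha_components: np.ndarray,
    weights: np.ndarray,
    n_samples: int,
    library_size: int = 5000,
    seed: int = 0,
) -> tuple[CountTable, np.ndarray]:
    """Draw counts exactly from a Dirichlet-multinomial mixture.

    Used to exercise the community-typing stage under its own generative
    model (the family-cohort generator produces log-normal overdispersion,
    which a Dirichlet-multinomial cannot represent).  Returns the table and
    the true component labels.
    """
    rng = np.random.default_rng(seed)
    alpha_components = np.atleast_2d(np.asarray(alpha_components, dtype=float))
    K, p = alpha_components.shape
    weights = np.asarray(weights, dtype=float)
    if len(weights) != K or abs(weights.sum() - 1.0) > 1e-9:
        raise DysbiomeError("weights must match components and sum to 1")
    labels = rng.choice(K, size=n_samples, p=weights)
    counts = np.empty((n_samples, p), dtype=np.int64)
    for i, k in enumerate(labels):
        comp = rng.dirichlet(alpha_components[k])
        counts[i] = rng.multinomial(library_size, comp)
    ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    taxa = [f"ASV-{j + 1:03d}" for j in range(p)]
    return CountTable(pd.DataFrame(counts, index=ids, columns=taxa)), labels


def generate_pedigree(config: SimulationConfig) -> Pedigree:
    """Nuclear families drawn from the configured family-size templates.

    Each family has two unrelated founders (father, mother) and a template
    number of children; sexes of parents follow their role, children are
    assigned at random.
    """
    rng = np.random.default_rng(config.seed)
    sizes = sorted(config.family_size_distribution)
    probs = [config.family_size_distribution[s] for s in sizes]
    rows = []
    for fam in range(config.n_families):
        fam_id = f"FAM{fam + 1:04d}"
        father = f"{fam_id}_P1"
        mother = f"{fam_id}_P2"
        rows.append((father, "", "", "M", fam_id))
        rows.append((mother, "", "", "F", fam_id))
        n_children = int(rng.choice(sizes, p=probs))
        for c in range(n_children):
            sex = "M" if rng.random() < 0.5 else "F"
            rows.append((f"{fam_id}_C{c + 1}", father, mother, sex, fam_id))
    df = pd.DataFrame(
        rows, columns=["subject_id", "father_id", "mother_id", "sex", "family_id"])
    return Pedigree(df)


def _cluster_shifts(spec: ClusterSpec, n_taxa: int, rng: np.random.Generator) -> np.ndarray:
    """Cluster-centre offsets: orthonormal zero-sum directions scaled so all
    pairwise Aitchison (= Euclidean on centred logs) distances equal
    ``separation``."""
    K = spec.n_clusters
    raw = rng.normal(size=(n_taxa, K))
    raw -= raw.mean(axis=0, keepdims=True)  # zero-sum: purely compositional
    q, _ = np.linalg.qr(raw)
    return (spec.separation / np.sqrt(2.0)) * q[:, :K].T  # K x n_taxa


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw one cohort (counts + metadata + pedigree + truth) from the
    configured generative model.  Identical config and seed give identical
    output."""
    rng = np.random.default_rng(config.seed)
    pedigree = generate_pedigree(config)
    kin = kinship_matrix(pedigree)
    subjects = pedigree.subject_ids
    n = len(subjects)
    ped = pedigree.data.set_index("subject_id")

    taxa = config.taxon_ids()
    baseline = config.resolved_baseline()
    log2fc = config.resolved_log2fc()
    disp = config.resolved_dispersion()

    # ---------------------------------------------------------- demography
    is_parent = ped["father_id"] == ""
    age = np.where(is_parent.loc[subjects],
                   rng.normal(52.0, 8.0, n), rng.normal(24.0, 6.0, n))
    age = np.clip(age, 7.0, 90.0)
    bmi = np.clip(rng.normal(25.0, 4.0, n), 15.0, 45.0)
    sex = ped.loc[subjects, "sex"].to_numpy()

    is_ibd = rng.random(n) < config.ibd_prevalence
    sub_dx = rng.choice(["CD", "UC", "uIBD"], size=n, p=[0.54, 0.43, 0.03])
    diagnosis = np.where(is_ibd, sub_dx, "Control")

    # ------------------------------------------------------ genetic effects
    genetic = np.zeros((n, config.n_taxa))
    h2_targets = {}
    if config.heritable_taxa:
        L = np.linalg.cholesky(kin.values + 1e-9 * np.eye(n))
        for taxon, h2 in config.heritable_taxa.items():
            if taxon not in taxa:
                raise DysbiomeError(f"heritable taxon {taxon!r} not in table")
            t = taxa.index(taxon)
            sigma_g = np.sqrt(h2 / (1.0 - h2)) * config.sample_noise_sd
            genetic[:, t] = sigma_g * (L @ rng.standard_normal(n))
            h2_targets[taxon] = h2

    # ------------------------------------------------------ planted clusters
    cluster_labels = np.zeros(n, dtype=int)
    cluster_offsets = np.zeros((n, config.n_taxa))
    if config.cluster_spec is not None:
        spec = config.cluster_spec
        shifts = _cluster_shifts(spec, config.n_taxa, rng)
        weights = spec.weights or tuple([1.0 / spec.n_clusters] * spec.n_clusters)
        cluster_labels = rng.choice(spec.n_clusters, size=n, p=list(weights))
        cluster_offsets = shifts[cluster_labels]

    # ------------------------------------------------------------- counts
    noise_scale = np.where(is_ibd,
                           config.sample_noise_sd * config.dispersion_inflation_ibd,
                           config.sample_noise_sd)
    eps = rng.standard_normal((n, config.n_taxa))
    for i, j, rho in config.coupling_pairs:
        eps[:, j] = rho * eps[:, i] + np.sqrt(1.0 - rho ** 2) * eps[:, j]
    for i, j, rho in config.ibd_coupling_pairs:
        eps[is_ibd, j] = (rho * eps[is_ibd, i]
                          + np.sqrt(1.0 - rho ** 2) * eps[is_ibd, j])
    eps = eps * noise_scale[:, None]
    lam = (baseline[None, :]
           + np.log(2.0) * log2fc[None, :] * is_ibd[:, None]
           + genetic + cluster_offsets + eps)
    lam -= lam.max(axis=1, keepdims=True)
    comp = np.exp(lam)
    comp /= comp.sum(axis=1, keepdims=True)

    library = rng.lognormal(config.library_size_mean_log,
                            config.library_size_sd_log, n)
    mu = library[:, None] * comp
    shape = np.broadcast_to(disp[None, :], mu.shape)
    gamma_mean = rng.gamma(shape, mu / shape)
    counts = rng.poisson(gamma_mean).astype(np.int64)

    # ------------------------------------------------ latent dysbiosis score
    w = np.log(2.0) * log2fc
    norm = np.linalg.norm(w)
    if norm > 0:
        dys = (lam @ w) / norm
        dys = (dys - dys.mean()) / (dys.std() if dys.std() > 0 else 1.0)
    else:
        dys = np.zeros(n)

    # ------------------------------------------------------------ biomarkers
    cpl = config.biomarker_coupling
    meta = pd.DataFrame({
        "sample_id": subjects,
        "subject_id": subjects,
        "family_id": ped.loc[subjects, "family_id"].to_numpy(),
        "time_point": "BL",
        "diagnosis": diagnosis,
        "age": np.round(age, 1),
        "sex": sex,
        "bmi": np.round(bmi, 2),
        "ASCA_IgA": cpl.get("ASCA_IgA", 0.0) * dys + rng.standard_normal(n),
        "ASCA_IgG": cpl.get("ASCA_IgG", 0.0) * dys + rng.standard_normal(n),
        "GP2_IgA": cpl.get("GP2_IgA", 0.0) * dys + rng.standard_normal(n),
        "GP2_IgG": cpl.get("GP2_IgG", 0.0) * dys + rng.standard_normal(n),
        "calprotectin": np.clip(
            50.0 + 40.0 * cpl.get("calprotectin", 0.0) * dys
            + rng.normal(0.0, 20.0, n), 0.0, None),
        "BSS": np.clip(np.round(
            4.0 + cpl.get("BSS", 0.0) * dys + rng.standard_normal(n)), 1, 7),
    })
    if config.include_prs:
        for col, dx in (("CD_PRS", "CD"), ("UC_PRS", "UC")):
            meta[col] = rng.standard_normal(n) + 0.5 * (diagnosis == dx)
        meta["IBD_PRS"] = rng.standard_normal(n) + 0.5 * is_ibd

    taxonomy = {
        t: f"Bacteria; {_GENUS_POOL[i % len(_GENUS_POOL)]}"
        for i, t in enumerate(taxa)
    }
    table = CountTable(pd.DataFrame(counts, index=subjects, columns=taxa),
                       taxonomy)
    truth = {
        "log2fc": log2fc,
        "h2_targets": h2_targets,
        "cluster_labels": cluster_labels,
        "latent_dysbiosis": dys,
        "is_ibd": is_ibd.astype(int),
        "config": {
            k: v for k, v in dataclasses.asdict(config).items()
            if isinstance(v, (int, float, str, bool))
        },
    }
    return SyntheticCohort(table, CohortMetadata(meta), pedigree, kin, truth)
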