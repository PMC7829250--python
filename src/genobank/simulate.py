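"""Synthetic gene-bank generator.

Emulates the structure of a large cereal gene-bank collection: several
subpopulations with divergent allele frequencies (Balding-Nichols model),
a major-gene categorical trait (spike-morphology / growth-habit analogue),
polygenic quantitative traits with high heritability and subpopulation mean
shifts, multi-year phenotype records, and configurable missingness in labels
and phenotypes.  Every emission is deterministic under the configured seed.

No linkage disequilibrium is simulated: GBLUP-type models act through the
realized relationship matrix, which Balding-Nichols drift plus binomial
sampling already provides at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "TraitSpec",
    "SimConfig",
    "SimTruth",
    "simulate_genotypes",
    "simulate_categorical",
    "simulate_quantitative",
    "nominate_core",
    "simulate_genebank",
]


@dataclass
class TraitSpec:
    """Specification of one polygenic quantitative trait.

    h2 is narrow-sense heritability on the single-record scale,
    sigma_g2 / (sigma_g2 + sigma_e2), with the genetic variance standardized
    to hit the target exactly in each realization.  ``subpop_shifts`` are
    non-genetic additive offsets per subpopulation (e.g. different scoring
    conventions).  ``effect_correlation`` is the correlation of QTL effects
    between subpopulations: 1.0 means a single shared architecture, smaller
    values erode across-population transferability.
    """

    name: str
    h2: float = 0.8
    n_qtl: int = 100
    subpop_shifts: tuple[float, ...] | None = None
    effect_correlation: float = 1.0
    mean: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")
        if not 0.0 <= self.effect_correlation <= 1.0:
            raise ValueError("effect_correlation must lie in [0, 1]")


@dataclass
class SimConfig:
    """Configuration of the synthetic gene-bank."""

    seed: int = 0
    n_per_subpop: tuple[int, ...] = (1000, 1000)
    m: int = 5000
    fst: float = 0.1
    n_class_loci: int | None = None  # default: one locus per subpopulation
    class_rule: str = "subpop_loci"  # or "single_locus"
    label_noise: float = 0.0
    missing_label_rate: float = 0.0
    traits: tuple[TraitSpec, ...] = (TraitSpec("trait1", h2=0.8, n_qtl=100),)
    years: tuple[int, ...] = (2015, 2016, 2017, 2018, 2019)
    records_per_accession: tuple[int, int] = (3, 5)
    sigma_year2: float = 1.0
    missing_phenotype_rate: float = 0.0
    core_fraction: float = 0.1

    def __post_init__(self):
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must lie in [0, 1)")
        for r in (self.label_noise, self.missing_label_rate, self.missing_phenotype_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")

    @property
    def n(self) -> int:
        return int(sum(self.n_per_subpop))

    @property
    def k_subpops(self) -> int:
        return len(self.n_per_subpop)


@dataclass
class SimTruth:
    """Ground truth of a simulation run, for parameter-recovery checks."""

    subpop: pd.Series  # accession -> subpopulation label
    true_g: pd.DataFrame = field(default_factory=pd.DataFrame)  # accession x trait
    true_class: pd.Series | None = None
    variance_components: dict = field(default_factory=dict)  # trait -> (sigma_g2, sigma_e2)
    qtl: dict = field(default_factory=dict)  # trait -> (marker indices, effects per subpop)
    class_loci: np.ndarray | None = None
    year_effects: pd.Series | None = None
    ancestral_freqs: np.ndarray | None = None
    subpop_freqs: np.ndarray | None = None


def _subpop_labels(cfg: SimConfig) -> np.ndarray:
    return np.repeat([f"pop{i + 1}" for i in range(cfg.k_subpops)], cfg.n_per_subpop)


def simulate_genotypes(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Balding-Nichols structured genotypes.

    Ancestral frequencies ~ Uniform(0.05, 0.95); subpopulation frequencies
    ~ Beta(p(1-F)/F, (1-p)(1-F)/F); genotypes ~ Binomial(2, p_sub).  With
    ``class_rule='subpop_loci'`` the first K markers are reserved as
    major-gene class loci with strongly divergent frequencies (about 0.9 in
    the matching subpopulation, 0.05 elsewhere), the analogue of a
    morphological key trait that also marks population structure.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    K, m = cfg.k_subpops, cfg.m
    p_anc = rng.uniform(0.05, 0.95, size=m)
    if cfg.fst > 0:
        a = p_anc * (1.0 - cfg.fst) / cfg.fst
        b = (1.0 - p_anc) * (1.0 - cfg.fst) / cfg.fst
        p_sub = rng.beta(a, b, size=(K, m))
    else:
        p_sub = np.tile(p_anc, (K, 1))
    n_class = cfg.n_class_loci if cfg.n_class_loci is not None else K
    class_loci = np.arange(min(n_class, m))
    if cfg.class_rule == "subpop_loci":
        for j, locus in enumerate(class_loci):
            owner = j % K
            for k in range(K):
                p_sub[k, locus] = 0.9 if k == owner else 0.05
    subpop = _subpop_labels(cfg)
    dosages = np.empty((cfg.n, m), dtype=float)
    start = 0
    for k, nk in enumerate(cfg.n_per_subpop):
        dosages[start : start + nk] = rng.binomial(2, p_sub[k], size=(nk, m))
        start += nk
    ids = [f"ACC{i:05d}" for i in range(cfg.n)]
    geno = GenotypeMatrix(ids, [f"M{j:05d}" for j in range(m)], dosages)
    truth = SimTruth(
        subpop=pd.Series(subpop, index=ids, name="subpop"),
        class_loci=class_loci,
        ancestral_freqs=p_anc,
        subpop_freqs=p_sub,
    )
    return geno, truth


def simulate_categorical(
    geno: GenotypeMatrix,
    cfg: SimConfig,
    truth: SimTruth,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Major-gene categorical trait with optional label noise and missingness.

    ``subpop_loci`` rule: class = argmax over class loci of the dosage
    (ties broken by lowest locus index), one class per locus.
    ``single_locus`` rule: dosage at the first class locus >= 1 -> class 'B',
    else class 'A'.  Returns the *observed* labels (with noise and missing
    entries); the noiseless truth is stored in ``truth.true_class``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    loci = truth.class_loci
    if loci is None or np.any(loci >= geno.m):
        raise ValueError("class loci must be a subset of the markers")
    D = geno.dosages[:, loci]
    if cfg.class_rule == "single_locus":
        classes = np.where(D[:, 0] >= 1.0, "B", "A")
        class_names = np.array(["A", "B"])
    else:
        class_names = np.array([f"class{chr(65 + (j % 26))}" for j in range(len(loci))])
        classes = class_names[np.argmax(D, axis=1)]
    true_class = pd.Series(classes, index=geno.accession_ids, name="class")
    truth.true_class = true_class
    observed = true_class.copy()
    if cfg.label_noise > 0:
        flip = rng.random(geno.n) < cfg.label_noise
        pool = np.unique(classes)
        for i in np.flatnonzero(flip):
            others = pool[pool != observed.iloc[i]]
            if len(others):
                observed.iloc[i] = rng.choice(others)
    if cfg.missing_label_rate > 0:
        miss = rng.random(geno.n) < cfg.missing_label_rate
        observed[miss] = pd.NA
    return observed


def simulate_quantitative(
    geno: GenotypeMatrix,
    cfg: SimConfig,
    truth: SimTruth,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Polygenic traits and multi-year phenotype records.

    For each trait, QTL are drawn from the non-class markers with effects
    shared across subpopulations at the configured correlation; the genetic
    values are standardized so the realized single-record heritability
    equals the target exactly; records are ``value = mean + subpop shift +
    g + year effect + residual`` over 3-5 years per accession.

    Returns a long-format record table (accession, trait, year, value).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    ids = geno.accession_ids
    n = geno.n
    subpop = truth.subpop.to_numpy()
    pops = [f"pop{i + 1}" for i in range(cfg.k_subpops)]
    pop_index = np.array([pops.index(s) for s in subpop])
    n_class = len(truth.class_loci) if truth.class_loci is not None else 0
    candidate_loci = np.arange(n_class, geno.m)

    year_eff = pd.Series(
        rng.normal(0.0, np.sqrt(cfg.sigma_year2), size=len(cfg.years)),
        index=list(cfg.years),
        name="year_effect",
    )
    truth.year_effects = year_eff

    rows = []
    true_g = {}
    for trait in cfg.traits:
        if trait.n_qtl > len(candidate_loci):
            raise ValueError("n_qtl exceeds available markers")
        qtl = rng.choice(candidate_loci, size=trait.n_qtl, replace=False)
        shared = rng.normal(size=trait.n_qtl)
        rho = trait.effect_correlation
        effects = np.empty((cfg.k_subpops, trait.n_qtl))
        for k in range(cfg.k_subpops):
            specific = rng.normal(size=trait.n_qtl)
            effects[k] = rho * shared + np.sqrt(1.0 - rho**2) * specific
        Wq = geno.dosages[:, qtl] - geno.dosages[:, qtl].mean(axis=0)
        g_raw = np.einsum("ij,ij->i", Wq, effects[pop_index])
        sd = g_raw.std()
        if sd == 0:
            sd = 1.0
        if trait.h2 > 0:
            g = g_raw / sd * np.sqrt(trait.h2)
            sigma_g2 = trait.h2
        else:
            g = np.zeros(n)
            sigma_g2 = 0.0
        sigma_e2 = max(1.0 - trait.h2, 1e-12)
        true_g[trait.name] = g
        truth.variance_components[trait.name] = (sigma_g2, sigma_e2)
        truth.qtl[trait.name] = (qtl, effects)

        shifts = np.asarray(
            trait.subpop_shifts
            if trait.subpop_shifts is not None
            else np.zeros(cfg.k_subpops),
            dtype=float,
        )
        has_pheno = rng.random(n) >= cfg.missing_phenotype_rate
        lo, hi = cfg.records_per_accession
        n_rec = rng.integers(lo, hi + 1, size=n)
        for i in range(n):
            if not has_pheno[i]:
                continue
            yrs = rng.choice(list(cfg.years), size=min(n_rec[i], len(cfg.years)), replace=False)
            for yr in yrs:
                val = (
                    trait.mean
                    + shifts[pop_index[i]]
                    + g[i]
                    + year_eff.loc[yr]
                    + rng.normal(0.0, np.sqrt(sigma_e2))
                )
                rows.append((ids[i], trait.name, int(yr), val))
    truth.true_g = pd.DataFrame(true_g, index=ids)
    return pd.DataFrame(rows, columns=["accession", "trait", "year", "value"])


def nominate_core(
    subpop: pd.Series, fraction: float, seed: int, strategy: str = "stratified_random"
) -> list[str]:
    """Stratified random core set: `fraction` of each subpopulation, seeded.

    A stand-in for an externally curated core collection; must leave a
    non-empty remainder to serve as a test set.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    if strategy != "stratified_random":
        raise ValueError(f"unknown strategy {strategy!r}")
    rng = np.random.default_rng(seed)
    core: list[str] = []
    for _, ids in subpop.groupby(subpop):
        members = list(ids.index)
        k = int(round(fraction * len(members)))
        k = min(k, len(members) - 1)
        if k > 0:
            core.extend(rng.choice(members, size=k, replace=False))
    if len(core) >= len(subpop):
        raise ValueError("core covers the whole population; no test set remains")
    return sorted(core)


def simulate_genebank(cfg: SimConfig):
    """Full simulation bundle: genotypes, labels, records, core ids, truth.

    Per-stage generators are derived deterministically from ``cfg.seed`` so
    that each stage is reproducible in isolation.
    """
    geno, truth = simulate_genotypes(cfg)
    labels = simulate_categorical(geno, cfg, truth)
    records = simulate_quantitative(geno, cfg, truth)
    core = nominate_core(truth.subpop, cfg.core_fraction, cfg.seed + 3)
    return geno, labels, records, core, truth
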