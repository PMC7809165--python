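"""Synthetic cohorts with planted microbiome-mediated genetic effects.

The generator emulates a commercial swine trial: 0/1/2 SNP dosages, a
cross-classified husbandry design (contemporary groups, pens nested within
them, sires, two dam lines), rarefied zero-inflated OTU counts whose
(latent) CLR abundances respond to marker dosages, and correlated
fat-deposition-style traits that load on latent factors. Every planted
effect is recorded in a :class:`TruthSet` so downstream fits can be scored
for parameter recovery.

Data-generating chain per individual i:

1.  marker dosage  G_ij ~ Binomial(2, MAF_j),  MAF_j ~ U(maf_range)
2.  latent log-abundance  z_ik = base_k + sum alpha * G + design + noise
    counts ~ Multinomial(depth, softmax(z_i)) — low-proportion features
    drop out of the finite multinomial draw, producing zero inflation
    without a separate hurdle model
3.  factor score  f_il = sum gamma' * G + sum beta * clr(z)_i + design + e
4.  trait  y_ip = loading * f + uniqueness noise (plus any trait-targeted
    effects)

The noiseless mediator seen by step 3 is the row-centered latent
log-abundance, which equals clr(softmax(z)); the observed CLR (from counts)
is this plus multinomial sampling noise, so mediated signals attenuate the
way real rarefied data would. Four independent RNG streams (genotype /
design / microbiome / phenotype) are spawned from the master seed so layers
can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compositions import OtuTable

__all__ = [
    "SimConfig",
    "TruthSet",
    "GenotypeMatrix",
    "CohortData",
    "simulate_cohort",
    "smoke_config",
    "full_scale_config",
]

N_CHROMOSOMES = 18


@dataclass
class GenotypeMatrix:
    """Individuals x markers minor-allele dosages with marker metadata."""

    dosages: pd.DataFrame
    marker_info: pd.DataFrame  # columns: marker, chrom, index (panel order), pos

    @property
    def markers(self) -> list[str]:
        return list(self.dosages.columns)


@dataclass
class SimConfig:
    """Generator settings; defaults give the smoke-scale cohort.

    Effect specs are lists of triples:
    ``genetic_effects``  (marker, otu, alpha)   — G -> latent CLR abundance
    ``mediator_effects`` (otu, target, beta)    — CLR abundance -> trait/factor
    ``direct_effects``   (marker, target, gamma)— G -> trait/factor
    where ``target`` is a trait id or a latent-factor name. ``loadings``
    maps factor -> list of (trait, loading, uniqueness_variance).
    """

    n_individuals: int = 500
    n_markers: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_otus: int = 100
    rarefaction_depth: int = 10_000
    n_cg: int = 12
    n_sires: int = 28
    n_pens: int = 331
    n_damlines: int = 2
    genetic_effects: list[tuple[str, str, float]] = field(default_factory=list)
    mediator_effects: list[tuple[str, str, float]] = field(default_factory=list)
    direct_effects: list[tuple[str, str, float]] = field(default_factory=list)
    loadings: dict[str, list[tuple[str, float, float]]] = field(
        default_factory=lambda: {
            "FATg": [("BF1", 1.0, 0.30), ("BF2", 0.85, 0.30), ("BF3", 0.70, 0.30)],
            "FATt": [("BF4", 1.0, 0.30), ("BFt", 0.80, 0.30), ("BEL", 0.60, 0.30)],
        }
    )
    var_cg: float = 0.15
    var_pen: float = 0.05
    var_sire: float = 0.10
    var_resid: float = 0.60
    damline_effect: float = 0.10
    otu_baseline_sd: float = 2.0
    otu_noise_sd: float = 1.0
    otu_stage: str = "S2"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_individuals", "n_markers", "n_otus", "rarefaction_depth",
                     "n_cg", "n_sires", "n_pens", "n_damlines"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.n_pens < self.n_cg:
            raise ValueError("need at least one pen per contemporary group")
        for name in ("var_cg", "var_pen", "var_sire", "var_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for factor, entries in self.loadings.items():
            for trait, _, uniq in entries:
                if uniq < 0:
                    raise ValueError(
                        f"uniqueness variance for {trait} ({factor}) negative"
                    )

    # id helpers -----------------------------------------------------------
    def marker_ids(self) -> list[str]:
        return [f"snp{j:05d}" for j in range(self.n_markers)]

    def otu_ids(self) -> list[str]:
        return [f"otu{j:04d}" for j in range(self.n_otus)]

    def trait_ids(self) -> list[str]:
        return [t for entries in self.loadings.values() for t, _, _ in entries]

    def factor_ids(self) -> list[str]:
        return list(self.loadings)

    def validate_effects(self) -> None:
        markers = set(self.marker_ids())
        otus = set(self.otu_ids())
        targets = set(self.trait_ids()) | set(self.factor_ids())
        for m, o, _ in self.genetic_effects:
            if m not in markers:
                raise ValueError(f"genetic effect references unknown marker {m!r}")
            if o not in otus:
                raise ValueError(f"genetic effect references unknown OTU {o!r}")
        for o, t, _ in self.mediator_effects:
            if o not in otus:
                raise ValueError(f"mediator effect references unknown OTU {o!r}")
            if t not in targets:
                raise ValueError(f"mediator effect references unknown target {t!r}")
        for m, t, _ in self.direct_effects:
            if m not in markers:
                raise ValueError(f"direct effect references unknown marker {m!r}")
            if t not in targets:
                raise ValueError(f"direct effect references unknown target {t!r}")


@dataclass
class TruthSet:
    """Planted parameters and realized latent quantities, pre-noise."""

    genetic_effects: list[tuple[str, str, float]]
    mediator_effects: list[tuple[str, str, float]]
    direct_effects: list[tuple[str, str, float]]
    loadings: dict[str, list[tuple[str, float, float]]]
    factor_scores: pd.DataFrame
    mafs: pd.Series
    cg_effects: np.ndarray
    pen_effects: np.ndarray
    sire_effects: np.ndarray
    latent_clr: pd.DataFrame


@dataclass
class CohortData:
    """Bundle of one simulated cohort plus its ground truth."""

    genotypes: GenotypeMatrix
    otus: OtuTable
    phenotypes: pd.DataFrame
    design: pd.DataFrame
    truth: TruthSet
    config: SimConfig


def _balanced_labels(labels: list, n: int, rng: np.random.Generator) -> np.ndarray:
    reps = np.tile(labels, n // len(labels) + 1)[:n]
    return reps[rng.permutation(n)]


def simulate_cohort(config: SimConfig) -> CohortData:
    """Generate one cohort; identical config (incl. seed) is bit-identical."""
    config.validate_effects()
    n = config.n_individuals
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    rng_geno = np.random.default_rng(seeds[0])
    rng_design = np.random.default_rng(seeds[1])
    rng_micro = np.random.default_rng(seeds[2])
    rng_pheno = np.random.default_rng(seeds[3])

    ids = [f"id{i:05d}" for i in range(n)]
    markers = config.marker_ids()
    otus = config.otu_ids()

    # --- genotypes --------------------------------------------------------
    lo, hi = config.maf_range
    mafs = rng_geno.uniform(lo, hi, size=config.n_markers)
    dosage = rng_geno.binomial(2, mafs, size=(n, config.n_markers)).astype(np.int8)
    chrom = 1 + (np.arange(config.n_markers) * N_CHROMOSOMES) // config.n_markers
    within = np.zeros(config.n_markers, dtype=int)
    for c in range(1, N_CHROMOSOMES + 1):
        mask = chrom == c
        within[mask] = np.arange(mask.sum())
    marker_info = pd.DataFrame(
        {"marker": markers, "chrom": chrom, "index": within,
         "pos": (within + 1) * 50_000}
    )
    genotypes = GenotypeMatrix(
        dosages=pd.DataFrame(dosage, index=ids, columns=markers),
        marker_info=marker_info,
    )

    # --- design: pens nested within contemporary groups -------------------
    cg = _balanced_labels(list(range(1, config.n_cg + 1)), n, rng_design)
    pens_per_cg = np.array_split(np.arange(1, config.n_pens + 1), config.n_cg)
    pen = np.zeros(n, dtype=int)
    for level, pens in zip(range(1, config.n_cg + 1), pens_per_cg):
        mask = cg == level
        pen[mask] = pens[rng_design.integers(0, len(pens), size=mask.sum())]
    sire = _balanced_labels(list(range(1, config.n_sires + 1)), n, rng_design)
    damline = _balanced_labels(list(range(1, config.n_damlines + 1)), n, rng_design)
    design = pd.DataFrame(
        {"cg": cg, "damline": damline, "sire": sire, "pen": pen}, index=ids
    )

    cg_eff = rng_design.normal(0, np.sqrt(config.var_cg), config.n_cg)
    pen_eff = rng_design.normal(0, np.sqrt(config.var_pen), config.n_pens)
    sire_eff = rng_design.normal(0, np.sqrt(config.var_sire), config.n_sires)
    design_value = (
        cg_eff[cg - 1] + pen_eff[pen - 1] + sire_eff[sire - 1]
        + config.damline_effect * (damline - 1.5)
    )

    # --- microbiome -------------------------------------------------------
    base = rng_micro.normal(0, config.otu_baseline_sd, config.n_otus)
    z = np.tile(base, (n, 1))
    z += rng_micro.normal(0, config.otu_noise_sd, size=(n, config.n_otus))
    z += design_value[:, None] * 0.5  # shared husbandry imprint on the flora
    otu_pos = {o: j for j, o in enumerate(otus)}
    marker_pos = {m: j for j, m in enumerate(markers)}
    for m, o, alpha in config.genetic_effects:
        z[:, otu_pos[o]] += alpha * dosage[:, marker_pos[m]]
    latent_clr = z - z.mean(axis=1, keepdims=True)  # clr of softmax(z)
    props = np.exp(z - z.max(axis=1, keepdims=True))
    props /= props.sum(axis=1, keepdims=True)
    counts = np.vstack(
        [rng_micro.multinomial(config.rarefaction_depth, p) for p in props]
    )
    otu_table = OtuTable(
        data=pd.DataFrame(counts, index=ids, columns=otus),
        stage=config.otu_stage,
        kind="counts",
    )

    # --- phenotypes -------------------------------------------------------
    factor_scores = {}
    trait_extra: dict[str, np.ndarray] = {}
    for factor in config.factor_ids():
        score = design_value + rng_pheno.normal(0, np.sqrt(config.var_resid), n)
        for m, t, gamma in config.direct_effects:
            if t == factor:
                score = score + gamma * dosage[:, marker_pos[m]]
        for o, t, beta in config.mediator_effects:
            if t == factor:
                score = score + beta * latent_clr[:, otu_pos[o]]
        factor_scores[factor] = score
    traits = {}
    for factor, entries in config.loadings.items():
        for trait, loading, uniq in entries:
            y = loading * factor_scores[factor]
            if uniq > 0:
                y = y + rng_pheno.normal(0, np.sqrt(uniq), n)
            for m, t, gamma in config.direct_effects:
                if t == trait:
                    y = y + gamma * dosage[:, marker_pos[m]]
            for o, t, beta in config.mediator_effects:
                if t == trait:
                    y = y + beta * latent_clr[:, otu_pos[o]]
            traits[trait] = y
    phenotypes = pd.DataFrame(traits, index=ids)

    truth = TruthSet(
        genetic_effects=list(config.genetic_effects),
        mediator_effects=list(config.mediator_effects),
        direct_effects=list(config.direct_effects),
        loadings={k: list(v) for k, v in config.loadings.items()},
        factor_scores=pd.DataFrame(factor_scores, index=ids),
        mafs=pd.Series(mafs, index=markers),
        cg_effects=cg_eff,
        pen_effects=pen_eff,
        sire_effects=sire_eff,
        latent_clr=pd.DataFrame(latent_clr, index=ids, columns=otus),
    )
    return CohortData(genotypes, otu_table, phenotypes, design, truth, config)


def smoke_config(**overrides) -> SimConfig:
    """Small default cohort: 500 individuals, 2,000 markers, 100 OTUs."""
    return SimConfig(**overrides)


def full_scale_config(**overrides) -> SimConfig:
    """Full-scale preset matching the study cohort: 1,183 individuals,
    40,542 markers on 18 autosomes, 12 contemporary groups, 28 sires,
    331 pens, 2 dam lines, counts rarefied to 10,000."""
    defaults = dict(
        n_individuals=1183,
        n_markers=40_542,
        n_otus=300,
        rarefaction_depth=10_000,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)
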