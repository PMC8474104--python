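"""Synthetic cohort generator.

Builds phased haplotype panels by mosaic copying from a founder pool, with a
deletion allele seeded on a configurable number of independent founder
backgrounds (recurrent origins). Copy-number dependent probe intensities and
a logistic case/control phenotype with confounding covariates complete the
dataset, so every downstream stage can be exercised without real cohort data.

The number of deletion origins is the lever controlling marker-deletion LD:
one origin yields a single shared flanking haplotype (high r-squared with its
private markers), many origins scatter the deletion across unrelated
backgrounds and destroy LD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import HaplotypePanel, RecombinationMap
from .tables import ETHNICITY_DEFAULT, IntensityTable, PhenotypeTable


class ConfigError(ValueError):
    """Invalid simulation configuration."""


# Region layout loosely modelled on a sub-telomeric 400kb window with the
# deletion near the middle of a low-recombination core.
REGION_START = 84_870
REGION_END = 398_421
DELETION_POS = 223_493


@dataclass
class IntensityParams:
    """Per-copy-number summed-intensity model and channel-split noise.

    means/sds are indexed by probe copy number 0,1,2 (copy number =
    2 - deletion genotype). Defaults reproduce heavily overlapping class
    densities with troughs near 0.2 and 0.5-0.9.
    """

    means: tuple[float, float, float] = (0.15, 0.45, 0.80)
    sds: tuple[float, float, float] = (0.07, 0.10, 0.12)
    control_mean: float = 0.75
    control_sd: float = 0.10
    split_noise_sd: float = 0.05

    def validate(self) -> None:
        if not (self.means[0] < self.means[1] < self.means[2]):
            raise ConfigError("intensity means must strictly increase with copy number")
        if any(s < 0 for s in self.sds) or self.control_sd < 0 or self.split_noise_sd < 0:
            raise ConfigError("intensity SDs must be non-negative")


@dataclass
class PhenoParams:
    """Logistic disease model: protective deletion plus confounders."""

    baseline_case_prob: float = 0.55
    or_het: float = 0.79
    or_hom: float = 0.59
    sex_effect_or: float = 1.15
    ethnicity_labels: tuple[str, ...] = ETHNICITY_DEFAULT
    ethnicity_freqs: tuple[float, ...] = (0.492, 0.312, 0.089, 0.107)
    ethnicity_ors: tuple[float, ...] = (1.0, 0.9, 1.1, 1.0)
    rs334_freq: float = 0.054
    rs334_or: float = 0.25

    def validate(self) -> None:
        if not 0 < self.baseline_case_prob < 1:
            raise ConfigError("baseline_case_prob must be in (0,1)")
        if self.or_het <= 0 or self.or_hom <= 0 or self.rs334_or <= 0 or self.sex_effect_or <= 0:
            raise ConfigError("odds ratios must be > 0")
        if len(self.ethnicity_labels) != len(self.ethnicity_freqs) or \
                len(self.ethnicity_labels) != len(self.ethnicity_ors):
            raise ConfigError("ethnicity parameter lengths differ")
        if abs(sum(self.ethnicity_freqs) - 1.0) > 1e-6:
            raise ConfigError("ethnicity frequencies must sum to 1")
        if not 0 <= self.rs334_freq <= 1:
            raise ConfigError("rs334_freq must be in [0,1]")


@dataclass
class SimulationConfig:
    n_individuals: int = 3036
    n_flank_snps: int = 178
    n_del_probes: int = 6
    n_control_probes: int = 3
    del_freq: float = 0.382
    n_del_origins: int = 8
    # fraction of an origin background's chromosomes that carry the deletion;
    # interpolates from 1 (single old origin) toward this floor as origins
    # multiply, so recurrent backgrounds exist with and without the deletion
    origin_penetrance_floor: float | None = None
    n_founders: int = 30
    recomb_rate_cM_per_Mb: float = 1.0
    copy_switch_scale: float = 50.0  # multiplies cM distance into switch hazard
    recomb_map: RecombinationMap | None = None
    intensity_params: IntensityParams = field(default_factory=IntensityParams)
    pheno_params: PhenoParams = field(default_factory=PhenoParams)
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 1:
            raise ConfigError("n_individuals must be >= 1")
        if not 0.0 <= self.del_freq <= 1.0:
            raise ConfigError("del_freq must be in [0,1]")
        if self.n_del_origins < 1:
            raise ConfigError("n_del_origins must be >= 1")
        if self.n_del_origins > self.n_founders:
            raise ConfigError(
                f"n_del_origins ({self.n_del_origins}) exceeds n_founders ({self.n_founders})")
        if self.n_flank_snps < 1:
            raise ConfigError("need at least one flanking SNP")
        if self.copy_switch_scale < 0 or self.recomb_rate_cM_per_Mb < 0:
            raise ConfigError("rates must be non-negative")
        if self.origin_penetrance_floor is not None and not \
                0 < self.origin_penetrance_floor <= 1:
            raise ConfigError("origin_penetrance_floor must be in (0,1]")
        self.intensity_params.validate()
        self.pheno_params.validate()

    def origin_penetrance(self) -> float:
        """P(deletion | origin background), shrinking with origin count."""
        floor = self.origin_penetrance_floor
        if floor is None:
            floor = min(1.0, max(0.45, self.del_freq / 0.95))
        pi = 1.0 - (1.0 - floor) * (1.0 - 1.0 / self.n_del_origins)
        return max(pi, self.del_freq / 0.999)  # keep background weight feasible


def _variant_grid(config: SimulationConfig) -> tuple[np.ndarray, list[str], int]:
    """Evenly spaced flanking SNP positions with the deletion inserted."""
    flank = np.linspace(REGION_START, REGION_END, config.n_flank_snps).astype(np.int64)
    flank = np.unique(flank)
    while len(flank) < config.n_flank_snps:  # guard against collisions at tiny spans
        flank = np.unique(np.concatenate([flank, flank[-1:] + 1]))
    del_idx = int(np.searchsorted(flank, DELETION_POS))
    positions = np.insert(flank, del_idx, DELETION_POS)
    ids = [f"snp{i:04d}" for i in range(len(flank))]
    ids.insert(del_idx, "DEL")
    return positions, ids, del_idx


def _founder_pool(config: SimulationConfig, rng: np.random.Generator,
                  n_variants: int, del_idx: int) -> tuple[np.ndarray, np.ndarray]:
    """Founder haplotypes and their copying weights.

    Each founder receives a couple of private marker alleles so that a
    single-origin deletion is taggable by flanking variation; origin founders
    jointly carry copying weight del_freq.
    """
    n_f = config.n_founders
    freqs = rng.uniform(0.1, 0.9, size=n_variants)
    founders = (rng.random((n_f, n_variants)) < freqs).astype(np.int8)
    flank_cols = np.array([j for j in range(n_variants) if j != del_idx])
    n_private = min(len(flank_cols), 2 * n_f)
    private_cols = rng.choice(flank_cols, size=n_private, replace=False)
    for k, col in enumerate(private_cols):
        founders[:, col] = 0
        founders[k % n_f, col] = 1
    origins = rng.choice(n_f, size=config.n_del_origins, replace=False)
    founders[:, del_idx] = 0
    founders[origins, del_idx] = 1
    pi = config.origin_penetrance()
    origin_weight = config.del_freq / pi  # total copying weight on origin backgrounds
    weights = np.full(n_f, (1.0 - origin_weight) / (n_f - config.n_del_origins)
                      if n_f > config.n_del_origins else 0.0)
    weights[origins] = origin_weight / config.n_del_origins
    weights /= weights.sum()
    return founders, weights


def simulate_haplotype_panel(config: SimulationConfig,
                             rng: np.random.Generator | None = None) -> HaplotypePanel:
    """Mosaic-copying panel of 2*n_individuals chromosomes.

    Each chromosome copies founder haplotypes left to right, switching
    founders between adjacent variants with probability
    1 - exp(-copy_switch_scale * distance_cM); founder draws follow weights
    that fix the expected deletion frequency at del_freq.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    positions, ids, del_idx = _variant_grid(config)
    n_var = len(positions)
    founders, weights = _founder_pool(config, rng, n_var, del_idx)

    rmap = config.recomb_map or RecombinationMap.uniform(positions, config.recomb_rate_cM_per_Mb)
    cum_cm = rmap.cumulative_at(positions)
    d_cm = np.diff(cum_cm)
    p_switch = 1.0 - np.exp(-config.copy_switch_scale * np.maximum(d_cm, 0.0))

    n_chrom = 2 * config.n_individuals
    path = np.empty((n_chrom, n_var), dtype=np.int32)
    path[:, 0] = rng.choice(config.n_founders, size=n_chrom, p=weights)
    for j in range(1, n_var):
        switch = rng.random(n_chrom) < p_switch[j - 1]
        path[:, j] = path[:, j - 1]
        k = int(switch.sum())
        if k:
            path[switch, j] = rng.choice(config.n_founders, size=k, p=weights)
    alleles = founders[path, np.arange(n_var)[None, :]]
    # penetrance thinning: only part of an origin background carries the
    # deletion, so recurrent haplotypes segregate both with and without it
    pi = config.origin_penetrance()
    if pi < 1.0:
        on_origin = alleles[:, del_idx] == 1
        carry = rng.random(n_chrom) < pi
        alleles[:, del_idx] = (on_origin & carry).astype(np.int8)
    return HaplotypePanel(alleles=alleles, variant_ids=ids,
                          positions_bp=positions, del_index=del_idx)


def pair_into_diploids(panel: HaplotypePanel) -> np.ndarray:
    """Diploid genotypes {0,1,2}: consecutive chromosome pairs summed."""
    return panel.genotypes()


def simulate_intensities(del_genotypes: np.ndarray, config: SimulationConfig,
                         rng: np.random.Generator | None = None,
                         individual_ids: list[str] | None = None) -> IntensityTable:
    """Two-channel probe intensities.

    Deletion probes: summed intensity s ~ Normal(mean[c], sd[c]) with c the
    probe copy number 2 - genotype, clipped at 0; split into (x, y) by a
    per-probe HWE allele ratio plus noise so x + y = s exactly. Control
    probes are genotype-independent three-cluster SNP intensities.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    g = np.asarray(del_genotypes, dtype=int)
    n = len(g)
    ids = individual_ids if individual_ids is not None else [f"ind{i:05d}" for i in range(n)]
    ip = config.intensity_params
    means = np.asarray(ip.means)
    sds = np.asarray(ip.sds)

    rows = []
    copy_number = 2 - g
    for k in range(config.n_del_probes):
        s = rng.normal(means[copy_number], sds[copy_number])
        s = np.clip(s, 0.0, None)
        f = rng.uniform(0.2, 0.8)
        probe_geno = rng.binomial(2, f, size=n)
        ratio = np.clip(probe_geno / 2.0 + rng.normal(0.0, ip.split_noise_sd, size=n), 0.0, 1.0)
        x = s * ratio
        rows.append(pd.DataFrame({"individual_id": ids, "probe_id": f"delprobe{k+1}",
                                  "x": x, "y": s - x}))
    for k in range(config.n_control_probes):
        s = np.clip(rng.normal(ip.control_mean, ip.control_sd, size=n), 0.0, None)
        f = rng.uniform(0.2, 0.8)
        probe_geno = rng.binomial(2, f, size=n)
        ratio = np.clip(probe_geno / 2.0 + rng.normal(0.0, ip.split_noise_sd, size=n), 0.0, 1.0)
        x = s * ratio
        rows.append(pd.DataFrame({"individual_id": ids, "probe_id": f"control{k+1}",
                                  "x": x, "y": s - x}))
    df = pd.concat(rows, ignore_index=True)
    del_probes = [f"delprobe{k+1}" for k in range(config.n_del_probes)]
    return IntensityTable(df=df, deletion_probes=del_probes)


def simulate_phenotypes(del_genotypes: np.ndarray, config: SimulationConfig,
                        rng: np.random.Generator | None = None,
                        individual_ids: list[str] | None = None) -> PhenotypeTable:
    """Case/control status from a logistic model with confounders.

    Linear predictor: logit(baseline) + log(or_het)[g=1] + log(or_hom)[g=2]
    + log(sex_or)*sex + ethnicity effect + log(rs334_or)*rs334 dosage.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    g = np.asarray(del_genotypes, dtype=int)
    n = len(g)
    ids = individual_ids if individual_ids is not None else [f"ind{i:05d}" for i in range(n)]
    pp = config.pheno_params

    sex = rng.integers(0, 2, size=n)
    eth_idx = rng.choice(len(pp.ethnicity_labels), size=n, p=np.asarray(pp.ethnicity_freqs))
    ethnicity = np.asarray(pp.ethnicity_labels)[eth_idx]
    rs334 = rng.binomial(2, pp.rs334_freq, size=n)

    lp = (np.log(pp.baseline_case_prob / (1 - pp.baseline_case_prob))
          + np.log(pp.or_het) * (g == 1)
          + np.log(pp.or_hom) * (g == 2)
          + np.log(pp.sex_effect_or) * sex
          + np.log(np.asarray(pp.ethnicity_ors))[eth_idx]
          + np.log(pp.rs334_or) * rs334)
    p_case = 1.0 / (1.0 + np.exp(-lp))
    status = (rng.random(n) < p_case).astype(int)
    df = pd.DataFrame({"individual_id": ids, "status": status, "sex": sex,
                       "ethnicity": ethnicity, "rs334_genotype": rs334})
    return PhenotypeTable(df=df)


@dataclass
class Dataset:
    """Bundle of all simulated components with consistent individual ids."""

    panel: HaplotypePanel
    intensities: IntensityTable
    phenotypes: PhenotypeTable
    recomb_map: RecombinationMap

    def __post_init__(self) -> None:
        ids = self.panel.individual_ids
        if self.intensities.individuals != ids or self.phenotypes.individuals != ids:
            raise ConfigError("individual identifiers inconsistent across components")


def simulate_dataset(config: SimulationConfig) -> Dataset:
    """Full cohort: panel, intensities, phenotypes, map — one seed, one stream."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    panel = simulate_haplotype_panel(config, rng)
    g = panel.deletion_genotypes()
    intens = simulate_intensities(g, config, rng, panel.individual_ids)
    pheno = simulate_phenotypes(g, config, rng, panel.individual_ids)
    rmap = config.recomb_map or RecombinationMap.uniform(
        panel.positions_bp, config.recomb_rate_cM_per_Mb)
    return Dataset(panel=panel, intensities=intens, phenotypes=pheno, recomb_map=rmap)
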