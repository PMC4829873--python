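"""Synthetic RNA-seq datasets with known trait-associated genes.

The generator emulates the structure of a bulk RNA-seq study with a
continuous per-sample phenotype: negative-binomially distributed counts
with sample-specific library sizes, a chosen subset of genes whose log2
normalized expression linearly drives the trait through Gaussian noise,
optional covariate effects, optional gross trait outliers, and a
cutoff-based dichotomization of the trait into two groups.

The defaults mirror a human-cohort scale experiment: 2,000 genes by 89
samples, 50 trait-associated genes of unit effect, unit trait noise, and
moderate biological overdispersion.  Ground truth (which genes drive the
trait, with what slopes) is returned alongside the data so recovery is
directly assertable.  Everything is reproducible from the single seed in
the configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .normalization import log2_cpm, tmm_factors

__all__ = [
    "SynthConfig",
    "SynthTruth",
    "simulate_counts",
    "simulate_trait",
    "simulate_dataset",
    "inject_outliers",
    "dichotomize_trait",
    "null_config",
]


@dataclass(frozen=True)
class SynthConfig:
    """Generative settings for one synthetic dataset.

    Attributes
    ----------
    n_genes, n_samples : int
        Matrix dimensions (genes x samples).
    n_tags : int
        Number of genes whose expression drives the trait.  Zero gives a
        null dataset (trait independent of every gene).
    effect_size : float
        Trait units per log2-expression unit for every driver gene.
    trait_intercept : float
        Baseline trait value (defaults to a BMI-like 25).
    trait_noise_sd : float
        SD of the Gaussian noise added to the trait.
    dispersion : float
        Negative-binomial dispersion phi in the variance function
        ``var = mu + phi * mu**2`` (the mean-quadratic convention).
    lib_size_range : (int, int)
        Library sizes are drawn uniformly from this inclusive range.
    base_mean_log_mu, base_mean_log_sigma : float
        Gene base expression (counts-per-million scale) is drawn
        log-normally: ``exp(Normal(log_mu, log_sigma))``.
    binary_covariate_effect, continuous_covariate_effect : float or None
        When set, a two-level covariate ("sex", levels F/M) and/or a
        continuous one ("age", uniform 30-70, standardized before entering
        the trait) are generated with the given trait coefficients.
    outlier_fraction, outlier_magnitude : float
        Settings consumed by :func:`inject_outliers` — fraction of samples
        whose trait is displaced, and the displacement in trait-SD units.
    seed : int
        Single seed from which counts, trait, covariates and outliers all
        derive deterministically.
    """

    n_genes: int = 2000
    n_samples: int = 89
    n_tags: int = 50
    effect_size: float = 1.0
    trait_intercept: float = 25.0
    trait_noise_sd: float = 1.0
    dispersion: float = 0.1
    lib_size_range: tuple[int, int] = (500_000, 2_000_000)
    base_mean_log_mu: float = 3.5
    base_mean_log_sigma: float = 1.5
    binary_covariate_effect: float | None = None
    continuous_covariate_effect: float | None = None
    outlier_fraction: float = 0.0
    outlier_magnitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_samples < 2:
            raise ValueError("need at least 1 gene and 2 samples")
        if not 0 <= self.n_tags <= self.n_genes:
            raise ValueError("n_tags must lie in [0, n_genes]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        lo, hi = self.lib_size_range
        if lo <= 0 or hi < lo:
            raise ValueError("lib_size_range must be positive and ordered")
        if self.trait_noise_sd < 0:
            raise ValueError("trait_noise_sd must be nonnegative")
        if not 0 <= self.outlier_fraction < 0.5:
            raise ValueError("outlier_fraction must lie in [0, 0.5)")

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stream,))
        )


@dataclass(frozen=True)
class SynthTruth:
    """Ground truth behind a simulated phenotype."""

    tag_genes: tuple[str, ...]
    true_slopes: dict[str, float] = field(default_factory=dict)
    covariate_coefficients: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def to_frame(self, gene_ids) -> pd.DataFrame:
        """Per-gene truth table (gene_id, is_tag, true_beta1)."""
        tags = set(self.tag_genes)
        return pd.DataFrame(
            {
                "is_tag": [g in tags for g in gene_ids],
                "true_beta1": [self.true_slopes.get(g, 0.0) for g in gene_ids],
            },
            index=pd.Index(gene_ids, name="gene_id"),
        )


def _gene_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"g{i + 1:0{width}d}" for i in range(n)]


def _sample_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"s{i + 1:0{width}d}" for i in range(n)]


def simulate_counts(config: SynthConfig) -> pd.DataFrame:
    """Draw the negative-binomial count matrix.

    Gene base means (counts-per-million scale) are log-normal; library
    sizes are uniform over ``lib_size_range``; counts for gene g in sample
    k are NB with mean ``mu_g * N_k / 1e6`` and variance
    ``mu + dispersion * mu**2``.
    """
    rng = config._rng(1)
    mu = rng.lognormal(config.base_mean_log_mu, config.base_mean_log_sigma,
                       size=config.n_genes)
    lib = rng.integers(config.lib_size_range[0], config.lib_size_range[1] + 1,
                       size=config.n_samples)
    mean = mu[:, None] * (lib[None, :] / 1e6)
    r = 1.0 / config.dispersion  # NB size; p = r / (r + mean)
    counts = rng.negative_binomial(r, r / (r + mean))
    return pd.DataFrame(counts, index=_gene_ids(config.n_genes),
                        columns=_sample_ids(config.n_samples))


def simulate_trait(
    counts: pd.DataFrame, config: SynthConfig
) -> tuple[pd.DataFrame, SynthTruth]:
    """Generate the phenotype table driven by randomly chosen driver genes.

    The trait is assembled from the same log2 TMM counts-per-million
    transform the scans use, so the configured effect size is exactly the
    slope a per-gene regression estimates:

        trait_i = intercept + sum_TAG effect * (x_gi - mean_g x)
                  + covariate terms + Normal(0, noise_sd)

    Driver expressions are centered so the intercept stays interpretable;
    centering does not alter slopes.  Covariates, when configured, are
    appended to the returned phenotype table.
    """
    rng = config._rng(2)
    samples = counts.columns
    n = len(samples)
    expression = log2_cpm(counts, tmm_factors(counts))

    tag_idx = rng.choice(counts.shape[0], size=config.n_tags, replace=False)
    tag_idx = np.sort(tag_idx)
    tag_genes = tuple(counts.index[tag_idx])
    trait = np.full(n, float(config.trait_intercept))
    for g in tag_genes:
        x = expression.loc[g].to_numpy()
        trait = trait + config.effect_size * (x - x.mean())

    phenotype = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    covariate_coefs: dict[str, float] = {}
    if config.binary_covariate_effect is not None:
        level = rng.integers(0, 2, size=n)
        phenotype["sex"] = np.where(level == 1, "M", "F")
        trait = trait + config.binary_covariate_effect * level
        covariate_coefs["sex"] = config.binary_covariate_effect
    if config.continuous_covariate_effect is not None:
        age = rng.uniform(30.0, 70.0, size=n)
        phenotype["age"] = age
        z = (age - age.mean()) / age.std()
        trait = trait + config.continuous_covariate_effect * z
        covariate_coefs["age"] = config.continuous_covariate_effect

    trait = trait + rng.normal(0.0, config.trait_noise_sd, size=n)
    phenotype.insert(0, "trait", trait)

    truth = SynthTruth(
        tag_genes=tag_genes,
        true_slopes={g: config.effect_size for g in tag_genes},
        covariate_coefficients=covariate_coefs,
        seed=config.seed,
    )
    return phenotype, truth


def simulate_dataset(
    config: SynthConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SynthTruth]:
    """Counts, phenotype and truth in one call (outliers applied if set)."""
    counts = simulate_counts(config)
    phenotype, truth = simulate_trait(counts, config)
    if config.outlier_fraction > 0 and config.outlier_magnitude != 0:
        phenotype, _ = inject_outliers(phenotype, config)
    return counts, phenotype, truth


def inject_outliers(
    phenotype: pd.DataFrame, config: SynthConfig, trait: str = "trait"
) -> tuple[pd.DataFrame, list]:
    """Displace a random fraction of trait values by gross amounts.

    Each selected sample's trait moves by ``outlier_magnitude`` trait
    standard deviations, with random sign.  Returns the corrupted copy and
    the affected sample identifiers; fraction 0 returns an identical copy.
    """
    rng = config._rng(3)
    out = phenotype.copy()
    n = len(out)
    m = int(round(config.outlier_fraction * n))
    if m == 0:
        return out, []
    idx = np.sort(rng.choice(n, size=m, replace=False))
    sign = rng.choice([-1.0, 1.0], size=m)
    sd = float(out[trait].std(ddof=1))
    values = out[trait].to_numpy(dtype=float)
    values[idx] += sign * config.outlier_magnitude * sd
    out[trait] = values
    return out, list(out.index[idx])


def dichotomize_trait(
    phenotype: pd.DataFrame,
    cutoff: float,
    trait: str = "trait",
    group: str = "group",
    labels: tuple[str, str] = ("low", "high"),
) -> pd.DataFrame:
    """Add a binary group column: ``high`` where trait >= cutoff else ``low``.

    This is the conversion step the association approach makes
    unnecessary (e.g. over-weight vs normal at BMI 25); it is provided so
    two-group methods can be run and compared.  A cutoff leaving either
    group empty raises ``ValueError``.
    """
    out = phenotype.copy()
    values = out[trait].to_numpy(dtype=float)
    high = values >= cutoff
    if high.all() or not high.any():
        raise ValueError(
            f"cutoff {cutoff!r} leaves an empty group "
            f"(trait range [{values.min():g}, {values.max():g}])"
        )
    out[group] = np.where(high, labels[1], labels[0])
    return out


def null_config(**overrides) -> SynthConfig:
    """Convenience: the no-association study configuration.

    Default scale (2,000 genes x 89 samples) with zero driver genes, used
    for calibration experiments where every discovery is false.
    """
    overrides.setdefault("n_tags", 0)
    overrides.setdefault("effect_size", 0.0)
    return SynthConfig(**overrides)
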