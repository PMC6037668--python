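"""Twin-structured synthetic cohorts with planted microbiota-phenotype effects.

The generator emulates the structure of a deeply phenotyped adult twin
cohort: mostly female, age around 60, BMI around 26, with binary disease
and medication phenotypes at prevalences between 1% and 40%, blocks of
intercorrelated compositional marker traits, and technical confounders
(DNA extraction batch, sample collection method, sequencing run and
sequencing depth).

Binary phenotypes are generated from a latent Gaussian copula so that both
the marginal prevalence and the pairwise Phi coefficient of chosen
phenotype pairs can be controlled.  The Gaussian latent is mapped through
its CDF to a uniform variate and then through the logistic quantile
function, giving each phenotype a standard-logistic liability.  Planted
effects add ``log_odds_per_sd * standardized_trait`` to that liability, so
the conditional model ``P(case | x) = expit(beta * x - c)`` holds exactly
and the true marginal log-odds per SD of the clean trait signal is the
planted ``beta`` itself -- which is what makes analytic parameter-recovery
tests possible downstream.

Twin pairs share a family identifier, a family random intercept on every
trait, a family component of each liability, and sex.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

logger = logging.getLogger(__name__)

__all__ = [
    "PlantedEffect",
    "SimConfig",
    "CohortFixture",
    "InfeasibleCorrelationError",
    "simulate_phenotypes",
    "simulate_traits_and_effects",
    "simulate_cohort",
    "write_fixture",
    "read_fixture",
]


class InfeasibleCorrelationError(ValueError):
    """A requested Phi target cannot be realized by any latent correlation."""


@dataclass(frozen=True)
class PlantedEffect:
    """Ground-truth effect linking one trait to one phenotype.

    ``log_odds_per_sd`` is the marginal log-odds ratio per 1 SD of the
    clean (confounder-free) trait signal.
    """

    phenotype: str
    trait: str
    log_odds_per_sd: float


@dataclass
class SimConfig:
    """Parameters of one synthetic cohort; ``seed`` fully determines the output.

    Defaults mirror the demographic and technical structure of an older,
    mostly female twin cohort profiled by 16S sequencing.
    """

    n_individuals: int
    phenotype_specs: list[tuple[str, float]]
    seed: int
    n_twin_pairs: int = 0
    phi_targets: list[tuple[str, str, float]] = field(default_factory=list)
    n_trait_blocks: int = 17
    traits_per_block: int = 4
    within_block_rho: float = 0.7
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    # demographics
    age_mean: float = 60.0
    age_sd: float = 12.0
    bmi_mean: float = 26.0
    bmi_sd: float = 5.0
    female_fraction: float = 0.89
    # technical factors
    n_extractors: int = 3
    n_collection_methods: int = 2
    n_sequencing_runs: int = 8
    depth_meanlog: float = 10.0   # lognormal read depth, ~22k reads
    depth_sdlog: float = 0.5
    batch_effect_sd: float = 0.3  # per-level trait shift, in trait SD units
    depth_effect_sd: float = 0.15  # per-trait slope on standardized log-depth
    # family structure
    family_trait_icc: float = 0.3
    family_liability_rho: float = 0.2
    # phenotype missingness
    missing_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        if self.n_twin_pairs < 0 or 2 * self.n_twin_pairs > self.n_individuals:
            raise ValueError("need n_individuals >= 2 * n_twin_pairs")
        if not self.phenotype_specs:
            raise ValueError("at least one phenotype is required")
        names = [name for name, _ in self.phenotype_specs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate phenotype names")
        for name, prev in self.phenotype_specs:
            if not 0.0 < prev < 1.0:
                raise ValueError(f"prevalence of {name!r} must be in (0,1), got {prev}")
        for a, b, phi in self.phi_targets:
            if a not in names or b not in names:
                raise ValueError(f"phi target references unknown phenotype: ({a}, {b})")
            if a == b or not -1.0 < phi < 1.0:
                raise ValueError(f"invalid phi target ({a}, {b}, {phi})")
        if self.traits_per_block < 1:
            raise ValueError("traits_per_block must be >= 1")
        if self.n_trait_blocks < 1:
            raise ValueError("n_trait_blocks must be >= 1")
        if not 0.0 <= self.within_block_rho < 1.0:
            raise ValueError("within_block_rho must be in [0,1)")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must be in [0,1)")
        trait_names = set(self.trait_names())
        for eff in self.planted_effects:
            if eff.phenotype not in names:
                raise ValueError(f"planted effect references unknown phenotype {eff.phenotype!r}")
            if eff.trait not in trait_names:
                raise ValueError(f"planted effect references unknown trait {eff.trait!r}")

    def trait_names(self) -> list[str]:
        return [
            f"block{b + 1:02d}_t{j + 1}"
            for b in range(self.n_trait_blocks)
            for j in range(self.traits_per_block)
        ]

    def phenotype_names(self) -> list[str]:
        return [name for name, _ in self.phenotype_specs]

    def prevalences(self) -> dict[str, float]:
        return dict(self.phenotype_specs)


@dataclass
class CohortFixture:
    """One simulated cohort: three aligned tables plus the planted truth."""

    phenotypes: pd.DataFrame
    traits: pd.DataFrame
    covariates: pd.DataFrame
    truth: list[PlantedEffect]


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # counter-based fan-out: one user seed, independent per-purpose streams
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stream,)))


def _latent_rho(p1: float, p2: float, phi_target: float, pair: tuple[str, str]) -> float:
    """Latent Gaussian correlation whose thresholded binaries have the target Phi."""
    t1 = stats.norm.ppf(1.0 - p1)
    t2 = stats.norm.ppf(1.0 - p2)
    denom = np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))

    def realized_phi(rho: float) -> float:
        cov = [[1.0, rho], [rho, 1.0]]
        p11 = stats.multivariate_normal(mean=[0.0, 0.0], cov=cov).cdf([-t1, -t2])
        return (p11 - p1 * p2) / denom

    lo, hi = -0.999, 0.999
    f_lo, f_hi = realized_phi(lo) - phi_target, realized_phi(hi) - phi_target
    if f_lo * f_hi > 0:
        raise InfeasibleCorrelationError(
            f"phi target {phi_target} for pair {pair} is infeasible at "
            f"prevalences ({p1}, {p2})"
        )
    return float(optimize.brentq(lambda r: realized_phi(r) - phi_target, lo, hi, xtol=1e-10))


def _latent_correlation_matrix(config: SimConfig) -> np.ndarray:
    names = config.phenotype_names()
    prev = config.prevalences()
    R = np.eye(len(names))
    idx = {n: i for i, n in enumerate(names)}
    for a, b, phi in config.phi_targets:
        rho = _latent_rho(prev[a], prev[b], phi, (a, b))
        R[idx[a], idx[b]] = R[idx[b], idx[a]] = rho
    eigvals = np.linalg.eigvalsh(R)
    if eigvals.min() < 1e-10:
        raise InfeasibleCorrelationError(
            "latent correlation matrix implied by phi_targets is not positive "
            f"definite (min eigenvalue {eigvals.min():.3g}); offending pairs: "
            f"{[(a, b) for a, b, _ in config.phi_targets]}"
        )
    return R


def _sample_ids(n: int) -> list[str]:
    return [f"S{i + 1:05d}" for i in range(n)]


def _family_ids(config: SimConfig) -> np.ndarray:
    """Family labels: twin pairs first (two members each), then singletons."""
    n, npairs = config.n_individuals, config.n_twin_pairs
    fams = [f"F{p + 1:05d}" for p in range(npairs) for _ in (0, 1)]
    fams += [f"F{npairs + s + 1:05d}" for s in range(n - 2 * npairs)]
    return np.asarray(fams)


def _correlated_mvn(rng: np.random.Generator, chol: np.ndarray, n: int) -> np.ndarray:
    return rng.standard_normal((n, chol.shape[0])) @ chol.T


def simulate_phenotypes(config: SimConfig) -> pd.DataFrame:
    """Draw binary phenotype statuses from the latent Gaussian copula.

    Returns a samples x phenotypes table of 1.0 / 0.0 values.  The uniform
    latents and family labels are stored in ``df.attrs`` so that
    :func:`simulate_traits_and_effects` can inject planted trait effects
    into the same liabilities.
    """
    R = _latent_correlation_matrix(config)
    chol = np.linalg.cholesky(R)
    rng = _rng(config, stream=1)
    n = config.n_individuals
    families = _family_ids(config)
    fam_codes, fam_index = pd.factorize(families)

    z_ind = _correlated_mvn(rng, chol, n)
    z_fam = _correlated_mvn(rng, chol, len(fam_index))[fam_codes]
    rho_f = config.family_liability_rho
    z = np.sqrt(1.0 - rho_f) * z_ind + np.sqrt(rho_f) * z_fam
    u = stats.norm.cdf(z)

    names = config.phenotype_names()
    prev = config.prevalences()
    status = np.column_stack([(u[:, j] > 1.0 - prev[nm]).astype(float) for j, nm in enumerate(names)])
    df = pd.DataFrame(status, index=_sample_ids(n), columns=names)
    df.index.name = "sample_id"
    df.attrs["latent_uniform"] = pd.DataFrame(u, index=df.index, columns=names)
    df.attrs["families"] = pd.Series(families, index=df.index, name="family_id")
    return df


def _block_correlated(rng: np.random.Generator, n: int, config: SimConfig) -> np.ndarray:
    """n x T matrix, unit variance, equicorrelation rho within each block."""
    rho = config.within_block_rho
    cols = []
    for _ in range(config.n_trait_blocks):
        shared = rng.standard_normal((n, 1))
        noise = rng.standard_normal((n, config.traits_per_block))
        cols.append(np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * noise)
    return np.concatenate(cols, axis=1)


def _solve_intercept(eta: np.ndarray, prevalence: float) -> float:
    """c such that mean(expit(eta - c)) equals the target prevalence."""
    def f(c: float) -> float:
        return float(np.mean(expit(eta - c)) - prevalence)
    lo, hi = eta.min() + logit(1e-12), eta.max() - logit(1e-12)
    return float(optimize.brentq(f, lo, hi, xtol=1e-12))


def simulate_traits_and_effects(
    config: SimConfig, phenotypes: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate block-correlated traits, covariates, and plant the effects.

    The phenotype table must come from :func:`simulate_phenotypes` with the
    same config; its statuses are re-thresholded in place for phenotypes
    that carry planted effects (statuses of effect-free phenotypes are
    unchanged by construction).
    """
    if "latent_uniform" not in phenotypes.attrs:
        raise ValueError(
            "phenotype table lacks latent liabilities; generate it with "
            "simulate_phenotypes from the same config"
        )
    rng = _rng(config, stream=2)
    n = config.n_individuals
    samples = phenotypes.index
    families = phenotypes.attrs["families"]
    fam_codes, fam_index = pd.factorize(families)
    n_fam = len(fam_index)

    # clean trait signal: block-correlated at both family and individual level
    icc = config.family_trait_icc
    x_ind = _block_correlated(rng, n, config)
    x_fam = _block_correlated(rng, n_fam, config)[fam_codes]
    x_clean = np.sqrt(1.0 - icc) * x_ind + np.sqrt(icc) * x_fam

    # covariates; twins share sex
    age = rng.normal(config.age_mean, config.age_sd, n)
    bmi = rng.normal(config.bmi_mean, config.bmi_sd, n)
    sex_fam = np.where(rng.random(n_fam) < config.female_fraction, "F", "M")
    sex = sex_fam[fam_codes]
    extractor = rng.integers(0, config.n_extractors, n)
    collection = rng.integers(0, config.n_collection_methods, n)
    run = rng.integers(0, config.n_sequencing_runs, n)
    depth = np.exp(rng.normal(config.depth_meanlog, config.depth_sdlog, n))
    depth = np.maximum(np.round(depth), 1.0)

    # technical structure injected into the observed traits
    n_traits = x_clean.shape[1]
    x_obs = x_clean.copy()
    for codes, n_levels in (
        (extractor, config.n_extractors),
        (collection, config.n_collection_methods),
        (run, config.n_sequencing_runs),
    ):
        shifts = rng.normal(0.0, config.batch_effect_sd, (n_levels, n_traits))
        x_obs += shifts[codes]
    z_logdepth = (np.log(depth) - config.depth_meanlog) / config.depth_sdlog
    depth_slopes = rng.normal(0.0, config.depth_effect_sd, n_traits)
    x_obs += np.outer(z_logdepth, depth_slopes)

    trait_names = config.trait_names()
    traits = pd.DataFrame(x_obs, index=samples, columns=trait_names)
    traits.index.name = "sample_id"

    covariates = pd.DataFrame(
        {
            "age": age,
            "bmi": bmi,
            "sex": sex,
            "sequencing_depth": depth,
            "dna_extractor": [f"ext{k + 1}" for k in extractor],
            "collection_method": [f"method{k + 1}" for k in collection],
            "sequencing_run": [f"run{k + 1}" for k in run],
            "family_id": families.to_numpy(),
        },
        index=samples,
    )
    covariates.index.name = "sample_id"

    # plant effects on the logistic liability and re-threshold
    u = phenotypes.attrs["latent_uniform"]
    prev = config.prevalences()
    trait_idx = {t: j for j, t in enumerate(trait_names)}
    effects_by_pheno: dict[str, list[PlantedEffect]] = {}
    for eff in config.planted_effects:
        effects_by_pheno.setdefault(eff.phenotype, []).append(eff)
    for pheno, effs in effects_by_pheno.items():
        eta = np.zeros(n)
        for eff in effs:
            x = x_clean[:, trait_idx[eff.trait]]
            eta += eff.log_odds_per_sd * x
        liability = logit(np.clip(u[pheno].to_numpy(), 1e-15, 1 - 1e-15)) + eta
        c = _solve_intercept(eta, prev[pheno])
        phenotypes[pheno] = (liability > c).astype(float)

    return traits, covariates


def simulate_cohort(config: SimConfig) -> CohortFixture:
    """Full cohort draw: phenotypes, traits, covariates and truth.

    Phenotype missingness (``missing_fraction`` of entries set to unknown)
    is applied after effect planting, emulating incomplete questionnaires.
    """
    phenotypes = simulate_phenotypes(config)
    traits, covariates = simulate_traits_and_effects(config, phenotypes)
    if config.missing_fraction > 0:
        rng = _rng(config, stream=3)
        mask = rng.random(phenotypes.shape) < config.missing_fraction
        values = phenotypes.to_numpy(copy=True)
        values[mask] = np.nan
        latent, fams = phenotypes.attrs["latent_uniform"], phenotypes.attrs["families"]
        phenotypes = pd.DataFrame(values, index=phenotypes.index, columns=phenotypes.columns)
        phenotypes.index.name = "sample_id"
        phenotypes.attrs["latent_uniform"] = latent
        phenotypes.attrs["families"] = fams
    return CohortFixture(phenotypes, traits, covariates, list(config.planted_effects))


_FIXTURE_FILES = {
    "phenotypes": "phenotypes.tsv",
    "traits": "traits.tsv",
    "covariates": "covariates.tsv",
    "truth": "truth.tsv",
}


def write_fixture(fixture: CohortFixture, directory: str | Path) -> dict[str, Path]:
    """Write the fixture as TSV files; the directory must already exist."""
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"fixture directory does not exist: {directory}")
    paths = {}
    for name, df in (
        ("phenotypes", fixture.phenotypes),
        ("traits", fixture.traits),
        ("covariates", fixture.covariates),
    ):
        path = directory / _FIXTURE_FILES[name]
        df.to_csv(path, sep="\t", na_rep="NA", index_label="sample_id")
        paths[name] = path
    truth = pd.DataFrame(
        [(e.phenotype, e.trait, e.log_odds_per_sd) for e in fixture.truth],
        columns=["phenotype", "trait", "log_odds_per_sd"],
    )
    path = directory / _FIXTURE_FILES["truth"]
    truth.to_csv(path, sep="\t", index=False)
    paths["truth"] = path
    return paths


def read_fixture(directory: str | Path) -> CohortFixture:
    """Read a fixture written by :func:`write_fixture`."""
    directory = Path(directory)
    tables = {}
    for name in ("phenotypes", "traits", "covariates"):
        path = directory / _FIXTURE_FILES[name]
        tables[name] = pd.read_csv(path, sep="\t", index_col="sample_id", na_values="NA")
    truth_df = pd.read_csv(directory / _FIXTURE_FILES["truth"], sep="\t")
    truth = [
        PlantedEffect(r.phenotype, r.trait, float(r.log_odds_per_sd))
        for r in truth_df.itertuples()
    ]
    return CohortFixture(tables["phenotypes"], tables["traits"], tables["covariates"], truth)
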