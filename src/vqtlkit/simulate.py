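"""Simulation of genotype/covariate vectors and quantitative traits.

The generators cover the ideal heteroskedastic model

    y_i ~ Normal(beta0 + beta * x_i,  sigma2 * alpha^(-x_i))

and four departures from it (additive variance, log-Gaussian, gamma,
bimodal mixture) that emulate residual distributions commonly seen in
genomic trait data.  Covariates may be discrete biallelic genotypes
{0,1,2}, continuous imputed dosages in [0,2], binary indicators, or
arbitrary continuous values.

Every generator is deterministic given a seed; benchmark suites derive
one substream per dataset from a master seed via ``numpy`` seed
sequences keyed by a counter, so the suite is reproducible regardless
of execution order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import yaml

from .exceptions import InvalidArgumentError

logger = logging.getLogger(__name__)

FAMILIES = ("ideal", "additive_variance", "log_gaussian", "gamma", "bimodal")
COVARIATE_KINDS = ("discrete", "imputed", "binary", "continuous")

#: Standard deviation of the component draws in the imputed-dosage mixture.
#: The second parameter of the component normals is read as a VARIANCE of
#: 0.5, hence sd = sqrt(0.5).
IMPUTED_COMPONENT_SD = float(np.sqrt(0.5))

HYPOTHESIS_CLASSES = (
    "strong_null",
    "weak_null",
    "weak_alternative",
    "strong_alternative",
)


def hypothesis_class(beta: float, log_alpha: float) -> str:
    """Classify a (mean effect, variance effect) pair.

    The four cells cross mean effect (beta zero / nonzero) with variance
    effect (log alpha zero / nonzero):

    ==============  ==========  ===============
    class           beta        log alpha
    ==============  ==========  ===============
    strong_null     0           0
    weak_null       nonzero     0
    weak_alternative  0         nonzero
    strong_alternative nonzero  nonzero
    ==============  ==========  ===============
    """
    if log_alpha == 0:
        return "strong_null" if beta == 0 else "weak_null"
    return "weak_alternative" if beta == 0 else "strong_alternative"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated (covariate, trait) generating process.

    Parameters
    ----------
    n : sample count (>= 4).
    pi_maf : minor allele frequency in (0, 1).
    beta0 : intercept of the trait mean.
    beta : mean effect size.
    sigma2 : residual variance at x = 0 (> 0); defaults to 1.0.
    log_alpha : heteroskedastic effect; the trait variance is
        ``sigma2 * alpha**(-x)`` in the multiplicative families and
        ``sigma2 + alpha * x`` in the additive family (there ``log_alpha``
        stores the additive coefficient alpha itself, with null at 0).
    family : trait model, one of ``FAMILIES``.
    lambda_mix : mixture weight of the Normal(10, 1) component (bimodal only).
    covariate_kind : one of ``COVARIATE_KINDS``.
    seed : base seed for dataset generation.
    """

    n: int
    pi_maf: float
    beta0: float = 0.0
    beta: float = 0.0
    sigma2: float = 1.0
    log_alpha: float = 0.0
    family: str = "ideal"
    lambda_mix: float = 0.4
    covariate_kind: str = "discrete"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 4:
            raise InvalidArgumentError(f"n must be >= 4, got {self.n}")
        if not 0.0 < self.pi_maf < 1.0:
            raise InvalidArgumentError(
                f"pi_maf must be in (0, 1), got {self.pi_maf}"
            )
        if self.sigma2 <= 0:
            raise InvalidArgumentError(f"sigma2 must be > 0, got {self.sigma2}")
        if self.family not in FAMILIES:
            raise InvalidArgumentError(f"unknown family {self.family!r}")
        if self.covariate_kind not in COVARIATE_KINDS:
            raise InvalidArgumentError(
                f"unknown covariate_kind {self.covariate_kind!r}"
            )
        if not 0.0 <= self.lambda_mix <= 1.0:
            raise InvalidArgumentError("lambda_mix must be in [0, 1]")

    @property
    def hypothesis_class(self) -> str:
        return hypothesis_class(self.beta, self.log_alpha)


@dataclass
class SimulatedDataset:
    """One simulated covariate/trait pair with its generating truth."""

    x: np.ndarray
    y: np.ndarray
    truth: SimulationConfig
    hypothesis_class: str
    is_permutation_null: bool = False
    dataset_id: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.shape[0] != self.truth.n:
            raise InvalidArgumentError(
                "x and y must both have length truth.n"
            )


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_discrete_genotypes(n: int, pi_maf: float, seed) -> np.ndarray:
    """Biallelic genotypes: two Bernoulli(pi_maf) draws per sample,
    i.e. Binomial(2, pi_maf) minor-allele counts in {0, 1, 2}."""
    if n < 1:
        raise InvalidArgumentError(f"n must be >= 1, got {n}")
    if not 0.0 <= pi_maf <= 1.0:
        raise InvalidArgumentError(f"pi_maf must be in [0, 1], got {pi_maf}")
    rng = _as_rng(seed)
    return rng.binomial(2, pi_maf, size=n).astype(float)


def simulate_imputed_genotypes(n: int, pi_maf: float, seed) -> np.ndarray:
    """Continuous dosages in [0, 2] emulating imputed genotypes.

    A latent genotype z ~ Binomial(2, pi_maf) selects a mixture branch:
    |c0| for z = 0, c1 for z = 1, and 2 - |c2| for z = 2, with
    c0, c2 ~ Normal(0, var 0.5) and c1 ~ Normal(1, var 0.5).  Values are
    clipped to [0, 2]; the number of clipped draws is logged at debug
    level.
    """
    if n < 1:
        raise InvalidArgumentError(f"n must be >= 1, got {n}")
    if not 0.0 <= pi_maf <= 1.0:
        raise InvalidArgumentError(f"pi_maf must be in [0, 1], got {pi_maf}")
    rng = _as_rng(seed)
    z = rng.binomial(2, pi_maf, size=n)
    c0 = np.abs(rng.normal(0.0, IMPUTED_COMPONENT_SD, size=n))
    c1 = rng.normal(1.0, IMPUTED_COMPONENT_SD, size=n)
    c2 = np.abs(rng.normal(0.0, IMPUTED_COMPONENT_SD, size=n))
    x = np.where(z == 0, c0, np.where(z == 1, c1, 2.0 - c2))
    clipped = int(np.sum((x < 0) | (x > 2)))
    if clipped:
        logger.debug("imputed-genotype simulation clipped %d draws", clipped)
    return np.clip(x, 0.0, 2.0)


def simulate_covariate(config: SimulationConfig, seed) -> np.ndarray:
    """Draw the covariate vector for ``config.covariate_kind``.

    ``binary`` draws Bernoulli(pi_maf) indicators (e.g. sex); ``continuous``
    draws Uniform(0, 2) dosage-scale values (e.g. normalized age).
    """
    rng = _as_rng(seed)
    kind = config.covariate_kind
    if kind == "discrete":
        return simulate_discrete_genotypes(config.n, config.pi_maf, rng)
    if kind == "imputed":
        return simulate_imputed_genotypes(config.n, config.pi_maf, rng)
    if kind == "binary":
        return rng.binomial(1, config.pi_maf, size=config.n).astype(float)
    return rng.uniform(0.0, 2.0, size=config.n)


def simulate_trait_ideal(x, config: SimulationConfig, seed) -> np.ndarray:
    """Ideal heteroskedastic model: y ~ N(beta0 + beta*x, sigma2 * alpha^(-x))."""
    if config.sigma2 <= 0:
        raise InvalidArgumentError("sigma2 must be > 0")
    x = np.asarray(x, dtype=float)
    rng = _as_rng(seed)
    mean = config.beta0 + config.beta * x
    var = config.sigma2 * np.exp(-config.log_alpha * x)
    return rng.normal(mean, np.sqrt(var))


def simulate_trait_nonideal(x, config: SimulationConfig, seed) -> np.ndarray:
    """Draw traits under one of the four non-ideal families.

    additive_variance
        y ~ N(beta0 + beta*x, sigma2 + alpha*x); ``config.log_alpha``
        holds the additive coefficient alpha (null at 0).
    log_gaussian
        y = exp(z) with z an ideal-model draw.
    gamma
        y ~ Gamma(shape mu, scale 1) with mu = 1/(beta0 + beta*x), i.e.
        mean mu and variance mu (a continuous analogue of overdispersed
        Poisson counts, for which the mean-centered square-root
        transform is the classical variance stabilizer); requires a
        strictly positive linear predictor.
    bimodal
        with probability lambda_mix a Normal(10, 1) draw, otherwise an
        ideal-model draw.
    """
    x = np.asarray(x, dtype=float)
    rng = _as_rng(seed)
    fam = config.family
    if fam == "additive_variance":
        var = config.sigma2 + config.log_alpha * x
        if np.any(var <= 0):
            raise InvalidArgumentError(
                "additive variance sigma2 + alpha*x must be positive for all x"
            )
        mean = config.beta0 + config.beta * x
        return rng.normal(mean, np.sqrt(var))
    if fam == "log_gaussian":
        return np.exp(simulate_trait_ideal(x, config, rng))
    if fam == "gamma":
        lin = config.beta0 + config.beta * x
        if np.any(lin <= 0):
            raise InvalidArgumentError(
                "gamma family requires beta0 + beta*x > 0 for every x"
            )
        mu = 1.0 / lin
        # shape mu, scale 1: mean mu, variance mu (Poisson-like coupling)
        return rng.gamma(shape=mu, scale=1.0)
    if fam == "bimodal":
        ideal = simulate_trait_ideal(x, config, rng)
        spike = rng.normal(10.0, 1.0, size=x.shape[0])
        pick = rng.random(x.shape[0]) < config.lambda_mix
        return np.where(pick, spike, ideal)
    raise InvalidArgumentError(f"not a non-ideal family: {fam!r}")


def simulate_trait(x, config: SimulationConfig, seed) -> np.ndarray:
    if config.family == "ideal":
        return simulate_trait_ideal(x, config, seed)
    return simulate_trait_nonideal(x, config, seed)


def simulate_dataset(config: SimulationConfig, seed=None) -> SimulatedDataset:
    """Draw one (x, y) dataset under ``config``."""
    rng = _as_rng(config.seed if seed is None else seed)
    x = simulate_covariate(config, rng)
    # guard against degenerate covariates that no test can use
    tries = 0
    while np.ptp(x) == 0 and tries < 100:
        x = simulate_covariate(config, rng)
        tries += 1
    y = simulate_trait(x, config, rng)
    return SimulatedDataset(
        x=x,
        y=y,
        truth=config,
        hypothesis_class=config.hypothesis_class,
        is_permutation_null=False,
    )


def generate_benchmark_suite(
    configs: Sequence[SimulationConfig] | SimulationConfig,
    reps: int,
    seed: int,
) -> list[SimulatedDataset]:
    """Generate ``reps`` datasets per config, each paired with one
    mean-effect-preserving permutation null.

    Returns ``2 * reps * len(configs)`` datasets; the permutation null of
    dataset ``k`` immediately follows it and carries
    ``is_permutation_null=True``.  Substreams are keyed by
    ``(config index, replicate index)`` so the suite is identical no
    matter how it is executed.
    """
    from .permfdr import mean_preserving_permutation

    if reps < 1:
        raise InvalidArgumentError("reps must be >= 1")
    if isinstance(configs, SimulationConfig):
        configs = [configs]
    out: list[SimulatedDataset] = []
    for j, config in enumerate(configs):
        for k in range(reps):
            ss = np.random.SeedSequence(entropy=seed, spawn_key=(j, k))
            rng = np.random.default_rng(ss)
            ds = simulate_dataset(config, seed=rng)
            ds.dataset_id = f"c{j}_r{k}"
            perm = mean_preserving_permutation(ds.y, ds.x, rng=rng)
            null = SimulatedDataset(
                x=ds.x.copy(),
                y=perm.y_perm,
                truth=config,
                hypothesis_class=ds.hypothesis_class,
                is_permutation_null=True,
                dataset_id=f"c{j}_r{k}_perm",
            )
            out.append(ds)
            out.append(null)
    return out


def default_grid() -> dict:
    """The packaged simulation grid (sample sizes, MAFs, effect sizes)."""
    text = resources.files("vqtlkit.data").joinpath("grids.yaml").read_text()
    return yaml.safe_load(text)


def grid_configs(grid: dict | None = None, family: str = "ideal",
                 covariate_kind: str = "discrete") -> list[SimulationConfig]:
    """Expand the default (or a custom) grid into SimulationConfig objects."""
    grid = grid or default_grid()
    configs = []
    for n in grid["n"]:
        for maf in grid["pi_maf"]:
            for beta in grid["beta"]:
                for la in grid["log_alpha"]:
                    for b0 in grid["beta0"]:
                        configs.append(SimulationConfig(
                            n=n, pi_maf=maf, beta0=b0, beta=beta,
                            sigma2=grid.get("sigma2", 1.0), log_alpha=la,
                            family=family, covariate_kind=covariate_kind,
                        ))
    return configs


def write_suite_tsv(datasets: Iterable[SimulatedDataset], prefix: str) -> None:
    """Write a suite as <prefix>.traits.tsv / .covariates.tsv / .manifest.tsv.

    Trait and covariate matrices have one row per replicate and one column
    per sample; the manifest lists every generating parameter plus the
    hypothesis class and permutation-null flag.
    """
    import pandas as pd

    datasets = list(datasets)
    ids = [ds.dataset_id or f"d{i}" for i, ds in enumerate(datasets)]
    n = max(ds.truth.n for ds in datasets)
    samples = [f"s{j}" for j in range(n)]
    traits = pd.DataFrame(
        [np.pad(ds.y, (0, n - ds.y.size), constant_values=np.nan)
         for ds in datasets], index=ids, columns=samples)
    covs = pd.DataFrame(
        [np.pad(ds.x, (0, n - ds.x.size), constant_values=np.nan)
         for ds in datasets], index=ids, columns=samples)
    manifest = pd.DataFrame([
        {
            "dataset_id": i,
            **{k: getattr(ds.truth, k) for k in (
                "n", "pi_maf", "beta0", "beta", "sigma2", "log_alpha",
                "family", "lambda_mix", "covariate_kind", "seed")},
            "hypothesis_class": ds.hypothesis_class,
            "is_permutation_null": ds.is_permutation_null,
        }
        for i, ds in zip(ids, datasets)
    ]).set_index("dataset_id")
    traits.to_csv(prefix + ".traits.tsv", sep="\t", index_label="dataset_id")
    covs.to_csv(prefix + ".covariates.tsv", sep="\t",
                index_label="dataset_id")
    manifest.to_csv(prefix + ".manifest.tsv", sep="\t")
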