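"""Synthetic quantitative-genetics populations for the RFI prediction pipeline.

The simulator emulates the data structure of a feed-efficiency study in
dairy cattle: a genotyped herd in which some animals carry longitudinal
weekly dry-matter-intake (DMI) records and the rest contribute genotypes
only.  The generative model is purely additive:

* genotypes — independent bi-allelic SNPs, allele counts Binomial(2, p_j)
  with per-locus frequency p_j ~ Uniform(maf_range); an optional block-LD
  mode copies a locus from its left neighbour with probability
  ``ld_copy_prob`` (off by default);
* breeding values — a random subset of ``n_qtl`` loci receives Gaussian
  additive effects, scaled so the per-animal genetic variance is the
  configured fraction (``heritability``) of the total per-animal
  phenotypic deviation variance;
* weekly DMI — population mean + year-season-of-calving (YSC) effect +
  parity-by-age (ParAge) effect + slopes on days-in-milk, milk energy and
  metabolic body weight + random ration-cohort effect + breeding value +
  weekly residual.

Variance bookkeeping is on the *per-animal* scale: the total per-animal
deviation (breeding value + cohort effect + mean weekly residual) has unit
variance by construction, with fractions ``heritability`` (genetic),
``cohort_variance_fraction`` (ration cohort) and the remainder residual.
Weekly residuals are i.i.d. with variance ``n_weeks × residual fraction``
so that their per-animal mean has exactly the residual fraction.

The number and size of QTL for residual feed intake are unknown in real
cattle; the defaults here (``n_qtl`` = 100, Gaussian effects) are
placeholders for a generic polygenic architecture and should be treated as
such.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, impute_missing, recode_minor_allele

__all__ = [
    "FixedEffectMagnitudes",
    "SimulationParams",
    "SimulatedPopulation",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_population",
    "make_split",
    "realized_heritability",
]

WEEKLY_RECORD_COLUMNS = (
    "animal_id", "week", "dim", "dmi", "milk_e", "mbw",
    "ysc", "par_age", "ration", "birth_date",
)


class ConfigurationError(ValueError):
    """Invalid simulation parameters; the message names the offending field."""


@dataclass(frozen=True)
class FixedEffectMagnitudes:
    """Spread of the categorical effects and the three covariate slopes.

    ``ysc_sd`` / ``par_age_sd`` are standard deviations (kg/day) of the
    per-level effects; the betas are regression slopes of DMI on
    days-in-milk (kg/day per day), milk energy (kg/day per Mcal/day) and
    metabolic body weight (kg/day per kg^0.75).
    """

    ysc_sd: float = 0.8
    par_age_sd: float = 0.5
    beta_dim: float = 0.01
    beta_milk_e: float = 0.30
    beta_mbw: float = 0.05

    def zeroed(self) -> "FixedEffectMagnitudes":
        return FixedEffectMagnitudes(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the population simulator; defaults are desk-scale.

    ``heritability`` is the fraction of per-animal phenotypic deviation
    variance that is additive-genetic (default 0.15, typical of residual
    feed intake); ``heritability`` = 1 is the degenerate noise-free limit
    used in exactness tests.  ``test_fraction`` of animals are born on or
    after January 1 of ``birth_year_range[1]`` (the natural split date for
    :func:`make_split`), the rest before.
    """

    n_animals: int = 200
    n_markers: int = 1000
    n_qtl: int = 100
    maf_range: tuple[float, float] = (0.05, 0.5)
    heritability: float = 0.15
    n_weeks_per_animal: int = 20
    n_cohorts: int = 20
    cohort_variance_fraction: float = 0.10
    fixed_effects: FixedEffectMagnitudes = field(default_factory=FixedEffectMagnitudes)
    n_ysc_levels: int = 19
    n_par_age_levels: int = 20
    missing_rate: float = 0.0
    birth_year_range: tuple[int, int] = (2006, 2010)
    test_fraction: float = 0.3
    ld_copy_prob: float = 0.0
    mean_dmi: float = 23.0
    seed: int = 0

    def __post_init__(self) -> None:
        def bad(fieldname: str, msg: str) -> ConfigurationError:
            return ConfigurationError(f"{fieldname}: {msg}")

        if self.n_animals < 1:
            raise bad("n_animals", "must be a positive integer")
        if self.n_markers < 1:
            raise bad("n_markers", "must be a positive integer")
        if not 1 <= self.n_qtl <= self.n_markers:
            raise bad("n_qtl", f"must be in [1, n_markers={self.n_markers}]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise bad("maf_range", "must satisfy 0 < low <= high <= 0.5")
        if not 0.0 < self.heritability <= 1.0:
            raise bad("heritability", "must be in (0, 1]")
        if not 0.0 <= self.cohort_variance_fraction < 1.0:
            raise bad("cohort_variance_fraction", "must be in [0, 1)")
        if self.heritability + self.cohort_variance_fraction > 1.0:
            raise bad("cohort_variance_fraction",
                      "heritability + cohort fraction must not exceed 1")
        if self.n_weeks_per_animal < 1:
            raise bad("n_weeks_per_animal", "must be a positive integer")
        if self.n_cohorts < 1:
            raise bad("n_cohorts", "must be a positive integer")
        if not 0.0 <= self.missing_rate < 1.0:
            raise bad("missing_rate", "must be in [0, 1)")
        if self.birth_year_range[0] >= self.birth_year_range[1]:
            raise bad("birth_year_range", "first year must precede last year")
        if not 0.0 <= self.test_fraction < 1.0:
            raise bad("test_fraction", "must be in [0, 1)")
        if not 0.0 <= self.ld_copy_prob < 1.0:
            raise bad("ld_copy_prob", "must be in [0, 1)")

    @property
    def residual_variance_fraction(self) -> float:
        return 1.0 - self.heritability - self.cohort_variance_fraction

    @property
    def split_date(self) -> _dt.date:
        """January 1 of the last birth year: the natural train/test split."""
        return _dt.date(self.birth_year_range[1], 1, 1)


@dataclass
class SimulatedPopulation:
    """Ground truth and observables produced by the simulator.

    ``true_rfi`` is the per-animal deviation after fixed effects that the
    RFI pipeline aims to recover: breeding value plus the mean weekly
    residual.  The cohort effect is kept separately because the RFI model
    absorbs it as a random effect.
    """

    params: SimulationParams
    genotypes: GenotypeMatrix
    true_effects: np.ndarray           # per-marker, zero off-QTL
    true_breeding_values: np.ndarray   # per-animal
    cohort_assignments: np.ndarray     # per-animal ration index
    cohort_effects: np.ndarray         # per-cohort
    weekly_records: pd.DataFrame       # WEEKLY_RECORD_COLUMNS
    true_rfi: np.ndarray               # per-animal: bv + mean weekly residual
    birth_dates: np.ndarray            # per-animal datetime.date

    @property
    def animal_ids(self) -> np.ndarray:
        return self.genotypes.animal_ids

    def phenotype_series(self) -> pd.Series:
        """Per-animal RFI-scale phenotype (true deviation), keyed by animal id."""
        return pd.Series(self.true_rfi, index=list(self.animal_ids), name="rfi")

    def breeding_value_series(self) -> pd.Series:
        return pd.Series(self.true_breeding_values, index=list(self.animal_ids),
                         name="breeding_value")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                        spawn_key=(stream,)))


def simulate_genotypes(params: SimulationParams) -> GenotypeMatrix:
    """Draw the animals × markers allele-count matrix.

    Locus j has frequency p_j ~ Uniform(maf_range) and genotypes
    Binomial(2, p_j) independently per animal; a fraction ``missing_rate``
    of entries is then masked uniformly at random.  Deterministic given
    ``params.seed``.
    """
    rng = _rng(params.seed, 0)
    n, m = params.n_animals, params.n_markers
    p = rng.uniform(params.maf_range[0], params.maf_range[1], size=m)
    values = rng.binomial(2, p, size=(n, m)).astype(float)
    if params.ld_copy_prob > 0:
        copy = rng.random(m) < params.ld_copy_prob
        copy[0] = False
        for j in np.flatnonzero(copy):
            values[:, j] = values[:, j - 1]
    if params.missing_rate > 0:
        mask = rng.random((n, m)) < params.missing_rate
        values[mask] = np.nan
    width_a = max(4, len(str(n)))
    width_m = max(5, len(str(m)))
    animal_ids = np.asarray([f"A{i + 1:0{width_a}d}" for i in range(n)], dtype=object)
    marker_ids = np.asarray([f"M{j + 1:0{width_m}d}" for j in range(m)], dtype=object)
    return GenotypeMatrix(animal_ids, marker_ids, values)


def _centered_dosages(genotypes: GenotypeMatrix) -> np.ndarray:
    G = genotypes
    if G.n_missing:
        G = impute_missing(recode_minor_allele(G))
    W = G.values.astype(float)
    return W - W.mean(axis=0, keepdims=True)


def simulate_phenotypes(
    genotypes: GenotypeMatrix, params: SimulationParams
) -> SimulatedPopulation:
    """Lay breeding values, fixed effects and weekly DMI on top of genotypes.

    Deterministic given ``params.seed``; independent of the genotype draw's
    random stream so the same genotypes can be re-used.
    """
    if genotypes.n_animals != params.n_animals or genotypes.n_markers != params.n_markers:
        raise ConfigurationError(
            f"n_animals/n_markers: genotypes are {genotypes.n_animals}×"
            f"{genotypes.n_markers}, params say {params.n_animals}×{params.n_markers}"
        )
    rng = _rng(params.seed, 1)
    n, m = params.n_animals, params.n_markers
    n_weeks = params.n_weeks_per_animal

    # additive genetic values, scaled to the target variance fraction
    W = _centered_dosages(genotypes)
    qtl = rng.choice(m, size=params.n_qtl, replace=False)
    effects = np.zeros(m)
    effects[qtl] = rng.normal(size=params.n_qtl)
    bv = W @ effects
    sd = bv.std()
    if sd > 0:
        scale = np.sqrt(params.heritability) / sd
    else:  # monomorphic corner: no genetic variance available
        scale = 0.0
    effects *= scale
    bv = W @ effects

    # cohorts and per-animal variance components
    cohorts = rng.integers(params.n_cohorts, size=n)
    cohort_effects = rng.normal(
        0.0, np.sqrt(params.cohort_variance_fraction), size=params.n_cohorts
    )
    resid_frac = params.residual_variance_fraction
    weekly_sd = np.sqrt(n_weeks * resid_frac) if resid_frac > 0 else 0.0
    eps = (rng.normal(0.0, weekly_sd, size=(n, n_weeks))
           if weekly_sd > 0 else np.zeros((n, n_weeks)))
    eps_bar = eps.mean(axis=1)

    # fixed-effect structure
    fx = params.fixed_effects
    ysc_levels = rng.integers(params.n_ysc_levels, size=n)
    par_levels = rng.integers(params.n_par_age_levels, size=n)
    ysc_effects = rng.normal(0.0, fx.ysc_sd, size=params.n_ysc_levels)
    par_effects = rng.normal(0.0, fx.par_age_sd, size=params.n_par_age_levels)

    # covariates: weekly grid 50-200 days postpartum, per-animal milk/weight
    week = np.arange(n_weeks)
    dim = 53.5 + 7.0 * week                          # mid-week days in milk
    milk_base = rng.normal(30.0, 3.0, size=n)
    milk_e = milk_base[:, None] + rng.normal(0.0, 1.0, size=(n, n_weeks))
    bw = rng.normal(650.0, 50.0, size=n)
    mbw = (bw[:, None] + rng.normal(0.0, 10.0, size=(n, n_weeks))) ** 0.75

    dmi = (
        params.mean_dmi
        + ysc_effects[ysc_levels][:, None]
        + par_effects[par_levels][:, None]
        + fx.beta_dim * dim[None, :]
        + fx.beta_milk_e * milk_e
        + fx.beta_mbw * mbw
        + cohort_effects[cohorts][:, None]
        + bv[:, None]
        + eps
    )

    # birth dates: a test_fraction of animals born on/after the split date
    n_test = int(round(params.test_fraction * n))
    late = np.zeros(n, dtype=bool)
    late[rng.choice(n, size=n_test, replace=False)] = True
    y0, y1 = params.birth_year_range
    start_early = _dt.date(y0, 1, 1).toordinal()
    start_late = _dt.date(y1, 1, 1).toordinal()
    span_early = start_late - start_early
    offsets = np.where(
        late,
        start_late + rng.integers(365, size=n),
        start_early + rng.integers(span_early, size=n),
    )
    birth_dates = np.asarray([_dt.date.fromordinal(int(o)) for o in offsets],
                             dtype=object)

    ids = genotypes.animal_ids
    records = pd.DataFrame({
        "animal_id": np.repeat(ids, n_weeks),
        "week": np.tile(week, n),
        "dim": np.tile(dim, n),
        "dmi": dmi.ravel(),
        "milk_e": milk_e.ravel(),
        "mbw": mbw.ravel(),
        "ysc": np.repeat([f"ysc{v:02d}" for v in ysc_levels], n_weeks),
        "par_age": np.repeat([f"pa{v:02d}" for v in par_levels], n_weeks),
        "ration": np.repeat([f"r{v:02d}" for v in cohorts], n_weeks),
        "birth_date": np.repeat(birth_dates, n_weeks),
    })

    return SimulatedPopulation(
        params=params,
        genotypes=genotypes,
        true_effects=effects,
        true_breeding_values=bv,
        cohort_assignments=cohorts,
        cohort_effects=cohort_effects,
        weekly_records=records,
        true_rfi=bv + eps_bar,
        birth_dates=birth_dates,
    )


def simulate_population(params: SimulationParams) -> SimulatedPopulation:
    """Genotypes plus phenotypes in one call (the usual entry point)."""
    return simulate_phenotypes(simulate_genotypes(params), params)


def make_split(
    population: SimulatedPopulation, split_date: _dt.date | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Partition animal ids by birth date: before split → train pool, on/after → test.

    Raises if either side is empty, since every validation design needs both.
    """
    if split_date is None:
        split_date = population.params.split_date
    before = np.asarray([d < split_date for d in population.birth_dates], dtype=bool)
    train = population.animal_ids[before]
    test = population.animal_ids[~before]
    if len(train) == 0:
        raise ValueError(f"empty training pool: no animal born before {split_date}")
    if len(test) == 0:
        raise ValueError(f"empty test set: no animal born on/after {split_date}")
    return train, test


def realized_heritability(population: SimulatedPopulation) -> float:
    """Sample genetic-variance fraction of the per-animal total deviation.

    Total deviation = breeding value + assigned cohort effect + mean weekly
    residual; the ratio estimates the configured ``heritability``.
    """
    bv = population.true_breeding_values
    cohort = population.cohort_effects[population.cohort_assignments]
    eps_bar = population.true_rfi - bv
    total = bv + cohort + eps_bar
    return float(np.var(bv, ddof=1) / np.var(total, ddof=1))
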