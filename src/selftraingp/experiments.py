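"""Validation designs for supervised vs self-trained genomic prediction.

Three designs are provided, mirroring the standard reference-population
experiments:

* :func:`learning_curve` — supervised accuracy as a function of the number
  of labelled training animals, resampled without replacement from a pool;
* :func:`ratio_sweep` — a grid over (n labelled × n pseudo-labelled) in
  which each replicate trains the base predictor f and the self-trained
  predictor f* on the *same* labelled sample, so accuracy differences are
  paired;
* :func:`plateau_search` — per replicate, grow the pseudo-labelled set in
  fixed increments (nested supersets) until the per-step gain in test
  correlation drops below a tolerance, and record the stopping ratio of
  pseudo-labelled to labelled animals and the maximum gain over the
  supervised baseline.

Accuracy is the Pearson correlation between predicted and measured
phenotypes on one fixed test set (plus mean squared error); replicate
summaries carry means and 95% t-confidence intervals.

Every replicate draws from its own seeded stream derived from the master
seed, the setting label and the replicate index, so any cell of any design
is independently reproducible.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix
from .selftrain import (PredictorSpec, TrainedPredictor, predict_phenotypes,
                        self_train, train_base)

logger = logging.getLogger(__name__)

__all__ = [
    "Metrics",
    "ReplicateSummary",
    "ExperimentConfig",
    "SweepCell",
    "SweepResult",
    "PlateauReplicate",
    "PlateauResult",
    "evaluate",
    "mean_ci_halfwidth",
    "learning_curve",
    "ratio_sweep",
    "plateau_search",
    "replicate_rng",
]


@dataclass(frozen=True)
class Metrics:
    """Test-set accuracy: Pearson correlation and mean squared error.

    ``correlation`` is NaN when either vector is constant (undefined);
    MSE is always defined.
    """

    correlation: float
    mse: float


def evaluate(f: TrainedPredictor, GT: GenotypeMatrix, PT) -> Metrics:
    """Correlation and MSE of ``f``'s predictions against measured phenotypes."""
    if GT.n_animals < 3:
        raise ValueError("need at least 3 test animals to evaluate")
    if isinstance(PT, pd.Series):
        PT = PT.reindex(list(GT.animal_ids)).to_numpy(float)
    PT = np.asarray(PT, dtype=float)
    if len(PT) != GT.n_animals:
        raise ValueError(f"{len(PT)} phenotypes for {GT.n_animals} test animals")
    pred = predict_phenotypes(f, GT)
    mse = float(np.mean((pred - PT) ** 2))
    if np.ptp(pred) == 0 or np.ptp(PT) == 0:
        logger.warning("evaluate: constant vector; correlation undefined")
        return Metrics(float("nan"), mse)
    corr = float(np.corrcoef(pred, PT)[0, 1])
    return Metrics(corr, mse)


def mean_ci_halfwidth(values: np.ndarray, confidence: float = 0.95,
                      normal: bool = False) -> float:
    """Half-width of the two-sided CI for a mean of i.i.d. replicate values.

    Uses Student's t with n−1 degrees of freedom by default (``normal=True``
    switches to the z approximation).  NaN for fewer than two values.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        return float("nan")
    alpha = 1.0 - confidence
    crit = (stats.norm.ppf(1 - alpha / 2) if normal
            else stats.t.ppf(1 - alpha / 2, n - 1))
    return float(crit * values.std(ddof=1) / np.sqrt(n))


@dataclass
class ReplicateSummary:
    """Per-replicate metrics for one setting, with mean and 95% CI."""

    label: str
    correlations: np.ndarray
    mses: np.ndarray

    @property
    def n_replicates(self) -> int:
        return len(self.correlations)

    @property
    def mean_correlation(self) -> float:
        return float(np.mean(self.correlations))

    @property
    def ci_correlation(self) -> float:
        return mean_ci_halfwidth(self.correlations)

    @property
    def mean_mse(self) -> float:
        return float(np.mean(self.mses))

    @property
    def ci_mse(self) -> float:
        return mean_ci_halfwidth(self.mses)

    def as_row(self) -> dict:
        return {
            "setting": self.label,
            "mean_correlation": self.mean_correlation,
            "ci_correlation": self.ci_correlation,
            "mean_mse": self.mean_mse,
            "ci_mse": self.ci_mse,
            "n_replicates": self.n_replicates,
        }


@dataclass(frozen=True)
class ExperimentConfig:
    """Shared design parameters.

    Defaults mirror the full-scale validation design (learning curve
    n = 20…540 step 20; sweep 300/400/500 labelled × 200…800 pseudo-
    labelled; 100 replicates; plateau increment 200 with tolerance 1e-4,
    i.e. 0.01% on the correlation-as-percentage scale, applied per
    replicate).  ``plateau_tolerance=0`` disables the early stop so the
    search runs to pool exhaustion.
    """

    labeled_sizes: tuple[int, ...] = tuple(range(20, 541, 20))
    sweep_labeled_sizes: tuple[int, ...] = (300, 400, 500)
    unlabeled_sizes: tuple[int, ...] = (200, 400, 600, 800)
    n_replicates: int = 100
    plateau_increment: int = 200
    plateau_tolerance: float = 1e-4
    seed: int = 0
    predictor: PredictorSpec = field(default_factory=PredictorSpec)

    def __post_init__(self) -> None:
        for name in ("labeled_sizes", "sweep_labeled_sizes"):
            if any(s <= 0 for s in getattr(self, name)):
                raise ValueError(f"{name} must be positive")
        if any(s < 0 for s in self.unlabeled_sizes):
            raise ValueError("unlabeled_sizes must be nonnegative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be positive")
        if self.plateau_increment < 1:
            raise ValueError("plateau_increment must be positive")
        if self.plateau_tolerance < 0:
            raise ValueError("plateau_tolerance must be nonnegative")


def replicate_rng(master_seed: int, label: str, replicate: int) -> np.random.Generator:
    """Independent seeded stream for one replicate of one setting.

    The stream key is (CRC32 of the setting label, replicate index) under
    the master seed, so a single cell can be reproduced without running
    the rest of the design.
    """
    key = zlib.crc32(label.encode("utf-8"))
    seq = np.random.SeedSequence(entropy=master_seed, spawn_key=(key, replicate))
    return np.random.default_rng(seq)


def _phenotype_array(phenotypes: pd.Series, ids: Sequence) -> np.ndarray:
    values = phenotypes.reindex(list(ids))
    if values.isna().any():
        missing = values.index[values.isna()][:5].tolist()
        raise ValueError(f"phenotypes missing for animals {missing}")
    return values.to_numpy(float)


def learning_curve(
    genotypes: GenotypeMatrix,
    phenotypes: pd.Series,
    pool_ids: Sequence,
    test_ids: Sequence,
    config: ExperimentConfig,
) -> list[ReplicateSummary]:
    """Supervised accuracy vs number of labelled training animals.

    For each size n in ``config.labeled_sizes``: ``n_replicates`` samples of
    n animals are drawn without replacement from the pool, a supervised
    predictor is trained on each and evaluated on the fixed test set.
    """
    pool = np.asarray(pool_ids, dtype=object)
    G_test = genotypes.subset_animals(test_ids)
    P_test = _phenotype_array(phenotypes, test_ids)
    summaries = []
    for n in config.labeled_sizes:
        if n > len(pool):
            raise ValueError(f"labeled size {n} exceeds pool of {len(pool)}")
        label = f"n_labeled={n}"
        corrs = np.empty(config.n_replicates)
        mses = np.empty(config.n_replicates)
        for rep in range(config.n_replicates):
            rng = replicate_rng(config.seed, label, rep)
            sample = np.sort(rng.choice(pool, size=n, replace=False))
            f = train_base(genotypes.subset_animals(sample),
                           phenotypes, config.predictor)
            metrics = evaluate(f, G_test, P_test)
            corrs[rep], mses[rep] = metrics.correlation, metrics.mse
            logger.debug("learning_curve %s rep %d: r=%.4f", label, rep,
                         metrics.correlation)
        summaries.append(ReplicateSummary(label, corrs, mses))
        logger.info("learning_curve %s: mean r=%.4f ± %.4f", label,
                    summaries[-1].mean_correlation, summaries[-1].ci_correlation)
    return summaries


@dataclass
class SweepCell:
    """One (n_labeled, n_unlabeled) cell: paired base vs augmented metrics."""

    n_labeled: int
    n_unlabeled: int
    base: ReplicateSummary
    augmented: ReplicateSummary

    @property
    def diff_correlations(self) -> np.ndarray:
        """Per-replicate paired difference R_SSL − R_SL."""
        return self.augmented.correlations - self.base.correlations

    @property
    def diff_mses(self) -> np.ndarray:
        return self.augmented.mses - self.base.mses

    @property
    def mean_diff_correlation(self) -> float:
        return float(np.mean(self.diff_correlations))

    @property
    def ci_diff_correlation(self) -> float:
        return mean_ci_halfwidth(self.diff_correlations)


@dataclass
class SweepResult:
    cells: dict[tuple[int, int], SweepCell]
    skipped: list[tuple[int, int, str]]

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for (nl, nu), cell in self.cells.items():
            rows.append({
                "n_labeled": nl, "n_unlabeled": nu,
                "mean_r_sl": cell.base.mean_correlation,
                "mean_r_ssl": cell.augmented.mean_correlation,
                "mean_diff": cell.mean_diff_correlation,
                "ci_diff": cell.ci_diff_correlation,
                "mean_mse_sl": cell.base.mean_mse,
                "mean_mse_ssl": cell.augmented.mean_mse,
                "n_replicates": cell.base.n_replicates,
            })
        return pd.DataFrame(rows)


def ratio_sweep(
    genotypes: GenotypeMatrix,
    phenotypes: pd.Series,
    pool_labeled: Sequence,
    pool_unlabeled: Sequence,
    test_ids: Sequence,
    config: ExperimentConfig,
) -> SweepResult:
    """Paired supervised/self-trained accuracy over the size grid.

    Within a replicate both predictors share the identical labelled sample
    and test set, so the per-replicate difference is paired.  Infeasible
    cells (sizes exceeding the pools) are skipped and reported.
    """
    pool_l = np.asarray(pool_labeled, dtype=object)
    pool_u = np.asarray(pool_unlabeled, dtype=object)
    G_test = genotypes.subset_animals(test_ids)
    P_test = _phenotype_array(phenotypes, test_ids)
    cells: dict[tuple[int, int], SweepCell] = {}
    skipped: list[tuple[int, int, str]] = []
    for nl in config.sweep_labeled_sizes:
        for nu in config.unlabeled_sizes:
            if nl > len(pool_l):
                skipped.append((nl, nu, f"labeled pool has {len(pool_l)}"))
                continue
            if nu > len(pool_u):
                skipped.append((nl, nu, f"unlabeled pool has {len(pool_u)}"))
                continue
            label = f"sweep nl={nl} nu={nu}"
            base_c = np.empty(config.n_replicates)
            base_m = np.empty(config.n_replicates)
            aug_c = np.empty(config.n_replicates)
            aug_m = np.empty(config.n_replicates)
            for rep in range(config.n_replicates):
                rng = replicate_rng(config.seed, label, rep)
                labeled = np.sort(rng.choice(pool_l, size=nl, replace=False))
                unlabeled = np.sort(rng.choice(pool_u, size=nu, replace=False))
                G1 = genotypes.subset_animals(labeled)
                G2 = (genotypes.subset_animals(unlabeled) if nu else None)
                result = self_train(G1, phenotypes, G2, config.predictor)
                mb = evaluate(result.base, G_test, P_test)
                ma = evaluate(result.augmented, G_test, P_test)
                base_c[rep], base_m[rep] = mb.correlation, mb.mse
                aug_c[rep], aug_m[rep] = ma.correlation, ma.mse
            cells[(nl, nu)] = SweepCell(
                nl, nu,
                ReplicateSummary(label + " base", base_c, base_m),
                ReplicateSummary(label + " augmented", aug_c, aug_m),
            )
            logger.info("ratio_sweep nl=%d nu=%d: mean diff %.4f", nl, nu,
                        cells[(nl, nu)].mean_diff_correlation)
    for nl, nu, reason in skipped:
        logger.warning("ratio_sweep: skipped cell nl=%d nu=%d (%s)", nl, nu, reason)
    return SweepResult(cells, skipped)


@dataclass
class PlateauReplicate:
    """Trace of one replicate's incremental search."""

    replicate: int
    baseline_correlation: float            # R_SL of the supervised base
    step_correlations: list[float]         # R_SSL at each visited n_unlabeled
    step_sizes: list[int]
    stopped_at: int                        # n_unlabeled at the stopping step
    exhausted: bool

    def improvement(self) -> float:
        """Maximum gain over the supervised baseline among visited steps."""
        return max(self.step_correlations) - self.baseline_correlation


@dataclass
class PlateauResult:
    """Across-replicate plateau summaries for one labelled-set size."""

    n_labeled: int
    replicates: list[PlateauReplicate]

    @property
    def ratios(self) -> np.ndarray:
        return np.asarray([r.stopped_at / self.n_labeled for r in self.replicates])

    @property
    def improvements(self) -> np.ndarray:
        return np.asarray([r.improvement() for r in self.replicates])

    @property
    def n_exhausted(self) -> int:
        return sum(r.exhausted for r in self.replicates)

    @property
    def mean_ratio(self) -> float:
        return float(np.mean(self.ratios))

    @property
    def ci_ratio(self) -> float:
        return mean_ci_halfwidth(self.ratios)

    @property
    def mean_improvement(self) -> float:
        return float(np.mean(self.improvements))

    @property
    def ci_improvement(self) -> float:
        return mean_ci_halfwidth(self.improvements)


def stopping_step(step_correlations: Sequence[float], baseline: float,
                  tolerance: float) -> int | None:
    """Index of the first step whose gain over the previous step is < tolerance.

    The first step is compared against the supervised baseline.  Returns
    None if no step triggers the stop (pool exhausted first).  A
    tolerance of 0 never stops.  This pure function is the stopping rule
    shared by the incremental search and any full-scan replay of it.
    """
    if tolerance <= 0:
        return None
    prev = baseline
    for i, corr in enumerate(step_correlations):
        if corr - prev < tolerance:
            return i
        prev = corr
    return None


def plateau_search(
    genotypes: GenotypeMatrix,
    phenotypes: pd.Series,
    pool_labeled: Sequence,
    pool_unlabeled: Sequence,
    test_ids: Sequence,
    config: ExperimentConfig,
    labeled_sizes: Sequence[int] | None = None,
) -> dict[int, PlateauResult]:
    """Grow the pseudo-labelled set until gains fall below tolerance.

    Per replicate: draw the labelled sample and a permutation of the
    unlabelled pool; successive increments of ``config.plateau_increment``
    animals are *nested* (each step adds new animals to the previous set).
    The search stops at the first step whose correlation gain over the
    previous step is below ``config.plateau_tolerance``, or at pool
    exhaustion (flagged).  No step beyond the stopping step is evaluated.
    """
    pool_l = np.asarray(pool_labeled, dtype=object)
    pool_u = np.asarray(pool_unlabeled, dtype=object)
    if config.plateau_increment > len(pool_u):
        raise ValueError(
            f"unlabeled pool of {len(pool_u)} is smaller than one increment "
            f"of {config.plateau_increment}"
        )
    sizes = labeled_sizes if labeled_sizes is not None else config.sweep_labeled_sizes
    G_test = genotypes.subset_animals(test_ids)
    P_test = _phenotype_array(phenotypes, test_ids)
    results: dict[int, PlateauResult] = {}
    for nl in sizes:
        if nl > len(pool_l):
            raise ValueError(f"labeled size {nl} exceeds pool of {len(pool_l)}")
        label = f"plateau nl={nl}"
        reps: list[PlateauReplicate] = []
        for rep in range(config.n_replicates):
            rng = replicate_rng(config.seed, label, rep)
            labeled = np.sort(rng.choice(pool_l, size=nl, replace=False))
            order = rng.permutation(pool_u)
            G1 = genotypes.subset_animals(labeled)
            f = train_base(G1, phenotypes, config.predictor)
            baseline = evaluate(f, G_test, P_test).correlation
            step_corrs: list[float] = []
            step_sizes: list[int] = []
            prev = baseline
            k = config.plateau_increment
            stopped_at = None
            exhausted = False
            while True:
                if k > len(order):
                    exhausted = True
                    stopped_at = step_sizes[-1] if step_sizes else 0
                    break
                G2 = genotypes.subset_animals(order[:k])
                result = self_train(G1, phenotypes, G2, config.predictor)
                corr = evaluate(result.augmented, G_test, P_test).correlation
                step_corrs.append(corr)
                step_sizes.append(k)
                if config.plateau_tolerance > 0 and corr - prev < config.plateau_tolerance:
                    stopped_at = k
                    break
                prev = corr
                k += config.plateau_increment
            reps.append(PlateauReplicate(
                replicate=rep,
                baseline_correlation=baseline,
                step_correlations=step_corrs,
                step_sizes=step_sizes,
                stopped_at=stopped_at,
                exhausted=exhausted,
            ))
            logger.debug("plateau nl=%d rep %d: stop at %d (%s)", nl, rep,
                         stopped_at, "exhausted" if exhausted else "tolerance")
        results[nl] = PlateauResult(nl, reps)
        logger.info("plateau nl=%d: mean ratio %.3f, mean max gain %.4f", nl,
                    results[nl].mean_ratio, results[nl].mean_improvement)
    return results
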