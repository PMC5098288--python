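"""Self-training (semi-supervised) genomic prediction around an SVR base.

The algorithm uses genotyped-and-phenotyped animals (G1, P1) together with
genotype-only animals (G2):

* Step 1 — train a base predictor ``f`` on (G1, P1);
* Step 2 — predict self-trained phenotypes ``P2_hat = f(G2)``;
* Step 3 — retrain on the concatenation (G1‖G2, P1‖P2_hat) to obtain the
  augmented predictor ``f*``.

Exactly one relabel-retrain round is performed; pseudo-labelled animals
enter Step 3 with equal weight and no confidence filtering.  The shipped
base predictor is epsilon-insensitive support-vector regression with an
RBF kernel, k(u, v) = exp(-gamma ||u - v||^2), with defaults C = 1,
gamma = 1/n_markers and epsilon = 0.1; an opt-in grid search tunes C and
gamma by k-fold cross-validation inside the labelled training set only.
Marker columns are standardized by training-set statistics (zero-variance
columns become all-zero rather than being dropped, so marker sets stay
aligned across G1, G2 and any test matrix).

Any object with the same fit/predict surface can replace SVR; only SVR is
shipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PredictorSpec",
    "TrainedPredictor",
    "SelfTrainResult",
    "train_base",
    "predict_phenotypes",
    "self_train",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class PredictorSpec:
    """Configuration of the base predictor.

    ``gamma=None`` means 1/n_markers, resolved at fit time.  With
    ``tuning="grid"``, C and the gamma scale are chosen by k-fold
    cross-validation (mean squared error) over ``grid_C`` ×
    ``grid_gamma_scale``/n_markers; ties break toward the first grid point
    in iteration order, and fold assignment is seeded for reproducibility.
    """

    kind: str = "svm_rbf"
    C: float = 1.0
    gamma: float | None = None
    epsilon: float = 0.1
    tuning: str = "none"
    grid_C: tuple[float, ...] = (0.25, 1.0, 4.0)
    grid_gamma_scale: tuple[float, ...] = (0.25, 1.0, 4.0)
    cv_folds: int = 5
    standardize_features: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind != "svm_rbf":
            raise ValueError(f"unknown predictor kind {self.kind!r}")
        if self.C <= 0 or self.epsilon <= 0:
            raise ValueError("C and epsilon must be positive")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be positive when given")
        if self.tuning not in ("none", "grid"):
            raise ValueError(f"tuning must be 'none' or 'grid', got {self.tuning!r}")
        if self.tuning == "grid" and (not self.grid_C or not self.grid_gamma_scale):
            raise ValueError("tuning grid must be non-empty")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be at least 2")


class TrainedPredictor:
    """A fitted genomic predictor bound to its marker set.

    Prediction applies the stored training standardization and only accepts
    matrices whose marker set matches training (column order is
    normalized automatically).
    """

    def __init__(
        self,
        model: SVR,
        marker_ids: np.ndarray,
        center: np.ndarray,
        scale: np.ndarray,
        spec: PredictorSpec,
        chosen: dict | None = None,
    ) -> None:
        self.model = model
        self.marker_ids = np.asarray(marker_ids, dtype=object)
        self.center = np.asarray(center, dtype=float)
        self.scale = np.asarray(scale, dtype=float)
        self.spec = spec
        self.chosen = chosen or {}

    def _transform(self, G: GenotypeMatrix) -> np.ndarray:
        train_set = set(self.marker_ids)
        given_set = set(G.marker_ids)
        if train_set != given_set:
            missing = sorted(train_set - given_set)
            extra = sorted(given_set - train_set)
            raise ValueError(
                f"marker set mismatch: {len(missing)} missing (e.g. {missing[:3]}), "
                f"{len(extra)} extra (e.g. {extra[:3]})"
            )
        G = G.reorder_markers(self.marker_ids)
        if np.isnan(G.values).any():
            raise ValueError("genotype matrix contains missing entries; impute first")
        return (G.values - self.center) / self.scale

    def predict(self, G: GenotypeMatrix) -> np.ndarray:
        """Predicted phenotype per animal, in G's row order."""
        if G.n_animals == 0:
            return np.empty(0)
        return self.model.predict(self._transform(G))


def _resolve_gamma(spec: PredictorSpec, n_markers: int) -> float:
    return spec.gamma if spec.gamma is not None else 1.0 / n_markers


def _standardization(
    values: np.ndarray, standardize: bool
) -> tuple[np.ndarray, np.ndarray]:
    if not standardize:
        m = values.shape[1]
        return np.zeros(m), np.ones(m)
    center = values.mean(axis=0)
    scale = values.std(axis=0)
    scale[scale == 0] = 1.0  # zero-variance columns become all-zero features
    return center, scale


def _align_phenotypes(G: GenotypeMatrix, P) -> np.ndarray:
    if isinstance(P, pd.Series):
        aligned = P.reindex(list(G.animal_ids))
        if aligned.isna().any():
            missing = aligned.index[aligned.isna()][:5].tolist()
            raise ValueError(f"phenotypes missing for animals {missing}")
        y = aligned.to_numpy(float)
    else:
        y = np.asarray(P, dtype=float)
        if len(y) != G.n_animals:
            raise ValueError(
                f"{len(y)} phenotypes for {G.n_animals} genotyped animals"
            )
    if not np.isfinite(y).all():
        raise ValueError("phenotypes contain non-finite values")
    return y


def _cv_mse(X: np.ndarray, y: np.ndarray, C: float, gamma: float,
            epsilon: float, folds: int, seed: int) -> float:
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    errors = []
    for train_idx, val_idx in kf.split(X):
        model = SVR(kernel="rbf", C=C, gamma=gamma, epsilon=epsilon)
        model.fit(X[train_idx], y[train_idx])
        pred = model.predict(X[val_idx])
        errors.append(np.mean((pred - y[val_idx]) ** 2))
    return float(np.mean(errors))


def train_base(G1: GenotypeMatrix, P1, spec: PredictorSpec | None = None) -> TrainedPredictor:
    """Step 1: fit the base predictor on labelled animals.

    ``P1`` may be an array aligned with ``G1.animal_ids`` or a Series keyed
    by animal id.  The genotype matrix must be fully imputed.
    """
    spec = spec or PredictorSpec()
    if G1.n_animals < 2:
        raise ValueError("need at least 2 labelled animals to train")
    if np.isnan(G1.values).any():
        raise ValueError("genotype matrix contains missing entries; impute first")
    y = _align_phenotypes(G1, P1)
    center, scale = _standardization(G1.values, spec.standardize_features)
    X = (G1.values - center) / scale
    gamma0 = _resolve_gamma(spec, G1.n_markers)

    chosen = {"C": spec.C, "gamma": gamma0}
    if spec.tuning == "grid":
        folds = min(spec.cv_folds, G1.n_animals)
        best = None
        for C in spec.grid_C:
            for gscale in spec.grid_gamma_scale:
                gamma = gscale / G1.n_markers if spec.gamma is None else gscale * spec.gamma
                mse = _cv_mse(X, y, C, gamma, spec.epsilon, folds, spec.seed)
                if best is None or mse < best[0]:
                    best = (mse, C, gamma)
        _, C, gamma = best
        chosen = {"C": C, "gamma": gamma, "cv_mse": best[0]}
        logger.info("train_base: grid search chose C=%.3g gamma=%.3g "
                    "(cv mse %.4g)", C, gamma, best[0])
    model = SVR(kernel="rbf", C=chosen["C"], gamma=chosen["gamma"],
                epsilon=spec.epsilon)
    model.fit(X, y)
    return TrainedPredictor(model, G1.marker_ids, center, scale, spec, chosen)


def predict_phenotypes(f: TrainedPredictor, G: GenotypeMatrix) -> np.ndarray:
    """Step 2: predict (self-trained) phenotypes for a genotype matrix."""
    return f.predict(G)


@dataclass
class SelfTrainResult:
    """Outputs of one self-training round."""

    base: TrainedPredictor                   # f
    augmented: TrainedPredictor              # f*
    self_trained_phenotypes: np.ndarray      # P2_hat, aligned with G2 rows
    n_labeled: int
    n_unlabeled: int


def self_train(
    G1: GenotypeMatrix,
    P1,
    G2: GenotypeMatrix | None,
    spec: PredictorSpec | None = None,
) -> SelfTrainResult:
    """Run the three-step self-training round.

    ``G2`` may be None or empty, in which case the augmented predictor is a
    retrain on the labelled data alone and predicts identically to the base
    (the supervised-equivalence contract).  The predictor spec — including
    any tuning mode — is re-applied unchanged at Step 3.
    """
    spec = spec or PredictorSpec()
    f = train_base(G1, P1, spec)
    y1 = _align_phenotypes(G1, P1)
    if G2 is None or G2.n_animals == 0:
        return SelfTrainResult(f, f, np.empty(0), G1.n_animals, 0)
    p2_hat = predict_phenotypes(f, G2)
    combined = G1.concat_animals(G2)
    y = np.concatenate([y1, p2_hat])
    f_star = train_base(combined, y, spec)
    return SelfTrainResult(f, f_star, p2_hat, G1.n_animals, G2.n_animals)


# ----------------------------------------------------------------------
# Model serialization
# ----------------------------------------------------------------------

def save_model(f: TrainedPredictor, path: str | Path) -> None:
    """Persist a predictor as a versioned joblib archive."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "spec": f.spec.__dict__,
        "marker_ids": list(f.marker_ids),
        "center": f.center,
        "scale": f.scale,
        "chosen": f.chosen,
        "model": f.model,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> TrainedPredictor:
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model archive version {version!r} does not match supported "
            f"version {MODEL_FORMAT_VERSION}"
        )
    spec = PredictorSpec(**payload["spec"])
    return TrainedPredictor(
        payload["model"],
        np.asarray(payload["marker_ids"], dtype=object),
        payload["center"],
        payload["scale"],
        spec,
        payload.get("chosen"),
    )
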