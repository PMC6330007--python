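"""Trait-distribution classification and prescriptive transformations.

A trait sample is summarized as a vector of one-sided Kolmogorov-Smirnov
statistics against a bank of reference densities whose location and
scale are matched to the sample's mean and variance; a random-forest
classifier trained on simulated data from seven generating models maps
that feature vector to a model-family label.  Labels with a known
mean-variance coupling come with a prescriptive transformation:
log-Gaussian traits get a log transform, gamma traits a mean-centered
square-root transform; all other labels need none.

The seven labels are: the ideal multiplicative-heteroskedasticity model
(``bth_ideal``), additive variance, exponential mean (Gaussian noise
around an exponential-of-linear-predictor mean), exponential residual
(shifted exponential noise around a linear mean), log-Gaussian, gamma,
and a bimodal Gaussian mixture.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .exceptions import InvalidArgumentError
from .simulate import (SimulationConfig, simulate_discrete_genotypes,
                       simulate_trait_ideal, simulate_trait_nonideal)

CLASS_LABELS = (
    "bth_ideal",
    "additive_variance",
    "exponential_mean",
    "exponential_residual",
    "log_gaussian",
    "gamma",
    "bimodal",
)

TRANSFORM_KINDS = ("none", "log", "mean_centered_sqrt")

MODEL_FORMAT_VERSION = 1


class _Mixture:
    """Two-component Gaussian mixture N(0,1) / N(delta,1) with weight lam
    on the shifted component."""

    def __init__(self, delta: float, lam: float):
        self.delta = delta
        self.lam = lam

    def stats(self):
        mean = self.lam * self.delta
        var = 1.0 + self.lam * (1.0 - self.lam) * self.delta ** 2
        return mean, var

    def rvs(self, size, random_state):
        pick = random_state.random(size) < self.lam
        z = random_state.normal(0.0, 1.0, size)
        return z + np.where(pick, self.delta, 0.0)


def _frozen(dist):
    class _Wrap:
        def __init__(self, d):
            self.d = d

        def stats(self):
            m, v = self.d.stats(moments="mv")
            return float(m), float(v)

        def rvs(self, size, random_state):
            return self.d.rvs(size=size, random_state=random_state)

    return _Wrap(dist)


@dataclass
class ReferenceBank:
    """Bank of moment-matchable reference densities.

    Every density exposes analytic mean/variance so a location-scale
    transform can match it exactly to a query sample's first two moments.
    """

    names: list
    densities: list

    @property
    def size(self) -> int:
        return len(self.densities)

    def sample_matched(self, index: int, mean: float, var: float,
                       size: int, rng) -> np.ndarray:
        d = self.densities[index]
        m, v = d.stats()
        raw = np.asarray(d.rvs(size=size, random_state=rng), dtype=float)
        z = (raw - m) / np.sqrt(v)
        return mean + np.sqrt(var) * z


def default_bank() -> ReferenceBank:
    """The default 79-density bank: location-scale and shape-varied
    standard families plus a grid of two-component Gaussian mixtures."""
    names, dens = [], []

    def add(name, d):
        names.append(name)
        dens.append(d)

    add("gaussian", _frozen(sps.norm()))
    for df in (3, 4, 5, 6, 7, 8, 10, 12, 15, 20, 30):
        add(f"t_df{df}", _frozen(sps.t(df)))
    add("laplace", _frozen(sps.laplace()))
    add("uniform", _frozen(sps.uniform()))
    add("logistic", _frozen(sps.logistic()))
    add("gumbel", _frozen(sps.gumbel_r()))
    add("exponential", _frozen(sps.expon()))
    for s in (0.25, 0.5, 0.75, 1.0, 1.25, 1.5):
        add(f"lognorm_s{s}", _frozen(sps.lognorm(s)))
    for a in (0.5, 1, 1.5, 2, 3, 4, 5, 7, 10, 15, 20):
        add(f"gamma_k{a}", _frozen(sps.gamma(a)))
    for a, b in ((0.5, 0.5), (0.3, 0.3), (2, 2), (5, 5), (2, 5), (5, 2),
                 (1, 3), (3, 1), (0.5, 2), (2, 0.5)):
        add(f"beta_{a}_{b}", _frozen(sps.beta(a, b)))
    for c in (0.75, 1.2, 1.5, 2.5, 4):
        add(f"weibull_c{c}", _frozen(sps.weibull_min(c)))
    for b in (3, 4, 5, 6, 8):
        add(f"pareto_b{b}", _frozen(sps.pareto(b)))
    for lam in (0.1, 0.2, 0.3, 0.4, 0.5):
        for delta in (1, 2, 3, 4, 5):
            add(f"mix_l{lam}_d{delta}", _Mixture(delta, lam))
    assert len(dens) == 79
    return ReferenceBank(names=names, densities=dens)


def ks_d_plus(sample_a, sample_b) -> float:
    """One-sided two-sample KS statistic D+ = sup_x [F_a(x) - F_b(x)]."""
    a = np.sort(np.asarray(sample_a, dtype=float))
    b = np.sort(np.asarray(sample_b, dtype=float))
    xs = np.concatenate([a, b])
    fa = np.searchsorted(a, xs, side="right") / a.size
    fb = np.searchsorted(b, xs, side="right") / b.size
    return float(np.max(fa - fb))


def ks_feature_vector(sample, bank: ReferenceBank | None = None,
                      ref_size: int = 100, seed=0,
                      by_group: bool = False, x=None) -> np.ndarray:
    """KS D+ statistics of a trait sample against every bank density.

    Each reference density is sampled ``ref_size`` times with location
    and scale matched to the query sample, and D+ (query ECDF above the
    reference ECDF) is recorded, giving one feature per density.  With
    ``by_group=True`` and a categorical covariate ``x``, a (groups x R)
    block of per-group features is returned instead.
    """
    bank = bank or default_bank()
    sample = np.asarray(sample, dtype=float)
    if by_group:
        if x is None:
            raise InvalidArgumentError("by_group requires the covariate x")
        x = np.asarray(x, dtype=float)
        return np.vstack([
            ks_feature_vector(sample[x == lv], bank, ref_size, seed=seed)
            for lv in np.unique(x)
        ])
    if sample.size < 20:
        raise InvalidArgumentError("need at least 20 observations")
    if np.ptp(sample) == 0:
        raise InvalidArgumentError("sample has zero variance")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    mean = float(sample.mean())
    var = float(sample.var(ddof=1))
    feats = np.empty(bank.size)
    for i in range(bank.size):
        ref = bank.sample_matched(i, mean, var, ref_size, rng)
        feats[i] = ks_d_plus(sample, ref)
    return feats


def _exponential_mean_trait(x, config, rng):
    """Gaussian noise around an exponential-of-linear-predictor mean."""
    mean = np.exp(config.beta0 + config.beta * x)
    var = config.sigma2 * np.exp(-config.log_alpha * x)
    return rng.normal(mean, np.sqrt(var))


def _exponential_residual_trait(x, config, rng):
    """Linear mean with mean-zero shifted-exponential residuals whose scale
    follows the multiplicative heteroskedasticity."""
    scale = np.sqrt(config.sigma2 * np.exp(-config.log_alpha * x))
    return config.beta0 + config.beta * x + rng.exponential(scale) - scale


def simulate_class_trait(label: str, x, config: SimulationConfig, rng):
    """Draw a trait under one of the seven classifier generating models."""
    if label == "bth_ideal":
        return simulate_trait_ideal(x, config, rng)
    if label == "exponential_mean":
        return _exponential_mean_trait(x, config, rng)
    if label == "exponential_residual":
        return _exponential_residual_trait(x, config, rng)
    import dataclasses

    fam = {"additive_variance": "additive_variance",
           "log_gaussian": "log_gaussian", "gamma": "gamma",
           "bimodal": "bimodal"}.get(label)
    if fam is None:
        raise InvalidArgumentError(f"unknown class label {label!r}")
    cfg = dataclasses.replace(config, family=fam)
    if fam == "gamma" and cfg.beta0 <= 0:
        cfg = dataclasses.replace(cfg, beta0=1.0)
    return simulate_trait_nonideal(x, cfg, rng)


#: The four (variance effect, mean effect) training cells.
TRAINING_CELLS = ((0.2, 0.5), (0.2, 0.0), (0.0, 0.5), (0.0, 0.0))


def build_training_set(bank: ReferenceBank | None = None,
                       samples_per_cell: int = 50, n: int = 200,
                       maf: float = 0.2, ref_size: int = 100,
                       seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Labeled KS feature vectors for the 7 classes x 4 effect cells.

    Returns ``(X, labels)`` with ``7 * 4 * samples_per_cell`` rows.  Each
    row is the feature vector of one simulated dataset (discrete
    genotypes at the given MAF, beta0 = 1, sigma2 = 1) under one class
    and one (log alpha, beta) cell; for the additive-variance class the
    variance-effect value is used as the additive coefficient.
    """
    bank = bank or default_bank()
    rows, labels = [], []
    counter = 0
    for label in CLASS_LABELS:
        for la, beta in TRAINING_CELLS:
            for _ in range(samples_per_cell):
                ss = np.random.SeedSequence(entropy=seed,
                                            spawn_key=(counter,))
                counter += 1
                rng = np.random.default_rng(ss)
                config = SimulationConfig(
                    n=n, pi_maf=maf, beta0=1.0, beta=beta, sigma2=1.0,
                    log_alpha=la)
                x = simulate_discrete_genotypes(n, maf, rng)
                while np.ptp(x) == 0:
                    x = simulate_discrete_genotypes(n, maf, rng)
                y = simulate_class_trait(label, x, config, rng)
                if np.ptp(y) == 0:
                    y = y + rng.normal(0, 1e-8, y.size)
                rows.append(ks_feature_vector(y, bank, ref_size, seed=rng))
                labels.append(label)
    return np.asarray(rows), np.asarray(labels)


@dataclass
class ClassifierModel:
    """Trained trait-distribution classifier with its CV report."""

    estimator: object
    bank_names: list
    classes: list
    cv_report: dict
    version: int = MODEL_FORMAT_VERSION

    def predict_proba(self, features) -> dict:
        feats = np.atleast_2d(np.asarray(features, dtype=float))
        probs = self.estimator.predict_proba(feats)[0]
        return {c: float(p) for c, p in zip(self.estimator.classes_, probs)}

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump({"version": self.version,
                         "bank_names": self.bank_names,
                         "classes": self.classes,
                         "cv_report": self.cv_report,
                         "estimator": self.estimator}, fh)

    @classmethod
    def load(cls, path) -> "ClassifierModel":
        with open(path, "rb") as fh:
            blob = pickle.load(fh)
        if blob.get("version") != MODEL_FORMAT_VERSION:
            raise InvalidArgumentError("unsupported classifier model version")
        return cls(estimator=blob["estimator"], bank_names=blob["bank_names"],
                   classes=blob["classes"], cv_report=blob["cv_report"])


def train_classifier(X, labels, folds: int = 5, seed: int = 0,
                     bank: ReferenceBank | None = None) -> ClassifierModel:
    """Fit a random forest on KS feature vectors with k-fold CV metrics.

    The CV report holds per-class precision/recall and the macro accuracy
    estimated by stratified ``folds``-fold cross-validation; the returned
    estimator is refit on all data.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.metrics import precision_recall_fscore_support
    from sklearn.model_selection import StratifiedKFold, cross_val_predict

    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    present = set(np.unique(labels))
    missing = [c for c in CLASS_LABELS if c not in present]
    if missing and present <= set(CLASS_LABELS):
        raise InvalidArgumentError(f"classes absent from training data: {missing}")
    counts = {c: int(np.sum(labels == c)) for c in present}
    if min(counts.values()) < 2:
        raise InvalidArgumentError("need at least 2 examples per class")
    rf = RandomForestClassifier(n_estimators=300, random_state=seed,
                                n_jobs=1)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = cross_val_predict(rf, X, labels, cv=cv)
    prec, rec, _, _ = precision_recall_fscore_support(
        labels, pred, labels=sorted(present), zero_division=0)
    report = {
        "macro_accuracy": float(np.mean(pred == labels)),
        "per_class": {
            c: {"precision": float(p), "recall": float(r)}
            for c, p, r in zip(sorted(present), prec, rec)
        },
        "folds": folds,
    }
    rf.fit(X, labels)
    bank = bank or default_bank()
    return ClassifierModel(estimator=rf, bank_names=list(bank.names),
                           classes=sorted(present), cv_report=report)


@dataclass
class TransformSpec:
    """A prescriptive trait transformation.

    ``log`` requires strictly positive traits; ``mean_centered_sqrt``
    requires non-negative traits and stores the subtracted mean of the
    square roots in ``offset`` once applied.
    """

    kind: str = "none"
    offset: float | None = None

    def __post_init__(self):
        if self.kind not in TRANSFORM_KINDS:
            raise InvalidArgumentError(f"unknown transform {self.kind!r}")


#: label -> recommended transformation
TRANSFORM_FOR_LABEL = {
    "log_gaussian": "log",
    "gamma": "mean_centered_sqrt",
}


def classify_and_recommend(y, x, model: ClassifierModel,
                           bank: ReferenceBank | None = None,
                           ref_size: int = 100, seed: int = 0,
                           ) -> tuple[dict, TransformSpec]:
    """Class probabilities for a (trait, covariate) pair plus the
    transformation prescribed for the most probable class."""
    bank = bank or default_bank()
    if list(bank.names) != list(model.bank_names):
        raise InvalidArgumentError(
            "reference bank does not match the one the model was trained with")
    feats = ks_feature_vector(np.asarray(y, dtype=float), bank,
                              ref_size=ref_size, seed=seed)
    probs = model.predict_proba(feats)
    top = max(probs, key=probs.get)
    return probs, TransformSpec(kind=TRANSFORM_FOR_LABEL.get(top, "none"))


def apply_transformation(y, spec: TransformSpec) -> np.ndarray:
    """Apply a prescriptive transformation to a trait vector.

    log: elementwise natural log (strictly positive input).
    mean_centered_sqrt: elementwise square root, then subtract the mean
    of the square roots so the output mean is exactly zero; the
    subtracted mean is recorded on ``spec.offset``.
    """
    y = np.asarray(y, dtype=float)
    if spec.kind == "none":
        return y.copy()
    if spec.kind == "log":
        if np.any(y <= 0):
            raise InvalidArgumentError("log transform requires positive traits")
        return np.log(y)
    if np.any(y < 0):
        raise InvalidArgumentError(
            "mean-centered sqrt requires non-negative traits")
    root = np.sqrt(y)
    offset = float(root.mean()) if spec.offset is None else spec.offset
    spec.offset = offset
    return root - offset
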