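"""Seeded generator of HDLSS two-class expression-like data with planted signal.

The generator emulates the statistical shape of small microarray
benchmark cohorts: far more features than samples, two imbalanced
classes, a small set of class-informative features, noisy redundant
copies of some of them, and scattered missing values. Its defaults mirror
a 70-train / 88-validation cohort with a 26/70 positive fraction.

Model: every feature is Gaussian with unit within-class standard
deviation. Noise features are N(0, 1) independent of the class;
informative feature j has class-conditional means 0 (negative) and
``effect_size`` (positive); a redundant feature is a randomly chosen
informative feature plus N(0, redundancy_noise_sd) observation noise.
Missing values (NaN) are planted uniformly at rate ``missing_rate`` over
a random half of the *noise* features only, so exclusion of
missing-valued features never destroys planted signal; set
``missing_anywhere=True`` to stress the exclusion rule itself.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .dataset_io import ExpressionDataset


class SyntheticSpecError(ValueError):
    pass


@dataclass
class SyntheticSpec:
    """Generator parameters; defaults are the package's reference conditions."""

    n_train: int = 70
    n_valid: int = 88
    n_features: int = 500
    n_informative: int = 10
    n_redundant: int = 10
    effect_size: float = 2.0
    positive_fraction: float = 26 / 70
    missing_rate: float = 0.05
    redundancy_noise_sd: float = 0.2
    missing_anywhere: bool = False
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_train, self.n_valid, self.n_features) <= 0:
            raise SyntheticSpecError("sample and feature counts must be positive")
        if self.n_informative < 0 or self.n_redundant < 0:
            raise SyntheticSpecError("planted feature counts must be nonnegative")
        if self.n_informative + self.n_redundant > self.n_features:
            raise SyntheticSpecError("n_informative + n_redundant must be <= n_features")
        if self.n_redundant > 0 and self.n_informative == 0:
            raise SyntheticSpecError("redundant features need informative sources")
        if not 0 < self.positive_fraction < 1:
            raise SyntheticSpecError("positive_fraction must be in (0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise SyntheticSpecError("missing_rate must be in [0, 1)")
        if self.redundancy_noise_sd < 0:
            raise SyntheticSpecError("redundancy_noise_sd must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


def _labels(n: int, positive_fraction: float, rng) -> np.ndarray:
    n_pos = int(round(positive_fraction * n))
    n_pos = min(max(n_pos, 1), n - 1)  # keep both classes represented
    labels = np.array([1] * n_pos + [0] * (n - n_pos), dtype=int)
    rng.shuffle(labels)
    return labels


def generate(spec: SyntheticSpec):
    """Draw (train, valid, truth) reproducibly from ``spec``.

    ``truth`` maps "informative" and "redundant" to the planted feature
    ids and "redundant_source" to the id of each redundant feature's
    source informative feature.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    f = spec.n_features
    feature_ids = [f"g{j:05d}" for j in range(f)]

    roles = rng.permutation(f)
    informative = np.sort(roles[: spec.n_informative])
    redundant = np.sort(roles[spec.n_informative : spec.n_informative + spec.n_redundant])
    noise = np.sort(roles[spec.n_informative + spec.n_redundant :])
    sources = rng.choice(informative, size=spec.n_redundant) if spec.n_redundant else np.array([], int)

    if spec.missing_anywhere:
        missing_eligible = np.arange(f)
    else:
        # random half of the noise features may carry missing values
        missing_eligible = np.sort(rng.choice(noise, size=len(noise) // 2, replace=False)) if len(noise) else np.array([], int)

    def draw(n: int, prefix: str) -> ExpressionDataset:
        labels = _labels(n, spec.positive_fraction, rng)
        X = rng.standard_normal((n, f))
        X[:, informative] += spec.effect_size * labels[:, None]
        for slot, src in zip(redundant, sources):
            X[:, slot] = X[:, src] + rng.normal(0.0, spec.redundancy_noise_sd, size=n)
        if spec.missing_rate > 0 and len(missing_eligible):
            holes = rng.random((n, len(missing_eligible))) < spec.missing_rate
            block = X[:, missing_eligible]
            block[holes] = np.nan
            X[:, missing_eligible] = block
        sample_ids = [f"{prefix}_s{i:04d}" for i in range(n)]
        return ExpressionDataset(X, labels, sample_ids, list(feature_ids))

    train = draw(spec.n_train, "train")
    valid = draw(spec.n_valid, "valid")
    truth = {
        "informative": [feature_ids[j] for j in informative],
        "redundant": [feature_ids[j] for j in redundant],
        "redundant_source": {
            feature_ids[slot]: feature_ids[src] for slot, src in zip(redundant, sources)
        },
    }
    return train, valid, truth


def summarize(dataset: ExpressionDataset) -> dict:
    """Exact class, feature and missing-cell counts."""
    return {
        "n_samples": dataset.n_samples,
        "n_features": dataset.n_features,
        "n_positive": int(np.sum(dataset.labels == 1)),
        "n_negative": int(np.sum(dataset.labels == 0)),
        "n_missing": int(np.isnan(dataset.matrix).sum()),
    }
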