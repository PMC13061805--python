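"""Mucin color quantification: EC vs LEGH classification from abundances.

Cytoplasmic mucin of normal endocervical (EC) cells stains pinkish
(Eosin Y dominant) while the gastric-type mucin of lobular endocervical
glandular hyperplasia (LEGH) stains yellowish (Orange G dominant).
This module turns unmixed abundance maps into patch-level features and
classifies them:

* 5 x 5 pixel patches are averaged per dye, then converted to
  *relative* abundances (fractions summing to 1), which are invariant
  to mucin thickness/concentration scaling;
* group differences are assessed with the Mann-Whitney U test (exact
  enumeration for small samples, tie-corrected normal approximation
  otherwise);
* classification uses two-class Fisher linear discriminant analysis on
  a chosen dye subset (default [EY, OG]), with LEGH as the positive
  class: a patch is called LEGH when the discriminant score is >= 0.

A seeded generator of Dirichlet-distributed relative-abundance
features for the two populations supports end-to-end testing without
specimen data.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

from .unmix import AbundanceMap

__all__ = [
    "MucinPatch",
    "LDAModel",
    "extract_patches",
    "relative_abundance",
    "mann_whitney",
    "fit_lda",
    "classify",
    "evaluate_classification",
    "generate_mucin_features",
]

EXACT_ENUMERATION_LIMIT = 12  # m + n at or below this uses full enumeration


@dataclass
class MucinPatch:
    """Per-dye mean and relative abundance of one 5 x 5 mucin window."""

    mean_abundance: np.ndarray
    relative_abundance: np.ndarray
    location: tuple[int, int]
    label: str = "unknown"
    dye_names: tuple[str, ...] = ("EY", "H", "LG", "OG")


@dataclass
class LDAModel:
    """Two-class Fisher discriminant D(x) = weights . x + bias.

    The positive class (default LEGH) is predicted when D(x) >= 0.
    """

    feature_names: tuple[str, ...]
    weights: np.ndarray
    bias: float
    positive_class: str = "LEGH"
    negative_class: str = "EC"

    def score(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(np.asarray(features, dtype=float))
        if features.shape[1] != self.weights.size:
            raise ValueError("feature dimensionality mismatch")
        return features @ self.weights + self.bias


def extract_patches(
    X: AbundanceMap,
    origins: list[tuple[int, int]],
    size: int = 5,
    labels: list[str] | None = None,
) -> list[MucinPatch]:
    """Average abundances over ``size`` x ``size`` windows at the given
    (row, col) origins; windows must lie inside the raster."""
    rasters = X.as_rasters()  # (r, h, w)
    if labels is None:
        labels = ["unknown"] * len(origins)
    patches = []
    for (row, col), label in zip(origins, labels, strict=True):
        if row < 0 or col < 0 or row + size > X.height or col + size > X.width:
            raise ValueError(f"window at ({row}, {col}) exceeds the raster bounds")
        mean = rasters[:, row : row + size, col : col + size].mean(axis=(1, 2))
        patches.append(
            MucinPatch(
                mean_abundance=mean,
                relative_abundance=relative_abundance(mean),
                location=(row, col),
                label=label,
                dye_names=X.dye_names,
            )
        )
    return patches


def relative_abundance(x_bar: np.ndarray) -> np.ndarray:
    """Fractions x_i / sum(x); invariant to positive scaling of x."""
    x = np.asarray(x_bar, dtype=float).ravel()
    total = x.sum()
    if total <= 0:
        raise ValueError("total abundance must be positive")
    return x / total


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U of group A against B with mid-rank tie handling."""
    pooled = np.concatenate([a, b])
    ranks = _stats.rankdata(pooled)  # midranks
    m = a.size
    return float(ranks[:m].sum() - m * (m + 1) / 2.0)


def mann_whitney(
    group_a: np.ndarray, group_b: np.ndarray, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Mann-Whitney U test; returns (U of group A, p-value).

    For m + n <= 12 the two-sided p-value comes from full enumeration of
    all C(m+n, m) group assignments of the pooled sample (permutation
    null, valid under ties):  p = P(|U - mn/2| >= |u_obs - mn/2|).
    Larger samples use the tie- and continuity-corrected normal
    approximation.
    """
    a = np.asarray(group_a, dtype=float).ravel()
    b = np.asarray(group_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if alternative != "two-sided":
        raise ValueError("only the two-sided alternative is supported")
    m, n = a.size, b.size
    u_obs = _u_statistic(a, b)
    if m + n <= EXACT_ENUMERATION_LIMIT:
        pooled = np.concatenate([a, b])
        ranks = _stats.rankdata(pooled)
        center = m * n / 2.0
        obs_dev = abs(u_obs - center)
        count = 0
        total = 0
        offset = m * (m + 1) / 2.0
        for combo in itertools.combinations(range(m + n), m):
            u = ranks[list(combo)].sum() - offset
            total += 1
            if abs(u - center) >= obs_dev - 1e-12:
                count += 1
        return u_obs, count / total
    result = _stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return u_obs, float(result.pvalue)


def fit_lda(
    features: np.ndarray,
    labels: list[str],
    feature_names: tuple[str, ...] = ("EY", "OG"),
    positive_class: str = "LEGH",
    negative_class: str = "EC",
    ridge: float = 1e-10,
) -> LDAModel:
    """Fit a two-class Fisher LDA with equal priors.

    weights are proportional to pooled_cov^-1 (mu_pos - mu_neg); the
    bias places the decision boundary at the midpoint of the projected
    class means.  A tiny ridge stabilizes a (near-)singular pooled
    covariance.
    """
    features = np.asarray(features, dtype=float)
    labels_arr = np.asarray(labels)
    if features.ndim != 2 or features.shape[1] != len(feature_names):
        raise ValueError("features must be (n_samples, n_features)")
    pos = features[labels_arr == positive_class]
    neg = features[labels_arr == negative_class]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("both classes need at least two samples")
    mu_pos = pos.mean(axis=0)
    mu_neg = neg.mean(axis=0)
    s_pos = np.cov(pos, rowvar=False, ddof=1)
    s_neg = np.cov(neg, rowvar=False, ddof=1)
    n_pos, n_neg = len(pos), len(neg)
    pooled = ((n_pos - 1) * np.atleast_2d(s_pos) + (n_neg - 1) * np.atleast_2d(s_neg)) / (
        n_pos + n_neg - 2
    )
    pooled = pooled + ridge * np.eye(pooled.shape[0])
    weights = np.linalg.solve(pooled, mu_pos - mu_neg)
    bias = -float(weights @ (mu_pos + mu_neg) / 2.0)
    return LDAModel(
        feature_names=tuple(feature_names),
        weights=weights,
        bias=bias,
        positive_class=positive_class,
        negative_class=negative_class,
    )


def classify(model: LDAModel, features: np.ndarray) -> list[str]:
    """Label each feature row: positive class iff D(x) >= 0 (ties positive)."""
    scores = model.score(features)
    return [
        model.positive_class if s >= 0 else model.negative_class for s in scores
    ]


def evaluate_classification(
    predicted: list[str], truth: list[str], positive_class: str = "LEGH"
) -> dict[str, float]:
    """Accuracy, precision, recall and F1 with the given positive class.

    Undefined ratios (zero denominator) are reported as ``nan``.
    """
    if len(predicted) != len(truth):
        raise ValueError("prediction/truth length mismatch")
    pred = np.asarray(predicted)
    true = np.asarray(truth)
    tp = int(np.sum((pred == positive_class) & (true == positive_class)))
    fp = int(np.sum((pred == positive_class) & (true != positive_class)))
    fn = int(np.sum((pred != positive_class) & (true == positive_class)))
    tn = len(truth) - tp - fp - fn
    accuracy = (tp + tn) / len(truth)
    precision = tp / (tp + fp) if tp + fp > 0 else math.nan
    recall = tp / (tp + fn) if tp + fn > 0 else math.nan
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        f1 = math.nan
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {"accuracy": accuracy, "precision": precision, "recall": recall, "f1": f1}


# Dirichlet concentrations of the two mucin populations over (EY, H, LG, OG):
# EC mucin is EY-rich, LEGH mucin OG-rich, with similar H and LG shares.
_EC_ALPHA = np.array([14.0, 5.0, 6.0, 5.0])
_LEGH_ALPHA = np.array([6.0, 5.0, 6.0, 13.0])


def generate_mucin_features(
    n_ec: int,
    n_legh: int,
    seed: int = 0,
    separation: float = 1.0,
) -> tuple[np.ndarray, list[str]]:
    """Draw synthetic relative-abundance features for EC and LEGH patches.

    Each patch is a Dirichlet draw over the four dyes; ``separation``
    interpolates the LEGH concentration vector between the EC one (0,
    indistinguishable populations) and the fully shifted OG-rich one
    (1, the default).  Returns (features (n, 4), labels).
    """
    rng = np.random.default_rng(seed)
    legh_alpha = _EC_ALPHA + separation * (_LEGH_ALPHA - _EC_ALPHA)
    ec = rng.dirichlet(_EC_ALPHA, size=n_ec)
    legh = rng.dirichlet(legh_alpha, size=n_legh)
    features = np.vstack([ec, legh])
    labels = ["EC"] * n_ec + ["LEGH"] * n_legh
    return features, labels
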