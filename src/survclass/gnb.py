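"""Generalized naive Bayes with a geometric-mean likelihood transform.

A standard naive Bayes posterior multiplies ``d`` per-gene likelihoods; at
transcriptome dimension the product underflows double precision and, even
in log space, saturates the posterior at 0/1.  Here the product is replaced
by its d-th root -- the geometric mean -- which preserves the argmax while
keeping the transformed likelihood on the scale of a single density value.
All arithmetic is carried out in log space; the transform is a division of
the summed log-likelihood by ``d``.

Class-conditional Gaussian parameters can be estimated with *soft* weights
derived from survival times: a two-class equal-variance Gaussian model of
the class-conditional survival densities yields a logistic membership
function P(C_k | y), and each class's mean and variance are the
corresponding weighted averages (single pass, no iteration).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

LIKELIHOOD_FLOOR = 1e-300
_LOG_FLOOR = np.log(LIKELIHOOD_FLOOR)


def log2_fpkm(x: np.ndarray) -> np.ndarray:
    """The model-scale transform for raw FPKM values: log2(x + 1)."""
    return np.log2(np.asarray(x, dtype=float) + 1.0)


def apply_preprocessing(x: np.ndarray, preprocessing: str) -> np.ndarray:
    if preprocessing == "log2p1":
        return log2_fpkm(x)
    if preprocessing == "none":
        return np.asarray(x, dtype=float)
    raise ValueError(f"unknown preprocessing {preprocessing!r}")


@dataclass
class GNBModel:
    """Two-class generalized naive Bayes model.

    ``means`` and ``variances`` are (2, d) arrays on the model scale, row
    order matching ``classes``.  The transform dimension equals the number
    of genes.  The first class is, by convention, the longer-survival one.
    """

    classes: tuple[str, str]
    priors: np.ndarray
    gene_ids: list[str]
    means: np.ndarray
    variances: np.ndarray
    preprocessing: str = "log2p1"
    variance_floor: float = 1e-6

    def __post_init__(self) -> None:
        self.priors = np.asarray(self.priors, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        if len(self.classes) != 2:
            raise ValueError("GNBModel is strictly two-class")
        if abs(self.priors.sum() - 1.0) > 1e-12:
            raise ValueError("priors must sum to 1")
        d = len(self.gene_ids)
        if self.means.shape != (2, d) or self.variances.shape != (2, d):
            raise ValueError("means/variances must have shape (2, n_genes)")
        if (self.variances < self.variance_floor - 1e-15).any():
            raise ValueError("variances below the variance floor")

    @property
    def transform_dimension(self) -> int:
        return len(self.gene_ids)


def transform_likelihood(per_gene_likelihoods) -> float:
    """Geometric mean of per-gene likelihoods, computed as exp(mean(log)).

    The raw product is never formed, so the result is finite for any
    dimension.
    """
    likes = np.asarray(per_gene_likelihoods, dtype=float)
    if likes.ndim != 1 or likes.size < 1:
        raise ValueError("need a 1-D vector with at least one likelihood")
    if (likes < 0).any() or not np.isfinite(likes).all():
        raise ValueError("likelihoods must be non-negative finite values")
    likes = np.maximum(likes, LIKELIHOOD_FLOOR)
    return float(np.exp(np.mean(np.log(likes))))


def _log_densities(model: GNBModel, x: np.ndarray, k: int) -> np.ndarray:
    m = model.means[k]
    v = model.variances[k]
    logpdf = -0.5 * (np.log(2.0 * np.pi * v) + (x - m) ** 2 / v)
    return np.maximum(logpdf, _LOG_FLOOR)


def gaussian_likelihood(model: GNBModel, x, k: int) -> np.ndarray:
    """Per-gene univariate Gaussian densities of ``x`` under class ``k``.

    ``x`` must already be on the model scale (see ``apply_preprocessing``).
    Densities are floored at 1e-300 so they are never exactly zero.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (model.transform_dimension,):
        raise ValueError(
            f"expected a vector of length {model.transform_dimension}, "
            f"got shape {x.shape}"
        )
    if not np.isfinite(x).all():
        raise ValueError("input vector contains non-finite values")
    return np.exp(_log_densities(model, x, k))


def log_posterior_matrix(model: GNBModel, X: np.ndarray) -> np.ndarray:
    """Unnormalised per-class log posterior for columns of a (d, n) matrix.

    Applies the model's preprocessing to raw expression values, then for
    each class computes log(prior) + mean over genes of the per-gene log
    density (the log of the geometric-mean-transformed likelihood).
    """
    X = apply_preprocessing(np.asarray(X, dtype=float), model.preprocessing)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != model.transform_dimension:
        raise ValueError(
            f"expected {model.transform_dimension} genes, got {X.shape[0]}"
        )
    out = np.empty((2, X.shape[1]))
    for k in range(2):
        m = model.means[k][:, None]
        v = model.variances[k][:, None]
        logpdf = -0.5 * (np.log(2.0 * np.pi * v) + (X - m) ** 2 / v)
        np.maximum(logpdf, _LOG_FLOOR, out=logpdf)
        out[k] = logpdf.mean(axis=0) + np.log(model.priors[k])
    return out


def posterior(model: GNBModel, x) -> np.ndarray:
    """Class posterior for one raw expression vector.

    Proportional to prior_k * (prod_i P(x_i | C_k))^(1/d), computed in log
    space until the final normalisation.  If every per-gene density of both
    classes hit the floor, the posterior degenerates to the priors and a
    warning is issued.
    """
    x = np.asarray(x, dtype=float)
    logpost = log_posterior_matrix(model, x)[:, 0]
    geo = logpost - np.log(model.priors)
    if (geo <= _LOG_FLOOR).all():
        warnings.warn(
            "all per-gene likelihoods floored for both classes; "
            "returning the priors",
            RuntimeWarning,
            stacklevel=2,
        )
        return model.priors.copy()
    shifted = logpost - logpost.max()
    p = np.exp(shifted)
    return p / p.sum()


def classify(model: GNBModel, x) -> str:
    """Label of the larger-posterior class; ties go to the first class."""
    post = posterior(model, x)
    return model.classes[0] if post[0] >= post[1] else model.classes[1]


@dataclass
class LogisticLink:
    """P(first class | y) = 1 / (1 + exp(a * (y - b)))."""

    a: float
    b: float

    def prob_first(self, y) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        z = np.clip(self.a * (y - self.b), -700.0, 700.0)
        return 1.0 / (1.0 + np.exp(z))


def fit_logistic_link(y, is_first) -> LogisticLink:
    """Equal-variance Gaussian link between survival time and class.

    With class-conditional survival densities N(mu_k, sigma^2), Bayes'
    rule under equal priors gives a logistic membership with
    ``a = (mu_2 - mu_1) / sigma^2`` and ``b = (mu_1 + mu_2) / 2``; the
    first class is the longer-surviving one, so P(first | y) increases
    with y.
    """
    y = np.asarray(y, dtype=float)
    is_first = np.asarray(is_first, dtype=bool)
    if is_first.all() or not is_first.any():
        raise ValueError("both classes must be non-empty")
    y1, y2 = y[is_first], y[~is_first]
    mu1, mu2 = float(y1.mean()), float(y2.mean())
    pooled = float(
        (np.sum((y1 - mu1) ** 2) + np.sum((y2 - mu2) ** 2)) / len(y)
    )
    if pooled <= 0.0:
        raise ValueError("zero pooled variance: survival times degenerate")
    return LogisticLink(a=(mu2 - mu1) / pooled, b=(mu1 + mu2) / 2.0)


def weighted_class_params(x, weights) -> tuple[float, float]:
    """Weighted mean and (biased) weighted variance of one gene's values."""
    x = np.asarray(x, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.shape != w.shape:
        raise ValueError("values and weights must have the same shape")
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    if abs(w.sum() - 1.0) > 1e-12:
        raise ValueError("weights must sum to 1")
    m = float(np.sum(w * x))
    v = float(np.sum(w * (x - m) ** 2))
    return m, v


def class_weight_vectors(
    labels, classes: tuple[str, str], y=None, use_soft_weights: bool = True
) -> np.ndarray:
    """Per-class normalised sample weights, shape (2, n).

    Soft mode weights each sample by the logistic membership P(C_k | y_i);
    hard mode uses normalised label indicators.
    """
    labels = np.asarray(labels)
    n = len(labels)
    is_first = labels == classes[0]
    if not is_first.any() or is_first.all():
        raise ValueError("both classes must be present")
    if use_soft_weights:
        if y is None:
            raise ValueError("soft weights require survival times y")
        link = fit_logistic_link(y, is_first)
        p_first = link.prob_first(y)
        raw = np.vstack([p_first, 1.0 - p_first])
    else:
        raw = np.vstack([is_first, ~is_first]).astype(float)
    sums = raw.sum(axis=1, keepdims=True)
    if (sums <= 0).any():
        raise ValueError("a class received zero total weight")
    return raw / sums


def fit_gnb(
    X,
    labels,
    gene_ids,
    classes: tuple[str, str],
    y=None,
    use_soft_weights: bool = True,
    variance_floor: float = 1e-6,
    preprocessing: str = "log2p1",
) -> GNBModel:
    """Fit the two-class model on a (genes, samples) expression matrix.

    Priors are the empirical label frequencies.  Per-gene means and
    variances are the survival-weighted estimates (soft mode, default) or
    plain per-class moments (hard mode).  Variances are floored; floored
    genes are reported through a warning.
    """
    X = apply_preprocessing(np.asarray(X, dtype=float), preprocessing)
    labels = np.asarray(labels)
    gene_ids = list(gene_ids)
    if X.shape != (len(gene_ids), len(labels)):
        raise ValueError("X must be (n_genes, n_samples)")
    weights = class_weight_vectors(
        labels, classes, y=y, use_soft_weights=use_soft_weights
    )
    priors = np.array(
        [np.mean(labels == classes[0]), np.mean(labels == classes[1])]
    )
    means = weights @ X.T  # (2, genes)
    # biased weighted variance, single pass over classes
    variances = np.empty_like(means)
    for k in range(2):
        variances[k] = (X - means[k][:, None]) ** 2 @ weights[k]
    floored = variances < variance_floor
    if floored.any():
        genes = sorted(
            {gene_ids[g] for g in np.unique(np.nonzero(floored)[1])}
        )
        warnings.warn(
            f"variance floored for {len(genes)} gene(s): {genes[:10]}",
            RuntimeWarning,
            stacklevel=2,
        )
        variances = np.maximum(variances, variance_floor)
    return GNBModel(
        classes=tuple(classes),
        priors=priors,
        gene_ids=gene_ids,
        means=means,
        variances=variances,
        preprocessing="none" if preprocessing == "none" else "log2p1",
        variance_floor=variance_floor,
    )
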