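"""Cross-validated single-gene discriminant ranking and panel selection.

Each gene is scored by ``d12 = 1 - error12``, the complement of the
cross-validated misclassification rate of a one-gene generalized naive
Bayes classifier.  Samples are partitioned into ``folds`` stratified
subsets; in the default ("train_on_one") rotation scheme the classifier is trained
on ONE subset and tested on the union of the others, and errors are pooled
over all rotations.  The conventional train-on-(k-1) scheme is available
via ``cv_mode="conventional"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .gnb import class_weight_vectors


@dataclass
class GeneScore:
    gene_id: str
    d12: float
    abs_standardized_diff: float
    rank: int | None = None


@dataclass
class GenePanel:
    split_id: str
    gene_ids: list[str]

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("panel gene ids must be unique")


def make_folds(labels, classes, folds: int, seed: int) -> np.ndarray:
    """Deterministic stratified fold assignment (class shares preserved)."""
    labels = np.asarray(labels)
    n = len(labels)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if n < folds:
        raise ValueError("need at least as many samples as folds")
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        assignment[idx] = np.arange(len(idx)) % folds
    return assignment


def cv_discriminant_matrix(
    X,
    labels,
    classes: tuple[str, str],
    y=None,
    folds: int = 12,
    seed: int = 0,
    cv_mode: str = "train_on_one",
    use_soft_weights: bool = True,
    variance_floor: float = 1e-6,
) -> np.ndarray:
    """d12 for every row of a (genes, samples) matrix, vectorised.

    ``X`` must already be on the model scale.  Rotations whose training
    subset misses a class are skipped with a warning; if every rotation is
    skipped an error is raised.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if X.ndim != 2 or X.shape[1] != len(labels):
        raise ValueError("X must be (n_genes, n_samples)")
    is_first = labels == classes[0]
    if not is_first.any() or is_first.all():
        raise ValueError("both classes must be present")
    if cv_mode not in ("train_on_one", "conventional"):
        raise ValueError("cv_mode must be 'train_on_one' or 'conventional'")
    fold = make_folds(labels, classes, folds, seed)
    err = np.zeros(X.shape[0])
    total = 0
    skipped = 0
    for f in range(folds):
        train = fold == f if cv_mode == "train_on_one" else fold != f
        test = ~train
        if not test.any():
            skipped += 1
            continue
        tr_labels = labels[train]
        if (tr_labels == classes[0]).all() or (tr_labels == classes[1]).all():
            skipped += 1
            continue
        w = class_weight_vectors(
            tr_labels,
            classes,
            y=None if y is None else np.asarray(y)[train],
            use_soft_weights=use_soft_weights,
        )
        Xtr, Xte = X[:, train], X[:, test]
        means = w @ Xtr.T  # (2, genes)
        scores = np.empty((2, X.shape[0], int(test.sum())))
        prior_first = float(np.mean(tr_labels == classes[0]))
        priors = (prior_first, 1.0 - prior_first)
        for k in range(2):
            v = np.maximum(
                (Xtr - means[k][:, None]) ** 2 @ w[k], variance_floor
            )
            m = means[k][:, None]
            v = v[:, None]
            scores[k] = (
                -0.5 * (np.log(2.0 * np.pi * v) + (Xte - m) ** 2 / v)
                + np.log(priors[k])
            )
        pred_first = scores[0] >= scores[1]  # tie -> first class
        err += (pred_first != is_first[test][None, :]).sum(axis=1)
        total += int(test.sum())
    if total == 0:
        raise ValueError("all cross-validation rotations were skipped")
    if skipped:
        warnings.warn(
            f"{skipped} of {folds} rotations skipped (training subset "
            "missing a class)",
            RuntimeWarning,
            stacklevel=2,
        )
    return 1.0 - err / total


def cv_discriminant(
    gene_values,
    labels,
    classes: tuple[str, str],
    y=None,
    folds: int = 12,
    seed: int = 0,
    cv_mode: str = "train_on_one",
    use_soft_weights: bool = True,
) -> float:
    """d12 of a single gene (convenience wrapper)."""
    gene_values = np.asarray(gene_values, dtype=float)
    return float(
        cv_discriminant_matrix(
            gene_values[None, :],
            labels,
            classes,
            y=y,
            folds=folds,
            seed=seed,
            cv_mode=cv_mode,
            use_soft_weights=use_soft_weights,
        )[0]
    )


def _standardized_diff(X: np.ndarray, is_first: np.ndarray) -> np.ndarray:
    m1 = X[:, is_first].mean(axis=1)
    m2 = X[:, ~is_first].mean(axis=1)
    pooled = np.sqrt(
        (X[:, is_first].var(axis=1) + X[:, ~is_first].var(axis=1)) / 2.0
    )
    return np.abs(m1 - m2) / np.maximum(pooled, 1e-12)


def score_genes(
    X,
    gene_ids,
    labels,
    classes: tuple[str, str],
    y=None,
    folds: int = 12,
    seed: int = 0,
    cv_mode: str = "train_on_one",
    use_soft_weights: bool = True,
) -> list[GeneScore]:
    """Score every gene; ``X`` is on the model scale."""
    X = np.asarray(X, dtype=float)
    gene_ids = list(gene_ids)
    if X.shape[0] != len(gene_ids):
        raise ValueError("one gene id per row required")
    d12 = cv_discriminant_matrix(
        X,
        labels,
        classes,
        y=y,
        folds=folds,
        seed=seed,
        cv_mode=cv_mode,
        use_soft_weights=use_soft_weights,
    )
    smd = _standardized_diff(X, np.asarray(labels) == classes[0])
    return [
        GeneScore(gene_id=g, d12=float(d), abs_standardized_diff=float(s))
        for g, d, s in zip(gene_ids, d12, smd)
    ]


def rank_genes(scores: list[GeneScore]) -> list[GeneScore]:
    """Sort by descending d12; ties broken by larger |standardized mean
    difference|, then lexicographic gene id.  Ranks are re-assigned 1..G."""
    ranked = sorted(
        scores,
        key=lambda s: (-s.d12, -s.abs_standardized_diff, s.gene_id),
    )
    return [
        GeneScore(
            gene_id=s.gene_id,
            d12=s.d12,
            abs_standardized_diff=s.abs_standardized_diff,
            rank=i + 1,
        )
        for i, s in enumerate(ranked)
    ]


def select_panel(
    ranked: list[GeneScore], size: int = 60, split_id: str = "root"
) -> GenePanel:
    """Top ``size`` genes of a ranked list."""
    if size < 1:
        raise ValueError("panel size must be >= 1")
    if size > len(ranked):
        raise ValueError(
            f"panel size {size} exceeds number of scored genes {len(ranked)}"
        )
    ordered = sorted(ranked, key=lambda s: s.rank)
    return GenePanel(
        split_id=split_id, gene_ids=[s.gene_id for s in ordered[:size]]
    )
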