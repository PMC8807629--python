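"""The two-level hierarchical survival classifier.

Fitting chains the pipeline stages: impute censored survival, build the
LL/LS/SL/SS partition, rank genes per separation step with the
cross-validated discriminant, keep a fixed-size panel per step, and fit one
generalized naive Bayes model per step on its own sample subset.
Prediction routes each sample through the root (L vs S) classifier and then
through the matching child.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .features import rank_genes, score_genes, select_panel
from .gnb import GNBModel, apply_preprocessing, fit_gnb, log_posterior_matrix
from .grouping import build_survival_tree
from .io import CohortDataset


@dataclass
class HierarchicalSurvivalModel:
    """Three fitted GNB models arranged as a two-level tree.

    ``root`` separates L from S, ``left`` LL from LS, ``right`` SL from SS.
    Each sub-model's gene list is its selected panel.  ``config`` is the
    fitting-time configuration snapshot.
    """

    root: GNBModel
    left: GNBModel
    right: GNBModel
    config: dict

    @property
    def panels(self) -> dict:
        return {
            "root": list(self.root.gene_ids),
            "L_side": list(self.left.gene_ids),
            "S_side": list(self.right.gene_ids),
        }


def _fit_split(
    X_model, gene_ids, labels, classes, y, cfg: PipelineConfig
) -> tuple[GNBModel, list]:
    scores = score_genes(
        X_model,
        gene_ids,
        labels,
        classes,
        y=y,
        folds=cfg.folds,
        seed=cfg.seed,
        cv_mode=cfg.cv_mode,
        use_soft_weights=cfg.use_soft_weights,
    )
    ranked = rank_genes(scores)
    panel = select_panel(ranked, size=cfg.panel_size, split_id=classes[0])
    rows = [gene_ids.index(g) for g in panel.gene_ids]
    model = fit_gnb(
        X_model[rows],
        labels,
        panel.gene_ids,
        classes,
        y=y,
        use_soft_weights=cfg.use_soft_weights,
        variance_floor=cfg.variance_floor,
        preprocessing="none",  # X is already on the model scale
    )
    # record the intended prediction-time transform
    model.preprocessing = cfg.preprocessing
    return model, ranked


def fit_hierarchical(
    cohort: CohortDataset, cfg: PipelineConfig | None = None
) -> tuple[HierarchicalSurvivalModel, pd.DataFrame]:
    """Fit the full tree on a joined cohort.

    Returns the model and the training survival-group labels (sample_id,
    level1, level2, imputed_time).
    """
    if cfg is None:
        cfg = PipelineConfig()
    clin = cohort.clinical.records
    sample_ids = list(clin["sample_id"])
    tree = build_survival_tree(
        clin["time"].to_numpy(),
        clin["event"].to_numpy(),
        sample_ids=sample_ids,
        split_rule=cfg.split_rule,
        mean_rule=cfg.mean_rule,
        min_leaf=cfg.min_leaf,
    )
    labels = tree.labels
    gene_ids = cohort.expression.gene_ids
    X_raw = cohort.expression.values.to_numpy()
    X_model = apply_preprocessing(X_raw, cfg.preprocessing)

    root_model, _ = _fit_split(
        X_model,
        gene_ids,
        labels["level1"].to_numpy(),
        ("L", "S"),
        labels["imputed_time"].to_numpy(),
        cfg,
    )

    children = {}
    for side, classes in (("L", ("LL", "LS")), ("S", ("SL", "SS"))):
        mask = (labels["level1"] == side).to_numpy()
        y_side = tree.side_imputed[side].loc[
            labels.loc[mask, "sample_id"]
        ].to_numpy()
        children[side], _ = _fit_split(
            X_model[:, mask],
            gene_ids,
            labels.loc[mask, "level2"].to_numpy(),
            classes,
            y_side,
            cfg,
        )

    model = HierarchicalSurvivalModel(
        root=root_model,
        left=children["L"],
        right=children["S"],
        config=cfg.to_dict(),
    )
    return model, labels


def _check_genes(expression, needed: set) -> None:
    missing = sorted(needed - set(expression.gene_ids))
    if missing:
        raise ValueError(
            f"expression matrix is missing {len(missing)} panel gene(s): "
            f"{missing[:10]}"
        )


def _posteriors(submodel: GNBModel, expression) -> np.ndarray:
    """(2, n) normalised posteriors of a sub-model on raw expression."""
    X = expression.values.loc[submodel.gene_ids].to_numpy()
    logpost = log_posterior_matrix(submodel, X)
    shifted = logpost - logpost.max(axis=0, keepdims=True)
    p = np.exp(shifted)
    return p / p.sum(axis=0, keepdims=True)


def predict_subgroup(
    model: HierarchicalSurvivalModel, expression
) -> pd.DataFrame:
    """Route samples to LL/LS/SL/SS.

    Returns a DataFrame with columns ``sample_id``, ``level1``, ``level2``,
    ``posterior_root_L`` and ``posterior_leaf`` (posterior of the assigned
    leaf within its sibling pair).  Missing panel genes raise an error.
    """
    needed = set().union(*(set(v) for v in model.panels.values()))
    _check_genes(expression, needed)
    sample_ids = expression.sample_ids
    n = len(sample_ids)

    p_root = _posteriors(model.root, expression)
    is_long = p_root[0] >= p_root[1]  # tie -> first (L)
    level1 = np.where(is_long, "L", "S")
    level2 = np.empty(n, dtype=object)
    p_leaf = np.empty(n)
    for side, child in (("L", model.left), ("S", model.right)):
        idx = np.flatnonzero(level1 == side)
        if len(idx) == 0:
            continue
        sub_expr = _Sub(expression, idx)
        p = _posteriors(child, sub_expr)
        first = p[0] >= p[1]
        level2[idx] = np.where(first, child.classes[0], child.classes[1])
        p_leaf[idx] = np.where(first, p[0], p[1])
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "level1": level1,
            "level2": level2,
            "posterior_root_L": p_root[0],
            "posterior_leaf": p_leaf,
        }
    )


class _Sub:
    """Column-subset view of an ExpressionMatrix (internal)."""

    def __init__(self, expression, idx):
        self.values = expression.values.iloc[:, idx]
        self.gene_ids = expression.gene_ids
        self.sample_ids = [expression.sample_ids[i] for i in idx]


def predict_two_group(
    model: HierarchicalSurvivalModel, expression
) -> pd.DataFrame:
    """Root-only prediction: L or S per sample."""
    _check_genes(expression, set(model.root.gene_ids))
    p_root = _posteriors(model.root, expression)
    is_long = p_root[0] >= p_root[1]
    return pd.DataFrame(
        {
            "sample_id": expression.sample_ids,
            "level1": np.where(is_long, "L", "S"),
            "posterior_root_L": p_root[0],
        }
    )
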