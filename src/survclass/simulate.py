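"""Synthetic cohorts with planted survival subgroups and informative genes.

Expression is log2-normal: per-gene Gaussian log2 expression with a planted
class-mean shift for the informative genes, exponentiated to FPKM-like
values (so the classifier's log transform sees the planted Gaussian
structure).  Survival is exponential with a subgroup-specific scale;
censoring is an independent uniform time calibrated so the expected
censored fraction matches the configured rate.

The module also provides the auxiliary random inputs used to verify the
analytic properties of the geometric-mean transform and the
equicorrelated-Gaussian example.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .grouping import LEVEL2_LABELS
from .io import ClinicalTable, CohortDataset, ExpressionMatrix

SPLIT_IDS = ("root", "L_side", "S_side")


@dataclass
class SyntheticConfig:
    """Generator settings; defaults mirror the study's panel geometry."""

    n_per_subgroup: tuple[int, int, int, int] = (100, 100, 100, 100)
    n_genes: int = 1408
    n_informative_per_split: int = 60
    effect_size: float = 1.0
    survival_scale: tuple[float, float, float, float] = (100.0, 40.0, 25.0, 8.0)
    censoring_rate: float = 0.2
    seed: int = 0
    structure_seed: int = 0
    base_log_mean_range: tuple[float, float] = (4.0, 10.0)
    log_sd: float = 1.0

    def __post_init__(self) -> None:
        if len(self.n_per_subgroup) != 4 or any(
            n < 1 for n in self.n_per_subgroup
        ):
            raise ValueError("n_per_subgroup must be 4 positive integers")
        if self.n_genes < 1 or self.n_informative_per_split < 1:
            raise ValueError("gene counts must be positive")
        if 3 * self.n_informative_per_split > self.n_genes:
            raise ValueError(
                "3 * n_informative_per_split must not exceed n_genes"
            )
        if len(self.survival_scale) != 4 or any(
            s <= 0 for s in self.survival_scale
        ):
            raise ValueError("survival scales must be 4 positive reals")
        ll, ls, sl, ss = self.survival_scale
        if not (ll > ls >= sl > ss):
            raise ValueError(
                "survival scales must be ordered LL > LS >= SL > SS"
            )
        if not (0.0 <= self.censoring_rate < 1.0):
            raise ValueError("censoring_rate must be in [0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")


@dataclass
class PlantedTruth:
    """True subgroup labels and the three disjoint informative gene sets."""

    subgroup: pd.Series  # sample_id -> LL/LS/SL/SS
    informative_genes: dict  # split id -> list of gene ids

    def __post_init__(self) -> None:
        sets = [set(v) for v in self.informative_genes.values()]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                if sets[i] & sets[j]:
                    raise ValueError("informative gene sets must be disjoint")


def _censoring_horizon(scales, weights, rate: float) -> float:
    """Upper bound c of Uniform(0, c) censoring giving the target rate.

    For T ~ Exp(scale s) and C ~ U(0, c), P(C < T) = (s/c)(1 - exp(-c/s));
    the cohort-level rate is the sample-size-weighted mixture.  The rate is
    continuous and strictly decreasing in c, so the root is bracketed and
    unique.
    """

    def censored_fraction(c):
        s = np.asarray(scales, dtype=float)
        return float(np.sum(weights * (s / c) * (1.0 - np.exp(-c / s))))

    lo, hi = 1e-9, 1e9 * max(scales)
    return brentq(lambda c: censored_fraction(c) - rate, lo, hi, xtol=1e-10)


def generate_cohort(
    cfg: SyntheticConfig,
) -> tuple[CohortDataset, PlantedTruth]:
    """Draw a cohort; deterministic given the config.

    Gene-level structure (which genes are informative, per-gene baseline
    means) is drawn from ``structure_seed`` while samples are drawn from
    ``seed``, so cohorts with different ``seed`` but equal
    ``structure_seed`` come from the same generative model -- the setting
    needed for independent-cohort validation.
    """
    rng = np.random.default_rng(cfg.seed)
    structure_rng = np.random.default_rng(cfg.structure_seed)
    n_per = np.asarray(cfg.n_per_subgroup, dtype=int)
    n = int(n_per.sum())
    subgroup = np.repeat(LEVEL2_LABELS, n_per)

    gene_ids = [f"G{i:05d}" for i in range(cfg.n_genes)]
    # sample ids are zero-padded so lexicographic joins keep cohort order
    width = len(str(n - 1))
    sample_ids = [f"P{i:0{width}d}" for i in range(n)]

    k = cfg.n_informative_per_split
    info_idx = structure_rng.choice(cfg.n_genes, size=3 * k, replace=False)
    informative = {
        "root": sorted(gene_ids[i] for i in info_idx[:k]),
        "L_side": sorted(gene_ids[i] for i in info_idx[k:2 * k]),
        "S_side": sorted(gene_ids[i] for i in info_idx[2 * k:]),
    }

    lo, hi = cfg.base_log_mean_range
    base = structure_rng.uniform(lo, hi, size=cfg.n_genes)
    Z = rng.normal(base[:, None], cfg.log_sd, size=(cfg.n_genes, n))
    shift = cfg.effect_size * cfg.log_sd / 2.0
    is_l = np.isin(subgroup, ("LL", "LS"))
    Z[info_idx[:k]] += np.where(is_l, shift, -shift)[None, :]
    Z[info_idx[k:2 * k]] += np.where(
        subgroup == "LL", shift, np.where(subgroup == "LS", -shift, 0.0)
    )[None, :]
    Z[info_idx[2 * k:]] += np.where(
        subgroup == "SL", shift, np.where(subgroup == "SS", -shift, 0.0)
    )[None, :]
    fpkm = np.exp2(Z)

    scales = np.asarray(cfg.survival_scale, dtype=float)
    t_true = rng.exponential(np.repeat(scales, n_per))
    if cfg.censoring_rate == 0.0:
        time, event = t_true, np.ones(n, dtype=int)
    else:
        c = _censoring_horizon(scales, n_per / n, cfg.censoring_rate)
        censor = rng.uniform(0.0, c, size=n)
        time = np.minimum(t_true, censor)
        event = (t_true <= censor).astype(int)
    # guard against zero times (measure-zero, but invariants require > 0)
    time = np.maximum(time, 1e-12)

    expr = ExpressionMatrix(
        pd.DataFrame(fpkm, index=gene_ids, columns=sample_ids)
    )
    clin = ClinicalTable(
        pd.DataFrame(
            {"sample_id": sample_ids, "time": time, "event": event}
        )
    )
    cohort = CohortDataset(expr, clin)
    truth = PlantedTruth(
        subgroup=pd.Series(subgroup, index=sample_ids, name="subgroup"),
        informative_genes=informative,
    )
    return cohort, truth


def sample_uniform_likelihoods(d: int, n: int, seed: int = 0) -> np.ndarray:
    """n i.i.d. vectors of d Uniform(0, 1) values, shape (n, d)."""
    if d < 1 or n < 1:
        raise ValueError("d and n must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.uniform(0.0, 1.0, size=(n, d))


def sample_equicorrelated_gaussians(
    d: int, r: float, n_per_class: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Two labelled Gaussian classes with covariance (1 - r) I + r J.

    Class means are (1, ..., 1) (label +1) and (-1, ..., -1) (label -1).
    Returns ``(X, labels)`` with X of shape (2 * n_per_class, d).
    """
    if not (0.0 <= r < 1.0):
        raise ValueError("correlation r must be in [0, 1)")
    if d < 1 or n_per_class < 1:
        raise ValueError("d and n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    # X = sqrt(r) * shared + sqrt(1 - r) * independent has the target cov
    n = n_per_class
    shared = rng.normal(size=(2 * n, 1))
    indep = rng.normal(size=(2 * n, d))
    X = np.sqrt(r) * shared + np.sqrt(1.0 - r) * indep
    labels = np.concatenate([np.ones(n), -np.ones(n)])
    X += labels[:, None]
    return X, labels
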