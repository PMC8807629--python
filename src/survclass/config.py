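"""Pipeline configuration.

All tunable knobs of the fitting pipeline live in :class:`PipelineConfig` so
that a fitted model can record the exact settings it was produced with.
Configs are read from flat key/value YAML files; unknown keys are rejected.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

VALID_SPLIT_RULES = ("median", "variance")
VALID_MEAN_RULES = ("km", "arithmetic")
VALID_CV_MODES = ("train_on_one", "conventional")
VALID_PREPROCESSING = ("log2p1", "none")


@dataclass
class PipelineConfig:
    """Knobs for model fitting.

    Parameters
    ----------
    folds : int
        Number of cross-validation subsets used by the per-gene discriminant.
    panel_size : int
        Number of genes retained per separation step.
    seed : int
        Seed for the (only) random element of fitting: fold assignment.
    variance_floor : float
        Lower bound for per-gene class variances (on the model scale).
    split_rule : str
        Threshold rule used to cut imputed survival times into two groups,
        ``"median"`` or ``"variance"`` (exhaustive within-class variance
        minimisation).
    mean_rule : str
        What "mean survival" means in the imputation rule: ``"km"`` (area
        under the product-limit curve, restricted to the last observed time)
        or ``"arithmetic"`` (plain mean of observed times).
    cv_mode : str
        ``"train_on_one"`` trains each rotation on one subset and tests on the
        remaining ones; ``"conventional"`` is the usual inverse.
    use_soft_weights : bool
        Estimate class-conditional Gaussian parameters with logistic
        survival-membership weights instead of hard label indicators.
    min_leaf : int
        Minimum samples per survival subgroup.
    preprocessing : str
        Expression transform applied before Gaussian modelling.
    """

    folds: int = 12
    panel_size: int = 60
    seed: int = 0
    variance_floor: float = 1e-6
    split_rule: str = "median"
    mean_rule: str = "km"
    cv_mode: str = "train_on_one"
    use_soft_weights: bool = True
    min_leaf: int = 10
    preprocessing: str = "log2p1"

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.panel_size < 1:
            raise ValueError("panel_size must be >= 1")
        if self.variance_floor <= 0:
            raise ValueError("variance_floor must be > 0")
        if self.split_rule not in VALID_SPLIT_RULES:
            raise ValueError(f"split_rule must be one of {VALID_SPLIT_RULES}")
        if self.mean_rule not in VALID_MEAN_RULES:
            raise ValueError(f"mean_rule must be one of {VALID_MEAN_RULES}")
        if self.cv_mode not in VALID_CV_MODES:
            raise ValueError(f"cv_mode must be one of {VALID_CV_MODES}")
        if self.preprocessing not in VALID_PREPROCESSING:
            raise ValueError(
                f"preprocessing must be one of {VALID_PREPROCESSING}"
            )
        if self.min_leaf < 2:
            raise ValueError("min_leaf must be >= 2")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_dict(data)
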