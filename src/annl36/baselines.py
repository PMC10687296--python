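"""Comparison models behind a uniform fit/predict contract.

The comparison set mirrors the experiment's baseline rows: decision-tree
regressors stratified by gender/region/age (DT-GE/RE/AG), support vector
regression with linear and polynomial kernels (SVR-LNR/SVR-POLY), and an
RBF network in standardized (RBF-S) and normalized (RBF-N) input coding —
realized as kernel ridge regression with a Gaussian kernel, a standard
RBF-network fit.  All internals delegate to scikit-learn; the uniform
contract (same feature encoding as the ANN, predictions on the percent
scale, evaluation through :mod:`annl36.metrics`) is what this module owns.

``gain_ratio`` — information gain divided by split information — is
implemented directly: it is the attribute-scoring statistic used to rank
region/age/gender against disease outcomes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
import logging
import math

import numpy as np
import pandas as pd

from .encode import CodingConfig
from .experiment import build_features

__all__ = ["BaselineSpec", "FittedBaseline", "gain_ratio", "fit_baseline", "predict_baseline", "BASELINE_IDS"]

logger = logging.getLogger(__name__)

BASELINE_IDS = ("DT-GE", "DT-RE", "DT-AG", "SVR-LNR", "SVR-POLY", "RBF-S", "RBF-N")

#: panel selected by the stratification suffix of the model id
_PANEL = {"GE": "gender", "RE": "region", "AG": "age"}


def _entropy(labels) -> float:
    n = len(labels)
    return -sum(c / n * math.log2(c / n) for c in Counter(labels).values())


def gain_ratio(feature, target) -> float:
    """Information gain of ``feature`` about ``target``, over split information.

    Shannon entropies in bits.  A feature with a single value has zero split
    information; the ratio is then defined as 0 (with a warning), matching
    the convention that a non-splitting attribute carries no usable gain.
    """
    f = list(feature)
    t = list(target)
    if len(f) != len(t) or len(f) < 2:
        raise ValueError("feature and target must have equal length >= 2")
    n = len(f)
    h_target = _entropy(t)
    split_info = _entropy(f)
    if split_info == 0.0:
        logger.warning("gain_ratio: single-valued feature, split information 0; returning 0")
        return 0.0
    cond = 0.0
    for value, count in Counter(f).items():
        subset = [ti for fi, ti in zip(f, t) if fi == value]
        cond += count / n * _entropy(subset)
    gain = h_target - cond
    # clip tiny negative float residue
    return max(gain, 0.0) / split_info


@dataclass
class BaselineSpec:
    """Declarative description of one comparison model."""

    model_id: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model_id not in BASELINE_IDS:
            raise ValueError(f"unknown model id {self.model_id!r}; choose from {BASELINE_IDS}")

    @property
    def panel(self) -> str | None:
        suffix = self.model_id.split("-")[-1]
        return _PANEL.get(suffix)


@dataclass
class FittedBaseline:
    spec: BaselineSpec
    estimator: object
    input_coder: CodingConfig
    coding_kind: str


def _make_estimator(spec: BaselineSpec, seed: int):
    from sklearn.kernel_ridge import KernelRidge
    from sklearn.svm import SVR
    from sklearn.tree import DecisionTreeRegressor

    hp = dict(spec.hyperparameters)
    if spec.model_id.startswith("DT"):
        return DecisionTreeRegressor(random_state=seed, **hp)
    if spec.model_id == "SVR-LNR":
        return SVR(kernel="linear", **{"C": 100.0, "epsilon": 1e-3, **hp})
    if spec.model_id == "SVR-POLY":
        return SVR(kernel="poly", **{"C": 100.0, "epsilon": 1e-3, "degree": 3, **hp})
    # RBF network stand-in: Gaussian-kernel ridge regression
    return KernelRidge(kernel="rbf", **{"alpha": 1e-3, "gamma": 1.0, **hp})


def fit_baseline(spec: BaselineSpec, table: pd.DataFrame, seed: int = 1) -> FittedBaseline:
    """Fit a comparison model on a prevalence table.

    The feature encoding matches the ANN's; RBF variants code the base-rate
    input standardized (``RBF-S``) or min-max normalized (``RBF-N``), all
    others min-max.  Targets are the raw percentages.
    """
    coding_kind = "zscore" if spec.model_id == "RBF-S" else "minmax"
    values = table["prevalence_pct"].to_numpy(dtype=float)
    coder = CodingConfig.fit(values, kind=coding_kind)
    X = build_features(table, coder, clamp=True)
    est = _make_estimator(spec, seed)
    est.fit(X, values)
    return FittedBaseline(spec=spec, estimator=est, input_coder=coder, coding_kind=coding_kind)


def predict_baseline(model: FittedBaseline, table: pd.DataFrame) -> np.ndarray:
    """Percent-scale predictions for the rows of ``table``."""
    X = build_features(table, model.input_coder, clamp=True)
    return np.asarray(model.estimator.predict(X), dtype=float)
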