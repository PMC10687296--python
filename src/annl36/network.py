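"""The fixed 23-weight feed-forward network and its deterministic forward pass.

Topology (canonical wiring): 10 inputs, two sigmoid hidden units without
biases, one linear output with a bias.  The 23 connection weights partition
exactly into the factor types of the L36 array:

====== ==========================  ==========
factor  role                        levels
====== ==========================  ==========
W1-W10  input -> hidden unit 1      2
W11     hidden unit 1 -> output     2
W12-W21 input -> hidden unit 2      3
W22     hidden unit 2 -> output     3
W23     output bias                 3
====== ==========================  ==========

so the 11 two-level columns drive the first hidden pathway and the 12
three-level columns the second pathway plus the bias.  The forward pass is

    y = W23 + W11 * sigma(sum_i W_i f_i) + W22 * sigma(sum_i W_{11+i} f_i)

with ``sigma`` the logistic sigmoid.  Outputs are on the coded target scale;
decoding back to percent is the caller's job (see :mod:`annl36.encode`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Topology", "Network", "build_network", "forward", "FEATURE_NAMES", "N_WEIGHTS"]

N_WEIGHTS = 23

#: Canonical feature layout fed to the 10 network inputs.
FEATURE_NAMES = (
    "year",          # 0 = 2013, 1 = 2019, 0.5 = pooled
    "gender",        # 0 = male, 1 = female, 0.5 = both
    "region_belgrade",
    "region_vojvodina",
    "region_sumadija_west",
    "region_east_south",
    "age_midpoint",  # coded to [0, 1]; population mean when unstratified
    "base_rate",     # the disease's observed share, coded to [0, 1]
    "stratum_size",  # stratum share of the cohort
    "const",         # always 1 (gives the hidden units an input bias)
)


@dataclass(frozen=True)
class Topology:
    """Network shape; the default is the canonical 10-2-1 wiring above."""

    n_inputs: int = 10
    n_hidden: int = 2
    n_outputs: int = 1

    @property
    def n_weights(self) -> int:
        # per hidden unit: n_inputs fan-in + 1 fan-out; plus one output bias
        return self.n_hidden * (self.n_inputs + 1) + 1


CANONICAL = Topology()


@dataclass(frozen=True)
class Network:
    """An immutable candidate network: a weight vector bound to a topology."""

    weights: np.ndarray
    topology: Topology = CANONICAL

    def predict(self, features: np.ndarray) -> np.ndarray:
        return forward(self, features)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("factor,value\n")
            for i, w in enumerate(self.weights, start=1):
                fh.write(f"W{i},{float(w)!r}\n")

    @classmethod
    def from_csv(cls, path, topology: Topology = CANONICAL) -> "Network":
        values = []
        with open(path) as fh:
            next(fh)
            for line in fh:
                _, v = line.strip().split(",")
                values.append(float(v))
        return build_network(np.array(values), topology)


def build_network(weights: np.ndarray, topology: Topology = CANONICAL) -> Network:
    """Validate a weight vector and freeze it into a network."""
    w = np.asarray(weights, dtype=float)
    if w.shape != (topology.n_weights,):
        raise ValueError(f"expected {topology.n_weights} weights, got shape {w.shape}")
    if not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite")
    w = w.copy()
    w.setflags(write=False)
    return Network(weights=w, topology=topology)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def forward(net: Network, features: np.ndarray) -> np.ndarray:
    """Coded-scale output for one feature vector or a stack of them.

    Deterministic and total on finite input; the output is bounded by
    ``|W23| + |W11| + |W22|``.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    n_in = net.topology.n_inputs
    if X.shape[1] != n_in:
        raise ValueError(f"expected {n_in} features, got {X.shape[1]}")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    w = net.weights
    h1 = _sigmoid(X @ w[:n_in])
    h2 = _sigmoid(X @ w[n_in + 1 : 2 * n_in + 1])
    out = w[2 * n_in + 2] + w[n_in] * h1 + w[2 * n_in + 1] * h2
    if np.asarray(features).ndim == 1:
        return float(out[0])
    return out
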