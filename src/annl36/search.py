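"""Taguchi robust-design search for the 23 network weights.

Instead of backpropagation, the weights are found by iterated evaluation
over the L36 orthogonal array:

1. A *level table* assigns each factor (weight) its current candidate
   values: 2 values for the two-level factors W1..W11, 3 for W12..W23.
2. The 36 array rows instantiate 36 candidate networks; each is scored by
   the objective (MMRE of decoded predictions against actual prevalences
   on the training split).
3. The *winner* is the best of the 36.  Additionally one *confirmation*
   candidate is assembled from the per-factor marginal means of log
   objective values — the classical Taguchi main-effect analysis followed
   by a confirmation experiment — and scored as well.
4. The level table contracts geometrically around the best weights seen so
   far: spacing halves each iteration (``contraction=0.5``), three-level
   factors keep their center ``{c - d, c, c + d}``, two-level factors
   straddle it ``{c - d/2, c + d/2}``.
5. The loop stops when the relative improvement of the best objective has
   stayed below ``epsilon`` (default 0.01) for ``patience`` consecutive
   iterations, or at ``max_iterations``.

The best-so-far network is cached and returned even when later contracted
grids no longer contain it, which makes the reported objective sequence
monotone non-increasing.  With a fixed dataset the whole search is
deterministic; the only randomness in the experiment is the train/test
split, which is seed-controlled upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import N_THREE_LEVEL, N_TWO_LEVEL, OrthogonalArray, load_l36
from .metrics import mmre
from .network import CANONICAL, Network, Topology, build_network

__all__ = [
    "LevelTable",
    "SearchConfig",
    "SearchTrace",
    "IterationRecord",
    "candidates_from_array",
    "evaluate_candidates",
    "refine_levels",
    "marginal_candidate",
    "run_search",
]

N_FACTORS = N_TWO_LEVEL + N_THREE_LEVEL


@dataclass
class LevelTable:
    """Current candidate values and spacing for each factor.

    ``levels[j]`` holds the ascending level values of factor j (2 values for
    j < 11, else 3); ``spacing[j]`` is the full gap between the extreme
    levels' neighbours used by the contraction rule; ``iteration`` counts
    refinements applied.
    """

    levels: list[np.ndarray]
    spacing: np.ndarray
    iteration: int = 0

    def __post_init__(self) -> None:
        if len(self.levels) != N_FACTORS:
            raise ValueError(f"need {N_FACTORS} factors, got {len(self.levels)}")
        for j, vals in enumerate(self.levels):
            want = 2 if j < N_TWO_LEVEL else 3
            if len(vals) != want:
                raise ValueError(f"factor W{j + 1}: expected {want} levels, got {len(vals)}")
            if np.any(np.diff(vals) <= 0):
                raise ValueError(f"factor W{j + 1}: levels must be ascending and distinct")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")

    @classmethod
    def initial(cls, bias_center: float = 0.5, scale: float = 1.0) -> "LevelTable":
        """Starting grid: two-level factors at ``{-s, +s}``, three-level at
        ``{-s, 0, +s}``; the output-bias factor W23 is centered at the coded
        target midpoint (``bias_center``) rather than 0 — with coded targets
        in an interior band of [0, 1], candidates then straddle the data
        instead of sitting two sigmoid-amplitudes away from it."""
        levels: list[np.ndarray] = []
        for j in range(N_FACTORS):
            if j < N_TWO_LEVEL:
                levels.append(np.array([-scale, scale]))
            elif j == N_FACTORS - 1:
                levels.append(np.array([bias_center - scale, bias_center, bias_center + scale]))
            else:
                levels.append(np.array([-scale, 0.0, scale]))
        spacing = np.array([2.0 * scale] * N_TWO_LEVEL + [scale] * N_THREE_LEVEL)
        return cls(levels=levels, spacing=spacing)

    def snapshot(self) -> list[list[float]]:
        return [list(map(float, v)) for v in self.levels]


@dataclass
class SearchConfig:
    """Knobs of the robust-design loop (defaults = the canonical experiment)."""

    contraction: float = 0.5
    epsilon: float = 0.01
    epsilon_mode: str = "relative"  # or "absolute"
    patience: int = 3
    max_iterations: int = 20
    use_confirmation: bool = True
    initial_scale: float = 1.0
    bias_center: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.contraction < 1:
            raise ValueError("contraction must be in (0, 1)")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.patience < 1 or self.max_iterations < 1:
            raise ValueError("patience and max_iterations must be >= 1")


@dataclass
class IterationRecord:
    iteration: int
    winner: str                      # "ANN<k>": best of the 36 array rows
    winner_objective: float
    best_objective: float            # best-so-far after this iteration
    levels: list[list[float]] = field(repr=False)
    confirmation_objective: float | None = None


@dataclass
class SearchTrace:
    records: list[IterationRecord] = field(default_factory=list)
    converged: bool = False

    @property
    def n_iterations(self) -> int:
        return len(self.records)

    def best_sequence(self) -> list[float]:
        return [r.best_objective for r in self.records]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "iteration": [r.iteration for r in self.records],
                "winner": [r.winner for r in self.records],
                "winner_objective": [r.winner_objective for r in self.records],
                "best_objective": [r.best_objective for r in self.records],
            }
        )


def candidates_from_array(array: OrthogonalArray, levels: LevelTable) -> np.ndarray:
    """Instantiate the 36 candidate weight vectors, in array row order."""
    out = np.empty((array.n_rows, N_FACTORS))
    for j in range(N_FACTORS):
        vals = levels.levels[j]
        idx = array.cells[:, j] - 1  # 1-based level indices
        if idx.max() >= len(vals):
            raise ValueError(f"factor W{j + 1}: level index exceeds level table")
        out[:, j] = vals[idx]
    return out


def evaluate_candidates(
    candidates: np.ndarray,
    X: np.ndarray,
    actual_pct: np.ndarray,
    coder,
    topology: Topology = CANONICAL,
) -> np.ndarray:
    """MMRE (percent, on the decoded percent scale) of each candidate."""
    vals = np.empty(len(candidates))
    for i, w in enumerate(candidates):
        net = build_network(w, topology)
        pred = coder.decode(net.predict(X))
        vals[i] = mmre(actual_pct, pred)
    return vals


def marginal_candidate(
    array: OrthogonalArray, levels: LevelTable, objectives: np.ndarray
) -> np.ndarray:
    """Classical Taguchi main-effect pick: per factor, the level with the
    lowest marginal mean of log objective over the rows that used it."""
    logv = np.log(np.maximum(objectives, 1e-300))
    w = np.empty(N_FACTORS)
    for j in range(N_FACTORS):
        vals = levels.levels[j]
        means = [logv[array.cells[:, j] == k + 1].mean() for k in range(len(vals))]
        w[j] = vals[int(np.argmin(means))]
    return w


def refine_levels(
    levels: LevelTable, winner: np.ndarray, config: SearchConfig
) -> LevelTable:
    """Contract the level grid around the winner's weight values.

    Spacing shrinks by the contraction factor; three-level factors become
    ``{c - d, c, c + d}`` (winner value retained), two-level factors
    ``{c - d/2, c + d/2}``.
    """
    new_spacing = config.contraction * levels.spacing
    new_levels: list[np.ndarray] = []
    for j in range(N_FACTORS):
        c, d = float(winner[j]), float(new_spacing[j])
        if j < N_TWO_LEVEL:
            new_levels.append(np.array([c - d / 2, c + d / 2]))
        else:
            new_levels.append(np.array([c - d, c, c + d]))
    return LevelTable(levels=new_levels, spacing=new_spacing, iteration=levels.iteration + 1)


def run_search(
    X: np.ndarray,
    actual_pct: np.ndarray,
    coder,
    config: SearchConfig | None = None,
    array: OrthogonalArray | None = None,
    topology: Topology = CANONICAL,
) -> tuple[Network, SearchTrace]:
    """Run the full robust-design loop on a prepared training design.

    ``X`` is the (n, 10) feature matrix, ``actual_pct`` the strictly positive
    percent targets, ``coder`` the fitted target coding (decode maps network
    output back to percent).  Returns the best network found anywhere in the
    search and the per-iteration trace.  Non-convergence within
    ``max_iterations`` is flagged on the trace, never raised.
    """
    config = config or SearchConfig()
    array = array or load_l36()
    if np.any(np.asarray(actual_pct) <= 0):
        raise ValueError("MMRE objective needs strictly positive actual values")

    levels = LevelTable.initial(bias_center=config.bias_center, scale=config.initial_scale)
    trace = SearchTrace()
    best_w: np.ndarray | None = None
    best_obj = np.inf
    prev_best = None
    stall = 0

    for it in range(1, config.max_iterations + 1):
        cands = candidates_from_array(array, levels)
        objectives = evaluate_candidates(cands, X, actual_pct, coder, topology)
        wi = int(np.argmin(objectives))  # ties: lowest row index
        winner_name, winner_obj = f"ANN{wi + 1}", float(objectives[wi])
        if winner_obj < best_obj:
            best_obj, best_w = winner_obj, cands[wi].copy()
        conf_obj = None
        if config.use_confirmation:
            conf = marginal_candidate(array, levels, objectives)
            conf_obj = float(
                evaluate_candidates(conf[None, :], X, actual_pct, coder, topology)[0]
            )
            if conf_obj < best_obj:
                best_obj, best_w = conf_obj, conf.copy()
        trace.records.append(
            IterationRecord(
                it, winner_name, winner_obj, best_obj, levels.snapshot(), conf_obj
            )
        )

        if prev_best is not None:
            gain = prev_best - best_obj
            threshold = config.epsilon * prev_best if config.epsilon_mode == "relative" else config.epsilon
            stall = stall + 1 if gain < threshold else 0
            if stall >= config.patience:
                trace.converged = True
                break
        prev_best = best_obj
        levels = refine_levels(levels, best_w, config)

    return build_network(best_w, topology), trace
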