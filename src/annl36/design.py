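"""Mixed-level orthogonal array L36(2^11 · 3^12) and factorial-plan arithmetic.

The L36 array assigns 23 experimental factors — here the 23 connection
weights W1..W23 of a small feed-forward network — to 36 runs such that

* each of the 11 two-level factors (W1..W11) takes each level 18 times,
* each of the 12 three-level factors (W12..W23) takes each level 12 times,
* every pair of factors sees every level combination equally often
  (strength-2 orthogonality: 9 times for 2x2 pairs, 6 for 2x3, 4 for 3x3).

A full factorial plan over the same factors would need
2^11 * 3^12 = 1 088 391 168 runs; the array reduces this to 36, a fraction
of 1 - 36/1 088 391 168 of the work removed.

The array is shipped as package data (``data/l36.csv``) rather than being
generated: it is the ground truth of the design, and every load re-validates
the balance invariants so a corrupted transcription cannot go unnoticed.
Level indices are 1-based throughout (L1 = 1), matching standard Taguchi
notation.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "OrthogonalArray",
    "FactorialPlan",
    "BalanceReport",
    "load_l36",
    "full_factorial_size",
    "reduction_fraction",
    "validate_balance",
]

N_FACTORS = 23
N_TWO_LEVEL = 11  # W1..W11
N_THREE_LEVEL = 12  # W12..W23
N_RUNS = 36


class ArrayIntegrityError(ValueError):
    """The embedded array violates an orthogonal-array invariant."""


@dataclass(frozen=True)
class FactorialPlan:
    """A full factorial plan: a list of (factor id, number of levels)."""

    factors: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.factors:
            raise ValueError("a factorial plan needs at least one factor")
        for name, n_levels in self.factors:
            if n_levels < 2:
                raise ValueError(f"factor {name!r} has {n_levels} levels; need >= 2")

    @classmethod
    def from_levels(cls, levels: Sequence[int]) -> "FactorialPlan":
        return cls(tuple((f"F{i + 1}", int(n)) for i, n in enumerate(levels)))


#: The plan the L36 array is a fraction of: 11 two-level + 12 three-level factors.
L36_PLAN = FactorialPlan(
    tuple((f"W{i + 1}", 2 if i < N_TWO_LEVEL else 3) for i in range(N_FACTORS))
)


@dataclass(frozen=True)
class OrthogonalArray:
    """A validated mixed-level orthogonal array of 1-based level indices.

    ``cells[i, j]`` is the level (1..n_levels of column j) that run i assigns
    to factor j.  ``columns`` holds ``(factor_id, n_levels)`` pairs in order.
    """

    columns: tuple[tuple[str, int], ...]
    cells: np.ndarray = field(repr=False)

    @property
    def n_rows(self) -> int:
        return int(self.cells.shape[0])

    @property
    def factor_ids(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.columns)

    def row(self, i: int) -> np.ndarray:
        """Level indices of run ``i`` (0-based; run ANN1 is ``row(0)``)."""
        return self.cells[i]

    def to_csv(self, path: str | Path) -> None:
        """Write the array as CSV (header W1..W23, cells 1/2/3)."""
        header = ",".join(self.factor_ids)
        np.savetxt(path, self.cells, fmt="%d", delimiter=",", header=header, comments="")

    @classmethod
    def from_csv(cls, path: str | Path) -> "OrthogonalArray":
        with open(path) as fh:
            names = fh.readline().strip().split(",")
        cells = np.loadtxt(path, delimiter=",", skiprows=1, dtype=np.int64, ndmin=2)
        n_levels = cells.max(axis=0)
        columns = tuple((n, int(k)) for n, k in zip(names, n_levels))
        arr = cls(columns=columns, cells=cells)
        _check(arr)
        return arr


@dataclass(frozen=True)
class BalanceReport:
    """Outcome of the balance audit of an array.

    ``level_counts[j]`` maps level -> occurrences for column j;
    ``pair_counts[(j, k)]`` maps (level_j, level_k) -> occurrences.
    ``violations`` is empty iff the array satisfies all invariants.
    """

    level_counts: dict[str, dict[int, int]]
    pair_counts: dict[tuple[str, str], dict[tuple[int, int], int]]
    violations: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return not self.violations


def load_l36() -> OrthogonalArray:
    """Load and validate the embedded L36(2^11 · 3^12) array.

    Raises :class:`ArrayIntegrityError` naming the offending column or pair
    if the embedded data has been corrupted.
    """
    ref = importlib.resources.files("annl36.data").joinpath("l36.csv")
    with importlib.resources.as_file(ref) as path:
        arr = OrthogonalArray.from_csv(path)
    if arr.n_rows != N_RUNS or len(arr.columns) != N_FACTORS:
        raise ArrayIntegrityError(
            f"expected {N_RUNS} rows x {N_FACTORS} columns, "
            f"got {arr.n_rows} x {len(arr.columns)}"
        )
    declared = [2] * N_TWO_LEVEL + [3] * N_THREE_LEVEL
    for (name, n_levels), want in zip(arr.columns, declared):
        if n_levels != want:
            raise ArrayIntegrityError(f"column {name}: declared {n_levels} levels, expected {want}")
    return arr


def _check(arr: OrthogonalArray) -> None:
    report = validate_balance(arr)
    if not report.ok:
        raise ArrayIntegrityError("; ".join(report.violations[:5]))
    for name, n_levels in arr.columns:
        j = arr.factor_ids.index(name)
        col = arr.cells[:, j]
        if col.min() < 1 or col.max() > n_levels:
            raise ArrayIntegrityError(f"column {name}: cell outside 1..{n_levels}")


def validate_balance(arr: OrthogonalArray) -> BalanceReport:
    """Audit per-column level counts and pairwise combination counts.

    A strength-2 orthogonal array must show every level of every column
    equally often, and every ordered pair of columns must show every level
    combination equally often.  Violations are reported, never raised.
    """
    n = arr.n_rows
    level_counts: dict[str, dict[int, int]] = {}
    pair_counts: dict[tuple[str, str], dict[tuple[int, int], int]] = {}
    violations: list[str] = []

    for j, (name, n_levels) in enumerate(arr.columns):
        col = arr.cells[:, j]
        counts = {lvl: int((col == lvl).sum()) for lvl in range(1, n_levels + 1)}
        level_counts[name] = counts
        want = n // n_levels
        bad = {lvl: c for lvl, c in counts.items() if c != want}
        if bad or sum(counts.values()) != n:
            violations.append(f"column {name}: level counts {counts}, expected {want} each")

    for j, k in combinations(range(len(arr.columns)), 2):
        (nj, lj), (nk, lk) = arr.columns[j], arr.columns[k]
        combos: dict[tuple[int, int], int] = {}
        for a, b in zip(arr.cells[:, j], arr.cells[:, k]):
            combos[(int(a), int(b))] = combos.get((int(a), int(b)), 0) + 1
        pair_counts[(nj, nk)] = combos
        want = n // (lj * lk)
        if len(combos) != lj * lk or any(c != want for c in combos.values()):
            violations.append(f"pair ({nj},{nk}): combination counts {combos}, expected {want} each")

    return BalanceReport(level_counts, pair_counts, tuple(violations))


def full_factorial_size(plan: FactorialPlan) -> int:
    """Exact number of runs of the full factorial plan: prod of level counts."""
    size = 1
    for _, n_levels in plan.factors:
        size *= int(n_levels)
    return size


def reduction_fraction(plan: FactorialPlan, n_runs: int) -> float:
    """Fraction of full-factorial runs removed by using ``n_runs`` instead.

    ``1 - n_runs / full_factorial_size(plan)``, computed in exact rational
    arithmetic before conversion to float.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    total = full_factorial_size(plan)
    if n_runs > total:
        raise ValueError(f"n_runs={n_runs} exceeds full factorial size {total}")
    return float(1 - Fraction(n_runs, total))
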