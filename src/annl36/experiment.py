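"""Experiment harness: from prevalence tables to fitted models and reports.

The modelling dataset is a long prevalence table (disease, panel, stratum,
year, percent).  The canonical experiment fits one network per survey year
on the rows of the 10 most prevalent diseases from the region and age
panels (20 rows per year; the gender panel prints pooled-year values and is
therefore excluded from per-year fits), with a seed-controlled 70/30
train/test split.

Feature construction follows :data:`annl36.network.FEATURE_NAMES`: survey
year, gender and region/age descriptors, the disease's observed share coded
by the chosen coding function (the informative input), the stratum's cohort
share, and a constant.  Targets are the same percentages coded with the same
function into the interior band [0.2, 0.8]; predictions are decoded back to
percent before any error is computed.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import load_composition
from .encode import CodingConfig
from .metrics import EvaluationReport, mmre, pearson, r2_cubic, spearman
from .network import Network
from .search import SearchConfig, SearchTrace, run_search

__all__ = [
    "load_prevalence",
    "load_variants",
    "top_diseases",
    "build_model_table",
    "build_features",
    "split_indices",
    "AnnFit",
    "fit_ann",
    "ExperimentResult",
    "run_experiment",
]

TARGET_BAND = (0.2, 0.8)
AGE_MIDPOINTS = {
    "15-24": 19.5, "25-34": 29.5, "35-44": 39.5, "45-54": 49.5,
    "55-64": 59.5, "65-74": 69.5, "75-84": 79.5, "85+": 90.0,
}


def load_prevalence() -> pd.DataFrame:
    """The transcribed published prevalence fixture (region/age/gender panels)."""
    ref = importlib.resources.files("annl36.data").joinpath("prevalence.csv")
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path)
    df["year"] = df["year"].astype(str)
    return df


def load_variants() -> pd.DataFrame:
    """Alternate printed values for quantities the source states inconsistently."""
    ref = importlib.resources.files("annl36.data").joinpath("prevalence_variants.csv")
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def top_diseases(table: pd.DataFrame, k: int = 10) -> list[str]:
    """The ``k`` most prevalent diseases by mean region-panel prevalence."""
    panel = table[table["panel"] == "region"]
    means = panel.groupby("disease")["prevalence_pct"].mean()
    return list(means.sort_values(ascending=False).index[:k])


def build_model_table(
    table: pd.DataFrame,
    year: int | str | None,
    panels: tuple[str, ...] = ("region", "age"),
    diseases: list[str] | None = None,
) -> pd.DataFrame:
    """Rows of the modelling dataset for one survey year (or all, if None)."""
    df = table[table["panel"].isin(panels)]
    if diseases is not None:
        df = df[df["disease"].isin(diseases)]
    if year is not None:
        df = df[df["year"] == str(year)]
    if df.empty:
        raise ValueError("model table selection is empty")
    return df.reset_index(drop=True)


def _stratum_shares() -> dict[str, float]:
    comp = load_composition()
    total = comp["total"]
    shares = {"all": 1.0}
    for g, n in comp["gender"].items():
        shares[g] = n / total
    for r, n in comp["regions"].items():
        shares[r] = n / total
    for a, n in comp["age_groups"].items():
        shares[a] = n / total
    return shares


def build_features(rows: pd.DataFrame, input_coder: CodingConfig, clamp: bool = False) -> np.ndarray:
    """(n, 10) feature matrix in :data:`FEATURE_NAMES` order.

    Unstratified descriptors take neutral values (gender 0.5, region 0.25
    each, age 0.5); the base-rate column is the row's observed share passed
    through ``input_coder`` (clamped for test rows whose value falls outside
    the training support).
    """
    shares = _stratum_shares()
    X = np.empty((len(rows), 10))
    for i, row in enumerate(rows.itertuples(index=False)):
        year = {"2013": 0.0, "2019": 1.0}.get(str(row.year), 0.5)
        gender = {"male": 0.0, "female": 1.0}.get(row.stratum, 0.5)
        region = [0.25] * 4
        if row.stratum in ("Belgrade", "Vojvodina", "Sumadija-West", "East-South"):
            region = [0.0] * 4
            region[["Belgrade", "Vojvodina", "Sumadija-West", "East-South"].index(row.stratum)] = 1.0
        age = 0.5
        if row.stratum in AGE_MIDPOINTS:
            age = (AGE_MIDPOINTS[row.stratum] - 19.5) / (90.0 - 19.5)
        base = input_coder.encode(row.prevalence_pct, clamp=clamp)
        size = shares.get(row.stratum, 1.0)
        X[i] = [year, gender, *region, age, base, size, 1.0]
    return X


def split_indices(n: int, split: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Seeded shuffle split; ``split`` is the training fraction."""
    if not 0 < split < 1:
        raise ValueError("split must be in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(split * n))
    n_train = min(max(n_train, 1), n - 1)
    return np.sort(order[:n_train]), np.sort(order[n_train:])


@dataclass
class AnnFit:
    """Everything produced by one per-year network fit."""

    year: str
    coding: str
    network: Network
    trace: SearchTrace
    input_coder: CodingConfig
    target_coder: CodingConfig
    train_idx: np.ndarray
    test_idx: np.ndarray
    table: pd.DataFrame = field(repr=False)
    predictions_pct: np.ndarray = field(repr=False)

    @property
    def actual_pct(self) -> np.ndarray:
        return self.table["prevalence_pct"].to_numpy(dtype=float)

    @property
    def train_mmre(self) -> float:
        return mmre(self.actual_pct[self.train_idx], self.predictions_pct[self.train_idx])

    @property
    def test_mmre(self) -> float:
        return mmre(self.actual_pct[self.test_idx], self.predictions_pct[self.test_idx])

    @property
    def iterations(self) -> int:
        return self.trace.n_iterations


def fit_ann(
    table: pd.DataFrame,
    coding: str = "fuzzy",
    seed: int = 1,
    split: float = 0.7,
    config: SearchConfig | None = None,
    year: str = "all",
) -> AnnFit:
    """Fit the 23-weight network to a prevalence table by Taguchi search.

    Coders are fitted on the training split only; test-split base rates
    outside the training support are clamped (logged by the coder).
    """
    actual = table["prevalence_pct"].to_numpy(dtype=float)
    train_idx, test_idx = split_indices(len(table), split, seed)
    train_vals = actual[train_idx]
    input_coder = CodingConfig.fit(train_vals, kind=coding)
    target_coder = CodingConfig.fit(train_vals, kind=coding, band=TARGET_BAND)

    X = np.empty((len(table), 10))
    X[train_idx] = build_features(table.iloc[train_idx], input_coder, clamp=False)
    X[test_idx] = build_features(table.iloc[test_idx], input_coder, clamp=True)

    net, trace = run_search(
        X[train_idx], train_vals, target_coder, config=config or SearchConfig(seed=seed)
    )
    predictions = np.asarray(target_coder.decode(net.predict(X)))
    return AnnFit(
        year=year,
        coding=coding,
        network=net,
        trace=trace,
        input_coder=input_coder,
        target_coder=target_coder,
        train_idx=train_idx,
        test_idx=test_idx,
        table=table,
        predictions_pct=predictions,
    )


@dataclass
class ExperimentResult:
    """Per-year fits plus pooled correlation measures (Table 7 style)."""

    fits: dict[str, AnnFit]
    coding: str
    seed: int

    @property
    def model_id(self) -> str:
        return f"ANN-L36-{self.coding.capitalize()}"

    def pooled(self) -> tuple[np.ndarray, np.ndarray]:
        actual = np.concatenate([f.actual_pct for f in self.fits.values()])
        pred = np.concatenate([f.predictions_pct for f in self.fits.values()])
        return actual, pred

    @property
    def train_mmre(self) -> float:
        """Mean training MMRE over the year panels."""
        return float(np.mean([f.train_mmre for f in self.fits.values()]))

    @property
    def test_mmre(self) -> float:
        return float(np.mean([f.test_mmre for f in self.fits.values()]))

    @property
    def max_iterations_used(self) -> int:
        return max(f.iterations for f in self.fits.values())

    def pooled_pearson(self) -> float:
        return pearson(*self.pooled())

    def pooled_spearman(self) -> float:
        return spearman(*self.pooled())

    def reports(self) -> list[EvaluationReport]:
        out = []
        for year, f in self.fits.items():
            a, p = f.actual_pct, f.predictions_pct
            out.append(
                EvaluationReport(
                    model=self.model_id,
                    phase="training",
                    year=year,
                    mmre_pct=f.train_mmre,
                    pearson_r=pearson(a, p),
                    spearman_rho=spearman(a, p),
                    r2_cubic=r2_cubic(a, p),
                )
            )
            out.append(
                EvaluationReport(
                    model=self.model_id, phase="testing", year=year, mmre_pct=f.test_mmre
                )
            )
        return out


def run_experiment(
    coding: str = "fuzzy",
    seed: int = 1,
    split: float = 0.7,
    table: pd.DataFrame | None = None,
    years: tuple[str, ...] = ("2013", "2019"),
    config: SearchConfig | None = None,
    n_diseases: int = 10,
) -> ExperimentResult:
    """The canonical per-year model-fitting experiment on the fixture table."""
    table = table if table is not None else load_prevalence()
    diseases = top_diseases(table, n_diseases)
    fits = {}
    for year in years:
        sub = build_model_table(table, year, diseases=diseases)
        fits[year] = fit_ann(sub, coding=coding, seed=seed, split=split, config=config, year=year)
    return ExperimentResult(fits=fits, coding=coding, seed=seed)
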