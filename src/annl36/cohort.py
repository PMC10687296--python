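"""Survey-cohort data model, synthetic generation, and contingency statistics.

The real microdata behind the two national cross-sectional waves (2013 and
2019, 27 801 respondents in total) is not publicly available, so this
module emulates it: a :class:`StratumParams` fixture carries the published
marginal counts (year, region, age band, gender) and per-disease marginal
prevalences, stratum cell counts are derived by largest-remainder
apportionment of the year totals over the product of pooled marginal
shares, and each of the 17 disease flags is drawn as an independent
Bernoulli per respondent.

The generator is deliberately simple: it reproduces the published
univariate structure (composition shares and per-year disease prevalences)
but has no comorbidity correlation and no region/age/gender gradient within
a year unless per-cell probabilities are supplied explicitly.

Closed-form 2x2 statistics (odds ratio with Woolf log-normal CI, pooled
two-proportion z test) are included for the contingency analyses.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "REGIONS",
    "AGE_GROUPS",
    "GENDERS",
    "DISEASES",
    "StratumParams",
    "TwoByTwo",
    "load_composition",
    "default_params",
    "generate_cohort",
    "aggregate_prevalence",
    "odds_ratio",
    "two_proportion_test",
    "round_half_up",
]

REGIONS = ("Belgrade", "Vojvodina", "Sumadija-West", "East-South")
AGE_GROUPS = ("15-24", "25-34", "35-44", "45-54", "55-64", "65-74", "75-84", "85+")
GENDERS = ("male", "female")
DISEASES = (
    "Asthma",
    "Chronic lung diseases",
    "Myocardial infarction",
    "Coronary heart disease",
    "Hypertension",
    "Stroke",
    "Arthrosis",
    "Lower back diseases",
    "Cervical spine diseases",
    "Diabetes mellitus",
    "Allergies",
    "Liver cirrhosis",
    "Urinary track diseases",
    "Kidney diseases",
    "Depression",
    "High Cholesterol",
    "Cancer",
)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (table style), not banker's rounding."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` proportional to ``weights``."""
    w = np.asarray(weights, dtype=float)
    quota = w / w.sum() * total
    base = np.floor(quota).astype(int)
    short = total - base.sum()
    order = np.argsort(-(quota - base), kind="stable")
    base[order[:short]] += 1
    return base


@dataclass
class StratumParams:
    """Cell counts and per-disease Bernoulli probabilities for the generator.

    ``cells`` has one row per (year, region, age_group, gender) with an
    integer ``count``; counts within a year sum to that year's cohort size.
    ``disease_probs[disease][year]`` is the marginal probability; optional
    ``cell_probs[(disease, year, region, age_group, gender)]`` entries
    override it per cell.
    """

    cells: pd.DataFrame
    disease_probs: dict[str, dict[int, float]]
    cell_probs: dict[tuple, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for disease, by_year in self.disease_probs.items():
            for year, p in by_year.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"probability for {disease}/{year} outside [0, 1]: {p}")
        for key, p in self.cell_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"cell probability {key} outside [0, 1]: {p}")
        if (self.cells["count"] < 0).any():
            raise ValueError("cell counts must be non-negative")

    def year_total(self, year: int) -> int:
        return int(self.cells.loc[self.cells["year"] == year, "count"].sum())

    def probability(self, disease: str, year: int, region: str, age: str, gender: str) -> float:
        key = (disease, year, region, age, gender)
        if key in self.cell_probs:
            return self.cell_probs[key]
        return self.disease_probs[disease][year]


def load_composition() -> dict:
    """The published composition fixture (counts and prevalences) as a dict."""
    ref = importlib.resources.files("annl36.data").joinpath("cohort_composition.yaml")
    with ref.open() as fh:
        return yaml.safe_load(fh)


def default_params(
    composition: dict | None = None, years: tuple[int, ...] = (2013, 2019)
) -> StratumParams:
    """Build :class:`StratumParams` from the composition fixture.

    Cell counts come from largest-remainder apportionment of each year's
    total over the product of the pooled region, age and gender shares
    (the waves' published marginals are pooled, so the same composition is
    used for both years).
    """
    comp = composition or load_composition()
    region_n = np.array([comp["regions"][r] for r in REGIONS], dtype=float)
    age_n = np.array([comp["age_groups"][a] for a in AGE_GROUPS], dtype=float)
    gender_n = np.array([comp["gender"][g] for g in GENDERS], dtype=float)
    weights = (
        region_n[:, None, None] / region_n.sum()
        * age_n[None, :, None] / age_n.sum()
        * gender_n[None, None, :] / gender_n.sum()
    ).ravel()

    rows = []
    for year in years:
        counts = _largest_remainder(weights, int(comp["years"][year]))
        i = 0
        for region in REGIONS:
            for age in AGE_GROUPS:
                for gender in GENDERS:
                    rows.append((year, region, age, gender, int(counts[i])))
                    i += 1
    cells = pd.DataFrame(rows, columns=["year", "region", "age_group", "gender", "count"])

    probs = {
        d: {int(y): float(p) / 100.0 for y, p in comp["disease_prevalence_pct"][d].items()}
        for d in DISEASES
    }
    return StratumParams(cells=cells, disease_probs=probs)


def generate_cohort(params: StratumParams, seed: int) -> pd.DataFrame:
    """Draw a synthetic cohort: one row per respondent.

    Stratum membership follows the configured cell counts exactly; disease
    flags are independent Bernoulli draws with the cell's probability.
    Fixed seed implies an identical DataFrame.
    """
    rng = np.random.default_rng(seed)
    blocks = []
    for _, cell in params.cells.iterrows():
        n = int(cell["count"])
        if n == 0:
            continue
        block = pd.DataFrame(
            {
                "year": np.full(n, cell["year"]),
                "region": np.full(n, cell["region"], dtype=object),
                "age_group": np.full(n, cell["age_group"], dtype=object),
                "gender": np.full(n, cell["gender"], dtype=object),
            }
        )
        for disease in params.disease_probs:
            p = params.probability(
                disease, int(cell["year"]), cell["region"], cell["age_group"], cell["gender"]
            )
            block[disease] = (rng.random(n) < p).astype(np.int8)
        blocks.append(block)
    return pd.concat(blocks, ignore_index=True)


def aggregate_prevalence(records: pd.DataFrame, by: list[str] | None = None) -> pd.DataFrame:
    """Stratified prevalence table: percent positive per disease and stratum.

    ``by`` lists the stratification columns (default ``["year"]``).  Returns
    long format with columns ``disease``, the ``by`` columns, ``n`` and
    ``prevalence_pct``.  Empty strata cannot occur (groups come from data).
    """
    if records.empty:
        raise ValueError("no records to aggregate")
    by = by or ["year"]
    diseases = [c for c in records.columns if c in DISEASES]
    rows = []
    for keys, grp in records.groupby(by, sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        for disease in diseases:
            rows.append(
                dict(
                    zip(by, keys),
                    disease=disease,
                    n=len(grp),
                    prevalence_pct=100.0 * float(grp[disease].mean()),
                )
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TwoByTwo:
    """Exposure-outcome counts: a=exposed cases, b=exposed non-cases,
    c=unexposed cases, d=unexposed non-cases."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    def corrected(self) -> "TwoByTwo":
        """Haldane–Anscombe 0.5 continuity correction (opt-in, explicit)."""
        return _CorrectedTable(self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5)


@dataclass(frozen=True)
class _CorrectedTable(TwoByTwo):
    a: float
    b: float
    c: float
    d: float


def odds_ratio(t: TwoByTwo, confidence: float = 0.95) -> tuple[float, float, float, float]:
    """Odds ratio ``ad/bc`` with Woolf log-normal CI and two-sided Wald p.

    Zero cells raise; apply ``t.corrected()`` explicitly for the documented
    0.5 continuity correction.
    """
    if min(t.a, t.b, t.c, t.d) <= 0:
        raise ZeroDivisionError(
            "zero cell in 2x2 table; apply the 0.5 continuity correction "
            "explicitly via TwoByTwo.corrected() if appropriate"
        )
    or_ = (t.a * t.d) / (t.b * t.c)
    se = np.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    z = stats.norm.ppf(0.5 + confidence / 2)
    lo, hi = np.exp(np.log(or_) - z * se), np.exp(np.log(or_) + z * se)
    wald = np.log(or_) / se
    p = 2 * stats.norm.sf(abs(wald))
    return float(or_), float(lo), float(hi), float(p)


def two_proportion_test(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z test, two-sided.

    ``z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2))`` with the pooled
    ``p = (x1+x2)/(n1+n2)``.
    """
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2) or n1 <= 0 or n2 <= 0:
        raise ValueError("need 0 <= x <= n and n > 0 on both sides")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        raise ValueError("degenerate pooled proportion; z undefined")
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    return float(z), float(2 * stats.norm.sf(abs(z)))
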