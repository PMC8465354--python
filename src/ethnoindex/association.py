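"""Demographic association analysis.

Knowledge is dichotomized per informant as the number of *distinct taxa*
cited (≤threshold vs >threshold), tabulated against a demographic factor,
and tested with the Pearson chi-square statistic — no continuity
correction, since the published education and age statistics reproduce
exactly only without it.  The age–knowledge relationship uses a different
response: *total use-reports* per informant, regressed on age by OLS.
"""

from __future__ import annotations

import enum
import logging
import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .data_model import (
    DatasetLevel,
    Education,
    Gender,
    SurveyDataset,
    education_label,
)

logger = logging.getLogger(__name__)

AGE_BIN_LABELS = ("<=30", "31-40", "41-50", "51-60", "61-70", "71-80")


class Factor(enum.Enum):
    GENDER = "gender"
    PLACE = "place"
    COMMUNITY = "community"
    EDUCATION = "education"
    AGE_CATEGORY = "age_category"


class CapabilityError(ValueError):
    """Operation needs informant-level data that the dataset lacks."""


class DegenerateTableError(ValueError):
    """A row or column marginal is zero."""


class ExpectedCountWarning(UserWarning):
    """Some expected cell count is below 5; the chi-square p is asymptotic."""


@dataclass(frozen=True)
class ContingencyTable:
    factor: Factor
    row_labels: tuple[str, ...]
    counts: tuple[tuple[int, int], ...]  # columns: (<=threshold, >threshold)
    threshold: int = 5

    def __post_init__(self) -> None:
        if len(self.counts) < 2:
            raise ValueError("contingency table needs at least 2 rows")
        if len(self.row_labels) != len(self.counts):
            raise ValueError("row_labels and counts length mismatch")
        if any(len(row) != 2 for row in self.counts):
            raise ValueError("counts must be r×2")
        if any(c < 0 for row in self.counts for c in row):
            raise ValueError("counts must be non-negative")

    @property
    def grand_total(self) -> int:
        return sum(c for row in self.counts for c in row)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class CorrelationResult:
    stratum: str  # "F", "M" or "all"
    n: int
    pearson_r: Optional[float]
    slope: Optional[float]
    intercept: Optional[float]
    p_value: Optional[float]

    @property
    def defined(self) -> bool:
        return self.pearson_r is not None


def age_bin(age: int) -> str:
    if age <= 30:
        return AGE_BIN_LABELS[0]
    if age > 80:
        raise ValueError(f"age {age} outside the surveyed bins")
    return AGE_BIN_LABELS[min((age - 31) // 10 + 1, 5)]


def _factor_levels_and_key(ds: SurveyDataset, factor: Factor):
    if factor is Factor.GENDER:
        return [g.value for g in Gender], lambda i: i.gender.value
    if factor is Factor.PLACE:
        villages = sorted({i.village for i in ds.informants})
        return villages, lambda i: i.village
    if factor is Factor.COMMUNITY:
        return ["Dard", "Gujjar", "Kashmiri"], lambda i: i.community.value
    if factor is Factor.EDUCATION:
        return [education_label(e) for e in Education], lambda i: education_label(i.education)
    if factor is Factor.AGE_CATEGORY:
        return list(AGE_BIN_LABELS), lambda i: age_bin(i.age)
    raise ValueError(factor)


def dichotomize_knowledge(
    ds: SurveyDataset,
    factor: Factor | str,
    threshold: int = 5,
) -> ContingencyTable:
    """Tabulate informants by factor level × (distinct taxa ≤/> threshold).

    Factor levels with no informants are dropped (a chi-square row of zeros
    is degenerate).  Requires informant-level data.
    """
    if isinstance(factor, str):
        factor = Factor(factor)
    if ds.level is not DatasetLevel.INFORMANT_LEVEL:
        raise CapabilityError(
            "dichotomize_knowledge needs informant-level data: per-informant "
            "distinct-taxa counts cannot be recovered from aggregate rows; "
            "supply a pre-tabulated r×2 table instead"
        )
    distinct: dict[str, set[str]] = defaultdict(set)
    for r in ds.reports:
        distinct[r.informant_id].add(r.taxon_id)
    levels, key = _factor_levels_and_key(ds, factor)
    tallies = {lvl: [0, 0] for lvl in levels}
    for informant in ds.informants:
        k = len(distinct.get(informant.informant_id, ()))
        tallies[key(informant)][0 if k <= threshold else 1] += 1
    kept = [lvl for lvl in levels if sum(tallies[lvl]) > 0]
    return ContingencyTable(
        factor=factor,
        row_labels=tuple(kept),
        counts=tuple((tallies[lvl][0], tallies[lvl][1]) for lvl in kept),
        threshold=threshold,
    )


def chi_square(table: ContingencyTable) -> ChiSquareResult:
    """Pearson chi-square without continuity correction.

    Expected counts come from the row/column marginals; p is the upper tail
    of the chi-square distribution with (r−1)(c−1) df.  Emits
    :class:`ExpectedCountWarning` when any expected count is below 5.
    """
    obs = table.as_array()
    if obs.sum() < 1:
        raise DegenerateTableError("empty table")
    row_marg = obs.sum(axis=1)
    col_marg = obs.sum(axis=0)
    if (row_marg == 0).any() or (col_marg == 0).any():
        raise DegenerateTableError("zero row or column marginal")
    expected = np.outer(row_marg, col_marg) / obs.sum()
    statistic = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(statistic, df))
    if (expected < 5).any():
        warnings.warn(
            f"{int((expected < 5).sum())} expected count(s) < 5; "
            "asymptotic p-value may be inaccurate",
            ExpectedCountWarning,
            stacklevel=2,
        )
    return ChiSquareResult(statistic=statistic, df=df, p_value=p)


def permutation_chi_square_p(
    table: ContingencyTable,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo p-value: shuffle column-class labels across subjects.

    Independent oracle for :func:`chi_square`; returns the add-one-smoothed
    permutation p-value.
    """
    obs_stat = chi_square(table).statistic
    rng = np.random.default_rng(seed)
    rows = np.repeat(np.arange(len(table.counts)),
                     [a + b for a, b in table.counts])
    cols = np.concatenate([
        np.array([0] * a + [1] * b) for a, b in table.counts
    ])
    r, c = len(table.counts), 2
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(cols)
        tab = np.zeros((r, c))
        np.add.at(tab, (rows, perm), 1)
        row_m = tab.sum(axis=1)
        col_m = tab.sum(axis=0)
        if (col_m == 0).any():
            stat = 0.0
        else:
            exp = np.outer(row_m, col_m) / tab.sum()
            stat = float(((tab - exp) ** 2 / exp).sum())
        if stat >= obs_stat - 1e-12:
            hits += 1
    return (hits + 1) / (n_permutations + 1)


def knowledge_age_regression(
    ds: SurveyDataset,
    stratify_by_gender: bool = True,
) -> list[CorrelationResult]:
    """OLS of total use-reports per informant on age, with Pearson r.

    Returns an "all" stratum plus per-gender strata when requested; strata
    with n < 3 are flagged undefined.
    """
    if ds.level is not DatasetLevel.INFORMANT_LEVEL:
        raise CapabilityError("knowledge_age_regression needs informant-level data")
    totals: dict[str, int] = defaultdict(int)
    for r in ds.reports:
        totals[r.informant_id] += r.count
    strata: dict[str, tuple[list[float], list[float]]] = {"all": ([], [])}
    if stratify_by_gender:
        strata.update({"F": ([], []), "M": ([], [])})
    for informant in ds.informants:
        y = totals.get(informant.informant_id, 0)
        strata["all"][0].append(informant.age)
        strata["all"][1].append(y)
        if stratify_by_gender:
            s = strata[informant.gender.value]
            s[0].append(informant.age)
            s[1].append(y)
    out: list[CorrelationResult] = []
    for name, (ages, ys) in strata.items():
        n = len(ages)
        if n < 3 or len(set(ages)) < 2:
            out.append(CorrelationResult(name, n, None, None, None, None))
            continue
        x = np.asarray(ages, dtype=float)
        y = np.asarray(ys, dtype=float)
        res = stats.linregress(x, y)
        out.append(CorrelationResult(
            stratum=name, n=n, pearson_r=float(res.rvalue),
            slope=float(res.slope), intercept=float(res.intercept),
            p_value=float(res.pvalue),
        ))
    return out


def read_contingency_table(path: str, factor: Factor | str,
                           threshold: int = 5) -> ContingencyTable:
    """Read a pre-tabulated ``row_label,le_count,gt_count`` CSV."""
    import csv

    if isinstance(factor, str):
        factor = Factor(factor)
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        need = {"row_label", "le_count", "gt_count"}
        if reader.fieldnames is None or not need <= set(reader.fieldnames):
            raise ValueError(f"{path}: expected columns {sorted(need)}")
        labels, counts = [], []
        for row in reader:
            labels.append(row["row_label"])
            counts.append((int(row["le_count"]), int(row["gt_count"])))
    return ContingencyTable(factor=factor, row_labels=tuple(labels),
                            counts=tuple(counts), threshold=threshold)
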