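"""The six survey-consensus indices: UV, Fq, Rf, FUV, ICF and RI.

All indices are computable from an aggregate dataset plus the informant
denominator; informant-level datasets work equally (a use-report row simply
has count 1).  Definitions:

* ``UV = ΣU / n`` — total use-reports for a taxon over the number of
  informants.  U counts use-reports, not distinct informants: a taxon cited
  by one informant for two categories contributes 2.
* ``Fq = 100·UV`` (percent).
* ``Rf = 100 · taxa cited in a village / total taxa in the study``.
* ``FUV = ΣUV_s / n_s`` — mean UV over a family's member taxa.
* ``ICF = (N_ur − N_t) / (N_ur − 1)`` per disease category; undefined when
  ``N_ur ≤ 1``.
* ``RI = 100 · (Rel PH + Rel BS) / 2`` with each factor normalized by its
  maximum over the annotated taxa.

Rounding to 2 decimals (half-up) happens only at presentation; unrounded
values are retained on every row type.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .data_model import SurveyDataset, round_half_up

logger = logging.getLogger(__name__)


class DomainError(ValueError):
    """An index was requested outside its mathematical domain."""


@dataclass(frozen=True)
class TaxonIndexRow:
    taxon_id: str
    botanical_name: str
    ur_total: int
    uv: float

    @property
    def fq_percent(self) -> float:
        return 100.0 * self.uv

    @property
    def fq_display(self) -> float:
        return round_half_up(self.fq_percent)


@dataclass(frozen=True)
class FamilyIndexRow:
    family: str
    taxa: tuple[str, ...]
    uv_sum: float

    @property
    def ns(self) -> int:
        return len(self.taxa)

    @property
    def fuv(self) -> float:
        return self.uv_sum / self.ns

    @property
    def fuv_display(self) -> float:
        return round_half_up(self.fuv)


@dataclass(frozen=True)
class CategoryIndexRow:
    category: str
    n_ur: int
    n_t: int
    icf: Optional[float]

    @property
    def defined(self) -> bool:
        return self.icf is not None

    @property
    def icf_display(self) -> Optional[float]:
        return None if self.icf is None else round_half_up(self.icf)


@dataclass(frozen=True)
class RelImportanceRow:
    taxon_id: str
    ph: int
    bs: int
    rel_ph: float
    rel_bs: float

    @property
    def ri(self) -> float:
        return (self.rel_ph + self.rel_bs) / 2.0 * 100.0


@dataclass(frozen=True)
class VillageFrequencyRow:
    village: str
    taxa_cited: int
    total_taxa: int

    @property
    def rf_percent(self) -> float:
        return 100.0 * self.taxa_cited / self.total_taxa

    @property
    def rf_display(self) -> float:
        return round_half_up(self.rf_percent)


def use_value(ds: SurveyDataset) -> list[TaxonIndexRow]:
    """One row per register taxon; unreported taxa get UV = 0."""
    n = ds.n_informants
    if not n:
        raise DomainError("use_value requires n_informants >= 1")
    totals: dict[str, int] = defaultdict(int)
    for r in ds.reports:
        totals[r.taxon_id] += r.count
    return [
        TaxonIndexRow(
            taxon_id=t.taxon_id,
            botanical_name=t.botanical_name,
            ur_total=totals.get(t.taxon_id, 0),
            uv=totals.get(t.taxon_id, 0) / n,
        )
        for t in ds.taxa
    ]


def family_use_value(ds: SurveyDataset) -> list[FamilyIndexRow]:
    """Group UV rows by family; FUV is the mean member UV."""
    rows = use_value(ds)
    family_of = {t.taxon_id: t.family for t in ds.taxa}
    grouped: dict[str, list[TaxonIndexRow]] = defaultdict(list)
    for row in rows:
        grouped[family_of[row.taxon_id]].append(row)
    return [
        FamilyIndexRow(
            family=fam,
            taxa=tuple(r.taxon_id for r in members),
            uv_sum=sum(r.uv for r in members),
        )
        for fam, members in sorted(grouped.items())
    ]


def icf_from_counts(n_ur: int, n_t: int) -> Optional[float]:
    """The consensus formula on raw counts; None when N_ur <= 1."""
    if n_ur < 0 or n_t < 0:
        raise DomainError("counts must be non-negative")
    if n_ur >= 1 and n_t > n_ur:
        raise DomainError("N_t cannot exceed N_ur")
    if n_ur <= 1:
        return None
    return (n_ur - n_t) / (n_ur - 1)


def icf(ds: SurveyDataset) -> list[CategoryIndexRow]:
    """Per-category consensus: N_ur = Σ counts, N_t = distinct taxa cited.

    Uncategorized reports are skipped with a warning; categories with
    N_ur <= 1 get a flagged-undefined ICF.
    """
    n_ur: dict[str, int] = defaultdict(int)
    taxa_sets: dict[str, set[str]] = defaultdict(set)
    skipped = 0
    for r in ds.reports:
        if r.category is None:
            skipped += 1
            continue
        n_ur[r.category] += r.count
        taxa_sets[r.category].add(r.taxon_id)
    if skipped:
        logger.warning("icf: skipped %d uncategorized report rows", skipped)
    return [
        CategoryIndexRow(category=cat, n_ur=n_ur[cat], n_t=len(taxa_sets[cat]),
                         icf=icf_from_counts(n_ur[cat], len(taxa_sets[cat])))
        for cat in sorted(n_ur)
    ]


def relative_importance(
    annotations: Sequence[tuple[str, int, int]],
) -> list[RelImportanceRow]:
    """RI rows from explicit (taxon_id, pharmacological functions, body
    systems) annotations.  Normalizes by the maxima over the annotated set."""
    if not annotations:
        raise DomainError("relative_importance requires at least one annotation")
    for tid, ph, bs in annotations:
        if ph < 1 or bs < 1:
            raise DomainError(f"taxon {tid}: ph and bs must be >= 1")
    max_ph = max(ph for _, ph, _ in annotations)
    max_bs = max(bs for _, _, bs in annotations)
    return [
        RelImportanceRow(taxon_id=tid, ph=ph, bs=bs,
                         rel_ph=ph / max_ph, rel_bs=bs / max_bs)
        for tid, ph, bs in annotations
    ]


def relative_frequency(ds: SurveyDataset) -> list[VillageFrequencyRow]:
    """Distinct taxa cited per village as a share of the full register.

    Reports without a village annotation are excluded; if none carry one,
    an empty list is returned with a warning.
    """
    if not ds.taxa:
        raise DomainError("relative_frequency requires a non-empty register")
    per_village: dict[str, set[str]] = defaultdict(set)
    for r in ds.reports:
        if r.village:
            per_village[r.village].add(r.taxon_id)
    if not per_village:
        logger.warning("relative_frequency: no village-annotated reports")
        return []
    total = len(ds.taxa)
    return [
        VillageFrequencyRow(village=v, taxa_cited=len(s), total_taxa=total)
        for v, s in sorted(per_village.items())
    ]


def village_frequency_from_counts(
    taxa_cited: Mapping[str, int], total_taxa: int
) -> list[VillageFrequencyRow]:
    """Rf rows from a pre-tabulated per-village distinct-taxa count."""
    if total_taxa < 1:
        raise DomainError("total_taxa must be >= 1")
    return [
        VillageFrequencyRow(village=v, taxa_cited=c, total_taxa=total_taxa)
        for v, c in taxa_cited.items()
    ]


def rank_report(rows: Sequence, key: str, top: int) -> list:
    """Stable descending sort on ``key``; ties broken by botanical name
    (falling back to the row's identifier fields) ascending."""
    if not rows:
        return []
    if not hasattr(rows[0], key):
        raise ValueError(f"unknown sort key {key!r} for {type(rows[0]).__name__}")

    def tiebreak(row):
        for attr in ("botanical_name", "taxon_id", "family", "category", "village"):
            if hasattr(row, attr):
                return getattr(row, attr)
        return ""

    ordered = sorted(rows, key=tiebreak)
    ordered.sort(key=lambda r: getattr(r, key), reverse=True)
    return ordered[:max(top, 0)]
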