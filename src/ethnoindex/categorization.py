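"""Map free-text ailments to the 15 disease categories and build descriptive profiles.

The default ailment map encodes the published category membership lists
(81 distinct ailments).  Lookup is normalization-first: lowercase, trimmed,
internal whitespace collapsed.  Slash-joined ailments in the source lists
("constipation/indigestion") are split into separate entries because
interview answers arrive one ailment at a time.
"""

from __future__ import annotations

import enum
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .data_model import (
    CATEGORY_CODES,
    LifeForm,
    Nativity,
    PlantPart,
    Preparation,
    Route,
    SurveyDataset,
    TaxonomicGroup,
    UseReport,
    round_half_up,
)

logger = logging.getLogger(__name__)


class CategorizationError(ValueError):
    """Raised when fallback policy is ``reject`` and ailments are unmapped."""


CATEGORY_LABELS: dict[str, str] = {
    "GAS": "Gastrointestinal problems",
    "CAR": "Cardiovascular problems",
    "DER": "Dermatological disorders",
    "GYN": "Gynecological problems",
    "NER": "Nervous system disorders",
    "PAR": "Parasitic problems",
    "CAN": "Cancer",
    "RES": "Respiratory complaints",
    "SKE": "Skeleto-muscular system disorders",
    "MET": "Metabolic syndromes",
    "ETH": "Ethnoveterinary ailments",
    "EY": "Energy yielding",
    "ENT": "Eyes, ears and nose problems",
    "FVR": "Fever",
    "IB": "Insect bites",
}

# Category membership lists as published.  "bronchitis" appears under both
# RES and ENT in the source; it is kept in RES only so that memberships stay
# disjoint — which makes the total exactly 81 ailments.
_MEMBERS: dict[str, tuple[str, ...]] = {
    "GAS": ("hepatotoxic", "ulcer", "choleretic", "constipation", "indigestion",
            "dysentery", "diarrhea", "excess gas", "heartburn", "nausea",
            "stomach pain", "vomiting", "kidney stone"),
    "CAR": ("blood purifier", "heart disorders", "heart attacks", "strokes"),
    "DER": ("abscess", "eczema", "acne", "itching", "ringworm", "alopecia",
            "blemishes", "leukoderma", "dandruff", "boils", "cuts", "burns",
            "scabies", "wounds"),
    "GYN": ("abortifacient", "oxytocic", "uterine hemorrhage",
            "menstrual problem", "genital tract problems",
            "lactation in women"),
    "NER": ("anxiety", "psychosis", "major depressive", "narcolepsy",
            "neuropathic pain", "vascular dementia"),
    "PAR": ("antihelminthic",),
    "CAN": ("persistent cough", "loss in weight", "fatigue"),
    "RES": ("asthma", "bronchitis", "common cold", "pneumonia",
            "shortness of breathing", "allergies", "tuberculosis"),
    "SKE": ("swelling", "arthritis", "rheumatic pain", "neck pain",
            "back pain", "muscle pain", "joint inflammation", "bone fracture"),
    "MET": ("obesity", "diabetes", "blood pressure", "excessive body fat",
            "abnormal cholesterol", "jaundice"),
    "ETH": ("animal wounds", "animal stomach problems",
            "milk yielding problems"),
    "EY": ("tonic", "laxative"),
    "ENT": ("throat pain", "toothache", "sinus infection"),
    "FVR": ("malaria", "typhoid", "high body temperature"),
    "IB": ("bee sting", "scorpion sting"),
}


def normalize_ailment(text: str) -> str:
    return re.sub(r"\s+", " ", text.strip().lower())


@dataclass(frozen=True)
class DiseaseCategory:
    code: str
    label: str
    member_ailments: frozenset[str]

    def __post_init__(self) -> None:
        if self.code not in CATEGORY_CODES:
            raise ValueError(f"unknown category code {self.code!r}")


class FallbackPolicy(enum.Enum):
    REJECT = "reject"
    UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class CategoryMap:
    """ailment → category-code lookup with a policy for unmapped ailments."""

    entries: Mapping[str, str]
    fallback: FallbackPolicy = FallbackPolicy.REJECT

    def __post_init__(self) -> None:
        normalized = {}
        for ailment, code in self.entries.items():
            if code not in CATEGORY_CODES:
                raise ValueError(f"unknown category code {code!r} for {ailment!r}")
            normalized[normalize_ailment(ailment)] = code
        object.__setattr__(self, "entries", normalized)

    def lookup(self, ailment: str) -> Optional[str]:
        return self.entries.get(normalize_ailment(ailment))

    def categories(self) -> tuple[DiseaseCategory, ...]:
        members: dict[str, set[str]] = {c: set() for c in CATEGORY_CODES}
        for ailment, code in self.entries.items():
            members[code].add(ailment)
        return tuple(
            DiseaseCategory(code, CATEGORY_LABELS[code], frozenset(members[code]))
            for code in CATEGORY_CODES
        )


def default_category_map(fallback: FallbackPolicy = FallbackPolicy.REJECT) -> CategoryMap:
    entries = {a: code for code, ailments in _MEMBERS.items() for a in ailments}
    return CategoryMap(entries=entries, fallback=fallback)


def read_category_map(path: str,
                      fallback: FallbackPolicy = FallbackPolicy.REJECT) -> CategoryMap:
    """Read an ``ailment,category`` CSV into a :class:`CategoryMap`."""
    import csv

    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"ailment", "category"} <= set(reader.fieldnames):
            raise ValueError(f"{path}: expected columns ailment,category")
        entries = {row["ailment"]: row["category"].strip() for row in reader}
    return CategoryMap(entries=entries, fallback=fallback)


def write_category_map(cmap: CategoryMap, path: str) -> None:
    import csv

    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["ailment", "category"])
        for ailment in sorted(cmap.entries):
            w.writerow([ailment, cmap.entries[ailment]])


def assign_categories(reports: Sequence[UseReport],
                      cmap: CategoryMap) -> list[UseReport]:
    """Set each report's category from its ailment text.

    Counts are never changed.  Unmapped ailments are rejected (with the
    offending strings listed) or left unassigned with a warning, per the
    map's fallback policy.  Reports that already carry a category keep it.
    """
    out: list[UseReport] = []
    unmapped: list[str] = []
    from dataclasses import replace

    for r in reports:
        if r.category is not None:
            out.append(r)
            continue
        code = cmap.lookup(r.ailment) if r.ailment else None
        if code is None:
            if cmap.fallback is FallbackPolicy.REJECT:
                unmapped.append(r.ailment)
                continue
            logger.warning("ailment %r not in category map; left unassigned",
                           r.ailment)
            out.append(r)
        else:
            out.append(replace(r, category=code))
    if unmapped:
        raise CategorizationError(
            f"unmapped ailment(s): {sorted(set(unmapped))}"
        )
    return out


# ---------------------------------------------------------------------------
# Descriptive profiles


class ProfileDimension(enum.Enum):
    LIFE_FORM = "life_form"
    PLANT_PART = "plant_part"
    PREPARATION = "preparation"
    ROUTE = "route"
    NATIVITY = "nativity"
    TAXONOMIC_GROUP = "taxonomic_group"


@dataclass(frozen=True)
class Profile:
    dimension: ProfileDimension
    counts: Mapping[str, int]
    percentages: Mapping[str, float]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def _dimension_label(taxon, dim: ProfileDimension) -> Optional[str]:
    if dim is ProfileDimension.LIFE_FORM:
        return taxon.life_form.value
    if dim is ProfileDimension.PLANT_PART:
        # each taxon contributes its single primary part
        return taxon.primary_part.value if taxon.primary_part else None
    if dim is ProfileDimension.PREPARATION:
        return taxon.preparation.value
    if dim is ProfileDimension.ROUTE:
        return taxon.route.value if taxon.route else None
    if dim is ProfileDimension.NATIVITY:
        return taxon.nativity.value if taxon.nativity else None
    if dim is ProfileDimension.TAXONOMIC_GROUP:
        return taxon.taxonomic_group.value if taxon.taxonomic_group else None
    raise ValueError(f"unknown dimension {dim!r}")


def profile(ds: SurveyDataset, dimension: ProfileDimension | str) -> Profile:
    """Tally each taxon once by its annotation on the requested dimension.

    Percentages are count/|taxa|×100 rounded half-up to 2 decimals, with
    |taxa| the full register size.  Taxa missing the annotation raise a
    validation error naming them.
    """
    if isinstance(dimension, str):
        try:
            dimension = ProfileDimension(dimension)
        except ValueError:
            raise ValueError(f"unknown profile dimension {dimension!r}") from None
    if not ds.taxa:
        raise ValueError("cannot profile an empty taxon register")
    counts: Counter[str] = Counter()
    missing: list[str] = []
    for t in ds.taxa:
        label = _dimension_label(t, dimension)
        if label is None:
            missing.append(t.taxon_id)
        else:
            counts[label] += 1
    if missing:
        raise ValueError(
            f"taxa missing {dimension.value} annotation: {missing}"
        )
    total = len(ds.taxa)
    percentages = {k: round_half_up(100.0 * v / total) for k, v in counts.items()}
    ordered = dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))
    return Profile(dimension=dimension, counts=ordered,
                   percentages={k: percentages[k] for k in ordered})


def nativity_summary(ds: SurveyDataset) -> Profile:
    """Native vs exotic taxon counts and percentages."""
    return profile(ds, ProfileDimension.NATIVITY)
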