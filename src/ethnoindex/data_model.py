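"""Survey domain types, delimited-text I/O and the informant-level → aggregate bridge.

The data model mirrors a three-table ethnomedicinal survey: an informant
roster, a taxon register and a use-report table.  A use-report is one
citation — one informant naming one taxon for one ailment — and is the
atomic count unit every index is built on.  Datasets exist at two levels:

* ``informant_level`` — one row per citation, ``count == 1`` everywhere;
* ``aggregate`` — rows grouped by (taxon, category, village) with summed
  counts and an explicit informant denominator ``n_informants``.

All index computations downstream accept either level; ``aggregate`` is
the bridge from interview records to published count tables.
"""

from __future__ import annotations

import csv
import enum
import io
import os
from collections import Counter
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence


class SchemaError(ValueError):
    """A required column is missing or an enum token cannot be parsed."""


class ReferentialIntegrityError(ValueError):
    """A report references an informant or taxon absent from its register."""


class UniquenessError(ValueError):
    """Duplicate identifiers within one register."""


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round for presentation the way the source tables do (0.005 → 0.01)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


class Gender(enum.Enum):
    F = "F"
    M = "M"


class Education(enum.IntEnum):
    """Ordered education levels; the integer value is the ordinal rank."""

    ILLITERATE = 0
    PRIMARY = 1
    MIDDLE = 2
    MATRIC = 3
    SENIOR_SECONDARY = 4
    GRADUATE = 5
    POSTGRADUATE = 6


class Community(enum.Enum):
    DARD = "Dard"
    GUJJAR = "Gujjar"
    KASHMIRI = "Kashmiri"


class LifeForm(enum.Enum):
    HERB = "Herb"
    SHRUB = "Shrub"
    TREE = "Tree"
    LIANA = "Liana"
    PARASITE = "Parasite"


class PlantPart(enum.Enum):
    BARK = "Bark"
    BULB = "Bulb"
    FLOWER = "Flower"
    LEAF = "Leaf"
    FRUIT = "Fruit"
    SEED = "Seed"
    RHIZOME = "Rhizome"
    ROOT = "Root"
    SHOOT = "Shoot"
    INFLORESCENCE = "Inflorescence"
    TUBER = "Tuber"
    WHOLE_PLANT = "WholePlant"


class Preparation(enum.Enum):
    POWDER = "Powder"
    JUICE_EXTRACT = "JuiceExtract"
    PASTE = "Paste"
    DECOCTION = "Decoction"
    CHEW = "Chew"


class Route(enum.Enum):
    ORAL = "Oral"
    TOPICAL = "Topical"
    BATH = "Bath"
    SMOKE_INHALATION = "SmokeInhalation"


class Nativity(enum.Enum):
    NATIVE = "Native"
    EXOTIC = "Exotic"


class TaxonomicGroup(enum.Enum):
    FUNGI = "Fungi"
    LYCOPHYTES_AND_FERNS = "LycophytesAndFerns"
    MONOCOT = "Monocot"
    DICOT = "Dicot"
    GYMNOSPERM = "Gymnosperm"


class DatasetLevel(enum.Enum):
    INFORMANT_LEVEL = "informant_level"
    AGGREGATE = "aggregate"


# The 15 disease-category codes.  The full category objects (labels and
# member ailments) live in :mod:`ethnoindex.categorization`; the bare codes
# are needed here for report validation.
CATEGORY_CODES = (
    "GAS", "CAR", "DER", "GYN", "NER", "PAR", "CAN", "RES",
    "SKE", "MET", "ETH", "EY", "ENT", "FVR", "IB",
)

AGE_MIN, AGE_MAX = 15, 110

# Accepted spellings per enum, beyond the canonical value/name.  Keys are
# casefolded before lookup; single-letter codes follow the source tables'
# abbreviation key (H/S/T/L/P, N/E, Wp/Lv/Rt/...).
_ENUM_ALIASES: dict[type, dict[str, object]] = {
    Gender: {"f": Gender.F, "female": Gender.F, "m": Gender.M, "male": Gender.M},
    Education: {
        "illiterate": Education.ILLITERATE,
        "primary": Education.PRIMARY,
        "middle": Education.MIDDLE,
        "matric": Education.MATRIC,
        "matriculation": Education.MATRIC,
        "seniorsecondary": Education.SENIOR_SECONDARY,
        "senior secondary": Education.SENIOR_SECONDARY,
        "graduate": Education.GRADUATE,
        "postgraduate": Education.POSTGRADUATE,
        "post graduate": Education.POSTGRADUATE,
    },
    Community: {"dard": Community.DARD, "gujjar": Community.GUJJAR,
                "kashmiri": Community.KASHMIRI},
    LifeForm: {
        "h": LifeForm.HERB, "herb": LifeForm.HERB,
        "s": LifeForm.SHRUB, "shrub": LifeForm.SHRUB,
        "t": LifeForm.TREE, "tree": LifeForm.TREE,
        "l": LifeForm.LIANA, "liana": LifeForm.LIANA,
        "p": LifeForm.PARASITE, "parasite": LifeForm.PARASITE,
    },
    PlantPart: {
        "b": PlantPart.BARK, "bark": PlantPart.BARK,
        "bb": PlantPart.BULB, "bulb": PlantPart.BULB,
        "fl": PlantPart.FLOWER, "flower": PlantPart.FLOWER,
        "lv": PlantPart.LEAF, "leaf": PlantPart.LEAF, "leaves": PlantPart.LEAF,
        "fr": PlantPart.FRUIT, "fruit": PlantPart.FRUIT,
        "se": PlantPart.SEED, "seed": PlantPart.SEED,
        "rh": PlantPart.RHIZOME, "rhizome": PlantPart.RHIZOME,
        "rt": PlantPart.ROOT, "root": PlantPart.ROOT,
        "sh": PlantPart.SHOOT, "st": PlantPart.SHOOT, "shoot": PlantPart.SHOOT,
        "stem": PlantPart.SHOOT,
        "inf": PlantPart.INFLORESCENCE, "inflorescence": PlantPart.INFLORESCENCE,
        "tu": PlantPart.TUBER, "tuber": PlantPart.TUBER,
        "wp": PlantPart.WHOLE_PLANT, "wholeplant": PlantPart.WHOLE_PLANT,
        "whole plant": PlantPart.WHOLE_PLANT,
    },
    Preparation: {
        "powder": Preparation.POWDER,
        "juiceextract": Preparation.JUICE_EXTRACT,
        "juice/extract": Preparation.JUICE_EXTRACT,
        "juice": Preparation.JUICE_EXTRACT,
        "extract": Preparation.JUICE_EXTRACT,
        "paste": Preparation.PASTE,
        "decoction": Preparation.DECOCTION,
        "chew": Preparation.CHEW,
        "chew/roasted": Preparation.CHEW,
    },
    Route: {
        "oral": Route.ORAL, "topical": Route.TOPICAL, "bath": Route.BATH,
        "smokeinhalation": Route.SMOKE_INHALATION,
        "smoke": Route.SMOKE_INHALATION,
    },
    Nativity: {"n": Nativity.NATIVE, "native": Nativity.NATIVE,
               "e": Nativity.EXOTIC, "exotic": Nativity.EXOTIC},
    TaxonomicGroup: {
        "fungi": TaxonomicGroup.FUNGI,
        "lycophytesandferns": TaxonomicGroup.LYCOPHYTES_AND_FERNS,
        "lycophytes and ferns": TaxonomicGroup.LYCOPHYTES_AND_FERNS,
        "monocot": TaxonomicGroup.MONOCOT,
        "monocotyledons": TaxonomicGroup.MONOCOT,
        "dicot": TaxonomicGroup.DICOT,
        "dicotyledons": TaxonomicGroup.DICOT,
        "gymnosperm": TaxonomicGroup.GYMNOSPERM,
        "gymnosperms": TaxonomicGroup.GYMNOSPERM,
    },
}


def parse_enum(cls: type, token: str):
    """Parse ``token`` into enum ``cls``; whitespace-trimmed, case-normalized.

    Accepts canonical values, member names and the table abbreviations.
    Raises :class:`SchemaError` for unknown tokens.
    """
    key = token.strip().casefold()
    alias = _ENUM_ALIASES.get(cls, {}).get(key)
    if alias is not None:
        return alias
    for member in cls:
        if str(member.value).casefold() == key or member.name.casefold() == key:
            return member
    raise SchemaError(f"unknown {cls.__name__} token: {token!r}")


@dataclass(frozen=True)
class Informant:
    informant_id: str
    age: int
    gender: Gender
    education: Education
    community: Community
    village: str

    def __post_init__(self) -> None:
        if not self.informant_id:
            raise SchemaError("informant_id must be non-empty")
        if not (AGE_MIN <= self.age <= AGE_MAX):
            raise SchemaError(
                f"informant {self.informant_id}: age {self.age} outside "
                f"[{AGE_MIN}, {AGE_MAX}]"
            )


@dataclass(frozen=True)
class TaxonRecord:
    taxon_id: str
    botanical_name: str
    family: str
    life_form: LifeForm
    parts_used: frozenset[PlantPart]
    preparation: Preparation
    route: Optional[Route] = None
    nativity: Optional[Nativity] = None
    voucher: str = ""
    taxonomic_group: Optional[TaxonomicGroup] = None
    primary_part: Optional[PlantPart] = None

    def __post_init__(self) -> None:
        if not self.taxon_id:
            raise SchemaError("taxon_id must be non-empty")
        if not self.family:
            raise SchemaError(f"taxon {self.taxon_id}: family must be non-empty")
        if not self.parts_used:
            raise SchemaError(f"taxon {self.taxon_id}: parts_used must be non-empty")
        if self.primary_part is None:
            # default: alphabetically first part (deterministic; writers put
            # the primary part first so file order round-trips it exactly)
            object.__setattr__(
                self, "primary_part",
                min(self.parts_used, key=lambda p: p.value),
            )
        elif self.primary_part not in self.parts_used:
            raise SchemaError(
                f"taxon {self.taxon_id}: primary_part not in parts_used"
            )


@dataclass(frozen=True)
class UseReport:
    taxon_id: str
    ailment: str = ""
    category: Optional[str] = None
    informant_id: Optional[str] = None
    village: Optional[str] = None
    count: int = 1

    def __post_init__(self) -> None:
        if self.count < 1:
            raise SchemaError(f"use-report count must be >= 1, got {self.count}")
        if self.category is not None and self.category not in CATEGORY_CODES:
            raise SchemaError(f"unknown disease category code: {self.category!r}")


@dataclass(frozen=True)
class SurveyDataset:
    """Validated container joining the informant, taxon and report tables."""

    taxa: tuple[TaxonRecord, ...]
    reports: tuple[UseReport, ...]
    informants: tuple[Informant, ...] = ()
    level: DatasetLevel = DatasetLevel.INFORMANT_LEVEL
    n_informants: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "taxa", tuple(self.taxa))
        object.__setattr__(self, "reports", tuple(self.reports))
        object.__setattr__(self, "informants", tuple(self.informants))
        _check_unique("informant_id", [i.informant_id for i in self.informants])
        _check_unique("taxon_id", [t.taxon_id for t in self.taxa])
        taxon_ids = {t.taxon_id for t in self.taxa}
        informant_ids = {i.informant_id for i in self.informants}
        bad_taxa = [
            (row, r.taxon_id)
            for row, r in enumerate(self.reports, start=1)
            if r.taxon_id not in taxon_ids
        ]
        if bad_taxa:
            raise ReferentialIntegrityError(
                "reports reference unknown taxa (row, taxon_id): "
                + ", ".join(f"({row}, {tid!r})" for row, tid in bad_taxa)
            )
        if self.level is DatasetLevel.INFORMANT_LEVEL:
            bad = [
                row for row, r in enumerate(self.reports, start=1)
                if r.informant_id is None or r.count != 1
            ]
            if bad:
                raise SchemaError(
                    "informant-level reports must carry informant_id and "
                    f"count=1; offending rows: {bad}"
                )
            dangling = [
                (row, r.informant_id)
                for row, r in enumerate(self.reports, start=1)
                if r.informant_id not in informant_ids
            ]
            if dangling:
                raise ReferentialIntegrityError(
                    "reports reference unknown informants (row, informant_id): "
                    + ", ".join(f"({row}, {iid!r})" for row, iid in dangling)
                )
            if self.n_informants is None:
                object.__setattr__(self, "n_informants", len(self.informants))
        else:
            if self.n_informants is None or self.n_informants <= 0:
                raise SchemaError(
                    "aggregate datasets require an explicit n_informants > 0"
                )

    @property
    def total_use_reports(self) -> int:
        return sum(r.count for r in self.reports)

    def taxon(self, taxon_id: str) -> TaxonRecord:
        for t in self.taxa:
            if t.taxon_id == taxon_id:
                return t
        raise KeyError(taxon_id)


def _check_unique(label: str, ids: Sequence[str]) -> None:
    dupes = [k for k, v in Counter(ids).items() if v > 1]
    if dupes:
        raise UniquenessError(f"duplicate {label}: {sorted(dupes)}")


def aggregate(ds: SurveyDataset) -> SurveyDataset:
    """Group reports by (taxon, category, village), summing counts.

    Idempotent on aggregate datasets.  The total use-report count is
    conserved and ``n_informants`` becomes the number of distinct cited
    informants (informant-level input) or is carried through unchanged.
    """
    if ds.level is DatasetLevel.AGGREGATE:
        n = ds.n_informants
    else:
        n = len({r.informant_id for r in ds.reports} | {i.informant_id for i in ds.informants})
        if n == 0:
            n = 1  # degenerate empty survey; keep the aggregate invariant valid
    grouped: Counter[tuple[str, Optional[str], Optional[str]]] = Counter()
    ailments: dict[tuple[str, Optional[str], Optional[str]], str] = {}
    for r in ds.reports:
        key = (r.taxon_id, r.category, r.village)
        grouped[key] += r.count
        ailments.setdefault(key, r.ailment)
    reports = tuple(
        UseReport(taxon_id=tid, ailment=ailments[(tid, cat, vil)], category=cat,
                  village=vil, count=c)
        for (tid, cat, vil), c in sorted(
            grouped.items(), key=lambda kv: (kv[0][0], kv[0][1] or "", kv[0][2] or "")
        )
    )
    return SurveyDataset(
        taxa=ds.taxa, reports=reports, informants=(),
        level=DatasetLevel.AGGREGATE, n_informants=n,
    )


# ---------------------------------------------------------------------------
# Delimited-text I/O

INFORMANT_COLUMNS = ("informant_id", "age", "gender", "education", "community",
                     "village")
TAXON_COLUMNS = ("taxon_id", "botanical_name", "family", "life_form",
                 "parts_used", "preparation", "route", "nativity", "voucher")
REPORT_COLUMNS = ("informant_id", "taxon_id", "ailment", "category", "village",
                  "count")


def _sniff_delimiter(path: str) -> str:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _read_rows(path: str, required: Sequence[str]) -> list[dict[str, str]]:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    delim = _sniff_delimiter(path)
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, header row required")
        fields = [f.strip() for f in reader.fieldnames]
        missing = [c for c in required if c not in fields]
        if missing:
            raise SchemaError(f"{path}: missing column(s) {missing}")
        rows = []
        for raw in reader:
            rows.append({(k or "").strip(): (v or "").strip()
                         for k, v in raw.items() if k is not None})
        return rows


def _parse_informant(row: Mapping[str, str]) -> Informant:
    return Informant(
        informant_id=row["informant_id"],
        age=int(row["age"]),
        gender=parse_enum(Gender, row["gender"]),
        education=parse_enum(Education, row["education"]),
        community=parse_enum(Community, row["community"]),
        village=row["village"],
    )


def _parse_taxon(row: Mapping[str, str]) -> TaxonRecord:
    parts_tokens = [p for p in row["parts_used"].split(";") if p.strip()]
    parts = [parse_enum(PlantPart, p) for p in parts_tokens]
    return TaxonRecord(
        taxon_id=row["taxon_id"],
        botanical_name=row["botanical_name"],
        family=row["family"],
        life_form=parse_enum(LifeForm, row["life_form"]),
        parts_used=frozenset(parts),
        primary_part=parts[0] if parts else None,
        preparation=parse_enum(Preparation, row["preparation"]),
        route=parse_enum(Route, row["route"]) if row.get("route") else None,
        nativity=parse_enum(Nativity, row["nativity"]) if row.get("nativity") else None,
        voucher=row.get("voucher", ""),
        taxonomic_group=(
            parse_enum(TaxonomicGroup, row["taxonomic_group"])
            if row.get("taxonomic_group") else None
        ),
    )


def _parse_report(row: Mapping[str, str]) -> UseReport:
    return UseReport(
        informant_id=row["informant_id"] or None,
        taxon_id=row["taxon_id"],
        ailment=row.get("ailment", ""),
        category=row["category"] or None,
        village=row["village"] or None,
        count=int(row["count"]) if row.get("count") else 1,
    )


def read_survey(
    informants_path: Optional[str],
    taxa_path: str,
    reports_path: str,
    level: DatasetLevel | str = DatasetLevel.INFORMANT_LEVEL,
    n_informants: Optional[int] = None,
) -> SurveyDataset:
    """Read the three survey tables into a validated :class:`SurveyDataset`.

    ``informants_path`` may be ``None`` for aggregate-only data, in which
    case ``n_informants`` must be supplied.
    """
    if isinstance(level, str):
        level = DatasetLevel(level)
    informants = (
        tuple(_parse_informant(r) for r in _read_rows(informants_path, INFORMANT_COLUMNS))
        if informants_path else ()
    )
    taxa = tuple(_parse_taxon(r) for r in _read_rows(taxa_path, TAXON_COLUMNS))
    reports = tuple(_parse_report(r) for r in _read_rows(reports_path, REPORT_COLUMNS))
    if level is DatasetLevel.AGGREGATE and n_informants is None and informants:
        n_informants = len(informants)
    return SurveyDataset(taxa=taxa, reports=reports, informants=informants,
                         level=level, n_informants=n_informants)


def write_survey(ds: SurveyDataset, informants_path: str, taxa_path: str,
                 reports_path: str) -> None:
    """Write the three survey tables with RFC-4180-style quoting."""
    with open(informants_path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(INFORMANT_COLUMNS)
        for i in ds.informants:
            w.writerow([i.informant_id, i.age, i.gender.value,
                        _EDU_LABELS[i.education], i.community.value, i.village])
    with open(taxa_path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(TAXON_COLUMNS + ("taxonomic_group",))
        for t in ds.taxa:
            parts = sorted(t.parts_used, key=lambda p: p.value)
            if t.primary_part is not None:
                parts = [t.primary_part] + [p for p in parts if p != t.primary_part]
            w.writerow([
                t.taxon_id, t.botanical_name, t.family, t.life_form.value,
                ";".join(p.value for p in parts), t.preparation.value,
                t.route.value if t.route else "",
                t.nativity.value if t.nativity else "", t.voucher,
                t.taxonomic_group.value if t.taxonomic_group else "",
            ])
    with open(reports_path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(REPORT_COLUMNS)
        for r in ds.reports:
            w.writerow([r.informant_id or "", r.taxon_id, r.ailment,
                        r.category or "", r.village or "", r.count])


_EDU_LABELS = {
    Education.ILLITERATE: "Illiterate",
    Education.PRIMARY: "Primary",
    Education.MIDDLE: "Middle",
    Education.MATRIC: "Matric",
    Education.SENIOR_SECONDARY: "SeniorSecondary",
    Education.GRADUATE: "Graduate",
    Education.POSTGRADUATE: "Postgraduate",
}


def education_label(level: Education) -> str:
    return _EDU_LABELS[level]


# ---------------------------------------------------------------------------
# Consistency audit against published per-taxon values


@dataclass(frozen=True)
class Discrepancy:
    taxon_id: str
    field: str
    printed: float
    recomputed: float


def validate_consistency(
    ds: SurveyDataset,
    printed: Mapping[str, Mapping[str, float]],
) -> list[Discrepancy]:
    """Audit published per-taxon Fq values against the dataset's counts.

    ``printed`` maps taxon_id → {"urs": ..., "fq": ...}.  Fq is recomputed
    as 100·URs/n from the *printed* UR count (the UR column is treated as
    primary); a record is emitted where the 2-decimal rounded values differ
    by more than 0.01.  Never raises.
    """
    n = ds.n_informants or len(ds.informants)
    out: list[Discrepancy] = []
    if not n:
        return out
    for taxon_id, vals in printed.items():
        if "fq" not in vals or "urs" not in vals:
            continue
        recomputed = round_half_up(100.0 * vals["urs"] / n)
        if abs(recomputed - round_half_up(vals["fq"])) > 0.01:
            out.append(Discrepancy(taxon_id, "fq", vals["fq"], recomputed))
    return out
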