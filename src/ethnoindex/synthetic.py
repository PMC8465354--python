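"""Synthetic informant-level surveys with the structure the analysis assumes.

One seeded generator stream drives draws in a fixed, documented order so
that adding a config field never silently reshuffles earlier draws:

1. taxon register: family partition, life form, parts, preparation, route,
   nativity, popularity weights, per-taxon category profiles;
2. informants: village, gender, age, education, community;
3. per informant: distinct-taxa knowledge count (zero-truncated Poisson
   with a log-linear mean), the taxa themselves (popularity-weighted,
   without replacement), then per chosen taxon a report count (truncated
   Poisson) and per report a disease category from the taxon's profile.

Every generated dataset passes data-model validation and feeds directly
into the index, categorization and association pipelines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import categorization
from .data_model import (
    CATEGORY_CODES,
    Community,
    DatasetLevel,
    Education,
    Gender,
    Informant,
    LifeForm,
    Nativity,
    PlantPart,
    Preparation,
    Route,
    SurveyDataset,
    TaxonRecord,
    UseReport,
)

_PROB_TOL = 1e-9


class ConfigError(ValueError):
    """The generator configuration is internally inconsistent."""


@dataclass(frozen=True)
class KnowledgeModel:
    """Log-linear mean for the zero-truncated Poisson distinct-taxa count.

    ``mu = base_rate * exp(age_coef*(age-age_mid)/10
                           + education_coef*edu_level
                           + community_offset)``
    with age centered at the midpoint of the configured age range and the
    education level its ordinal index (Illiterate=0 … Postgraduate=6).
    """

    base_rate: float = 4.0
    age_coef: float = 0.0       # per decade of age
    education_coef: float = 0.0  # per ordinal education level
    community_offsets: tuple[float, float, float] = (0.0, 0.0, 0.0)  # Dard, Gujjar, Kashmiri

    def __post_init__(self) -> None:
        if self.base_rate <= 0:
            raise ConfigError("base_rate must be > 0")
        if len(self.community_offsets) != 3:
            raise ConfigError("community_offsets must have 3 entries")


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    n_informants: int = 100
    n_taxa: int = 40
    n_families: int = 12
    villages: tuple[tuple[str, float], ...] = (
        ("Northwood", 0.4), ("Midvale", 0.35), ("Southfen", 0.25))
    gender_split: float = 0.25  # probability of F
    age_range: tuple[int, int] = (21, 80)
    education_probs: tuple[float, ...] = (
        0.25, 0.18, 0.23, 0.09, 0.16, 0.06, 0.03)
    community_probs: tuple[float, float, float] = (0.34, 0.21, 0.45)
    knowledge_model: KnowledgeModel = field(default_factory=KnowledgeModel)
    taxon_popularity: float = 0.3   # Dirichlet concentration; small → skewed
    category_profile_sharpness: float = 0.3  # Dirichlet over the 15 categories
    reports_per_taxon_mean: float = 1.3

    def __post_init__(self) -> None:
        if self.n_informants < 1 or self.n_taxa < 1:
            raise ConfigError("n_informants and n_taxa must be >= 1")
        if self.n_taxa < self.n_families:
            raise ConfigError("n_taxa must be >= n_families")
        if not self.villages:
            raise ConfigError("at least one village required")
        for name, probs in [
            ("village weights", [w for _, w in self.villages]),
            ("education_probs", list(self.education_probs)),
            ("community_probs", list(self.community_probs)),
        ]:
            if any(p < 0 for p in probs):
                raise ConfigError(f"{name} must be non-negative")
            if abs(sum(probs) - 1.0) > _PROB_TOL:
                raise ConfigError(f"{name} must sum to 1, got {sum(probs)!r}")
        if len(self.education_probs) != 7:
            raise ConfigError("education_probs must have 7 entries")
        if not (0.0 <= self.gender_split <= 1.0):
            raise ConfigError("gender_split must be a probability")
        if self.age_range[0] > self.age_range[1]:
            raise ConfigError("age_range min must be <= max")
        if self.taxon_popularity <= 0 or self.category_profile_sharpness <= 0:
            raise ConfigError("Dirichlet concentrations must be > 0")
        if self.reports_per_taxon_mean < 1.0:
            raise ConfigError("reports_per_taxon_mean must be >= 1")
        # worst-case knowledge mean must stay feasible
        km = self.knowledge_model
        age_mid = (self.age_range[0] + self.age_range[1]) / 2.0
        worst = km.base_rate * math.exp(
            abs(km.age_coef) * (self.age_range[1] - age_mid) / 10.0
            + max(km.education_coef * 6, 0.0)
            + max(km.community_offsets)
        )
        if worst > self.n_taxa:
            raise ConfigError(
                f"knowledge mean can reach {worst:.1f} which exceeds "
                f"n_taxa={self.n_taxa}"
            )


_LIFE_FORM_PROBS = {  # herb-dominant, mirroring a mountain survey flora
    LifeForm.HERB: 0.72, LifeForm.SHRUB: 0.12, LifeForm.TREE: 0.12,
    LifeForm.LIANA: 0.03, LifeForm.PARASITE: 0.01,
}

# canonical ailment per category so generated free text maps back through
# the default category map
_CANONICAL_AILMENT = {
    code: ailments[0] for code, ailments in categorization._MEMBERS.items()
}


def _truncated_poisson(rng: np.random.Generator, mu: float,
                       upper: Optional[int] = None) -> int:
    """Poisson(mu) conditioned on >= 1 (rejection sampling), capped at upper."""
    for _ in range(10_000):
        k = int(rng.poisson(mu))
        if k >= 1:
            return min(k, upper) if upper is not None else k
    return 1  # mu so small that rejection never landed; smallest legal value


def generate_survey(cfg: GeneratorConfig) -> SurveyDataset:
    """Deterministically generate an informant-level survey from ``cfg``."""
    rng = np.random.default_rng(cfg.seed)

    # --- taxon register ----------------------------------------------------
    fam_weights = rng.dirichlet(np.full(cfg.n_families, 0.5))
    extra = rng.multinomial(cfg.n_taxa - cfg.n_families, fam_weights)
    family_sizes = extra + 1  # every family gets at least one taxon
    families = [f"family_{i+1:02d}" for i in range(cfg.n_families)]
    life_forms = list(_LIFE_FORM_PROBS)
    lf_p = np.array([_LIFE_FORM_PROBS[lf] for lf in life_forms])
    parts = list(PlantPart)
    preparations = list(Preparation)
    routes = list(Route)

    taxa: list[TaxonRecord] = []
    k = 0
    for fam, size in zip(families, family_sizes):
        for _ in range(size):
            k += 1
            lf = life_forms[rng.choice(len(life_forms), p=lf_p)]
            n_parts = 1 + int(rng.random() < 0.2)
            chosen = [parts[j] for j in rng.choice(len(parts), size=n_parts,
                                                   replace=False)]
            taxa.append(TaxonRecord(
                taxon_id=f"taxon_{k:03d}",
                botanical_name=f"Genus species{k}",
                family=fam,
                life_form=lf,
                parts_used=frozenset(chosen),
                primary_part=chosen[0],
                preparation=preparations[rng.choice(len(preparations))],
                route=routes[rng.choice(len(routes), p=[0.65, 0.18, 0.13, 0.04])],
                nativity=Nativity.NATIVE if rng.random() < 0.65 else Nativity.EXOTIC,
                voucher=f"SYN{k:05d}",
            ))
    popularity = rng.dirichlet(np.full(cfg.n_taxa, cfg.taxon_popularity))
    profiles = rng.dirichlet(
        np.full(len(CATEGORY_CODES), cfg.category_profile_sharpness),
        size=cfg.n_taxa,
    )

    # --- informants ---------------------------------------------------------
    village_names = [v for v, _ in cfg.villages]
    village_p = np.array([w for _, w in cfg.villages])
    communities = [Community.DARD, Community.GUJJAR, Community.KASHMIRI]
    informants: list[Informant] = []
    for i in range(cfg.n_informants):
        village = village_names[rng.choice(len(village_names), p=village_p)]
        gender = Gender.F if rng.random() < cfg.gender_split else Gender.M
        age = int(rng.integers(cfg.age_range[0], cfg.age_range[1] + 1))
        education = Education(int(rng.choice(7, p=np.array(cfg.education_probs))))
        community = communities[rng.choice(3, p=np.array(cfg.community_probs))]
        informants.append(Informant(
            informant_id=f"inf_{i+1:04d}", age=age, gender=gender,
            education=education, community=community, village=village,
        ))

    # --- reports -------------------------------------------------------------
    km = cfg.knowledge_model
    age_mid = (cfg.age_range[0] + cfg.age_range[1]) / 2.0
    reports: list[UseReport] = []
    for informant in informants:
        offset = km.community_offsets[communities.index(informant.community)]
        mu = km.base_rate * math.exp(
            km.age_coef * (informant.age - age_mid) / 10.0
            + km.education_coef * int(informant.education)
            + offset
        )
        knowledge = _truncated_poisson(rng, mu, upper=cfg.n_taxa)
        chosen = rng.choice(cfg.n_taxa, size=knowledge, replace=False,
                            p=popularity, shuffle=False)
        for tix in chosen:
            n_rep = _truncated_poisson(rng, cfg.reports_per_taxon_mean)
            cats = rng.choice(len(CATEGORY_CODES), size=n_rep, p=profiles[tix])
            for c in cats:
                code = CATEGORY_CODES[c]
                reports.append(UseReport(
                    informant_id=informant.informant_id,
                    taxon_id=taxa[tix].taxon_id,
                    ailment=_CANONICAL_AILMENT[code],
                    category=code,
                    village=informant.village,
                    count=1,
                ))

    return SurveyDataset(
        taxa=tuple(taxa), reports=tuple(reports),
        informants=tuple(informants),
        level=DatasetLevel.INFORMANT_LEVEL,
    )


@dataclass(frozen=True)
class RecoveryReport:
    """Re-estimated generator effects next to their configured truths."""

    age_slope: Optional[float]
    age_pearson_r: Optional[float]
    age_p_value: Optional[float]
    age_effect_truth: float
    age_recovered: Optional[bool]
    education_chi2: Optional[float]
    education_p_value: Optional[float]
    education_effect_truth: float
    education_significant: Optional[bool]
    top_taxon_share: float
    expected_uniform_share: float

    def summary(self) -> str:
        lines = [
            f"age slope        : {self.age_slope!r} "
            f"(truth coef {self.age_effect_truth}/decade, p={self.age_p_value!r})",
            f"education chi2   : {self.education_chi2!r} "
            f"(truth coef {self.education_effect_truth}, p={self.education_p_value!r})",
            f"top taxon share  : {self.top_taxon_share:.4f} "
            f"(uniform expectation {self.expected_uniform_share:.4f})",
        ]
        return "\n".join(lines)


def recover_parameters(ds: SurveyDataset, truth: GeneratorConfig,
                       alpha: float = 0.05) -> RecoveryReport:
    """Re-estimate the configured age/education effects and popularity skew."""
    from .association import (
        CapabilityError,
        DegenerateTableError,
        Factor,
        chi_square,
        dichotomize_knowledge,
        knowledge_age_regression,
    )

    results = knowledge_age_regression(ds, stratify_by_gender=False)
    overall = next(r for r in results if r.stratum == "all")

    edu_stat = edu_p = None
    try:
        table = dichotomize_knowledge(ds, Factor.EDUCATION)
        res = chi_square(table)
        edu_stat, edu_p = res.statistic, res.p_value
    except (CapabilityError, DegenerateTableError, ValueError):
        pass

    totals: dict[str, int] = {}
    for r in ds.reports:
        totals[r.taxon_id] = totals.get(r.taxon_id, 0) + r.count
    total_ur = sum(totals.values())
    top_share = max(totals.values()) / total_ur if total_ur else 0.0

    km = truth.knowledge_model
    age_recovered = None
    if overall.defined:
        if km.age_coef > 0:
            age_recovered = overall.slope > 0 and overall.p_value < alpha
        elif km.age_coef < 0:
            age_recovered = overall.slope < 0 and overall.p_value < alpha
        else:
            age_recovered = overall.p_value >= alpha
    return RecoveryReport(
        age_slope=overall.slope,
        age_pearson_r=overall.pearson_r,
        age_p_value=overall.p_value,
        age_effect_truth=km.age_coef,
        age_recovered=age_recovered,
        education_chi2=edu_stat,
        education_p_value=edu_p,
        education_effect_truth=km.education_coef,
        education_significant=None if edu_p is None else edu_p < alpha,
        top_taxon_share=top_share,
        expected_uniform_share=1.0 / truth.n_taxa,
    )


def read_config(path: str) -> GeneratorConfig:
    """Read a flat ``key = value`` config file (floats, ints, tuples)."""
    import ast

    raw: dict[str, object] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            raw[key.strip()] = ast.literal_eval(value.strip())
    km_keys = {"base_rate", "age_coef", "education_coef", "community_offsets"}
    km_kwargs = {k: raw.pop(k) for k in list(raw) if k in km_keys}
    if km_kwargs:
        raw["knowledge_model"] = KnowledgeModel(**km_kwargs)  # type: ignore[arg-type]
    if "villages" in raw:
        raw["villages"] = tuple(tuple(v) for v in raw["villages"])  # type: ignore[union-attr]
    return GeneratorConfig(**raw)  # type: ignore[arg-type]
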