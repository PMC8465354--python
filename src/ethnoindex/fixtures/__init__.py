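"""Packaged transcription of the published aggregate survey tables.

The study deposited no raw informant×taxon data, so the packaged dataset is
aggregate-level: the taxon register with per-category use-report splits
(taxa.csv + use_reports.csv), the family use-value table (table4.csv), the
per-category consensus counts (table5.csv), per-village tallies (table1.csv)
and the five demographic contingency tables (table2_*.csv).  Study
constants: 102 informants, 107 taxa, 1631 total use-reports (the total the
category table reports).

The source tables are internally inconsistent in places (the register's
per-category splits do not reproduce every category-table marginal; a few
printed Fq values disagree with their UR counts).  The fixture stores both
representations as printed and exposes the disagreements — it never repairs
the source.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional

from ..association import ContingencyTable, Factor
from ..data_model import DatasetLevel, SurveyDataset, read_survey

N_INFORMANTS = 102
TOTAL_TAXA = 107
TOTAL_USE_REPORTS = 1631  # total printed with the category table


class FixtureIntegrityError(RuntimeError):
    """A packaged data file does not match its recorded checksum."""


@dataclass(frozen=True)
class CategoryRow:
    category: str
    n_t: int
    nt_pct: float
    n_ur: int
    nur_pct: float
    icf: float


@dataclass(frozen=True)
class FamilyRow:
    family: str
    urs: int
    uv: float
    fuv: float


@dataclass(frozen=True)
class VillageRow:
    village: str
    informants: int
    use_reports: int
    taxa_identified: int
    rf: float


@dataclass(frozen=True)
class FixtureBundle:
    dataset: SurveyDataset  # aggregate, built from the register's category splits
    table5: tuple[CategoryRow, ...]
    table4: tuple[FamilyRow, ...]
    table1: tuple[VillageRow, ...]
    contingency_tables: Mapping[str, ContingencyTable]
    printed_chi_square: Mapping[str, tuple[float, float]]  # factor → (stat, p)
    printed_taxon_values: Mapping[str, Mapping[str, float]]  # urs/fq/ri
    n_informants: int = N_INFORMANTS
    total_taxa: int = TOTAL_TAXA
    total_use_reports: int = TOTAL_USE_REPORTS

    def category_counts(self) -> dict[str, tuple[int, int]]:
        """table5.csv counts as {category: (n_ur, n_t)}."""
        return {r.category: (r.n_ur, r.n_t) for r in self.table5}

    def category_discrepancies(self) -> list[tuple[str, tuple[int, int], tuple[int, int]]]:
        """Categories where the register splits disagree with table5.csv.

        Returns (category, (n_ur, n_t) from splits, (n_ur, n_t) printed).
        """
        from collections import defaultdict

        n_ur: dict[str, int] = defaultdict(int)
        taxa: dict[str, set[str]] = defaultdict(set)
        for r in self.dataset.reports:
            n_ur[r.category] += r.count
            taxa[r.category].add(r.taxon_id)
        out = []
        for row in self.table5:
            got = (n_ur.get(row.category, 0), len(taxa.get(row.category, ())))
            if got != (row.n_ur, row.n_t):
                out.append((row.category, got, (row.n_ur, row.n_t)))
        return out


_DATA = resources.files(__package__) / "data"


def _path(name: str) -> str:
    return str(_DATA / name)


def _verify_checksums() -> None:
    manifest = (_DATA / "checksums.txt").read_text().strip().splitlines()
    for line in manifest:
        digest, name = line.split()
        actual = hashlib.sha256((_DATA / name).read_bytes()).hexdigest()
        if actual != digest:
            raise FixtureIntegrityError(
                f"packaged file {name} fails its checksum; reinstall the package"
            )


def _read_csv(name: str) -> list[dict[str, str]]:
    with open(_path(name), "r", encoding="utf-8", newline="") as fh:
        return list(csv.DictReader(fh))


def load_fixture(verify: bool = True) -> FixtureBundle:
    """Load the packaged aggregate survey and published index tables."""
    if verify:
        _verify_checksums()
    dataset = read_survey(
        informants_path=None,
        taxa_path=_path("taxa.csv"),
        reports_path=_path("use_reports.csv"),
        level=DatasetLevel.AGGREGATE,
        n_informants=N_INFORMANTS,
    )
    table5 = tuple(
        CategoryRow(r["category"], int(r["n_t"]), float(r["nt_pct"]),
                    int(r["n_ur"]), float(r["nur_pct"]), float(r["icf"]))
        for r in _read_csv("table5.csv")
    )
    table4 = tuple(
        FamilyRow(r["family"], int(r["urs"]), float(r["uv"]), float(r["fuv"]))
        for r in _read_csv("table4.csv")
    )
    table1 = tuple(
        VillageRow(r["village"], int(r["informants"]), int(r["use_reports"]),
                   int(r["taxa_identified"]), float(r["rf"]))
        for r in _read_csv("table1.csv")
    )
    tables: dict[str, ContingencyTable] = {}
    for factor in Factor:
        rows = _read_csv(f"table2_{factor.value}.csv")
        tables[factor.value] = ContingencyTable(
            factor=factor,
            row_labels=tuple(r["row_label"] for r in rows),
            counts=tuple((int(r["le_count"]), int(r["gt_count"])) for r in rows),
        )
    printed_chi = {
        r["factor"]: (float(r["statistic"]), float(r["p_value"]))
        for r in _read_csv("table2_printed.csv")
    }
    printed_taxon = {
        r["taxon_id"]: {"urs": float(r["urs"]), "fq": float(r["fq"]),
                        "ri": float(r["ri"])}
        for r in _read_csv("table3_printed.csv")
    }
    return FixtureBundle(
        dataset=dataset, table5=table5, table4=table4, table1=table1,
        contingency_tables=tables, printed_chi_square=printed_chi,
        printed_taxon_values=printed_taxon,
    )
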