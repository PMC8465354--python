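# ethnoindex

Quantitative ethnobotany survey analysis: a validated survey data model,
the six standard consensus/importance indices, disease categorization,
demographic association tests and a synthetic interview generator.

The package ships a transcription of a published high-altitude
ethnomedicinal survey (102 informants, 107 taxa, 1631 use-reports across 15 disease
categories) as machine-readable CSV fixtures, and reproduces the study's
published index values from those tables.

## Components

| module                     | contents |
|----------------------------|----------|
| `ethnoindex.data_model`    | `Informant` / `TaxonRecord` / `UseReport` / `SurveyDataset`, CSV readers/writers, validation, informant-level → aggregate bridge |
| `ethnoindex.categorization`| 15 disease categories, the default 81-ailment map, free-text ailment assignment, life-form/part/preparation/nativity profiles |
| `ethnoindex.indices`       | use value (UV), use frequency (Fq), per-village relative frequency (Rf), family use value (FUV), informant consensus factor (ICF), relative importance (RI), ranking |
| `ethnoindex.association`   | knowledge dichotomization (distinct taxa ≤5 / >5), Pearson chi-square (no continuity correction) with a permutation oracle, age–knowledge OLS regression |
| `ethnoindex.synthetic`     | seeded generator of informant-level surveys (log-linear Poisson knowledge model, Dirichlet taxon popularity and category profiles), parameter recovery |
| `ethnoindex.fixtures`      | the packaged survey transcription and published tables, checksum-verified |

## CLI

```sh
# generate a synthetic survey
ethnoindex simulate --seed 7 --out survey/

# validate the three CSVs
ethnoindex validate --survey survey/

# all index tables
ethnoindex indices --survey survey/ --out results/

# chi-square association for one factor, or from a pre-tabulated table
ethnoindex assoc --survey survey/ --factor education
ethnoindex assoc --factor education --table education_table.csv

# descriptive profile on one dimension
ethnoindex profile --survey survey/ --dimension life_form

# full pipeline with a human-readable summary
ethnoindex report --survey survey/ --out report/ --reproducible
```

Survey directories hold `informants.csv`, `taxa.csv` and `use_reports.csv`
(comma- or tab-delimited, header required; aggregate-only data may omit
`informants.csv` and pass `--level aggregate --n-informants N`).

## Notes on the packaged data

The source publication's tables are internally inconsistent in a few
places (a use-report split that contradicts its own total, per-category
sums that disagree between tables, three Fq values inconsistent with their
UR counts). The fixtures store everything *as printed*;
`validate_consistency` and `FixtureBundle.category_discrepancies()` surface
the disagreements instead of repairing them, and the test suite pins the
documented mismatches so silent "fixes" would fail.
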