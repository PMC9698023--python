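# Metadata column dictionary

Per-cat survey table: TSV, one row per cat, UTF-8, LF endings. Booleans are
`Y` / `N`, an empty cell means *missing*; list-valued fields are
pipe-separated and normalized case-insensitively (tokens `none`, `n/a`,
`na`, `no` and blanks are dropped).

| column | type | meaning |
|---|---|---|
| `cat_id` | string | unique identifier; must match the count-table sample id |
| `age_years` | real ≥ 0 | age at sampling, years |
| `body_condition_score` | int 1–9 | clinical adiposity scale (BCS) |
| `bmi` | real | body-mass index as provided by the survey (no formula is computed) |
| `fecal_score` | int | stool consistency score; recorded, never filtered on |
| `clinical_signs` | set | e.g. `diarrhea\|vomiting`; empty set required for the healthy cohort |
| `diagnoses` | set | reported diagnoses; empty set required |
| `antibiotics_last_12mo` | bool | any antibiotics in the previous 12 months |
| `medications` | set | current medications/supplements; screened against the exclusion list (probiotics, steroids, sucralfate, oclacitinib, cetirizine, benazepril) |
| `environment` | `home` \| `shelter` | living environment at sampling; always present |
| `fiv_status` | `positive` \| `negative` \| `unknown` | shelter cats with `unknown` are labeled negative for cohort grouping only (`effective_fiv_status`) |
| `diet_dry` | bool | diet includes dry kibble |
| `diet_wet` | bool | diet includes canned wet food |
| `diet_raw` | bool | diet includes raw food |
| `sex` | string | as reported |
| `spay_neuter` | bool | spayed/neutered |

Diet components enter statistical models as three binary main effects
without interactions; cats missing any diet component, or fed both dry and
raw food, are excluded from diet analyses (`select_diet_cohort`).
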