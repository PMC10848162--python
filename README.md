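# ibmfs — phenotype-first triage for inherited bone marrow failure syndromes

Inherited bone marrow failure syndromes (IBMFS) — dyskeratosis congenita
(DC), Diamond–Blackfan anemia (DBA), Shwachman–Diamond syndrome (SDS),
thrombocytopenia with absent radii (TAR), severe congenital neutropenia
(SCN), Fanconi anemia (FA) — are rare germline disorders combining
cytopenias, physical anomalies and cancer predisposition. Where
next-generation sequencing is not readily available, diagnosis starts
from phenotype: exclude acquired causes of marrow failure, read the CBC
history carefully, and match dysmorphology against each syndrome's
hallmark features.

`ibmfs` implements that workflow as a deterministic, auditable rule
engine for clinical phenomics researchers and dysmorphologists:

- **patient records** — a documented JSON dialect (HPO-coded features
  with onset ages, longitudinal CBC as inline rows or sidecar CSV,
  transfusion log, screening labs with explicit *not-done* states,
  family and prenatal history), validated with pydantic against a
  bundled mini-HPO catalog with descendant matching;
- **hematology** — cytopenia grading (anemia Hb < 10.5 g/dL with
  macrocytic/normocytic split; neutropenia in half-open bands
  severe < 500 ≤ moderate < 1,000 ≤ mild < 1,500 cells/µL;
  thrombocytopenia < 150,000/µL), uni/bi/pan-lineage classification,
  onset-age buckets (≤2, >2–≤5, >5–<18), transfusion dependency
  (≥ 2 RBC units in any inclusive 28-day span), persistent and cyclic
  neutropenia detection;
- **triage** — eligibility gate, acquired-cause exclusion, hereditary
  "beacons" (consanguinity, endogamy < 5,000 inhabitants, isonymy,
  familial hematologic disease, FGR/SGA, physical alterations), six
  per-syndrome rules with hallmark-based precedence
  (TAR > SCN > DC > SDS > DBA, FA as an order-the-DEB-test referral),
  and an undefined-IBMFS fallback, with a full audit log;
- **cohort analytics** — frequency tables with both raw and truncated
  percents, chi-square / one-way ANOVA group comparisons;
- **synthetic cohorts** — a deterministic 48-patient reference cohort
  reproducing a published Mexican referral-center case series at the
  patient level, and a seeded archetype simulator for property testing.

## Worked example

Write the reference cohort and classify one record:

```sh
$ ibmfs fixture --out cohort/
$ ibmfs classify cohort/p20.json --tsv
P20	DBA	DBA	TAR=0;SCN=0;DC=0;SDS=0;DBA=2;FA=0
```

Patient P20 — macrocytic anemia with reticulocytopenia from 8 months of
age, severe neutropenia later, four minor craniofacial features — fires
only the DBA rule (score 2: the CBC trigger plus the craniofacial minor
criterion) and is assigned primary suspicion **DBA**. The JSON report
(`ibmfs classify cohort/p20.json --audit`) carries the matched
evidence, e.g.:

```json
"matched_criteria": [
 ["cbc", "macrocytic anemia with reticulocytopenia"],
 ["minor", "HP:0001999 (Abnormal facial shape)"]
]
```

Summarize the whole cohort:

```sh
$ ibmfs cohort cohort/ --out summary.json --tables tables/
```

`summary.json` reports primary-label counts
`{"DBA": 15, "SDS": 9, "DC": 7, "TAR": 2, "SCN": 2, "undefined_IBMFS": 13}`
(35 of 48 with a specific suspicion), 23 pancytopenic patients, onset
buckets 22/9/14 over the 45 patients with hematologic onset, 10
transfusion-dependent patients, and feature-group prevalences
(craniofacial 40/48, neurological 25/48, integument 23/48, growth
restriction 21/48).

From Python:

```python
from ibmfs import build_reference_fixture, classify, load_catalog, summarize

catalog = load_catalog()
records, intended = build_reference_fixture()
results = [classify(r, catalog) for r in records]
summary = summarize(records, results, catalog)
print(summary.primary_label_counts)   # {'DBA': 15, 'DC': 7, 'SCN': 2, ...}
```

Simulated cohorts for stress testing: `ibmfs simulate --seed 1 --scale
10 --out sim/` draws 480 patients from the archetype parameters
(per-patient PRNG substreams; identical seed ⇒ byte-identical cohort)
and writes a `_labels.json` manifest of intended vs expected labels.

## Configuration

Thresholds (anemia cutoff, ANC bands, platelet threshold, macrocytosis
MCV table, reticulocytopenia cutoff, persistence fraction, RBC window)
and the rule precedence order live in a YAML config passed via
`--config`; unknown keys are rejected. The bundled feature catalog can
be extended — but rule-required groups cannot be shrunk. See
`docs/methods.md` for the model, its assumptions and the defaults.
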