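# Methods

## The triage model

The package encodes a phenotype-first decision algorithm for suspected
inherited bone marrow failure syndromes (IBMFS) as a deterministic rule
engine. The pipeline for one patient record is:

1. **Hematology profile.** Every CBC measurement is interpreted
   per lineage; the profile keeps the worst grade ever observed per
   lineage (erythroid / myeloid / megakaryocytic), so the cytopenia
   class reflects lifetime involvement, not a single draw. Derived
   flags: hematologic onset (age of the first measurement meeting any
   cytopenia criterion; with no abnormal series, the earliest dated
   hematologic feature annotation), onset bucket, transfusion
   dependency, persistent and cyclic neutropenia, and the
   macrocytic-anemia-with-reticulocytopenia trigger.
2. **Eligibility.** A qualifying presentation (any cytopenia, an
   annotated hematologic feature, or ≥ 2 non-hematological
   manifestations in *distinct* organ systems — counted over catalog
   organ-system roots so synonymous terms in one system are not double
   counted) together with at least one supporting criterion (positive
   family history, physical abnormality, hematologic onset < 18 y).
3. **Exclusion.** A positive diepoxybutane (DEB) breakage test is a
   confirmed Fanconi anemia diagnosis and terminates triage; a positive
   acquired-cause panel (nutritional deficiency, viral serology,
   drug/radiation exposure, PNH clone) excludes the record from
   hereditary triage. *Unknown never excludes*: every history and lab
   field is tri-state (true / false / unknown; absent JSON keys mean
   unknown), and unknowns are reported as incomplete work-up instead.
4. **Rules.** Six syndrome rules produce findings with matched/missing
   criteria, a score over the syndrome's own feature set, and a
   pathway:
   - **DC** — any cytopenia plus ≥ 1 element of the mucocutaneous triad
     (oral leukoplakia, nail dysplasia, reticulated skin pigmentation);
     the complete triad fires without hematology.
   - **SDS** — any cytopenia plus ≥ 3 of 8 associated features
     (exocrine pancreatic insufficiency, malabsorption, short stature,
     chondrodysplasia, thoracic anomaly, congenital heart defect,
     otologic anomaly, hepatomegaly); a positive 72-h fecal-fat test
     asserts the pancreatic-insufficiency criterion and fires with a
     cytopenia, or alone as a phenotype-only hallmark.
   - **DBA** — a single measurement with macrocytic anemia and absolute
     reticulocytes below the cutoff; minor features (short stature,
     microcephaly, craniofacial, neck, upper limb, cardiac,
     genitourinary) add score. Onset < 1 y with erythroid paucity on
     biopsy raises a `classic_dba` flag.
   - **TAR** — thrombocytopenia (ever) plus a radial-ray alteration
     with thumbs preserved; an asserted absent thumb vetoes TAR and
     raises an FA cross-flag (the one deliberate non-monotonicity).
   - **SCN** — persistent or cyclic neutropenia plus ≥ 2 of {short
     stature, congenital heart defect, urogenital alteration}. The
     associated set is read as the closed three-member list; a wider
     reading ("including…") exists but is not implemented.
   - **FA** — any cytopenia with ≥ 1 VACTERL-H/PHENOS feature, or ≥ 3
     such features alone. FA is a *referral* ("order DEB test"), never
     a primary suspicion here, because DEB-positive patients exit at
     the exclusion gate.
5. **Precedence.** When several rules fire the primary label follows
   hallmark specificity: TAR > SCN > DC > SDS > DBA (rarer, more
   structural hallmarks dominate; configurable). FA becomes
   `FA_referral` only when it fires exclusively and the DEB test is not
   done; an FA pattern with a negative DEB falls to undefined. An
   eligible, non-excluded record firing nothing is `undefined_IBMFS`.
   All findings and every gate decision are retained in an audit log;
   identical record + config ⇒ identical result.

Phenotype matching is by exact term or catalog descendant over a
bundled ~60-term mini-HPO table that encodes only the parent links the
rules need (e.g. developmental delay → neurological root). One
equivalence is declared explicitly: generic nail abnormality
(HP:0001597), the catalog parent of nail dysplasia (HP:0002164),
satisfies the nail triad element — both codes appear in clinical usage
for the same observation. Full-ontology reasoning is deliberately out
of scope.

## Thresholds and defaults

| parameter | default | unit | note |
|---|---|---|---|
| `hb_anemia` | 10.5 | g/dL | flat approximate pediatric reference; an age/sex table can replace it |
| `anc_severe` / `anc_moderate` / `anc_mild` | 500 / 1,000 / 1,500 | cells/µL | half-open bands [low, high): 1,000 → mild, 500 → moderate — the only exhaustive, deterministic reading of overlapping prose bands |
| `plt_threshold` | 150,000 | cells/µL | thrombocytopenia |
| `mcv_table` | flat 100 | fL | macrocytosis upper limit; no authoritative cutoff exists in the source criteria, so a conservative flat value ships and an age-banded table is configurable |
| `retic_abs_min` | 20 | ×10⁹/L | reticulocytopenia; likewise a package default, configurable |
| `persistence_fraction` | 0.9 | — | "lifelong" neutropenia tolerates occasional post-G-CSF/post-transfusion normal counts; any ANC ≥ `persistence_ceiling` (2,500) breaks persistence |
| `cyclic_crossings_min` / `cyclic_nadir` | 2 / 500 | — / cells/µL | cyclic pattern: ≥ 2 downward crossings of 1,500 with a nadir < 500; needs ≥ 4 measurements |
| `rbc_window_days` / `rbc_units_min` | 28 / 2 | days / units | transfusion dependency; the 28-day span is inclusive (day_j − day_i ≤ 28) |
| `settlement_endogamy_max` | 5,000 | inhabitants | endogamy beacon |

Units are fixed (Hb g/dL, counts cells/µL, reticulocytes absolute
×10⁹/L); records declaring other units are rejected rather than
converted. HbF% is carried as data with no enforced cutoff (elevated
HbF is suggestive of DBA but not specific). Erythrocyte ADA is carried
as an optional lab and does not gate the DBA rule, since no screening
threshold is established for the referral setting modeled here.

## The reference cohort

`build_reference_fixture()` returns 48 fully specified patient records
from two sibling pairs' worth of 46 families. It is one feasible
patient-level realization, frozen as data, of a published referral-
center case series known only through its cohort-level tables: group
sizes 15 DBA / 9 SDS / 7 DC / 2 TAR / 2 SCN / 13 undefined (35/48 with
a specific suspicion); 23 pancytopenic; hematologic onset in 45
patients split 22 / 9 / 14 across the ≤2 / >2–≤5 / >5–<18 buckets; 10
transfusion-dependent; 40 with craniofacial features, 25 neurological,
23 integument, 21 growth-restricted (8/9 of SDS, 8/15 of DBA); the
complete DC triad in 4 of 7; 29 male / 19 female; mean evaluation age
9.02 (SD 6.01). Three patients (one DC, two SDS) have no hematologic
abnormality and fire via phenotype-only pathways. Where the published
tables leave a per-patient value unconstrained it is filled minimally —
in particular, per-patient onset ages inside the printed bucket totals
were chosen so that onset-age and sex differences across groups are
*not* statistically significant, matching the source's reported
non-significance. The builder uses no randomness: the cohort is
bit-identical across runs and platforms.

## The simulator

`simulate_cohort(params, seed)` draws patients per syndrome archetype.
Feature prevalences are Bernoulli probabilities taken from the cohort
grid (e.g. leukoplakia 4/7 in DC, growth restriction 8/9 in SDS); CBC
series come from per-archetype trajectory templates (direction and
severity only — the published longitudinal plots print no axis values,
so trajectories are qualitative) with Gaussian measurement noise. Each
patient's PRNG substream is keyed by (seed, archetype, index) through
numpy `SeedSequence`, so cohorts are reproducible, order-invariant and
platform-stable. The generator records for every patient both the
intended archetype and the *expected* triage label: archetype feature
pools are constructed not to cross-fire other syndromes' rules, so a
record falls to `undefined_IBMFS` exactly when its sampled features
miss its own archetype's minimal rule, and the generator marks those
cases. Simulated deb tests are negative, mirroring the study design in
which DEB-positive patients are excluded upstream.

What the generator does **not** emulate: genotypes, telomere length,
treatment response, measurement artifacts, correlated feature
co-occurrence beyond the archetype, or diagnosis dates distinct from
onset. Passing label-recovery tests therefore show the engine is
faithful to its own rule semantics under sampling variation — not that
the rules have any particular sensitivity or specificity on real
patients.

## Numerical and design notes

- Severity bands and onset buckets are verified by brute-force sweeps;
  the transfusion-window scan is verified against an O(n²) all-pairs
  oracle; chi-square and ANOVA are scipy (`chi2_contingency` without
  Yates continuity correction by default — configurable — and
  `f_oneway`) and are tested against closed-form evaluation of the
  Pearson and F formulas on small tables.
- Percentages are exposed both raw and integer-truncated, because
  clinical tables mix the two conventions; rendered tables truncate.
- Descriptive statistics use the sample SD (n−1; undefined and
  reported as none for a single value) and midpoint medians.
- Degenerate inputs: an empty CBC series yields an all-none profile
  with unknown (not false) DBA trigger; anemia with unknown MCV
  defaults to normocytic with a provenance flag; cyclic assessment
  with < 4 measurements returns false and flags underpowering;
  records excluded at the gate keep `primary = not_eligible` with the
  reason in `excluded_as` and the audit, since the primary-label
  enumeration has no terminal "excluded" value and the
  exactly-one-primary invariant is kept.
- Malformed HPO identifiers that are unambiguous truncations
  (`HP:001972`, `HP:001,972`) are zero-padded on read with a logged
  warning; anything else is rejected with the nearest catalog labels.

## Known limitations

- The catalog is a working subset of HPO; terms outside it must be
  added via config before use, and negative findings (explicitly absent
  phenotypes) are not modeled.
- No probabilistic or Bayesian scoring: scores are criterion counts
  meant for audit and tie-breaking, not calibrated likelihoods.
- The precedence order resolves multi-syndrome firing deterministically
  but is a design choice (hallmark specificity), not an empirically
  fitted ranking; all fired findings remain in the report.
- Mortality, treatment decisions and variant interpretation are out of
  scope; personal malignancy is summarized as counts and a beacon only.
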