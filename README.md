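# painpheno

An end-to-end, tested pipeline studying whether SSRI co-prescription is
associated with worse postoperative pain control under prodrug opioids
(hydrocodone, codeine, tramadol — opioids that need CYP-2D6 activation,
which SSRIs inhibit), exercised entirely on a synthetic EHR so no
protected data is required.

The pipeline has five stages:

1. **synthetic_ehr** — generates a synthetic EHR extract (patients,
   encounters, diagnoses, medications, vitals, pain observations,
   template-built clinical notes) with a gold-label sidecar: true group
   assignments, depression provenance (note / diagnosis code / both) and
   pain trajectories. Deterministic given a seed.
2. **nlp** — rule-based depression phenotyping of notes: normalization
   and sentence splitting, lexicon concept matching with sense-exclusion
   rules ("ST depression", "depression fracture"), a from-scratch
   trigger/scope negation classifier, note-level majority voting
   (Affirmed wins ties) and patient-level flags; plus SSRI mention
   detection reusing the same negation engine, and precision/recall/F1
   evaluation against gold.
3. **cohort** — eligibility (adults, survived, first surgery on the
   configured procedure list), depression reconciliation across
   structured and note-derived sources, SSRI±/Prodrug± group assignment
   from distilled medication ingredients, daily oral-morphine-equivalent
   dose, opioid tolerance, Charlson comorbidity category, and a
   65-feature model matrix defined by a manifest file.
4. **outcomes** — pain-control statistic Δt = postoperative −
   preoperative pain at discharge, 3 weeks and 8 weeks, and stratified
   Welch comparisons of the prodrug arms.
5. **predict** — a bespoke elastic-net regression (cyclic coordinate
   descent on the exact displayed objective, ridge weight α·λ and lasso
   weight λ(1−α)/2, unpenalized intercept), evaluated by stratified
   10-fold cross-validation with nested 5-fold hyperparameter search,
   Mann–Whitney AUC with vertically averaged ROC curves, coefficient
   ranking, and pluggable SVC / random-forest comparators.

## CLI

```sh
painpheno simulate --seed 1 --out run/extract
painpheno phenotype --notes run/extract/notes.jsonl \
    --surgery-dates dates.csv --out run/nlp
painpheno cohort --extract run/extract --nlp run/nlp --out run/cohort
painpheno outcomes --cohort run/cohort --pain run/extract/pain.csv --out run/outcomes
painpheno predict --features run/cohort/features.csv \
    --outcomes run/outcomes/outcomes.csv --time-point discharge --seed 1 --out run/predict
painpheno run-all --config src/painpheno/data/default_config.yaml --seed 1 --out run
painpheno report --run run [--plots]
painpheno evaluate-nlp --pred run/nlp/note_labels.csv --gold run/extract/gold.json
```

`run-all` executes every stage, writes machine-readable outputs per
stage plus a provenance manifest (seed, config hash), and is
byte-identical on rerun with the same config and seed.

## Data files

Editable tab-delimited configuration ships under `src/painpheno/data/`:
depression and SSRI lexicons (`term`/`kind`, kinds: concept, exclusion,
pre_neg, post_neg, termination), the OME conversion table, the
drug-name → ingredient/therapeutic-class map, the Charlson code map,
the surgical procedure code stub list, and `feature_manifest.tsv` — the
single source of truth for the 65 feature names and their order.
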