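# pregmorb

Rule-based mining of maternal morbidities from semi-structured electronic
medical record (EMR) free text, with the downstream epidemiological toolkit
that typically accompanies such a study: multimorbidity burden summaries,
condition–outcome association screens, and comorbidity-phenotype clustering.
A calibrated synthetic cohort generator makes every step testable end to end
without access to real patient data.

## The scientific problem

Maternity EMRs often record pre-existing medical conditions as short,
semi-structured free text ("PCOS; hypothyroid", "iron deficiency anaemia;
astma") rather than coded diagnoses. Deep-learning NLP is hard to justify
here: the text is telegraphic, labelled data are scarce, and clinical users
need auditable decisions. A curated lexicon with exact-phrase and
edit-distance fuzzy matching is a transparent alternative that performs well
on this genre of text.

Once each record is reduced to a binary morbidity profile, three standard
analyses follow:

1. **Burden.** Count conditions per woman and classify records as *none* /
   *single* / *multimorbidity* (two or more), overall and stratified by age
   and body-mass-index (BMI) bands.
2. **Association.** For each morbidity–complication pair form the 2×2
   contingency table and compute the continuity-corrected chi-square

   χ²_c = N · (|ad − bc| − N/2)² / (r₁ r₂ c₁ c₂),

   with the φ coefficient (ad − bc)/√(r₁r₂c₁c₂) as effect size and the odds
   ratio ad/bc. The correction matters: the package reproduces nine published
   condition–gestational-diabetes statistics (e.g. obesity 822.8, overweight
   66.4) to one decimal *only* with the corrected form.
3. **Clustering.** k-means on the binary (or count/tf-idf) condition matrix,
   with k chosen by a formalised elbow criterion (maximum perpendicular
   distance from the inertia curve to its end-point chord), then per-cluster
   condition signatures and outcome-risk comparisons.

The synthetic generator draws condition flags from published marginal
prevalences (or planted latent cluster profiles), renders them to noisy
free text (typos, abbreviations, filler, case variation), and ties a binary
outcome to the *true* flags through a logistic model. Because the truth is
known, extraction fidelity, effect recovery, type-I error, and cluster
recovery are all directly measurable.

## Worked example

```python
from pregmorb import (SimulationConfig, burden_distribution,
                      default_morbidity_lexicon, extract_cohort,
                      generate_cohort)

records, truth = generate_cohort(SimulationConfig(n_records=3000, seed=11))
profiles = extract_cohort(records, default_morbidity_lexicon())
dist = burden_distribution(profiles)
print(dist.percent_multimorbidity)   # 42.4
```

Reproducing two published condition–GDM statistics from their contingency
cells:

```python
from pregmorb import chi_square_corrected
from pregmorb.reference import reference_table

chi_square_corrected(reference_table("obesity"))     # 822.79... -> 822.8
chi_square_corrected(reference_table("overweight"))  # 66.44...  -> 66.4
```

The `examples/` directory holds one short narrative script per capability
(simulation, extraction, burden summary, association screen, clustering,
full pipeline); each prints its results with a note on what they mean.

## Command line

A thin `pregmorb` CLI wraps the library for shell pipelines:

```sh
pregmorb simulate --n 2000 --seed 7 --out records.csv --emit-truth
pregmorb extract  --records records.csv --out profiles.csv
pregmorb summarize --profiles profiles.csv --records records.csv --out-dir summary/
pregmorb associate --profiles profiles.csv --outcomes records.truth.csv --out assoc.csv
pregmorb cluster  --profiles profiles.csv --k-range 1:8 --out-dir clusters/
pregmorb run-all  --n 2000 --seed 7 --out-dir bundle/   # + manifest w/ checksums
pregmorb verify   --bundle bundle/
```

## Layout

- `src/pregmorb/` — library (`textproc`, `lexicon`, `extraction`,
  `synthetic`, `summary`, `association`, `clustering`, `reference`,
  `pipeline`, `cli`).
- `src/pregmorb/data/` — morbidity and complication lexicons (YAML),
  stopword list, published reference contingency tables (CSV).
- `docs/methods.md` — the scientific and numerical account of every method,
  its parameters, and its limitations.
- `examples/`, `tests/`, `scripts/acceptance.py` — as above.
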