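# Default maternal morbidity lexicon: condition id -> surface keywords/phrases
# used for rule-based detection in the medical-conditions free-text field.
#
# The mental_disorders keyword list is the published one, verbatim. Every other
# entry is a reconstructed, editable starting point curated from the condition
# names the study surface reports; replace with a site-specific list for real
# data. Keywords are normalised (lowercase, punctuation-free) at load time.
# Optional per-entry keys: exclusions (phrases that consume a span without
# setting the flag), fuzzy_threshold (overrides the run default).

mental_disorders:
  display_name: Common mental disorders
  keywords:
    - anxiety
    - depression
    - panic
    - psychological
    - stress
    - bpad
    - bipolar
    - personality
    - borderline
    - schizophrenia
    - intellectually
    - bpd
    - fatigue
    - ptsd
    - psychosis
    - bulimia
    - psych
    - substance
    - suicidal
    - schizoaffective

pcos:
  display_name: Polycystic ovary syndrome
  keywords:
    - pcos
    - polycystic ovary syndrome
    - polycystic ovaries
    - polycystic

cardiovascular_disease:
  display_name: Cardiovascular disease
  keywords:
    - cardiac
    - cardiovascular
    - heart disease
    - arrhythmia
    - cardiomyopathy
    - valve disease
    - palpitations

substance_use:
  display_name: Substance use
  keywords:
    - substance use
    - substance abuse
    - drug use
    - smoking
    - smoker
    - alcohol
    - cannabis
    - opioid
    - methadone

thyroid_disease:
  display_name: Thyroid disease
  keywords:
    - thyroid
    - hypothyroidism
    - hypothyroid
    - hyperthyroidism
    - hyperthyroid
    - hashimoto
    - graves disease
    - goitre

urinary_tract_infection:
  display_name: Urinary tract infections
  keywords:
    - uti
    - urinary tract infection
    - recurrent uti
    - cystitis
    - pyelonephritis

hypertension:
  display_name: Hypertension (chronic)
  keywords:
    - hypertension
    - hypertensive
    - htn
  exclusions:
    - pregnancy induced hypertension
    - gestational hypertension

vitamin_deficiency:
  display_name: Vitamin deficiency
  keywords:
    - vitamin deficiency
    - vitamin d deficiency
    - vit d deficiency
    - low vitamin d
    - b12 deficiency
    - folate deficiency

asthma:
  display_name: Asthma
  keywords:
    - asthma
    - asthmatic

other_respiratory_disease:
  display_name: Other respiratory disease
  keywords:
    - copd
    - bronchitis
    - sleep apnoea
    - sleep apnea
    - tuberculosis
    - bronchiectasis

blood_disorders:
  display_name: Anemia and other blood disorders
  keywords:
    - anaemia
    - anemia
    - thalassaemia
    - thalassemia
    - thrombocytopenia
    - thrombophilia
    - von willebrand
    - sickle cell

iron_deficiency_anemia:
  display_name: Iron deficiency anemia
  keywords:
    - iron deficiency anaemia
    - iron deficiency anemia
    - iron deficiency
    - low iron
    - low ferritin

endometrial_disease:
  display_name: Endometrial / uterine disease
  keywords:
    - endometriosis
    - adenomyosis
    - uterine fibroids
    - fibroids
    - uterine disease
    - endometrial

migraine:
  display_name: Migraine
  keywords:
    - migraine
    - migraines

kidney_disease:
  display_name: Kidney disease
  keywords:
    - renal
    - kidney disease
    - nephropathy
    - kidney stones
    - glomerulonephritis

bowel_disease:
  display_name: Bowel disease
  keywords:
    - crohns
    - colitis
    - coeliac
    - celiac
    - inflammatory bowel
    - diverticulitis

genital_herpes:
  display_name: Genital herpes
  keywords:
    - herpes
    - hsv
    - genital herpes

hemorrhoids:
  display_name: Hemorrhoids
  keywords:
    - haemorrhoids
    - hemorrhoids
    - piles

autoimmune_disease:
  display_name: Autoimmune disease
  keywords:
    - lupus
    - sle
    - rheumatoid arthritis
    - rheumatoid
    - sjogren
    - scleroderma
    - autoimmune

musculoskeletal_disease:
  display_name: Musculoskeletal disease
  keywords:
    - scoliosis
    - sciatica
    - osteoarthritis
    - arthritis
    - fibromyalgia
    - back pain

infertility:
  display_name: Infertility
  keywords:
    - infertility
    - infertile
    - subfertility
    - ivf

preexisting_diabetes:
  display_name: Preexisting diabetes mellitus
  keywords:
    - t1dm
    - t2dm
    - type 1 diabetes
    - type 2 diabetes
    - diabetes mellitus
    - diabetic
  exclusions:
    - gestational diabetes
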