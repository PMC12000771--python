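# Default obstetric/labour complication lexicon, same schema as the morbidity
# lexicon; applied to the complications free-text field when no structured 0/1
# outcome columns are present.

gdm:
  display_name: Gestational diabetes mellitus
  keywords:
    - gdm
    - gestational diabetes
    - gestational diabetes mellitus

preeclampsia:
  display_name: Preeclampsia
  keywords:
    - preeclampsia
    - pre eclampsia
    - toxaemia

pih:
  display_name: Pregnancy-induced hypertension
  keywords:
    - pih
    - pregnancy induced hypertension
    - gestational hypertension

preterm:
  display_name: Preterm birth
  keywords:
    - preterm
    - preterm birth
    - preterm labour
    - premature delivery

induction:
  display_name: Induction of labour
  keywords:
    - induction
    - induction of labour
    - induced labour
    - iol

cesarean:
  display_name: Cesarean delivery
  keywords:
    - cesarean
    - caesarean
    - c section
    - lscs

birth_defect:
  display_name: Birth defect
  keywords:
    - birth defect
    - congenital anomaly
    - congenital malformation

scn_nicu:
  display_name: Special care nursery / NICU admission
  keywords:
    - scn
    - nicu
    - special care nursery
    - neonatal intensive care

shoulder_dystocia:
  display_name: Shoulder dystocia
  keywords:
    - shoulder dystocia

macrosomia:
  display_name: Macrosomia
  keywords:
    - macrosomia
    - macrosomic
    - large for gestational age
    - lga
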