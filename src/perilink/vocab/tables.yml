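# ICD-10-AM diagnosis and ACHI procedure code lists used to identify birth
# admissions and derive clinical variables from hospital records.
# Diagnosis entries are hierarchical prefixes or dotted ranges (O24 matches
# O24.1; O60.1-O60.3 expands to O60.1, O60.2, O60.3); procedure entries are
# ACHI code numbers or numeric ranges.

infant_birth_admission:
  liveborn:
    diagnosis: [Z38]
  perinatal_condition:
    diagnosis: [P]

maternal_delivery_admission:
  delivery:
    diagnosis: [O80-O84]
  outcome_of_delivery:
    diagnosis: [Z37]
  preterm_delivery:
    diagnosis: [O60.1-O60.3]
  delivery_procedures:
    procedure: ['90467-90470', '16520']
  postpartum_sutures:
    procedure: ['16571', '16573', '90479-90481', '90485']
  other_delivery_procedures:
    procedure: ['90472-90477']
  analgesia_anaesthesia:
    procedure: ['92506', '92507']
  induction_augmentation:
    procedure: ['90465', '90466']

variables:
  preterm:
    diagnosis: [P07.2, P07.3]
  apgar1_lt4:
    diagnosis: [P20.1]
  diabetes:
    diagnosis: [O24, E10, E11, E13, E14]
  hypertension:
    diagnosis: [O10, O11, O13-O16]
  induction:
    procedure: ['90465']
  caesarean:
    diagnosis: [O82]
    procedure: ['16520']
  placenta_praevia:
    diagnosis: [O44.1]
  placental_abruption:
    diagnosis: [O45]
  duration_lt26w:
    # the source vocabulary labels this row "< 25 weeks" while the variable
    # list and output tables say "< 26 weeks"; both labels are preserved.
    diagnosis: [O90.1, O90.2, O90.3]
    table_label: 'Duration of pregnancy < 25 weeks'

classification:
  singleton:
    diagnosis: [Z37.0-Z37.1, Z38.0-Z38.2, O80-O83]
  multiple:
    diagnosis: [Z37.2-Z37.7, Z38.3-Z38.8, O84]
  stillbirth:
    diagnosis: [Z37.1, Z37.3, Z37.4, Z37.6, Z37.7]
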