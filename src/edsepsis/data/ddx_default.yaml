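# Default catalog of clinical signs/symptoms, condition set, and the
# condition-conditional sign likelihoods P(sign present | condition).
# The sign-to-condition assignment is editable configuration curated from
# standard clinical descriptions, not ground truth.
symptoms:
  - elevated inflammatory markers
  - positive influenza test
  - altered mental status
  - dehydration + sweating
  - metabolic acidosis
  - abdominal pain
  - ketonuria
  - elevated liver enzymes
  - ascites
  - risk factors for lung injury
  - urticaria + angioedema
  - seizures
  - history of substance abuse
  - hypoxemia
  - jaundice
  - positive biopsy or imaging
  - risk factors for thrombosis
  - tachypnea
  - cough + sore throat
  - exposure to heat
  - elevated BNP
  - elevated tryptase + histamine
  - myalgia + headache
  - pulmonary edema
  - elevated lactate
  - elevated glucose
  - fever
  - elevated cardiac enzymes
  - positive covid-19 test
  - hematemesis or melena
  - dry mucous membranes
  - bilateral infiltrates on chest x-ray
  - suspicion of bacterial infection
  - elevated d-dimer
  - low urine output
  - tachycardia
  - positive toxicology screen
  - nausea + vomiting
  - cough + dyspnea
  - history of fluid loss
  - anemia
  - elevated lipase
  - positive blood culture
  - exposure to allergens
  - loss of taste or smell
  - ECG changes
  - hypotension
  - organ dysfunction
  - chest pain
  - weight loss + fatigue
  - dyspnea

diseases:
  - Severe Sepsis
  - cardiogenic shock
  - pulmonary embolism
  - hypovolemia
  - hypovolemic shock
  - cirrhosis
  - heart failure exacerbation
  - alcohol/drug withdrawal
  - gastrointestinal hemorrhage
  - anaphylaxis
  - acute respiratory distress syndrome
  - influenza
  - covid-19
  - myocardial infarction
  - coronary artery disease
  - malignancy
  - pancreatitis
  - heat stroke
  - diabetic ketoacidosis

# priors omitted -> uniform over the condition set

likelihoods:
  Severe Sepsis:
    suspicion of bacterial infection: 0.95
    fever: 0.9
    elevated lactate: 0.75
    hypotension: 0.6
    tachycardia: 0.45
  cardiogenic shock:
    hypotension: 0.9
    pulmonary edema: 0.75
    elevated cardiac enzymes: 0.6
    ECG changes: 0.45
    tachycardia: 0.3
  pulmonary embolism:
    risk factors for thrombosis: 0.9
    elevated d-dimer: 0.75
    tachypnea: 0.6
    chest pain: 0.45
    hypoxemia: 0.3
  hypovolemia:
    history of fluid loss: 0.9
    dry mucous membranes: 0.75
    low urine output: 0.6
    tachycardia: 0.45
    dehydration + sweating: 0.3
  hypovolemic shock:
    hypotension: 0.9
    history of fluid loss: 0.75
    tachycardia: 0.6
    low urine output: 0.45
    dry mucous membranes: 0.3
  cirrhosis:
    ascites: 0.9
    jaundice: 0.75
    elevated liver enzymes: 0.6
    altered mental status: 0.45
    anemia: 0.3
  heart failure exacerbation:
    elevated BNP: 0.9
    pulmonary edema: 0.75
    dyspnea: 0.6
    tachypnea: 0.45
    ECG changes: 0.3
  alcohol/drug withdrawal:
    history of substance abuse: 0.9
    seizures: 0.75
    positive toxicology screen: 0.6
    altered mental status: 0.45
    tachycardia: 0.3
  gastrointestinal hemorrhage:
    hematemesis or melena: 0.9
    anemia: 0.75
    hypotension: 0.6
    tachycardia: 0.45
    abdominal pain: 0.3
  anaphylaxis:
    urticaria + angioedema: 0.9
    exposure to allergens: 0.75
    elevated tryptase + histamine: 0.6
    hypotension: 0.45
    tachypnea: 0.3
  acute respiratory distress syndrome:
    bilateral infiltrates on chest x-ray: 0.9
    hypoxemia: 0.75
    risk factors for lung injury: 0.6
    tachypnea: 0.45
    dyspnea: 0.3
  influenza:
    positive influenza test: 0.9
    myalgia + headache: 0.75
    cough + sore throat: 0.6
    fever: 0.45
    cough + dyspnea: 0.3
  covid-19:
    positive covid-19 test: 0.9
    loss of taste or smell: 0.75
    cough + dyspnea: 0.6
    fever: 0.45
    hypoxemia: 0.3
  myocardial infarction:
    elevated cardiac enzymes: 0.9
    chest pain: 0.75
    ECG changes: 0.6
    tachycardia: 0.45
    dyspnea: 0.3
  coronary artery disease:
    chest pain: 0.9
    ECG changes: 0.75
    elevated cardiac enzymes: 0.6
    risk factors for thrombosis: 0.45
    dyspnea: 0.3
  malignancy:
    weight loss + fatigue: 0.9
    positive biopsy or imaging: 0.75
    anemia: 0.6
    elevated inflammatory markers: 0.45
    fever: 0.3
  pancreatitis:
    elevated lipase: 0.9
    abdominal pain: 0.75
    nausea + vomiting: 0.6
    elevated liver enzymes: 0.45
    fever: 0.3
  heat stroke:
    exposure to heat: 0.9
    altered mental status: 0.75
    dehydration + sweating: 0.6
    tachycardia: 0.45
    dry mucous membranes: 0.3
  diabetic ketoacidosis:
    elevated glucose: 0.9
    ketonuria: 0.75
    metabolic acidosis: 0.6
    nausea + vomiting: 0.45
    abdominal pain: 0.3
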