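{
  "columns": {
    "sex": "Sex",
    "gender": "Sex",
    "weight": "BodyWeight",
    "bodyweight": "BodyWeight",
    "body_weight": "BodyWeight",
    "body weight": "BodyWeight",
    "batch": "Batch",
    "date_of_experiment": "Batch",
    "assay_date": "Batch",
    "genotype": "Genotype",
    "biological_sample_group": "Genotype",
    "lifestage": "LifeStage",
    "life_stage": "LifeStage",
    "response": "Response"
  },
  "sex_values": {
    "f": "Female",
    "female": "Female",
    "m": "Male",
    "male": "Male"
  }
}
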