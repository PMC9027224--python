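{
  "name": "adult_male_synthetic",
  "sex": "male",
  "total_mass_kg": 73.0,
  "organ_masses_g": {
    "bone_surfaces": 120,
    "brain": 1450,
    "breasts": 25,
    "colon": 370,
    "esophagus": 40,
    "gonads": 35,
    "heart_contents": 510,
    "kidneys": 310,
    "liver": 1800,
    "lungs": 1200,
    "muscle": 29000,
    "red_marrow": 1170,
    "salivary_glands": 85,
    "skin": 3300,
    "small_intestine": 650,
    "spleen": 150,
    "stomach_wall": 150,
    "thyroid": 20,
    "urinary_bladder_contents": 200,
    "urinary_bladder_wall": 50
  }
}
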