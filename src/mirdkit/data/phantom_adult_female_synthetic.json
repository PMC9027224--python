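{
  "name": "adult_female_synthetic",
  "sex": "female",
  "total_mass_kg": 60.0,
  "organ_masses_g": {
    "bone_surfaces": 100,
    "brain": 1300,
    "breasts": 500,
    "colon": 360,
    "esophagus": 35,
    "gonads": 11,
    "heart_contents": 460,
    "kidneys": 275,
    "liver": 1400,
    "lungs": 950,
    "muscle": 17500,
    "red_marrow": 900,
    "salivary_glands": 70,
    "skin": 2300,
    "small_intestine": 600,
    "spleen": 130,
    "stomach_wall": 140,
    "thyroid": 17,
    "urinary_bladder_contents": 200,
    "urinary_bladder_wall": 40
  }
}
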