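# Five-category mode of travel to school: the higher-resolution variant,
# available only where the instrument distinguished individual modes.
name: ICAD_SchoolTravel1
description: Mode of travel to school.
variable_group: School_travel
target_categories:
  - Walk
  - Cycle
  - Public transport
  - Car
  - Other
  - Missing
rules:
  - study_id: SPEEDY
    wave: 1
    kind: category_map
    source_variable: W1_school_travel
    mapping:
      On foot: Walk
      Bicycle: Cycle
      Bus/train: Public transport
      Car: Car
  - study_id: KISS
    wave: 1
    kind: category_map
    source_variable: a_schulweg_hin_sommer
    mapping:
      Walk: Walk
      Cycle/scooter: Cycle
      Bus/train/tram: Public transport
      Car: Car
  - study_id: Ballabeina
    wave: 1
    kind: category_map
    source_variable: W1_a_schulweg
    mapping:
      Walk: Walk
      Cycle/scooter: Cycle
      Bus/tram: Public transport
      Car: Car
      Other: Other
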