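# Binary mode of travel to school: the maximal-coverage variant. Collapsing
# to active vs other lets even walk/cycle-only questionnaires contribute
# (via the negative-response inference rule in those studies' entries).
name: ICAD_SchoolTravel2
description: Mode of travel to school (active vs other).
variable_group: School_travel
target_categories:
  - Active mode of travel
  - Other mode of travel
  - Missing
rules:
  - study_id: SPEEDY
    wave: 1
    kind: category_map
    source_variable: W1_school_travel
    mapping:
      Bicycle: Active mode of travel
      On foot: Active mode of travel
      Car: Other mode of travel
      Bus/train: Other mode of travel
  - study_id: KISS
    wave: 1
    kind: category_map
    source_variable: a_schulweg_hin_sommer
    mapping:
      Walk: Active mode of travel
      Cycle/scooter: Active mode of travel
      Car: Other mode of travel
      Bus/train/tram: Other mode of travel
  - study_id: Ballabeina
    wave: 1
    kind: category_map
    source_variable: W1_a_schulweg
    mapping:
      Walk: Active mode of travel
      Cycle/scooter: Active mode of travel
      Bus/tram: Other mode of travel
      Car: Other mode of travel
      Other: Other mode of travel
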