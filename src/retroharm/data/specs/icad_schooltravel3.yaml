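# Duration of the journey to school, binned at <=5 / 6-15 / >15 minutes.
# SPEEDY asked duration separately for walking and cycling but only jointly
# for bus/car, so its duration is taken from the mode-specific item and is
# Missing for motorised travellers. Ballabeina collected duration only as
# coarse bands with incompatible boundaries and is excluded with a reason.
name: ICAD_SchoolTravel3
description: Duration of journey to school.
variable_group: School_travel
target_categories:
  - Less than or equal to 5 min
  - 6–15 min
  - More than 15 min
  - Missing
rules:
  - study_id: SPEEDY
    wave: 1
    kind: threshold_bin
    mode_gate:
      mode_variable: W1_school_travel
      sources:
        On foot:
          hours: W1_a2acthrs_clean
          minutes: W1_a2actmins_clean
        Bicycle:
          hours: W1_a3acthrs_clean
          minutes: W1_a3actmins_clean
    bins:
      - upper: 5
        label: Less than or equal to 5 min
      - lower: 5
        upper: 15
        label: 6–15 min
      - lower: 15
        label: More than 15 min
  - study_id: KISS
    wave: 1
    kind: threshold_bin
    source_variable: a_schulweg_hin_sommer_time
    bins:
      - upper: 5
        label: Less than or equal to 5 min
      - lower: 5
        upper: 15
        label: 6–15 min
      - lower: 15
        label: More than 15 min
  - study_id: Ballabeina
    wave: 1
    kind: exclusion
    reason: >-
      Category boundaries incompatible: the duration item offered the
      response bands <10 min, 10–20 min and >20 min, which could not be
      suitably collapsed or otherwise matched to the harmonised category
      boundaries.
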