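# Ramachandran risk score: age, BMI, family history (any member), physical
# activity (sedentary vs active), sex-specific waist.  Positive at >= 21 of
# 42.  'Sedentary' maps to the no-exercise-and-no-strenuous-work level of the
# activity factor; any exercise or strenuous work counts as active.
name: ramachandran
cut_point: 21
total_score: 42
items:
  - name: age
    kind: range
    factor: age
    bins:
      - {points: 0, max: 30}
      - {points: 10, min: 30, max: 45}
      - {points: 18, min: 45, max: 60}
      - {points: 19, min: 60}
  - name: bmi
    kind: range
    factor: bmi
    bins:
      - {points: 0, max: 25}
      - {points: 7, min: 25}
  - name: family_history
    kind: categorical
    factor: family_history
    points:
      none: 0
      one_parent_or_sibling: 7
      both_parents: 7
  - name: physical_activity
    kind: categorical
    factor: physical_activity
    points:
      regular_exercise_and_strenuous_work: 0
      one_of_the_two: 0
      neither: 4
  - name: waist
    kind: range
    factor: waist
    bins:
      - {points: 0, sex: female, max: 80}
      - {points: 5, sex: female, min: 80}
      - {points: 0, sex: male, max: 85}
      - {points: 5, sex: male, min: 85}
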