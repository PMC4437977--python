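# Mohan risk score (Indian Diabetes Risk Score): age, family history,
# physical activity, sex-specific waist circumference.  Positive at >= 60 of
# 100.  Family history points are parent-based in the source; the profile's
# combined parent/sibling level maps to the single-parent points.
name: mohan
cut_point: 60
total_score: 100
items:
  - name: age
    kind: range
    factor: age
    bins:
      - {points: 0, max: 35}
      - {points: 20, min: 35, max: 50}
      - {points: 30, min: 50}
  - name: family_history
    kind: categorical
    factor: family_history
    points:
      none: 0
      one_parent_or_sibling: 10
      both_parents: 20
  - name: physical_activity
    kind: categorical
    factor: physical_activity
    points:
      regular_exercise_and_strenuous_work: 0
      one_of_the_two: 20
      neither: 30
  - name: waist
    kind: range
    factor: waist
    bins:
      - {points: 0, sex: female, max: 80}
      - {points: 10, sex: female, min: 80, max: 90}
      - {points: 20, sex: female, min: 90}
      - {points: 0, sex: male, max: 90}
      - {points: 10, sex: male, min: 90, max: 100}
      - {points: 20, sex: male, min: 100}
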