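# Chaturvedi risk score: age, blood pressure (worse of systolic/diastolic),
# family history, sex-specific waist circumference.  Positive at >= 16 of 29.
name: chaturvedi
cut_point: 16
total_score: 29
items:
  - name: age
    kind: range
    factor: age
    bins:
      - {points: 0, max: 40}
      - {points: 4, min: 40, max: 50}
      - {points: 6, min: 50}
  - name: blood_pressure
    kind: max_of
    children:
      - name: systolic
        kind: range
        factor: systolic_bp
        bins:
          - {points: 0, max: 120}
          - {points: 5, min: 120, max: 140}
          - {points: 7, min: 140}
      - name: diastolic
        kind: range
        factor: diastolic_bp
        bins:
          - {points: 0, max: 80}
          - {points: 5, min: 80, max: 90}
          - {points: 7, min: 90}
  - name: family_history
    kind: categorical
    factor: family_history
    points:
      none: 0
      one_parent_or_sibling: 4
      both_parents: 4
  - name: waist
    kind: range
    factor: waist
    bins:
      - {points: 0, sex: female, max: 75, max_inclusive: true}
      - {points: 9, sex: female, min: 75, min_inclusive: false, max: 85, max_inclusive: true}
      - {points: 12, sex: female, min: 85, min_inclusive: false}
      - {points: 0, sex: male, max: 80, max_inclusive: true}
      - {points: 9, sex: male, min: 80, min_inclusive: false, max: 90, max_inclusive: true}
      - {points: 12, sex: male, min: 90, min_inclusive: false}
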