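# Named long-interval suppressive dalbavancin regimen presets.
# Days are 1-based calendar days: day n starts at (n-1)*24 h.
# All infusions default to 0.5 h; cycles repeat every `cycle_weeks` weeks.
"1500-d1-d8-q6w":
  doses:
    - {day: 1, amount_mg: 1500, duration_h: 0.5}
    - {day: 8, amount_mg: 1500, duration_h: 0.5}
  cycle_weeks: 6
  n_cycles: 6
"1500-d1-d15-q6w":
  doses:
    - {day: 1, amount_mg: 1500, duration_h: 0.5}
    - {day: 15, amount_mg: 1500, duration_h: 0.5}
  cycle_weeks: 6
  n_cycles: 6
"1000-q2w":
  doses:
    - {day: 1, amount_mg: 1000, duration_h: 0.5}
  cycle_weeks: 2
  n_cycles: 6
"1500-q3w":
  doses:
    - {day: 1, amount_mg: 1500, duration_h: 0.5}
  cycle_weeks: 3
  n_cycles: 6
"1500-q4w":
  doses:
    - {day: 1, amount_mg: 1500, duration_h: 0.5}
  cycle_weeks: 4
  n_cycles: 6
"1500-q5w":
  doses:
    - {day: 1, amount_mg: 1500, duration_h: 0.5}
  cycle_weeks: 5
  n_cycles: 6
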