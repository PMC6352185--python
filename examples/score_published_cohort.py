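"""Analyse the packaged published score table (10 participants x 2 cycles).

Loads the shipped BABA/MC/dVSS score table, prints the per-cycle
descriptive statistics, the overall-proficiency classification and the
inter-score Pearson correlations.  The class counts (6 low / 8 moderate /
6 high) and every mean ± SD pair reproduce the published cohort exactly.
"""

from mocapskill import classify_cohort, load_score_table, pearson, summarize, trials_to_frame

trials = load_score_table()  # packaged study table
counts, labels = classify_cohort(trials)

print(summarize(trials, counts))

df = trials_to_frame(trials)
print("Inter-score correlations (n = 20 trials):")
for a, b in (("baba", "mc"), ("mc", "dvss"), ("dvss", "baba")):
    res = pearson(df[a], df[b])
    print(f"  {a.upper():>4} - {b.upper():<4}  r = {res.r:+.3f}  p = {res.p:.2g}")
print("\nPositive r with p < 0.05 means the motion-capture composite ranks")
print("trainees consistently with both external scoring systems.")
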