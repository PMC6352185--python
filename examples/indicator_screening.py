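"""Screen kinematic indicators against external scores on a synthetic cohort.

Generates a 10-participant x 2-cycle cohort, computes indicators for every
trial and correlates each indicator (and ratio derivative) against the
dVSS score, flagging those significant at alpha = 0.05 — the procedure
used to choose the composite score's ingredients.
"""

from mocapskill import (
    CohortSpec,
    compute_indicators,
    generate_cohort,
    select_indicators,
    trial_key,
)

recordings, trials = generate_cohort(CohortSpec(seed=7))
indicator_sets = [
    compute_indicators(recordings[trial_key(t.participant_id, t.cycle)]) for t in trials
]

print(f"{'indicator':<22} {'target':<6} {'r':>7} {'p':>9}  selected")
for rep in select_indicators(indicator_sets, trials, alpha=0.05):
    if rep.target != "dvss":
        continue
    if rep.result is None:
        print(f"{rep.indicator:<22} {rep.target:<6} {'--':>7} {'--':>9}  (constant)")
    else:
        mark = "  *" if rep.selected else ""
        print(
            f"{rep.indicator:<22} {rep.target:<6} {rep.result.r:>+7.3f} "
            f"{rep.result.p:>9.3g}{mark}"
        )
print("\n* = p < 0.05.  Completion time and economy-of-motion correlate")
print("negatively with the simulator score; the workspace-usage rate trends")
print("positive but is weaker and not significant in every cohort at n = 20 —")
print("the same asymmetry of effect sizes the screening is designed to sort.")
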