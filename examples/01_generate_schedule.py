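"""Generate a synthetic task schedule and inspect its design statistics.

The schedule realizes the advice-taking lottery paradigm: 160 trials, a 2x2
stable/volatile phase structure applied independently to the card contingency
and the advisor's intentions, 55% blue outcomes, 56% accurate advice, and an
advisor privately informed at 80% accuracy.
"""

import numpy as np

import socarb

schedule = socarb.generate_schedule(socarb.GeneratorConfig(seed=1))

print(f"trials:                 {len(schedule)}")
print(f"blue outcome rate:      {schedule.outcome_color.mean():.4f}")
print(f"advice accuracy:        {schedule.advice_accurate.mean():.4f}")
print(f"advisor signal accuracy:"
      f" {(schedule.advisor_info == schedule.outcome_color).mean():.4f}")
r = np.corrcoef(schedule.advice_accurate, schedule.outcome_color)[0, 1]
print(f"advice/outcome corr:    {r:+.3f}  (|r| <= 0.1 by design)")

print("\nphase structure (first trial of each block):")
combo = None
for i in range(len(schedule)):
    c = (schedule.advice_phase[i], schedule.card_phase[i])
    if c != combo:
        combo = c
        print(f"  trial {i + 1:3d}: advice {c[0]:8s} card {c[1]}")

# The blue rate and advice accuracy are exact-count constructions, so they
# hold for every seed; only the positions of outcomes within blocks change.
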