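"""Simulate the six-observer cohort on a few lesions.

Each simulated observer executes four strategies per lesion: fully manual
(noisy threshold start + boundary editing), interactive threshold,
gradient-guided threshold (tighter spread), and select-the-best among four
predefined segmentations.  Every lesion x observer x strategy cell is
seeded independently, so results are reproducible and insensitive to
factorial order.
"""

from collections import Counter

from petseg import default_panel, ideal_pct, make_scenario_suite
from petseg.observers import Strategy, run_study

suite = make_scenario_suite(3, seed=0)
observers = default_panel()
records = run_study(suite, observers, seed=0)
print(f"{len(records)} records = {len(suite)} lesions x {len(observers)} observers "
      f"x 4 strategies\n")

for case in suite:
    print(f"{case.lesion_id}: overlap-optimal threshold {ideal_pct(case):.2f}%")
    for strategy in (Strategy.THRESHOLD, Strategy.GRADIENT):
        pcts = [
            r.provenance["pct"]
            for r in records
            if r.lesion_id == case.lesion_id and r.strategy is strategy
        ]
        print(f"  {strategy.value:>9} slider choices: {sorted(pcts)}")
    chosen = [
        r.provenance["chosen"]
        for r in records
        if r.lesion_id == case.lesion_id and r.strategy is Strategy.SELECT_BEST
    ]
    print(f"  select-the-best picks : {dict(Counter(chosen))}\n")

edits = [
    (r.observer_id, r.provenance["n_added"] + r.provenance["n_removed"])
    for r in records
    if r.strategy is Strategy.MANUAL and r.lesion_id == suite[0].lesion_id
]
print(f"manual boundary edits on {suite[0].lesion_id} (novices edit more):")
for obs, n in edits:
    print(f"  {obs}: {n} voxels toggled")
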