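# smartbed

Closed-loop pressure-ulcer prevention for a segmented smart medical bed.

Bed-bound patients develop pressure ulcers where sustained contact pressure
(above roughly 32 mmHg) cuts off capillary blood flow. `smartbed` models a
bed built from 20 independently height-adjustable slats (HoPBs), each with
10 pressure sensors, each able to move ±40 mm, and implements the full
control loop a caregiver would otherwise close by hand:

1. **Sense** — a 32×64 body-pressure image per 80 s period (a synthetic
   generator renders labeled frames for all 10 lying postures, so nothing
   needs downloading);
2. **Classify** — a convolutional-recurrent network (CNN embedding per
   pooled frame + LSTM over the window) predicts the posture;
3. **Score** — frames pool onto the 20×10 slat grid by exact fractional
   area-overlap averaging; per-slat heats calibrate so the sample's mean
   nonzero heat ↦ ulcer level 10 and its maximum ↦ 20; levels bin into
   phases 1–5 and dwell time into levels 1–8;
4. **Act** — a Mamdani fuzzy system (AND = min, implication = truncation,
   aggregation = max, centre-of-gravity defuzzification) over a generated
   8000-rule base (20 slats × 10 postures × 8 time levels × 5 phases) emits
   one crisp movement per slat in [−2, 2], applied at 20 mm/unit and clamped
   to the ±40 mm hardware range, plus a caregiver guidance report.

The package is aimed at researchers prototyping pressure-redistribution
control policies and at students of fuzzy control: every stage is a plain
library function, deterministic under a seed, and covered by oracle tests
(brute-force pooling integration, analytic centroids, an independent
all-rules dense-grid Mamdani evaluation).

## Worked example

Twelve 80 s periods of a supine occupant, scored and fed to the controller:

```python
import numpy as np
from smartbed import *
from smartbed.preprocess import time_to_level

frames = generate_sequence([(0, 12)], BodyParams(noise_sd=0.5), seed=3)
heats_all = np.concatenate([hopb_heat(pool_frame(f).values) for f in frames])
stats = calibrate(heats_all)          # mean_nonzero=8.42, max_pressure=18.01

heats = hopb_heat(pool_frame(frames[-1]).values)
levels = assign_levels(heats, stats)
hl = HoPBLevels(heat=heats, level=levels, phase=level_to_phase(levels),
                time_level=np.where(levels > 0, time_to_level(12), 0))
out = FuzzyEngine().infer(hl, 0)      # posture 0 = Supine
```

Selected slats (`heat → level/phase`, dwell time level 6, and the crisp
setting the controller returns):

```
slat  heat   level phase  setting
  4    7.86    9     3   -0.36076   # cervical: mild, eased down slightly
  6   17.42   19     5   -1.50000   # shoulder: sustained phase 5 -> large descent
 11   17.88   20     5   -1.50000   # pelvis: maximum load -> large descent
 14    7.82    9     3   +0.23924   # support slat rises to take over load
 17    1.11    1     1   +0.60000   # lightly loaded neighbour rises
```

Negative settings lower a slat (−1.5 units = −30 mm at the default gain),
positive settings raise support slats next to at-risk regions, and slats
with no contact stay exactly at 0. `BedSimulator.run()` iterates this cycle
with load-conserving pressure redistribution and produces the guidance
report (posture, at-risk regions with phases, contacted slats, and a
reposition recommendation).

A thin CLI wraps the same functions:

```bash
smartbed simulate --postures all --n-per-class 20 --seed 1 --out data/
smartbed train --n-per-class 200 --seed 0 --model-out model.npz
smartbed export-rules --out rules.txt
smartbed control --levels levels.csv --posture 0 --rules rules.txt --out settings.csv
smartbed run-loop --frames data/ --model model.npz --out run/
```

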