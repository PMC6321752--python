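# otolithist

Otolith Sr:Ca microchemistry analysis for migratory life-history inference:
from raw LA-ICP-MS isotope intensities to calibrated molar Sr:Ca transects,
change-point segmentation by semi-supervised recursive partitioning, and a
per-fish call of the migratory strategy — freshwater resident (FW), brackish
resident (B), anadromous (ANA), catadromous (CAT), amphidromous (AMPH), or
omitted (O).

## The problem

Otoliths (fish ear stones) accrete calcium-carbonate layers throughout life
and archive the chemistry of the ambient water. Strontium substitutes for
calcium in the otolith matrix roughly in proportion to its availability,
and seawater is Sr-rich relative to most fresh water, so the molar Sr:Ca
ratio measured along a laser-ablation transect from the otolith core
(first-formed material) to its edge (time of capture) is a chronological
record of the fish's movements across salinity gradients. Ecologists use
such transects to ask whether a population is diadromous — a question with
direct consequences for dam placement and fish-passage design — without
tagging or tracking a single fish.

This package is aimed at fish ecologists and otolith-chemistry labs who
want that analysis as reviewable, testable code rather than a chain of
spreadsheets: instrument data reduction, artifact cleanup, objective
change-point detection, and rule-based life-history classification, each
step inspectable and each parameter explicit.

## The method

**Quantification.** Raw per-isotope counts (e.g. ⁸⁷Sr and a minor Ca
isotope) are averaged ten reads to a point, screened against a
blank-derived limit of detection (threshold `blank mean − 3·SD` per
isotope, the conventional `+3·SD` available by a sign switch),
blank-subtracted, converted to elemental intensities via natural isotopic
abundances, and scaled to molar mmol Sr / mol Ca using bracketing
measurements of a certified reference material, with the calibration factor
interpolated linearly across each sample block to correct drift.

**Segmentation.** Each cleaned transect is partitioned by a univariate
regression tree on position: splits are grown greedily to maximize the
reduction in within-segment sum of squares, then pruned against a
*splitting condition* c — the minimum difference in adjacent segment means
(mmol/mol) for a split to be kept:

&nbsp;&nbsp;&nbsp;&nbsp;|μ<sub>i</sub> − μ<sub>i+1</sub>| ≥ c for every adjacent segment pair.

The working grid c ∈ {0.5, 0.7, 1.0} separates strong habitat shifts
(split even at c = 1.0) from subtle within-habitat movement (split only at
c = 0.5). Zero splits at every condition is the residency signal.

**Classification.** Segment means are banded low / intermediate / high
(configurable thresholds; defaults 1.5 and 3.0 mmol/mol) and the
core-first band sequence is matched against idealized templates: L → FW,
I|H → B, L…H… → ANA, H…L… → CAT, I…H…L → AMPH, else O. The capture context
checks the plausibility of the final band, and a short high-Sr:Ca core
segment on a freshwater-caught fish is set aside as a maternal signature
rather than read as catadromy. Every call records the rule that fired and
the calls at all conditions.

A fully ground-truthed synthetic-data generator (template profiles and
complete raw instrument blocks with blanks, bracketing standards, noise,
drift and recording-error outliers) makes every stage testable end to end.

## Worked example

```python
from otolithist import (SyntheticSpec, generate_profile,
                        remove_additive_outliers, fit_segments,
                        call_at_conditions)

spec = SyntheticSpec(strategy="ANA", n_points=500, noise_sd=0.1,
                     outlier_rate=0.01, seed=7)
profile, truth = generate_profile(spec)
cleaned, report = remove_additive_outliers(profile)
print("outliers removed:", report.n_removed)

seg = fit_segments(cleaned, condition=0.5)
for s in seg.segments:
    print(f"segment {s.start_um:7.1f}-{s.end_um:7.1f} um  "
          f"mean {s.mean:.2f}  sd {s.sd:.2f}  n {s.n}")

call = call_at_conditions(cleaned, capture=truth.capture_context)
print("category:", call.category, "| bands:", call.band_sequence,
      "| rule:", call.rule_fired)
print("splits by condition:", call.splits_by_condition)
```

prints

```
outliers removed: 3
segment     0.0-  745.0 um  mean 0.68  sd 0.09  n 149
segment   750.0- 1745.0 um  mean 4.00  sd 0.10  n 200
segment  1750.0- 2495.0 um  mean 0.68  sd 0.10  n 148
category: ANA | bands: ['L', 'H', 'L'] | rule: rule3
splits by condition: {1.0: 2, 0.7: 2, 0.5: 2}
```

Three recording-error spikes were flagged, the transect resolved into a
low → high → low sequence of means (0.68, 4.00, 0.68 mmol/mol) with both
breakpoints retained even at the strictest condition, and the
rise-and-return pattern with freshwater capture was called anadromous —
matching the generating truth (breakpoints at 747.5 and 1747.5 µm).

The same pipeline is scriptable from the shell:

```sh
otolithist simulate --strategy CAT --seed 3 --out-dir sim
otolithist prep sim/*.csv --out-dir prepped
otolithist segment prepped/sim*.csv --out-dir segments
otolithist classify prepped/sim*.csv --out calls.csv
otolithist report calls.csv metadata.csv
```

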