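# Methods

## Scope and model

The package infers a fish's migratory life history from the molar Sr:Ca
ratio measured along a laser-ablation transect of its otolith. The model
rests on three assumptions: (i) otolith material accretes chronologically,
so position along a core→edge transect is a proxy for age; (ii) otolith
Sr:Ca increases with the marine influence of the ambient water; (iii)
habitat shifts appear as step changes in the transect mean, so a
piecewise-constant mean model with an explicit minimum step size is an
appropriate description of the signal. All three are idealizations; see
Limitations.

## Quantification chain

Raw data are per-isotope counts-per-second streams for one Sr isotope and
one Ca isotope, with companion blank runs (carrier acid) and runs of a
certified reference material bracketing each block of samples.

1. **Block averaging.** Consecutive reads are averaged `block_size` at a
   time (default 10, matching a 10 Hz repetition rate at 5 µm/s scan
   speed, i.e. one point per 5 µm). The block time is the mean of the
   read times; positions are `time × scan_speed`. A trailing partial
   block is dropped. Block means are computed about a per-block baseline
   value, which makes averaging of constant streams exact in floating
   point and avoids accumulation error in general.
2. **Limit of detection.** Per isotope, the threshold is
   `blank_mean + lod_sign · lod_sd_multiplier · blank_sd` with defaults
   `lod_sign = −1`, `lod_sd_multiplier = 3`, i.e. `mean − 3·SD`. The
   negative sign is deliberate and preserved from the source protocol this
   pipeline operationalizes; the conventional `mean + 3·SD` screen is one
   config switch away (`lod_sign = +1`). The screen is applied to
   pre-correction intensities, and a point failing on either isotope is
   flagged whole, because the ratio needs both. Flag counts are
   non-increasing in the multiplier at the default sign (tested).
3. **Blank correction.** The pooled per-isotope blank mean (all reads of
   all blank runs in the bracket; sample SD, ddof = 1) is subtracted.
   Post-correction negatives near blank level are expected and left to the
   LOD flags; they are not clipped.
4. **Molar conversion and calibration.** Isotope intensities are divided
   by natural abundance to elemental intensities (defaults ⁸⁷Sr = 0.0700,
   ⁴³Ca = 0.00135; the Ca isotope label and abundance are configurable
   because minor-isotope choices vary between sessions and not every
   reported label corresponds to a stable natural isotope). The raw
   elemental Sr/Ca ratio is scaled by `certified / measured` of the
   reference material, interpolated linearly between the pre- and
   post-block standard runs at the run's fractional position in the block
   (run *i* of *k* sits at (i+1)/(k+1)); a single-sided bracket uses a
   constant factor. The certified value has **no default**: it belongs to
   the material's certificate. A certificate given as a mass ratio is
   converted with the atomic masses (M_Ca/M_Sr). Two identities pin this
   arithmetic down: scaling all intensities by k > 0 leaves every
   calibrated ratio unchanged, and calibrating the standard against itself
   returns the certified value to machine precision (both tested).

Order of operations: averaging precedes blank subtraction (irrelevant for
the means, relevant for LOD flagging, which is defined on averaged,
uncorrected points).

## Outlier removal and transect quality

Recording errors appear as isolated single-point excursions (additive
outliers), not steps. A point is flagged when its deviation from a centred
running median (window 7 points) exceeds `k × 1.4826 × MAD` of the
windowed residuals, with k = 5. The median filter passes genuine steps
untouched — at a step boundary the window majority is the point's own
level — so habitat shifts survive while spikes do not. Retained values are
never smoothed. Removing more than 5% of points raises a warning rather
than an error: mass removal usually means the detector is eating signal.
The detector is a deliberate, explicit replacement for model-based
additive-outlier routines whose fitted-model definitions are hard to
reproduce; equivalence with any such routine is not claimed.

Transect quality is coded from the declared core position: **F** (full,
edge–core–edge; core within the central tercile), **H** (half; transect
ends at the core, within one median point spacing), **P** (partial; past
the core but short of the far edge), **O** (core not declared or outside
the span). The core position is operator input, not auto-detected: a wrong
automatic core would silently corrupt every downstream call. Full
transects record the life history twice; `mirror_halves` splits them at
the core and scores the rank correlation of the two halves on a common
relative-position grid as a data-quality diagnostic.

## Segmentation

A univariate regression tree on position with Sr:Ca as the response,
grown then pruned:

- **Grow.** Recursively apply the best binary split — the cut maximizing
  the reduction in within-segment sum of squared errors, computed in
  closed form as `n_l·n_r/n · (μ_l − μ_r)²` — while the reduction is
  positive and both sides keep at least `min_segment_size` points
  (default 5, to suppress single-point pseudo-segments the outlier pass
  may miss). Ties break to the leftmost cut; a relative tolerance of
  1e-10 on the reduction keeps float cancellation from splitting
  constant stretches. On short profiles every greedy cut is verified
  against an exhaustive scan in the test suite.
- **Prune.** While any adjacent pair of segment means differs by less
  than the splitting condition, merge the currently smallest-difference
  pair and recompute means. Grow-then-prune (rather than refusing
  sub-condition splits during growth) is what guarantees the *final*
  partition satisfies the condition, since means move as segments merge.
  Merging smallest-first is deterministic and removes the weakest
  structure first.

The final partition provably satisfies `|μ_i − μ_{i+1}| ≥ condition`
(asserted on every output), and split counts are non-increasing as the
condition relaxes from 0.5 through 0.7 to 1.0 mmol/mol — the pruning for a
larger condition is a continuation of the same greedy merge sequence.
Breakpoints are reported midway between the boundary points of adjacent
segments. Cross-validated cost-complexity pruning and multivariate trees
are out of scope: the condition *is* the stopping rule, chosen on the
scale of the measurement.

## Classification

Segment means are banded **L** (≤ `low_max`), **H** (≥ `high_min`) or
**I**, with defaults 1.5 and 3.0 mmol/mol calibrated on the synthetic
templates; no universally valid numeric boundary between freshwater and
marine Sr:Ca exists, so these are explicit configuration and calls on real
data are threshold-sensitive by construction. The collapsed core-first
band sequence is matched against the templates in fixed order: single L →
FW; single I/H → B; starts L and reaches H → ANA; starts H and reaches L →
CAT; starts I, reaches H, then L → AMPH; anything else → O. The rules
partition the entire sequence space (verified by enumerating all collapsed
sequences up to length 5 against an independently written oracle). The
capture context acts as a plausibility check on the final band; `unknown`
disables the check rather than failing.

An initial H segment spanning less than 10% of the transect on a
freshwater-caught fish is annotated as a maternal signature — yolk
provisioned by a sea-run mother imprints marine chemistry on the core —
and set aside before matching, so such fish are not forced into CAT. The
stripping applies only under freshwater capture, where the ANA/CAT
ambiguity actually arises.

Across the condition grid the reported call uses the strictest (largest)
condition that yields a non-O call; calls at every condition are retained
on the result, and splits that appear only under relaxed conditions are
annotated as subtle shifts (movement within, rather than between, habitat
types).

## Synthetic data

The generator emulates, at the calibrated level: piecewise-constant
life-history signal bands (defaults 0.7 / 2.0 / 4.0 mmol/mol, chosen to
bracket the dynamic range seen across real freshwater-to-marine species
contrasts), habitat-shift breakpoints at configurable fractions, an
optional maternal core spike, independent Gaussian noise, and additive
outliers (single points, magnitude uniform in 3–10 × noise SD, random
sign). At the raw level it inverts the quantification model: counts are
`elemental × abundance + blank background` with a linearly drifting
sensitivity ratio, plus blank runs and bracketing standard runs consistent
with a known calibration factor. Instrument shot noise is represented at
the ratio level (one noise term controls the profile) with an optional
proportional count-noise term; blank runs carry their own Gaussian noise.
Truth objects record the exact discontinuities of the noise-free signal
(including the maternal spike edge) and the generating category, and every
draw is reproducible from the spec seed.

What the generator does **not** model: otolith growth rate and
age-structured deposition (positions map linearly to time), temperature
and physiological modulation of Sr uptake, within-habitat chemical
gradients, smooth transitional mixing at habitat boundaries, or ablation
artifacts beyond single-point spikes. Passing the synthetic round-trip
therefore demonstrates that the *pipeline arithmetic and decision rules*
are correct under the stated signal model — not that real fish with
gradual transitions, maternal effects of intermediate span, or
glacier-flour-enriched freshwater will classify correctly.

## Problem sizes used in the checks

The test suite and acceptance script run at sizes chosen to exercise the
method's working regime: 500 random profiles of ≤ 60 points for the
greedy-vs-exhaustive split check (the exhaustive oracle is quadratic);
300–500-point transects for template and round-trip checks; 200 seeded
replicates of the breakpoint-recovery benchmark (unit jumps, noise SD 0.2,
n = 500, recovery within ±10 points at condition 0.5); 50 replicates of
the full raw-counts round trip at noise SD 0.1.

## Numerical choices

- Floats are serialized with shortest-round-trip `repr` and parsed with
  round-trip precision, so profile I/O is bit-exact.
- Sample SDs use ddof = 1 throughout; a single observation reports SD 0.
- Percentages round half-up to one decimal (so 12.45 → 12.5), matching
  field reporting conventions, via `decimal` rather than banker's
  rounding.
- Cohort distribution summaries pool all retained points of a species,
  not per-fish means: the target is the point-value distribution.
- Degenerate inputs: a constant transect yields one segment at any
  condition; `best_split` on constants returns the leftmost admissible
  cut with zero reduction (rejected by the growth tolerance); a
  zero-variance half in the mirror-consistency score yields 1.0 only if
  the other half is flat at the same level, else 0.

## Limitations

Band thresholds, the splitting-condition grid and the capture-context
rules encode judgment, not physics; on real data, per-fish calls can
legitimately differ between threshold choices, and the package surfaces
this (calls at all conditions, rule trail, annotations) rather than hiding
it. Sr:Ca alone cannot separate all habitat pairs — glacially influenced
fresh water can carry elevated Sr — and no multi-element panel is
implemented. Ages, migration timing and movement distances are explicitly
out of scope.
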