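# Methods

## Model and assumptions

The package aligns two GC×GC-MS peak lists as sequences. The load-bearing
assumption is that the elution order of compounds along the combined retention
axis rt1 + rt2 is conserved between runs: under that assumption, peak
correspondence is a (possibly repeated) local sequence-alignment problem and
no retention-time transformation, landmark selection or warping is needed.
Retention times themselves never enter the score — only the ordering they
induce and the fragment spectra do. The assumption can fail when temperature
programs reorder co-eluting compounds; the synthetic generator's
`order_breaking` mode exists to stress exactly that case, and accuracy decays
gracefully with the fraction of locally swapped compounds because a swap costs
at most the two peaks involved.

## Spectral similarity

S(x_i, y_j) is the sample Pearson correlation of the two intensity vectors on
the sorted union of their m/z bins, absent bins set to 0. The union (rather
than the intersection) keeps absent-ion evidence, which is what discriminates
isomers with overlapping fragments; computing instead over a fixed
instrument-wide m/z range would add shared always-zero bins and change the
correlation, so the union is used consistently. m/z values are unit-mass bins
(fractional input rounds half-up), matching nominal-mass TOF peak tables. The
computation is arranged so S(a, b) == S(b, a) bit-exactly (symmetric dot
products, product of sums under one square root) and clipped to [−1, 1]
against last-bit rounding. A zero-variance vector leaves the correlation
undefined; it is reported as 0 with a warning — "no evidence of identity" —
rather than raising, so one pathological flat spectrum cannot abort a run.
No intensity transform (sqrt/log weighting) is applied: the plain correlation
is the similarity this method is defined with.

## Scoring and tracebacks

Pair score: w(i, j) = u·S(x_i, y_j) when S ≥ ρ, else −v, substituted into the
standard Smith–Waterman recurrence with linear gap penalty d, zero clamp and
zero borders. Scaling the match reward by S (rather than the constant u)
makes the LS likelihood informative: retaining a 0.99 pair is better evidence
than retaining a 0.81 pair. The boundary S = ρ counts as a match in both the
gate and the post-filter, so a matched step can never contradict its own
retention.

Defaults u = 1, v = 1, d = 0.5. They are deliberately unitless: u fixes the
scale, v = u makes a sub-threshold match as bad as the reward a full match
earns, and d < u keeps bridging a dropped peak (one gap, −0.5) cheaper than
forcing a mismatch (−1), which suits dropout-riddled peak lists. All three
are settable everywhere. The gap penalty is linear, not affine, exactly as the
recurrence is written.

Tracebacks (all emit repeated local alignments from one H):

* **SWRM** starts at the global maximum (ties: smallest i + j, then smallest
  i — determinism matters more than the choice), walks to a zero cell (s, t),
  and repeats inside rows 1..s × columns 1..t while s > 1 and t > 1.
* **SWRE** starts at (m, n). At a zero-valued cell the walk emits nothing and
  moves to the predecessor (diagonal, up, left — in that tie order) with
  maximal H, resuming normal traceback at the next positive cell and ending at
  the border. This realizes "restart from (s, t) within the sub-matrix"
  without a second max-scan, which would collapse SWRE into SWRM.
* **SWRME** scans columns n, n−1, … for the first non-zero column maximum
  (ties: smallest row), traces back from it, then repeats the scan restricted
  to the remaining sub-matrix, by analogy with the other two repeat schemes.

Predecessor ties during any walk resolve diagonal first, then vertical, then
horizontal: diagonal preference maximizes matched pairs, the quantity the
method exists to produce. The post-filter keeps match steps with S ≥ ρ, sorted
ascending; segment geometry guarantees the retained pairs are strictly
increasing in both coordinates and index-disjoint.

## Likelihood selection

LS = Σ S over retained pairs; LP = Π S, with the empty product defined as 0 so
an empty alignment can never be "most likely". The optimizer sweeps
ρ ∈ {0.1, 0.2, …, 0.9, 0.93, 0.95, 0.97, 0.99} × methods {SWRM, SWRE, SWRME}
jointly and returns the LS argmax; ties go to the larger (more conservative) ρ,
then the smaller method index. LP is computed and reported in the trace as a
diagnostic only — it rewards retaining *fewer* pairs (each extra factor < 1
shrinks it) and anti-tracks F1, visible in any sweep trace.

## Evaluation

Truth is compound-label equality between deduplicated lists (one peak per
label, keeping the largest area — the standard resolution when instrument
software reports a compound twice). TP/FP/FN/TN follow the m·n-pair universe
with TN = m·n − r − FP; the four counting identities are asserted at runtime
on every evaluation. Degenerate denominators return 0 (r = 0 ⇒ TPR = 0, t = 0
⇒ PPV = 0, both zero ⇒ F1 = 0) so batch summaries stay total. Unlabeled peaks
count in m and n — they occupy alignment slots and can create false
positives — but can never be true positives. Batch summaries report mean and
SE = sample SD/√N per metric (SE = 0 for N = 1). Pair plans enumerate all
unordered within-group pairs (homogeneous) or all cross-group pairs
(heterogeneous).

## Synthetic data

The generator emulates a standards-mixture study: 75 labeled compounds (the
scale of a typical standards run; biological extracts run ~450), rt1 uniform
over 60–3060 s (a ~50-minute primary ramp), rt2 uniform over 0.5–4.5 s (a 5-s
modulation window), spectra of 20 distinct bins on 10–750 m/z with
log-uniform intensities over three decades. A target is derived from a
reference by:

* a **shift model** on rt1 — none, affine, a smooth monotone logistic ramp
  (nonlinear, because real retention drift is), or order-breaking adjacent
  swaps. Systematic shifts are driven by the combined coordinate rt1 + rt2, so
  the smooth models preserve survivor elution order *exactly*; the default
  heterogeneous magnitudes cycle over 30/60/90/120 s, emulating different
  temperature gradients;
* Gaussian retention jitter (0.5 s on rt1, 0.01 s on rt2 by default) — the
  repeat-injection wobble;
* spectral corruption: per-bin multiplicative log-normal noise (σ = 0.25) plus
  dropout of weak bins (base probability 0.05, decaying with relative
  intensity) — crude, but it makes the Pearson similarity degrade smoothly
  with noise, which is all the alignment consumes;
* independent peak dropout (10% per list by default), applied to the compound
  pool for both reference and target so both orphan-reference and
  orphan-target peaks occur.

All draws come from seeded numpy Generators keyed by (seed, stream); output is
byte-reproducible.

What passing on this generator does **not** show: real spectra have correlated
fragment structure (isotope clusters, common losses) so cross-compound
similarities are higher and more structured than between random sparse
spectra; real dropout correlates with abundance; and co-elution produces mixed
spectra. The synthetic batches therefore bound the method's behavior under
its own assumptions, not its field performance — which is why the accuracy
checks are run at the honest study scale but read as calibration anchors, not
instrument-data claims.

## Numerical choices and degenerate inputs

Traceback move detection compares H against the exact candidate expressions
that produced it, so float equality is safe. Empty peak lists are rejected at
ordering; a peak list of one peak aligns fine. Duplicate labels without areas
fail dedup loudly (no basis to choose). An all-zero H yields an empty
alignment, k = 0, LS = LP = 0, and evaluation returns all-zero rates rather
than raising. Elution-ordering ties (equal rt1 + rt2) break by rt1, then rt2,
then input position, giving a total order and deterministic alignments.

## Problem sizes used in the checks

The test suite and the acceptance script run the oracle comparison on 200
random pairs with m, n ≤ 6 (exhaustive enumeration is exact there), identity
recovery and grid sweeps on 75-peak lists, and batch accuracy on 20 synthetic
pairs per condition — the same pair count a 5-run homogeneous study would
yield is 10, so 20 gives steadier means while staying close to study scale.

## Known limitations

Strictly one-to-one matching (no many-to-one); no use of retention-time
*distance* in the score or the likelihood — a known gap when spectra alone are
ambiguous; joint tuning of u, v, d is not attempted; and large order scrambles
defeat the core assumption by construction.
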