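# Methods

This note documents the models and procedures implemented in `strobescreen`,
the assumptions behind them, the defaults that matter, and what the
synthetic study does and does not establish about real data.

## Motion index

Activity in a well is quantified by frame differencing: for consecutive
grayscale frames, `MI_t = Σ |frame_{t+1} − frame_t|` over the pixels of the
well's region of interest, at 25 frames/s.  A stack of N frames yields N−1
samples; each sample is time-stamped at the later frame of its pair, and
stimulus schedules use half-open `[start, end)` intervals in seconds, so a
sample belongs to the segment in which its closing frame falls.
Differences are accumulated in int64, so 8- or 16-bit input can never wrap.
MI is left in raw arbitrary units — wells are compared at identical ROI
areas, enforced by the non-overlapping ROI grid — and no background
subtraction or per-animal tracking is attempted: the well is the unit of
analysis.

The battery-average MI (arithmetic mean over the full ~20 min battery)
summarizes viability; an average below 1 (strictly) is treated as lethality.
Dose–response summaries report per-concentration means of battery averages
with Student-t 95% confidence intervals, appropriate for the small well
counts (typically 12) per condition; with a single well the interval
degenerates to the mean.

## Strobe score and hit calling

The strobe score for a well and channel (blue or green strobe segment,
each 120 s at 4 Hz) is

```
score = mean_i ( max MI in window_i ) − mean MI over the baseline interval
```

with six 5 s windows placed at maximal even spread: window *i* starts at
`i·(D − 5)/5` into a segment of duration `D` (for D = 120 s: 0, 23, 46, 69,
92, 115 s; a 30 s segment gives six contiguous windows).  The baseline
interval defaults to the 30 s immediately preceding the segment.  The
baseline term is what makes the statistic signed: untreated larvae freeze
under strobing light, so window maxima fall below the pre-strobe activity
and vehicle wells score negative, while strobe-driven hyperactivity scores
strongly positive.  Raw window-max averaging alone could not produce
negative solvent scores; the subtraction makes the two phenotypes lie on
opposite sides of zero.

Scores are additionally min–max normalized to [0, 1] per screening batch and
channel (order-preserving; a constant batch has no defined range and is
rejected), but hit calling always operates on raw scores: the threshold is

```
threshold = max(solvent scores) + 2 · SD(solvent scores)      (sample SD)
```

and a compound is a hit when its best blue-channel score is **≥** the
threshold (ties count).  This empirical-max null needs no distributional
assumption on compound scores and is deliberately conservative: in
simulation with test wells drawn from the solvent distribution, the false
positive rate over 10,000 wells is far below 1%.  The green channel is
computed and reported for the two-channel scatter but not thresholded.
Before thresholding, the screening workflow removes wells whose
battery-average MI is below 1: a dead well has near-zero score, which would
otherwise clear a negative threshold, and lethality is a separate call made
earlier in the workflow, not a strobe phenotype.

Retest summaries (replicate dose series of hits) flag a condition as
distinct from vehicle when its mean score exceeds the vehicle mean by at
least two vehicle SDs — the same 2-SD convention as the primary rule.

## Profile classification and embedding

Full-battery MI vectors (optionally block-averaged; factor 25 gives
per-second means) form a wells × samples matrix.  Whether phenotype classes
are *predictable* is assessed with a 500-tree random forest under stratified
k-fold cross-validation (default 5 folds): every well's prediction comes
from a forest that never saw it, so the confusion matrix and per-class
recalls measure out-of-sample separability rather than memorization.
Results are deterministic under the seed and independent of the worker
count.  The 2-D t-SNE embedding (default perplexity 30, fixed seed,
PCA initialization) is for visual structure only; no coordinate-level
claims are attached to it.

## Chemotype triage

Compounds are fingerprinted with RDKit's hashed topological path
fingerprint (2048 bits, paths 1–7), compared by Tanimoto similarity
(`|a∧b| / |a∨b|`, defined as 1 for two empty vectors), and clustered by
average-linkage hierarchical clustering on distance 1 − similarity, cutting
the tree at distance 1 − 0.45: compounds merged at or below that distance
share a cluster.  Average linkage is the default (single and complete are
available) for robustness to within-cluster noise; cluster labels are
canonicalized by each cluster's smallest member id, making the assignment
invariant to input order.  One representative per cluster is chosen as the
medoid (maximal mean intra-cluster similarity, ties broken
lexicographically) — a reproducible stand-in for the expert judgment used
in practice.

## Oocyte percent block

Clamp-current traces (inward negative, −60 mV holding) carry labeled
epochs: baseline, GABA alone, GABA + test compound, washout.  Traces whose
mean baseline current is more negative than −1000 nA fail leak QC (exactly
−1000 nA passes; the exclusion is for *excessive* leak).  Epoch amplitude
is the baseline-subtracted mean over the final 1 s of the epoch (a
steady-state convention; the measurement window is a package choice).

GABA responses desensitize slowly ("rundown"), so untreated control oocytes
estimate the fractional loss `1 − post/pre`, averaged over controls and
floored at 0.  For a treated oocyte,

```
remaining  = I_coapp / I_pre
block%     = 100 · (1 − remaining / (1 − rundown)),   clipped to [0, 100]
```

Rundown is treated as a multiplicative amplitude loss, hence the division;
a subtractive mode (`remaining + rundown`) is available for sensitivity
analysis.  Crediting more rundown lowers the block estimate — current lost
to desensitization must not be attributed to the compound.  An inactive
compound yields 0% and a full blocker 100%, exactly so in the noiseless
limit.  Per-compound results are reported as mean ± SEM over oocytes, with
a warning when the count falls outside the 3–6 design range.

## Insect LC50

Diet-assay wells carry one dose and 3–5 neonate larvae; a well is scored
dead only if its least-affected larva is dead.  The per-larva death
probability is modeled as two-parameter log-logistic with asymptotes fixed
at 0 and 1, `p(d) = logistic(slope · (log d − log LC50))` (probit optional),
and the well-level likelihood uses `P(well dead) = p(d)^n_larvae`: fitting
the logistic directly to well outcomes would estimate the all-larvae-dead
dose, which is substantially above the per-larva LC50 (≈1.5× at 4 larvae).
When no larvae counts are available the exponent is 1 and the model reduces
to ordinary logistic regression on log dose.  Optimization is L-BFGS-B on
(log LC50, log slope) with the slope bounded in [0.05, 50]; confidence
intervals are profile-likelihood on log LC50.  Tables with no mortality
variation (all dead or all alive) are flagged non-converged with NaN
estimates rather than fabricating a fit.  Abbott background-mortality
correction is available but off by default, matching a design with diluent
check wells and no observed natural mortality.  The estimator is exactly
scale-equivariant: rescaling all doses by c rescales the estimate by c.

Under the reference design — 7 doses geometrically spanning 2–16 µg/well,
12 replicate wells per dose, 3–5 larvae per well, planted LC50
8.6 µg/well, slope 4 — the median relative error of the estimate over 200
simulations is about 8%.

## Synthetic data model

The generator produces every input the pipeline consumes, with one global
seed and per-well streams derived by stable hashing of (plate, well) labels,
so outputs are byte-identical across runs and independent of well order.

*Traces.*  A well's expected MI within a segment is `baseline × gain`, with
the gain selected by segment kind (acoustic/tap startle gain, strobe gain,
unity elsewhere).  Default phenotype classes: vehicle (baseline 30, startle
gain 3, strobe gain 0.15 — freezing), lethal control (flat near-zero level
0.3, guaranteeing battery average < 1), a hyperactive reference with
baseline 60 and strobe gain 6, maximally active near 0.39 µM (Hill midpoint
0.2 µM, slope 2) and lethal at ≥ 12.5 µM — reproducing the characteristic
rise-then-collapse dose–response — and inactive/active test-compound
classes.  Dose dependence interpolates level and noise between the vehicle
and full phenotype with a Hill function.  Noise is Gaussian per sample,
clipped at zero (MI is a nonnegative sum of absolute differences), plus a
per-well multiplicative random effect (CV 0.15 in the default classes)
emulating biological well-to-well variability of the 8-larva ensemble; the
random effect is off (CV 0) outside the configured defaults so noiseless
worked examples remain exact.  The default battery is 1200 s at 25 frames/s
(30,000 samples): acclimation, acoustic, tap and steady-light assays with
rests, then the blue (560 nm) and green (525 nm) strobe segments, each
120 s at 4 Hz.

*Frame stacks.*  Oracle fixtures for the MI formula: a round-robin pixel
set moves up or down by known amounts so the per-step total absolute change
equals a requested integer target exactly; per-pixel moves are capped at
half the dtype maximum so a feasible direction always exists, and targets
beyond `half_max × n_pixels` are rejected as unrepresentable.

*Ephys traces.*  Four epochs (baseline, GABA, co-application, washout) with
exponential onsets (τ = 0.5 s) and Gaussian noise.  Rundown is applied once
at entry into the co-application epoch and persists into washout, so the
control estimator `1 − post/pre` equals the planted rundown exactly and the
co-application amplitude is `I_GABA · (1 − rundown) · (1 − block)`.  A
geometric per-epoch decay was considered and rejected: it makes the control
estimate `1 − (1−r)²`, which would break the exact null/full-block limits
the estimator is required to satisfy.

*Mortality tables and fingerprints.*  Per-larva Bernoulli deaths under the
log-logistic curve with well outcomes by the least-affected-individual rule;
planted-cluster fingerprints share a core bit set sized so the within-cluster
Tanimoto is at least the requested value, with disjoint bit ranges across
clusters (between-cluster similarity exactly 0).

### What the synthetic study does not show

The generator emulates the *statistical structure* of the screen, not its
biology: there is no larval locomotion model, no camera or optics
simulation, no inter-larva resolution within a well, and phenotype classes
are cleanly parameterized rather than behaviorally emergent.  Passing tests
therefore demonstrate that the estimators and decision rules are correct
and well-calibrated under the assumed noise model — truncated Gaussian with
a per-well random effect, an assumption the source data do not constrain —
not that real screens achieve the same operating characteristics.  In
particular the synthetic solvent-score spread is narrower than a real
screen's, and real fingerprint clusters are not bit-disjoint, so real
cluster recovery at threshold 0.45 depends on the actual chemistry.

## Numerical conventions and degenerate inputs

- Single-frame stacks yield an empty MI trace (not an error); empty traces
  cannot be averaged.
- Time-window sampling uses `round(t · rate)` index boundaries on half-open
  intervals; an empty scoring window or baseline is an error.
- Score normalization rejects constant batches; hit calling requires at
  least two solvent wells (the SD is otherwise undefined).
- Threshold ties are hits (closed inequality).
- Clustering distances are symmetrized exactly and compound ids sorted
  before linkage so library-internal tie-breaking cannot depend on input
  order.
- `percent_block` is clipped to [0, 100]; amplitude noise can otherwise
  produce slightly negative or >100 values.
- All simulations are reproducible from a single integer seed; derived
  seeds stay below 2³¹.

## Problem sizes used in the checks

The automated checks run at deliberately compact scales chosen to exercise
every code path: 1,000 random frame stacks for oracle equivalence, 58 wells
per condition for score distributions, 10,000 simulated test wells for
hit-rule operating characteristics, 12 wells × 3 classes for the
classifier, 35 compounds in 11 planted clusters for triage, a 5 × 3
block/rundown grid for electrophysiology, 200 simulated diet assays for
LC50 recovery, and one 96-well plate for the end-to-end pipeline.
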