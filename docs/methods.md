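# Methods

## Model

A ChIP sample of N₁ uniquely aligned reads decomposes into Π₀N₁
background reads and (1−Π₀)N₁ enrichment reads; the matched control of
N₂ reads is assumed to be all background and (approximately) linearly
related to the background component of the ChIP sample.  The
normalization factor r = Π₀N₁/N₂ is the scale on which control bin
counts predict ChIP *background* bin counts; it is bounded above by the
depth ratio N₁/N₂ and below by 0.  Every estimator here is an instance
of the background-ratio estimator r̂ = Σ_{i∈B} n₁ᵢ / Σ_{i∈B} n₂ᵢ over a
background bin set B chosen by the method, with Π̂₀ = r̂·N₂/N₁.

Reads are shifted ⌊l/2⌋ bases toward their 3' end so plus- and
minus-strand tags stack at the fragment midpoint (l defaults to 200 bp,
a typical average fragment length).  Coordinates are 0-based half-open;
bins on a chromosome are [k·w, (k+1)·w) with the last bin truncated;
tags shifted past a chromosome end are clamped to the terminal base so
read counts are conserved.  Duplicate reads are kept; no mappability or
GC correction is attempted.

## The adaptive estimator

With bins of width w and totals nᵢ = n₁ᵢ+n₂ᵢ, zero-total bins are
dropped (m_w bins remain) and B_w(t) = {i : nᵢ ≤ t}.  The threshold
search walks the *distinct observed* totals in ascending order —
thresholds between observed totals define identical B sets — and
selects

    t*_w = first t with r̂_w(t) ≥ r̂_w(t_prev) and |B_w(t)| ≥ 0.75·m_w,

where t_prev is the previous distinct total (whether or not it was
itself eligible).  The 0.75 floor starts the search at the upper
quartile of the non-zero totals, where the ratio profile is stable.  If
no threshold qualifies (or only one distinct total exists) the estimate
falls back to all retained bins and the result is flagged; a threshold
whose own or preceding control sum is zero is skipped.  Along the width
grid (default {100, 200, 500, 1000, 2000, 5000, 10000} bp, ascending)
the final estimate is r̂_{w_i} at the first i with r̂_{w_{i+1}} ≥ r̂_{w_i}
(ties stop, honoring "larger than or equal"); a strictly decreasing
sequence through the grid returns the last width, flagged.  Both
fallbacks approach the depth-ratio upper bound, which is the correct
limit as bins grow to genome size.

The fixed-width search is verified exactly against an independent
brute-force enumeration of B_w(t) for every distinct total (property
test plus a 1000-table randomized suite).

## Comparator estimators

* **CisGenome-style** — B = {i : nᵢ ≤ 1} at w = 100 bp.  Deep data may
  contain no such bins; that is reported as a degenerate-background
  error rather than silently widened, mirroring the estimator's known
  failure mode on deeply sequenced samples.
* **SPP-style** — w = 1 kb; bins with min(p₁ᵢ, p₂ᵢ) ≤ 10⁻⁵ are
  excluded, where pₖᵢ is the exact upper-tail Poisson probability
  P(X ≥ nₖᵢ) at the uniform rate Nₖ·w/G.  Exclusion is applied after
  zero-bin filtering (unstated in the source description; a choice).
* **CCAT-style** — w = 1 kb with per-strand counts; r̂⁽⁰⁾ = N₁/N₂, then
  B = {i : n₁ᵢ⁺ < r̂⁽ʲ⁾·n₂ᵢ⁺} (strict, as printed) and r̂⁽ʲ⁺¹⁾ from the
  negative-strand ratio over B; tolerance 10⁻⁶, at most 100 iterations,
  non-convergence flagged.  An empty B is treated as a trivial fixed
  point (current estimate returned, flagged) — this makes the identity
  input ChIP ≡ control well-defined — while a non-empty B with zero
  negative-strand control mass is a hard error.
* **PeakSeq-style** — OLS slope (with intercept) of ChIP on control
  counts at w = 10 kb over *all* bins, zero-total bins included; only
  the no-exclusion variant (P_f = 0) is implemented.  Whether the
  original regression passes through the origin is not documented;
  intercept-included is this package's choice.  Note that with two
  conditionally independent noisy samples the OLS slope attenuates by
  Var(λ)/(Var(λ)+E[λ]) — visible in simulations, and part of why this
  estimator ranks worst there.

Π̂₀ > 1 (possible for conservative estimators) is returned as-is with a
warning flag, never an error.

## Simulator

The generator produces tag-level datasets with exact ground truth
(Π₀ and r are recomputed from the stored background/signal partition,
not asserted):

* **Shared background** — a latent intensity field, gamma with mean 1
  and variance `roughness` (default 0.25) per 1 kb window, shared by
  ChIP and control; reads pick windows proportionally to
  intensity×length and land uniformly inside.  This reproduces the
  approximately linear ChIP/control background relationship;
  `roughness → 0` recovers uniform sampling.  It stands in for split
  halves of a real deeply sequenced control so that tests need no
  external data; `split_subsample` (disjoint halves, then 1/d binomial
  thinning, exact-count mode behind a flag) is provided for users with
  real reads.
* **Point-source signal** (transcription-factor-like): p sites uniform
  on the genome, per-site counts exponential with mean c·N₂/p rounded
  to integers, read positions Normal(μᵢ, σ² = 900 bp²), random strands,
  ChIP only.  Defaults p = 1000, c = 1.
* **Artifacts**: ⌊0.005·N₂⌋ control-only reads split evenly over 20
  uniform loci, jittered ±50 bp — tight piles mimicking PCR
  over-amplification.  Spatial shape and the ±50 bp width are choices;
  locations are not forced away from true sites.
* **Diffuse domains** (histone-like): p = 50 regions, lengths uniform
  in 5–15 kb, reads uniform within regions, counts as above.
* **Power setting**: a synthetic pool of 1572 (location, strength)
  pairs with exponential strengths scaled so expected signal is c·N₂;
  1000 sites sampled without replacement, Poisson(strength) read
  counts, placed as point sources; artifacts added.  The pool stands in
  for a peak-caller-derived site catalogue from real data.

What the generator does *not* emulate: mappability holes, GC bias,
fine-scale (sub-kilobase) background autocorrelation, sequencing error,
fragment-length variability.  Passing tests therefore demonstrate the
estimators' statistical behavior under the stated mixture model, not
performance on any particular real dataset.

## Peak calling and FDR evaluation

Stage 1 scores 100 bp bins by the upper-tail binomial p-value of the
ChIP count with success probability r̂/(1+r̂) and retains bins with
p ≤ 0.05; retained bins are merged when their gap is ≤ `merge_gap`
(default 0: adjacent only — "nearby" is otherwise undefined).  Stage 2
finds the 20 bp bin (anchored at the region start) with the highest
ChIP count, leftmost on ties; the predicted site is that bin's center
and is scored on the half-open window [pos−110, pos+110).  The swap run
exchanges the samples and uses 1/r̂.  The declared set uses the largest
observed ChIP-side p-value s with R_I(s)/R_C(s) ≤ the nominal level
(searching only observed p-values; if none qualifies nothing is
declared, flagged).  Evaluation: a declared site within 100 bp of a
true site is a true positive; `power` counts distinct true sites
recovered, so duplicate hits on one site neither double-count nor
become false positives, while the TP/FP split keeps
declared = TP + FP.  MSE summaries use the population decomposition
MSE = bias² + variance.

## Problem sizes and numerical choices

Simulation-backed tests and the acceptance script run on a 12 Mbp,
4-chromosome genome with 200k background reads per sample (the scale of
a deeply covered yeast experiment after subsampling), 25 replicates for
estimator recovery and 50 for FDR evaluation — sizes chosen so the full
suite runs in minutes on a single CPU while Monte-Carlo errors stay
well below the effects being measured.  All randomness flows through
numpy `SeedSequence` spawning, making every result a pure function of
the seed.  Known limitations: the adaptive estimator carries a small
positive bias (order 0.5% at these settings) from weak-signal leakage
into low-total bins — intrinsic to thresholding on totals, and visible
in its MSE — and a smaller negative selection effect from the
stop-at-first-non-decrease rules; swap-FDR calling inherits sensitivity
to r̂ on both sides of the swap, so realized FDR shifts by roughly one
percentage point per percent error in r̂ at these depths.
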