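# Methods

## The prediction contract

All predictors in this package satisfy one contract, the only property the
half-frozen cache needs:

* a **trunk** maps one-hot DNA (L×4, columns A/C/G/T, N = all-zero row) to
  per-bin embeddings (one embedding per `bin_size_bp` of sequence), and is
  **local**: an edit confined to bin *b* changes embeddings only within
  `affected_radius_bins` of *b*;
* a **head** consumes all bin embeddings, may mix globally, and emits a
  symmetric `map_size × map_size` matrix of log observed/expected contact
  values, cropped by `crop_bins` per side, with entries within
  `diagonal_offset_bins` (= 2) of the main diagonal undefined.

Geometry presets: `reference` (1,310,720 bp, 2,048 bp bins, 640 bins,
crop 64, 512×512 map, central map bin 256) and CPU-sized `test`
(16,384 bp, 256 bp bins, 64 bins, crop 8, 48×48 map) plus `test_wide`
(128 bins) whose map accommodates a 50-bin dot spacing. The test presets are
the problem sizes used throughout the test suite and the acceptance script;
they preserve every structural ratio of the reference geometry except
absolute size.

### Convolutional tower model

`ConvTowerModel` is a seeded random-weight instance of the contract: a stem
convolution (kernel 5) followed by one (conv k=5 → ReLU → maxpool 2) stage
per factor of two of the bin size, then a 2D head that forms pairwise
features (mean and |difference| of bin embeddings), applies dilated 3×3
convolutions, a 1×1 projection, cropping, and symmetrization by transpose
averaging. Reverse-complement equivariance is *not* enforced and not
claimed.

The receptive-field half-width of this tower is analytically
`2 + 2·(2^n − 1)` bp for n stages — exactly two bins at both preset bin
sizes. Construction fails if an architecture's analytic receptive field
exceeds the geometry's declared `affected_radius_bins`, and
`measure_affected_radius` verifies the declared radius empirically by
perturbing single bins; a measured violation is a hard error. This is the
safety interlock that makes caching sound by construction.

Weights are random (He-initialized, seeded): training is out of scope, so
predictions are structured but arbitrary. Everything the cache and geometry
tests assert is weight-independent.

### Mechanistic surrogate

`MechanisticModel` is an interpretable instance used as ground truth for
optimizer tests. Per bin and strand it computes an occupancy

    o = min(softplus(k·(s_max − t)) / k,  o_sat)

where `s_max` is the best PWM log2-odds score of any window starting in the
bin, `t` is the exact-DP detection threshold at p = 1e-4, sharpness k = 2
squashes sub-threshold background toward zero occupancy while keeping
gradients finite, and `o_sat` = 1 caps the contribution of a single site.
The head follows loop-extrusion logic: with t_b = o⁺_b + o⁻_b,

    m[i, j] = −α · Σ_{i<b≤j} t_b/(1 + t_b)  +  β · o⁺_i · o⁻_j  (+ stripe)

so motif occupancy *between* two loci insulates them (α term) and a
convergent (+, −) pair of occupied loci forms a focal dot (β term). An
optional third term, `stripe_weight · (o⁺_i + o⁻_j)`, models the one-sided
stripe a lone extrusion barrier produces; it is **off by default** and
enabled (0.2) in the dot-design experiments, where it also serves a
numerical purpose: the pure product term has an exactly vanishing gradient
when both anchors start occupancy-free, so gradient descent cannot cold-start
a dot without it. Defaults α = β = 1; the dot experiments use a dot-dominated
instance (α = 1e-4, β = 4).

Because a motif window (19 bp) can straddle at most one bin edge, the
surrogate's affected radius is ≤ 1 bin, and it is cacheable under any
geometry declaring radius ≥ 1.

## Half-frozen prediction

`build_cache` runs the trunk once and freezes the embeddings together with a
SHA-256 fingerprint of the base sequence. For a set of edited bins,
`cache_window` dilates each bin by the affected radius (giving the **splice
span**, the bins whose embeddings must be replaced) and additionally by
`context_radius_bins` (giving the **tower input span**, the extra flanking
sequence supplied so the recomputed embeddings see no window-edge
artifacts); overlapping tower spans are merged, and windows are clipped at
sequence ends (where zero padding matches the full pass exactly). With the
default radii (2 + 3), one edited interior bin yields an 11-bin tower input
and a 5-bin splice; two anchors 50 bins apart splice 10 bins in total.
The context radius of 3 is one bin more than the analytic requirement of 2;
the extra margin is kept deliberately conservative.

`predict_with_cache` verifies the fingerprint and that the edited sequence
differs from the base only inside the declared bins, recomputes the windows,
splices, and runs the head. On the conv-tower models the cached path is
bit-identical to the full forward pass for interior edits (the test suite
asserts ≤1e-5 across 20 seeded models; observed deviation is 0.0), because
pooling windows are bin-aligned and the recomputed bins' receptive fields
lie inside the tower window. Trunk work is instrumented in units of bins
processed, so cost proportionality is asserted structurally rather than by
wall clock.

## The optimizer

Editable regions are bp spans (derived from map-bin selections) minus locked
spans; locked positions are excluded from the trainable parameter set, so
they cannot change under any update. Each editable position holds logits
initialized to `log(onehot + ε)` — the original base starts with a ~log(1/ε)
advantage, so smaller ε anchors the sequence harder and yields fewer edits.
The published exploration of ε describes exactly this direction; the package
default is ε = 1e-2.

Per iteration: Gumbel noise is added, a softmax at temperature τ gives the
relaxed sample, the argmax one-hot is taken forward and the softmax gradient
backward (straight-through); the sampled rows are substituted into the
constant base one-hot; every predictor evaluates through its cache; and the
composite loss

    total = λ · (edit count of the discrete sample)
          + Σ_models masked-L1(pred, target)      (L2/Huber selectable)
          + γ · Σ gated motif scores

is backpropagated to the logits and applied with Adam (β₁ 0.9, β₂ 0.999,
ε_adam 1e-12 — small enough that gradients attenuated by a nearly saturated
softmax still move). The motif penalty is a PWM log-odds convolution of the
straight-through one-hot over both strands, summed over positions whose
score exceeds the exact-DP threshold at p = 1e-4, with the gate treated as a
constant for gradients. The loss mask is evaluated once per symmetric pair,
on defined upper-triangle entries.

The returned sequence is the best *sampled discrete* sequence by total loss
over all iterations. The trace records, per iteration, proposed edits
(sampled base ≠ original), accepted edits (logit-consensus base ≠ original;
reversible later), and the loss breakdown; the final reported breakdown is
recomputed from scratch on the returned sequence and must equal
λ·HammingDistance + recomputed output loss + recomputed penalty.

Success criteria: a design is successful with ≥1 edit and map RMSD (upper
triangle, excluding the two nearest off-diagonals) above a configurable
detectability floor of 1e-6. The CTCF-free variant additionally requires the
boundary score to drop by ≥0.005 with zero motif hits in the edited bin.

### Protocol table

| protocol | λ | γ | target | editable |
|---|---|---|---|---|
| boundary | 125 | – | corner quarters = value (−0.5 default) | central bin |
| dot | 150 | – | 15×15 pile-up patch at anchors | two anchor bins |
| flame | 140 | – | 3-bin stripe = 1.0 | central bin |
| fountain | 0.01 | – | antidiagonal cone = 0.5, width ≤120 | central 50 bins |
| noctcf_boundary | 0.01 | 3000 | corner quarters = −0.2 | central bin |
| suppress_boundary | 0.01 | – | pre-design flat map, quarter mask | central bin, motifs ±15 bp locked |

All protocols default to 2,000 iterations with no early stopping; overrides
are echoed into the result. λ values are calibrated to reference-scale
output losses (quarter block ≈ 65,000 entries). On the desk-scale surrogate
the output loss is orders of magnitude smaller, so the ground-truth-recovery
experiments in the test suite run at λ = 0 (the pure output-fidelity limit);
the λ trade-off itself is exercised separately through the λ→∞ identity
limit and the paired-seed monotonicity of edit counts in λ.

## Map statistics

* **Boundary score**: mean over the upper-right quarter (rows in the left
  half, columns in the right half); lower = stronger insulation.
* **Dot score**: mean of the 15×15 block centered on the anchor
  intersection.
* **Flame score**: mean or 75th percentile (linear interpolation between
  order statistics) over the stripe mask.
* **SCD**: root-sum-of-squares over defined upper-triangle entries.
* **Total variation**: summed |adjacent differences| along both axes.
* **Map RMSD**: RMS difference over upper-triangle entries with j − i > 2.
* **Insulation profile**: diamond window (default 16 bins) mean of contacts
  crossing each bin; undefined within a window of the edges.
* **Flat regions**: maximal runs where an 11-bin rolling standard deviation
  of the insulation profile stays below a threshold (default 3× the median
  rolling SD, so a constant profile with homogeneous noise passes), clipped
  to >50 bins from the edges and ≥100 bins long (~205 kb at the reference
  bin size), longest first. The rolling statistic and its threshold are not
  pinned down by any external convention; both are exposed as parameters.
* **Relative suppression**: (b_after − b_initial)/(b_flat − b_initial); 0 =
  unchanged, 1 = suppressed to the flat level, >1 possible.

Undefined (near-diagonal) entries are excluded from every statistic, and all
target builders leave unmasked entries bit-identical to the base map.

## Motif machinery

PWMs carry probabilities, a background (uniform by default; estimable from
sequence), and a 1e-9 pseudocount applied in the numerator of the log2-odds
so zero entries stay finite. Score thresholds for a p-value are computed by
exact dynamic programming: per-position scores are discretized to 1,000
integer levels per position, the null distribution is the convolution of
per-position pmfs under the background, and the threshold is the smallest
*attainable* score whose inclusive tail mass is ≤ p. The test suite checks
this against exhaustive enumeration for widths ≤ 6 and against Biopython's
independent ScoreDistribution.

Scanning scores every offset on both strands (minus-strand hits are
reported at forward-strand starts; windows containing N score −∞). Derived
quantities: per-site motif scores, aggregated positive score (sum of
positive offsets, both strands), Jaccard pattern similarity over
(position, orientation) pairs (two empty sets count as identical), locked
spans (hits ±15 bp, merged), IUPAC consensus scanning with mismatch
allowances (used for the B-box RGTTCRNRTCC, ≤3 mismatches), and seeded
within-span shuffling that preserves per-span composition.

The packaged PWM (`data/ctcf_synthetic.meme`) is a **synthetic** 19-bp
CTCF-like matrix constructed for testing; real analyses should supply the
JASPAR CTCF matrix. No quantitative result here depends on the exact matrix,
only on the existence of a strong asymmetric motif.

## Synthetic data

* `random_sequence`, `motif_free_sequence` (background scrubbed of windows
  within 4 bits of the detection threshold, so surrogate occupancy is ~0 and
  a flat map means a flat window), `plant_motifs`, `word_with_score`-style
  weakened sites in the tests.
* `simulate_dot_map`: symmetric Gaussian bump plus seeded noise, for
  pile-up (`build_dot_patch`) testing.
* `generate_background`: k-mer-preserving shuffle (k = 8 default) repeated
  until the predicted map's SCD and total variation fall below ceilings of
  30 and 1,300 quoted at reference map size and rescaled by defined-entry
  count (square-rooted for SCD); conserves the k-mer spectrum exactly. The
  shuffle samples the last-exit arborescence with Wilson's loop-erased
  random walks, which remains efficient on large de Bruijn graphs.
* `insert_copies`: equal-length overwrites at seeded random non-overlapping
  positions avoiding locked spans; placements are drawn sequentially from
  one stream, so the n-copy insertion extends the (n−1)-copy one — this
  makes dose–response monotonicity a deterministic property per seed.
* `b2_like_element`: a 220-bp synthetic retroelement stand-in whose only
  structured feature is a B-box realization; given a PWM its flanks are
  scrubbed so its motif content is null.

### What the surrogates do and do not show

Passing tests demonstrate that the cache is exact for local-receptive-field
trunks, that the optimizer respects constraints and recovers planted
mechanistic structure (motifs for boundaries, convergent orientation for
dots, dose-dependent suppression by motif-null insertions), and that every
score and mask implements its stated formula. They do not show that designs
against a *trained* genome-folding model would validate experimentally, nor
do they reproduce quantities that depend on trained weights, real genomes,
or hardware (edit counts on genomic windows, motif counts of real designs,
cross-model correlations, memory/runtime gains).

## Numerical choices

* Map-entry comparisons between cached and full paths use a 1e-5 absolute
  tolerance (head sums are not associative); observed agreement is exact.
* Percentiles use linear interpolation.
* Ties in the per-bin score maximum route gradients to the first argmax.
* The p-value DP's discretization error is bounded by W/1000 of the largest
  per-position score span; tests budget exactly that.
* Boundary-score floating comparisons in the success criteria carry a 1e-12
  slack so exact-threshold cases (Δ = 0.005) pass deterministically.
* All randomness flows through seeded `numpy` generators; identical seeds
  give bit-identical designs, traces, and serialized summaries.

## Known limitations

* The random-tower surrogate's output scale is arbitrary, so the published
  background-acceptance ceilings are only meaningful after rescaling, and
  the desk-scale surrogate sits above them; background tests therefore
  calibrate permissive ceilings from seeded maps.
* Locked-motif suppression cannot weaken a mechanistic-surrogate boundary
  whose occupancy comes from a locked detectable site — the surrogate has no
  silencing pathway (no analogue of retroelement-embedded motif silencing);
  the unconstrained arm reaches relative suppression ≈ 1.
* The optimizer is first-order: it cannot reposition or reorient existing
  motifs ("recombination"-like moves), and λ large enough to pin every
  position freezes it entirely — by design, this is the λ→∞ identity limit.
* Fountain targets have no mechanistic ground truth in either surrogate;
  the protocol is exercised structurally (masks, multi-model loss) only.
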