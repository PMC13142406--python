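# foldtailor

Design DNA sequences that fold chromatin on demand.

Local features of mammalian genome organization — insulating **boundaries**,
focal **dots** (loops), one-sided **flames** (stripes), and cone-shaped
**fountains** — emerge from loop extrusion and are visible in Hi-C contact
maps. `foldtailor` turns a contact-map predictor into a sequence *editor*: it
searches, by gradient descent over a relaxed one-hot encoding, for a handful
of nucleotide edits inside a restricted window that reshape the predicted map
toward a user-specified target pattern.

Two ideas make this practical:

1. **Half-frozen prediction.** Pooling convolutional predictors map megabase
   one-hot DNA to bin-level embeddings before any global mixing, and a local
   edit can only perturb embeddings within the trunk's receptive field
   (±2 bins of 2,048 bp at reference geometry). The trunk is therefore run
   **once** over the full window and cached; after an edit only an 11-bin
   window is recomputed, 5 bins are spliced over the cache, and the 2D head
   runs on the full embedding matrix. The result is numerically identical to
   a full forward pass (Pearson r = 1.0) at a fraction of the trunk cost.

2. **Straight-through Gumbel-Softmax editing.** Each editable position holds
   trainable logits over A/C/G/T. Every iteration draws a discrete sample
   (forward) with relaxed gradients (backward) at temperature τ and descends

   ```
   Loss = λ·InputLoss + OutputLoss (+ γ·Σ motif scores)
   ```

   where InputLoss is the literal edit count, OutputLoss is a masked L1
   distance between predicted and target maps, and the optional γ-penalty
   suppresses the formation of scanner-detectable CTCF motifs. λ trades map
   fidelity against parsimony; protocols for each feature ship with
   published defaults (boundary λ=125, dot λ=150, flame λ=140, fountain and
   penalized/locked designs λ=0.01; 2,000 iterations, no early stopping).

The package includes the feature mask builders and scores (boundary score =
mean of the upper-right map quarter; dot score = mean of a 15×15 anchor
patch; flame score = stripe mean or 75th percentile; SCD; total variation;
map RMSD excluding the two nearest off-diagonals; diamond-window insulation
profiles and flat-region finding), a FIMO-style PWM scanner with exact
dynamic-programming p-values, k-mer-preserving shuffles, B-box consensus
scanning, and fully synthetic surrogates so the entire stack runs offline:
a seeded random convolutional tower, and a *mechanistic* surrogate whose map
follows loop-extrusion logic from PWM occupancy — so that designed
boundaries should plant CTCF-like motifs and designed dots should recover
the convergent (+/−) anchor orientation, checkably.

Pretrained genome-folding weights and experimental Hi-C data are out of
scope: predictions come from the surrogates (or any user model implementing
the same trunk/head contract), and the scientific claims tested here are the
ones that do not depend on trained weights.

## Worked example

Design a strong boundary (target −0.5) in the central 256-bp bin of a
16-kb motif-free window, against the mechanistic surrogate:

```python
import foldtailor as ft
from foldtailor.synth import MechanisticModel, motif_free_sequence

pwm = ft.packaged_ctcf_pwm()                  # synthetic CTCF-like PWM
geom = ft.GEOMETRY_PRESETS["test"]            # 16,384 bp, 64 bins, 48x48 map
model = MechanisticModel(geom, pwm)
seq = motif_free_sequence(geom.input_length_bp, pwm, seed=100)

result = ft.run_protocol(
    "boundary", model, seq,
    overrides=dict(max_iter=400, seed=0, learning_rate=0.3, lambda_input=0.0),
    target_value=-0.5, pwm=pwm,
)
print("success        :", result.success)
print("edits          :", result.n_edits)
print("boundary before: %+.4f" % result.scores_before["boundary"])
print("boundary after : %+.4f" % result.scores_after["boundary"])
```

prints

```
success        : True
edits          : 85
boundary before: -0.0003
boundary after : -0.5003
```

The flat window (boundary score ≈ 0) becomes a boundary at almost exactly
the requested strength, and rescanning the edited bin finds a newly created
motif hit — `[(8429, '+', 17.2)]` (position, strand, log2-odds score) — the
optimizer rediscovered that insulation requires a CTCF site, without being
told so.

A command-line interface wraps the protocols
(`foldtailor design-boundary|design-dot|design-flame|design-fountain|
design-noctcf|suppress-boundary|score-map|scan-motifs|make-background|
make-fixtures|cache-build`); every run writes FASTA, TSV maps/traces, a JSON
summary and a manifest with all seeds and digests.

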