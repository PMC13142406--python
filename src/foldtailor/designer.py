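"""Gradient-based discrete sequence design against contact-map targets.

The optimizer maintains trainable logits over the four bases at every
editable position.  Each iteration draws a straight-through Gumbel-Softmax
sample (discrete one-hot forward, relaxed softmax gradient at temperature
tau), substitutes it into the sequence, predicts the contact map through the
half-frozen cache, and descends the composite loss

    total = lambda * InputLoss + OutputLoss (+ gamma * sum of motif scores)

where the input loss is the literal edit count of the discretized sample,
the output loss is a masked L1 (optionally L2/Huber) distance to the target
map, and the optional motif penalty discourages the formation of scanner-
detectable motif hits (their log-odds scores, gated at the scan threshold,
summed).  Locked positions are excluded from the trainable set entirely, so
they can never change.  The best discretized sequence (lowest total loss over
all iterations) is returned.

Initial logits are log(onehot + epsilon): the original base starts with a
log(1/epsilon)-scale advantage, so smaller epsilon anchors the sequence more
strongly and yields fewer edits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concat
from .cache import (
    ActivationCache,
    build_cache,
    predict_with_cache,
    predict_with_cache_tensor,
)
from .maps import (
    ContactMap,
    TargetMap,
    boundary_score,
    boundary_target,
    dot_target,
    flame_target,
    fountain_target,
    map_rmsd,
)
from .motifs import PWM, MotifSet, locked_spans, pwm_score_threshold, scan_pwm
from .seqcore import ALPHABET, Sequence, count_edits, encode_one_hot

__all__ = [
    "OptimizerConfig",
    "EditableRegion",
    "LossBreakdown",
    "EditTrace",
    "DesignResult",
    "compute_loss",
    "design",
    "is_success",
    "noctcf_success",
    "run_protocol",
    "PROTOCOLS",
]


@dataclass(frozen=True)
class OptimizerConfig:
    lambda_input: float = 0.01   # edit-count weight (lambda)
    tau: float = 1.0             # Gumbel-Softmax temperature
    epsilon: float = 1e-2        # initial logit floor for non-original bases
    gamma_motif: float = 0.0     # motif-penalty weight (gamma)
    learning_rate: float = 0.1
    max_iter: int = 2000
    early_stop: int | None = None  # patience in iterations; None = off
    seed: int = 0
    report_every: int = 100
    output_loss: str = "l1"      # l1 | l2 | huber

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.lambda_input < 0 or self.gamma_motif < 0:
            raise ValueError("lambda and gamma must be non-negative")
        if self.output_loss not in ("l1", "l2", "huber"):
            raise ValueError(f"unknown output loss {self.output_loss!r}")


@dataclass
class EditableRegion:
    """Base-pair spans open to edits, minus locked spans (e.g. motifs +-15 bp)."""

    editable_bp_spans: list[tuple[int, int]]
    locked_bp_spans: list[tuple[int, int]] = field(default_factory=list)

    def resolved_spans(self, length: int) -> list[tuple[int, int]]:
        """Editable minus locked, clipped, merged, sorted."""
        allowed = np.zeros(length, dtype=bool)
        for lo, hi in self.editable_bp_spans:
            allowed[max(0, lo) : min(length, hi)] = True
        for lo, hi in self.locked_bp_spans:
            allowed[max(0, lo) : min(length, hi)] = False
        spans: list[tuple[int, int]] = []
        idx = np.nonzero(allowed)[0]
        if idx.size == 0:
            return spans
        start = prev = idx[0]
        for i in idx[1:]:
            if i != prev + 1:
                spans.append((int(start), int(prev) + 1))
                start = i
            prev = i
        spans.append((int(start), int(prev) + 1))
        return spans


@dataclass
class LossBreakdown:
    input_loss: float       # edit count
    output_loss: float      # masked map distance
    motif_penalty: float    # gamma * sum of gated motif scores
    lambda_input: float

    @property
    def total(self) -> float:
        return self.lambda_input * self.input_loss + self.output_loss + self.motif_penalty


@dataclass
class EditTrace:
    """Per-iteration proposed/accepted edits and loss trajectory.

    A "proposed" edit is a sampled base differing from the original at that
    iteration; an "accepted" edit is a position whose logit consensus
    (argmax) differs from the original after the update.  Accepted edits can
    be reversed later.
    """

    edits: list[list[tuple[int, str, str, bool, bool]]] = field(default_factory=list)
    losses: list[LossBreakdown] = field(default_factory=list)
    best_iteration: int = -1


@dataclass
class DesignResult:
    original: Sequence
    optimized: Sequence
    map_before: ContactMap
    map_after: ContactMap
    loss: LossBreakdown
    trace: EditTrace
    config: OptimizerConfig
    target: TargetMap
    edited_bins: list[int]
    scores_before: dict = field(default_factory=dict)
    scores_after: dict = field(default_factory=dict)
    motifs_before: MotifSet | None = None
    motifs_after: MotifSet | None = None
    success: bool = False
    protocol: str = ""

    @property
    def n_edits(self) -> int:
        return count_edits(self.original, self.optimized)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def _output_distance(diff: Tensor, kind: str) -> Tensor:
    if kind == "l1":
        return diff.abs()
    if kind == "l2":
        return diff * diff
    # Huber (delta = 1): 0.5 d^2 inside, |d| - 0.5 outside
    a = diff.abs()
    m = a.minimum_const(1.0)
    return m * (a - m * 0.5)


def _masked_output_loss(pred: Tensor, target: TargetMap, kind: str) -> Tensor:
    mask = target.loss_mask & target.target.upper_mask()
    if not mask.any():
        raise ValueError("effective loss mask is empty")
    tgt = np.nan_to_num(target.target.matrix)
    diff = (pred - Tensor(tgt)) * Tensor(mask.astype(np.float64))
    return _output_distance(diff, kind).sum()


def compute_loss(
    pred: ContactMap,
    target: TargetMap,
    n_edits: int,
    config: OptimizerConfig,
    motif_scores_sum: float = 0.0,
) -> LossBreakdown:
    """Composite loss for a discrete prediction (non-differentiable path)."""
    out = _masked_output_loss(Tensor(np.nan_to_num(pred.matrix)), target, config.output_loss)
    return LossBreakdown(
        input_loss=float(n_edits),
        output_loss=float(out.data),
        motif_penalty=config.gamma_motif * motif_scores_sum,
        lambda_input=config.lambda_input,
    )


def _motif_penalty_tensor(
    x: Tensor, span: tuple[int, int], pwm: PWM, threshold: float
) -> Tensor:
    """Sum of above-threshold PWM log-odds scores over both strands within
    `span` of the (4, L) straight-through one-hot.  The threshold gate is
    computed on forward values and treated as constant for gradients."""
    w = pwm.width
    lo, hi = span
    lo = max(0, lo - (w - 1))
    hi = min(x.shape[1], hi + (w - 1))
    sub = x[:, lo:hi]
    kernels = np.stack([pwm.log_odds.T, pwm.reverse_complement().log_odds.T])  # (2,4,W)
    scores = sub.conv1d(Tensor(kernels), pad="valid")  # (2, n_offsets)
    gate = (scores.data >= threshold - 1e-12).astype(np.float64)
    return (scores * Tensor(gate)).sum()


# ---------------------------------------------------------------------------
# the optimizer
# ---------------------------------------------------------------------------

def design(
    predictors: list[tuple[object, ActivationCache, TargetMap]],
    original: Sequence,
    region: EditableRegion,
    config: OptimizerConfig,
    pwm: PWM | None = None,
) -> DesignResult:
    """Optimize `original` so every predictor's map approaches its target.

    `predictors` is a list of (model, cache, target) triples sharing one
    geometry; the output loss is the sum of per-model masked losses.
    Fully deterministic for a given config (one seeded generator drives the
    Gumbel noise).
    """
    if not predictors:
        raise ValueError("at least one predictor is required")
    geometry = predictors[0][0].geometry
    for model, cache, _t in predictors:
        if model.geometry != geometry:
            raise ValueError("all predictors must share one geometry")
        if cache.base_fingerprint != original.fingerprint():
            raise ValueError("cache fingerprint does not match the original sequence")
    if config.gamma_motif > 0 and pwm is None:
        raise ValueError("a PWM is required when gamma_motif > 0")

    length = len(original)
    spans = region.resolved_spans(length)
    positions = np.concatenate(
        [np.arange(lo, hi) for lo, hi in spans]
    ) if spans else np.array([], dtype=int)
    edited_bins = sorted({int(p) // geometry.bin_size_bp for p in positions})

    base_oh = encode_one_hot(original).matrix  # (L, 4)
    base_x = base_oh.T  # (4, L)
    n_pos = len(positions)
    base_rows = base_oh[positions] if n_pos else np.zeros((0, 4))
    orig_codes = np.argmax(base_rows, axis=1) if n_pos else np.array([], dtype=int)

    rng = np.random.default_rng(config.seed)
    logits = np.log(base_rows + config.epsilon) if n_pos else np.zeros((0, 4))
    adam_m = np.zeros_like(logits)
    adam_v = np.zeros_like(logits)
    # small adam_eps keeps updates alive when gradients pass through a
    # nearly saturated softmax (large original-base advantage)
    beta1, beta2, adam_eps = 0.9, 0.999, 1e-12

    thr = pwm_score_threshold(pwm, 1e-4) if (pwm is not None and config.gamma_motif > 0) else None
    penalty_span = (int(positions.min()), int(positions.max()) + 1) if n_pos else (0, 0)

    trace = EditTrace()
    best_total = np.inf
    best_codes = orig_codes.copy()
    best_iter = -1
    stall = 0

    for it in range(config.max_iter):
        if n_pos == 0:
            break
        leaf = Tensor(logits.copy(), requires_grad=True)
        gumbel = -np.log(-np.log(rng.uniform(1e-12, 1.0, size=logits.shape)))
        soft = ((leaf + Tensor(gumbel)) * (1.0 / config.tau)).softmax(axis=1)
        codes = np.argmax(soft.data, axis=1)
        hard = np.eye(4)[codes]
        st = Tensor(hard) + soft - soft.detach()  # straight-through sample

        # assemble the full (4, L) input: frozen pieces + sampled rows
        pieces = []
        cursor = 0
        row_cursor = 0
        for lo, hi in spans:
            if lo > cursor:
                pieces.append(Tensor(base_x[:, cursor:lo]))
            pieces.append(st[row_cursor : row_cursor + (hi - lo)].transpose(1, 0))
            row_cursor += hi - lo
            cursor = hi
        if cursor < length:
            pieces.append(Tensor(base_x[:, cursor:]))
        x = concat(pieces, axis=1)

        # forward value equals the integer edit count of the hard sample
        n_edit_t = (st * Tensor(1.0 - base_rows)).sum()
        out_t = None
        for model, cache, target in predictors:
            pred_t = predict_with_cache_tensor(model, cache, x, edited_bins)
            term = _masked_output_loss(pred_t, target, config.output_loss)
            out_t = term if out_t is None else out_t + term
        penalty_t = None
        if thr is not None:
            penalty_t = _motif_penalty_tensor(x, penalty_span, pwm, thr) * config.gamma_motif
        total_t = out_t + n_edit_t * config.lambda_input
        if penalty_t is not None:
            total_t = total_t + penalty_t
        total_t.backward()

        # Adam step
        g = leaf.grad
        adam_m = beta1 * adam_m + (1 - beta1) * g
        adam_v = beta2 * adam_v + (1 - beta2) * g * g
        mh = adam_m / (1 - beta1 ** (it + 1))
        vh = adam_v / (1 - beta2 ** (it + 1))
        logits = logits - config.learning_rate * mh / (np.sqrt(vh) + adam_eps)

        consensus = np.argmax(logits, axis=1)
        proposed = codes != orig_codes
        accepted = consensus != orig_codes
        events = [
            (
                int(positions[i]),
                ALPHABET[orig_codes[i]],
                ALPHABET[codes[i] if proposed[i] else consensus[i]],
                bool(proposed[i]),
                bool(accepted[i]),
            )
            for i in np.nonzero(proposed | accepted)[0]
        ]
        trace.edits.append(events)
        n_edits_val = int(proposed.sum())
        trace.losses.append(
            LossBreakdown(
                input_loss=float(n_edits_val),
                output_loss=float(out_t.data),
                motif_penalty=float(penalty_t.data) if penalty_t is not None else 0.0,
                lambda_input=config.lambda_input,
            )
        )
        if float(total_t.data) < best_total - 1e-12:
            best_total = float(total_t.data)
            best_codes = codes.copy()
            best_iter = it
            stall = 0
        else:
            stall += 1
            if config.early_stop is not None and stall >= config.early_stop:
                break

    trace.best_iteration = best_iter

    # materialize the best sequence
    bases = list(original.bases)
    for i, p in enumerate(positions):
        bases[p] = ALPHABET[best_codes[i]]
    optimized = Sequence(id=f"{original.id}_designed", bases="".join(bases))

    model0, cache0, target0 = predictors[0]
    map_before = predict_with_cache(model0, cache0, encode_one_hot(original), [])
    map_after = predict_with_cache(
        model0, cache0, encode_one_hot(optimized), edited_bins
    ) if edited_bins else map_before

    n_edits = count_edits(original, optimized)
    out_final = 0.0
    for model, cache, target in predictors:
        pred_t = (
            predict_with_cache_tensor(
                model, cache, Tensor(encode_one_hot(optimized).matrix.T), edited_bins
            )
            if edited_bins
            else Tensor(np.nan_to_num(map_before.matrix))
        )
        out_final += float(_masked_output_loss(pred_t, target, config.output_loss).data)
    pen_final = 0.0
    if thr is not None:
        pen_final = config.gamma_motif * float(
            _motif_penalty_tensor(
                Tensor(encode_one_hot(optimized).matrix.T), penalty_span, pwm, thr
            ).data
        )
    loss = LossBreakdown(float(n_edits), out_final, pen_final, config.lambda_input)

    result = DesignResult(
        original=original,
        optimized=optimized,
        map_before=map_before,
        map_after=map_after,
        loss=loss,
        trace=trace,
        config=config,
        target=target0,
        edited_bins=edited_bins,
    )
    result.success = is_success(result)
    if pwm is not None:
        result.motifs_before = scan_pwm(original, pwm)
        result.motifs_after = scan_pwm(optimized, pwm)
    return result


def is_success(result: DesignResult, rmsd_threshold: float = 1e-6) -> bool:
    """At least one edit and a detectable change in the predicted map."""
    if result.n_edits < 1:
        return False
    return map_rmsd(result.map_before, result.map_after) > rmsd_threshold


def noctcf_success(
    result: DesignResult, pwm: PWM, edited_bin_span: tuple[int, int]
) -> bool:
    """Boundary weakened by >= 0.005 with zero motif hits in the edited bin."""
    before = boundary_score(result.map_before)
    after = boundary_score(result.map_after)
    if not after <= before - 0.005 + 1e-12:
        return False
    lo, hi = edited_bin_span
    w = pwm.width
    lo = max(0, lo - (w - 1))
    hi = min(len(result.optimized), hi + (w - 1))
    sub = Sequence(id="edited_bin", bases=result.optimized.bases[lo:hi])
    return len(scan_pwm(sub, pwm)) == 0


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------

#: Per-feature defaults: lambda, edit region, target construction.
PROTOCOLS = {
    "boundary": dict(lambda_input=125.0, target_value=-0.5),
    "dot": dict(lambda_input=150.0),
    "flame": dict(lambda_input=140.0, target_value=1.0),
    "fountain": dict(lambda_input=0.01, target_value=0.5),
    "noctcf_boundary": dict(lambda_input=0.01, gamma_motif=3000.0, target_value=-0.2),
    "suppress_boundary": dict(lambda_input=0.01),
}


def run_protocol(
    name: str,
    models: object | list,
    original: Sequence,
    overrides: dict | None = None,
    *,
    pwm: PWM | None = None,
    dot_patch=None,
    distance_bins: int = 50,
    target_value: float | None = None,
    fountain_width_bins: int = 120,
    fountain_center_bins: int = 50,
    flat_reference: ContactMap | None = None,
    caches: list[ActivationCache] | None = None,
    lock_motifs: bool = True,
) -> DesignResult:
    """Wire masks, editable regions and loss weights for a named protocol.

    boundary / flame / noctcf_boundary edit the central bin; dot edits the
    two anchor bins; fountain edits the central `fountain_center_bins` bins;
    suppress_boundary edits the central bin with every detected motif
    (+-15 bp) locked and the flat pre-design map as the target.
    """
    if name not in PROTOCOLS:
        raise ValueError(f"unknown protocol {name!r}; valid: {sorted(PROTOCOLS)}")
    overrides = dict(overrides or {})
    if not isinstance(models, (list, tuple)):
        models = [models]
    geometry = models[0].geometry
    if caches is None:
        caches = [build_cache(m, encode_one_hot(original)) for m in models]
    base_maps = [
        ContactMap(m._head(Tensor(c.embeddings.matrix)).data, geometry.diagonal_offset_bins)
        for m, c in zip(models, caches)
    ]

    proto = PROTOCOLS[name]
    value = target_value if target_value is not None else proto.get("target_value")
    m = geometry.map_size
    center = geometry.central_map_bin
    locked: list[tuple[int, int]] = []

    if name in ("boundary", "noctcf_boundary"):
        targets = [boundary_target(bm, value) for bm in base_maps]
        editable_map_bins = [center]
    elif name == "flame":
        targets = [flame_target(bm, value) for bm in base_maps]
        editable_map_bins = [center]
    elif name == "dot":
        if dot_patch is None:
            raise ValueError("dot protocol requires a dot patch")
        targets = [dot_target(bm, dot_patch, distance_bins) for bm in base_maps]
        a1, a2 = targets[0].anchors
        editable_map_bins = [a1, a2]
    elif name == "fountain":
        width = min(fountain_width_bins, m)
        targets = [fountain_target(bm, value, width) for bm in base_maps]
        half = min(fountain_center_bins, m) // 2
        editable_map_bins = list(range(center - half, center - half + min(fountain_center_bins, m)))
    elif name == "suppress_boundary":
        if flat_reference is None:
            raise ValueError(
                "suppress_boundary requires the flat pre-design map as flat_reference"
            )
        if pwm is None:
            raise ValueError("suppress_boundary requires a PWM to lock motifs")
        from .maps import _quarter_blocks

        ur, ll = _quarter_blocks(m)
        targets = [
            TargetMap(flat_reference, (ur | ll) & flat_reference.defined(), "boundary")
            for _ in base_maps
        ]
        editable_map_bins = [center]
        if lock_motifs:
            hits = scan_pwm(original, pwm)
            locked = locked_spans(hits, pwm.width, flank_bp=15)

    editable_spans = [
        geometry.seq_bin_span_bp(geometry.map_bin_to_seq_bin(b)) for b in editable_map_bins
    ]
    region = EditableRegion(editable_spans, locked)

    cfg_kwargs = {k: v for k, v in proto.items() if k != "target_value"}
    cfg_kwargs.update(overrides)
    config = OptimizerConfig(**cfg_kwargs)

    predictors = list(zip(models, caches, targets))
    result = design(predictors, original, region, config, pwm=pwm)
    result.protocol = name

    # feature scores before/after
    from .maps import dot_score as _dot_score, flame_score as _flame_score

    if name in ("boundary", "noctcf_boundary", "suppress_boundary"):
        result.scores_before = {"boundary": boundary_score(result.map_before)}
        result.scores_after = {"boundary": boundary_score(result.map_after)}
    elif name == "dot":
        anchors = targets[0].anchors
        side = dot_patch.side
        result.scores_before = {"dot": _dot_score(result.map_before, anchors, side)}
        result.scores_after = {"dot": _dot_score(result.map_after, anchors, side)}
    elif name == "flame":
        mask = targets[0].loss_mask
        result.scores_before = {"flame": _flame_score(result.map_before, mask)}
        result.scores_after = {"flame": _flame_score(result.map_after, mask)}
    elif name == "fountain":
        mask = targets[0].loss_mask
        result.scores_before = {"fountain": _flame_score(result.map_before, mask)}
        result.scores_after = {"fountain": _flame_score(result.map_after, mask)}
    return result


def save_design_result(result: DesignResult, outdir: str | Path) -> None:
    """Serialize a design as a results directory.

    Writes original/optimized FASTA, before/after maps and the target as
    TSV matrices, the per-iteration loss trajectory and edit trace as TSV,
    and a JSON summary (scores, motif counts, success flags, config echo).
    """
    import json

    import pandas as pd

    from .seqcore import write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(outdir / "original.fasta", [result.original])
    write_fasta(outdir / "optimized.fasta", [result.optimized])
    np.savetxt(outdir / "map_before.tsv", result.map_before.matrix, delimiter="\t")
    np.savetxt(outdir / "map_after.tsv", result.map_after.matrix, delimiter="\t")
    np.savetxt(outdir / "map_target.tsv", result.target.target.matrix, delimiter="\t")
    pd.DataFrame(
        [
            {
                "iteration": i,
                "input_loss": lb.input_loss,
                "output_loss": lb.output_loss,
                "motif_penalty": lb.motif_penalty,
                "total": lb.total,
            }
            for i, lb in enumerate(result.trace.losses)
        ]
    ).to_csv(outdir / "loss_trajectory.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "iteration": i,
                "position": pos,
                "from_base": fb,
                "to_base": tb,
                "proposed": prop,
                "accepted": acc,
            }
            for i, events in enumerate(result.trace.edits)
            for (pos, fb, tb, prop, acc) in events
        ]
    ).to_csv(outdir / "edit_trace.tsv", sep="\t", index=False)
    summary = {
        "protocol": result.protocol,
        "success": bool(result.success),
        "n_edits": result.n_edits,
        "edited_bins": list(result.edited_bins),
        "scores_before": result.scores_before,
        "scores_after": result.scores_after,
        "map_rmsd": map_rmsd(result.map_before, result.map_after),
        "motifs_before": len(result.motifs_before) if result.motifs_before else None,
        "motifs_after": len(result.motifs_after) if result.motifs_after else None,
        "loss": {
            "input_loss": result.loss.input_loss,
            "output_loss": result.loss.output_loss,
            "motif_penalty": result.loss.motif_penalty,
            "total": result.loss.total,
        },
        "best_iteration": result.trace.best_iteration,
        "config": {
            k: getattr(result.config, k)
            for k in (
                "lambda_input", "tau", "epsilon", "gamma_motif", "learning_rate",
                "max_iter", "early_stop", "seed", "output_loss",
            )
        },
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
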