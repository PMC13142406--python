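"""Synthetic sequences, simulated maps and surrogate predictors.

Everything here makes the design stack testable without genome downloads or
trained weights: seeded random sequences, motif planting, simulated dot
maps for pile-up construction, neutral background generation by shuffle-and-
filter, element insertion, and two surrogate predictor families:

* ``random_tower`` — a seeded random-weight pooling tower (arbitrary but
  structured maps; exercises caching and geometry contracts).
* ``mechanistic`` — a fully interpretable model whose map follows loop-
  extrusion logic from PWM occupancy: motif occupancy in a bin insulates
  contacts across it, and a (+ strand, - strand) occupancy pair at two loci
  creates a focal dot.  This gives the optimizer a ground truth: designing a
  boundary should plant motifs, designing a dot should plant a convergent
  pair.

The mechanistic head, for per-bin strand occupancies o+ and o- (softplus of
the best within-bin PWM log-odds over a detection threshold, saturated):

    m[i, j] = -alpha * sum_{i < b <= j} t_b / (1 + t_b) + beta * o+_i * o-_j

with t_b = o+_b + o-_b, symmetrized and cropped like any predictor output.
An optional single-anchor stripe term (off by default) is described on
:class:`MechanisticModel`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat
from .foldmodel import BinEmbeddings, ModelGeometry, build_model, default_arch
from .maps import ContactMap, scd, total_variation
from .motifs import PWM, pwm_score_threshold
from .seqcore import (
    OneHotSequence,
    Sequence,
    encode_one_hot,
    kmer_shuffle,
    overwrite_span,
    reverse_complement,
)

__all__ = [
    "BackgroundConfig",
    "SurrogateSpec",
    "MechanisticModel",
    "make_surrogate",
    "random_sequence",
    "plant_motifs",
    "simulate_dot_map",
    "generate_background",
    "BackgroundSequence",
    "insert_copies",
    "b2_like_element",
    "B_BOX_CONSENSUS",
]

#: RNA Pol III internal promoter B-box consensus carried by SINE B2 elements.
B_BOX_CONSENSUS = "RGTTCRNRTCC"


@dataclass(frozen=True)
class BackgroundConfig:
    """Shuffle-and-filter settings for neutral background sequences.

    The SCD/TV ceilings are quoted at the reference map size and rescale
    with the defined-entry count for other geometries (linearly for total
    variation, square-rooted for SCD — both are sums over entries).
    """

    shuffle_k: int = 8
    scd_max: float = 30.0
    tv_max: float = 1300.0
    max_tries: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.scd_max <= 0 or self.tv_max <= 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class SurrogateSpec:
    kind: str  # "random_tower" | "mechanistic"
    geometry: ModelGeometry
    pwm: PWM | None = None
    alpha: float = 1.0          # insulation weight
    beta: float = 1.0           # dot weight
    stripe_weight: float = 0.0  # single-anchor stripe term (off by default)
    occupancy_saturation: float = 1.0
    seed: int = 0


class MechanisticModel:
    """PWM-occupancy surrogate predictor (differentiable end to end).

    Satisfies trunk locality with affected radius <= 1 bin (a motif window
    can straddle at most one bin edge), so it is cacheable under any
    geometry declaring radius >= 1.
    """

    def __init__(self, geometry: ModelGeometry, pwm: PWM, alpha: float = 1.0,
                 beta: float = 1.0, occupancy_saturation: float = 1.0,
                 detection_pvalue: float = 1e-4, sharpness: float = 2.0,
                 stripe_weight: float = 0.0):
        if geometry.affected_radius_bins < 1:
            raise ValueError("mechanistic surrogate needs affected radius >= 1")
        if pwm.width > geometry.bin_size_bp:
            raise ValueError("motif wider than a bin breaks single-bin locality")
        self.geometry = geometry
        self.pwm = pwm
        self.alpha = alpha
        self.beta = beta
        # optional one-sided barrier term: a lone '+' site at locus i (or '-'
        # at j) enriches contacts along its row (column), like a stripe; it
        # also lets gradient descent escape the cold start of the pure
        # product dot term, whose gradient vanishes when both anchors are
        # occupancy-free
        self.stripe_weight = stripe_weight
        self.occupancy_saturation = occupancy_saturation
        self.sharpness = sharpness  # squashes sub-threshold content to ~0
        self.threshold = pwm_score_threshold(pwm, detection_pvalue)
        self.trunk_bins_processed = 0
        self._kernels = Tensor(
            np.stack([pwm.log_odds.T, pwm.reverse_complement().log_odds.T])
        )  # (2, 4, W)

    def _trunk(self, x: Tensor, capture: str | None = None) -> Tensor:
        """(4, L) -> (n_window_bins, 2) strand occupancies."""
        if capture is not None:
            raise KeyError("mechanistic surrogate has no named layers")
        bsz = self.geometry.bin_size_bp
        length = x.shape[1]
        if length % bsz:
            raise ValueError("window length must be a whole number of bins")
        self.trunk_bins_processed += length // bsz
        scores = x.conv1d(self._kernels, pad="valid")  # (2, L - W + 1)
        pad = length - scores.shape[1]
        if pad:
            scores = concat([scores, Tensor(np.full((2, pad), -1e9))], axis=1)
        per_bin = scores.reshape(2, length // bsz, bsz).max(axis=2)  # (2, n_bins)
        occ = ((per_bin - Tensor(np.full((2, 1), self.threshold))) * self.sharpness).softplus() * (
            1.0 / self.sharpness
        )
        occ = occ.minimum_const(self.occupancy_saturation)
        return occ.transpose(1, 0)  # (n_bins, 2)

    def _head(self, emb: Tensor) -> Tensor:
        n = emb.shape[0]
        op = emb[:, 0]
        om = emb[:, 1]
        t = op + om
        u = t / (t + 1.0)
        s = u.cumsum(0)
        ins = (s.reshape(1, n) - s.reshape(n, 1)).abs()
        upper = np.triu(np.ones((n, n)), k=1)
        dot_u = (op.reshape(n, 1) * om.reshape(1, n)) * Tensor(upper)
        dots = dot_u + dot_u.transpose()
        full = ins * (-self.alpha) + dots * self.beta
        if self.stripe_weight:
            stripe_u = (op.reshape(n, 1) + om.reshape(1, n)) * Tensor(upper)
            full = full + (stripe_u + stripe_u.transpose()) * self.stripe_weight
        c = self.geometry.crop_bins
        return full[c : n - c, c : n - c]

    def predict_tensor(self, x: Tensor) -> Tensor:
        if x.shape != (4, self.geometry.input_length_bp):
            raise ValueError("wrong input length")
        return self._head(self._trunk(x))

    def predict_map(self, oh: OneHotSequence) -> ContactMap:
        out = self.predict_tensor(Tensor(oh.matrix.T))
        return ContactMap(out.data, self.geometry.diagonal_offset_bins)

    def trunk_embeddings(self, oh_window: OneHotSequence, bin_offset: int) -> BinEmbeddings:
        g = self.geometry
        emb = self._trunk(Tensor(oh_window.matrix.T))
        n_win = emb.shape[0]
        safe = np.ones(n_win, dtype=bool)
        cr = g.context_radius_bins
        if bin_offset > 0:
            safe[:cr] = False
        if bin_offset + n_win < g.n_bins:
            safe[max(0, n_win - cr):] = False
        return BinEmbeddings(emb.data, bin_offset, safe)


def make_surrogate(spec: SurrogateSpec):
    """Build a predictor from a surrogate specification."""
    if spec.kind == "random_tower":
        return build_model(spec.geometry, default_arch(spec.geometry), spec.seed)
    if spec.kind == "mechanistic":
        if spec.pwm is None:
            raise ValueError("mechanistic surrogate requires a PWM")
        return MechanisticModel(
            spec.geometry, spec.pwm, spec.alpha, spec.beta,
            spec.occupancy_saturation, stripe_weight=spec.stripe_weight,
        )
    raise ValueError(f"unknown surrogate kind {spec.kind!r}")


# ---------------------------------------------------------------------------
# sequence fixtures
# ---------------------------------------------------------------------------

def random_sequence(length: int, seed: int, gc: float = 0.5, id: str = "random") -> Sequence:
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = rng.choice(list("ACGT"), size=length, p=p)
    return Sequence(id=id, bases="".join(bases))


def motif_free_sequence(
    length: int, pwm: PWM, seed: int, margin: float = 4.0, id: str = "motif_free"
) -> Sequence:
    """Random sequence scrubbed of windows approaching the detection score.

    Any window (either strand) scoring above threshold(1e-4) - `margin` is
    redrawn until none remain, so a mechanistic surrogate sees an
    essentially flat, occupancy-free window.
    """
    from .motifs import _window_scores

    rng = np.random.default_rng(seed)
    seq = random_sequence(length, seed=seed, id=id)
    cut = pwm_score_threshold(pwm, 1e-4) - margin
    rc = pwm.reverse_complement()
    for _round in range(100):
        bad: set[int] = set()
        for p in (pwm, rc):
            s = _window_scores(seq, p)
            bad.update(int(o) for o in np.nonzero(s >= cut)[0])
        if not bad:
            return seq
        bases = list(seq.bases)
        for off in bad:
            for k in range(off, min(length, off + pwm.width)):
                bases[k] = "ACGT"[rng.integers(4)]
        seq = Sequence(id=id, bases="".join(bases))
    raise RuntimeError("failed to scrub motif-like windows")


def plant_motifs(
    seq: Sequence, word: Sequence, placements: list[tuple[int, str]]
) -> Sequence:
    """Overwrite `word` (or its reverse complement on '-') at each placement."""
    spans = sorted((off, off + len(word)) for off, _s in placements)
    for (a0, a1), (b0, _b1) in zip(spans, spans[1:]):
        if b0 < a1:
            raise ValueError("overlapping motif placements")
    out = seq
    for off, strand in placements:
        w = word if strand == "+" else reverse_complement(word)
        out = overwrite_span(out, off, w)
    return out


def simulate_dot_map(
    geometry: ModelGeometry,
    anchors: tuple[int, int],
    amplitude: float = 1.0,
    width_bins: float = 3.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ContactMap:
    """Symmetric map with a Gaussian dot at `anchors` plus seeded noise."""
    m = geometry.map_size
    a1, a2 = anchors
    if abs(a2 - a1) <= geometry.diagonal_offset_bins:
        raise ValueError("anchors fall inside the undefined band")
    rng = np.random.default_rng(seed)
    i, j = np.indices((m, m))
    upper = j > i
    bump = amplitude * np.exp(
        -((i - min(a1, a2)) ** 2 + (j - max(a1, a2)) ** 2) / (2 * width_bins**2)
    )
    mat = np.where(upper, bump, 0.0)
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=(m, m))
        mat = mat + np.where(upper, noise, 0.0)
    mat = mat + mat.T
    return ContactMap(mat, geometry.diagonal_offset_bins)


@dataclass
class BackgroundSequence:
    sequence: Sequence
    tries: int
    scd: float
    total_variation: float


def _defined_entry_count(map_size: int, band: int) -> int:
    return sum(map_size - d for d in range(band + 1, map_size))


def generate_background(
    seed_seq: Sequence, model, cfg: BackgroundConfig
) -> BackgroundSequence:
    """Shuffle until the predicted map is featureless.

    Repeats a k-mer-preserving shuffle of `seed_seq` (k = cfg.shuffle_k)
    until both the SCD and the total variation of the predicted map fall
    below the (geometry-rescaled) ceilings.  Base composition — indeed the
    whole k-mer spectrum — is preserved exactly.
    """
    g = model.geometry
    if len(seed_seq) != g.input_length_bp:
        raise ValueError("seed sequence must have full model input length")
    from .foldmodel import GEOMETRY_PRESETS

    ref = GEOMETRY_PRESETS["reference"]
    factor = _defined_entry_count(g.map_size, g.diagonal_offset_bins) / _defined_entry_count(
        ref.map_size, ref.diagonal_offset_bins
    )
    scd_max = cfg.scd_max * np.sqrt(factor)
    tv_max = cfg.tv_max * factor
    best: BackgroundSequence | None = None
    for t in range(cfg.max_tries):
        cand = kmer_shuffle(seed_seq, cfg.shuffle_k, seed=cfg.seed + t)
        cmap = model.predict_map(encode_one_hot(cand))
        s, tv = scd(cmap), total_variation(cmap)
        cur = BackgroundSequence(cand, t + 1, s, tv)
        if s < scd_max and tv < tv_max:
            return cur
        if best is None or (s + tv) < (best.scd + best.total_variation):
            best = cur
    raise RuntimeError(
        f"no background within thresholds after {cfg.max_tries} tries; "
        f"best candidate: SCD={best.scd:.3f} (max {scd_max:.3f}), "
        f"TV={best.total_variation:.3f} (max {tv_max:.3f})"
    )


def insert_copies(
    seq: Sequence,
    element: Sequence,
    n_copies: int,
    locked: list[tuple[int, int]],
    editable_span: tuple[int, int],
    seed: int,
) -> Sequence:
    """Overwrite `n_copies` of `element` at seeded random non-overlapping
    positions inside `editable_span`, never touching locked spans.

    Placements are drawn sequentially from one seeded stream, so for a fixed
    seed the n-copy insertion extends the (n-1)-copy insertion.
    """
    lo, hi = editable_span
    length = len(element)
    free = np.zeros(len(seq), dtype=bool)
    free[lo:hi] = True
    for a, b in locked:
        free[a:b] = False
    rng = np.random.default_rng(seed)
    out = seq
    for copy_i in range(n_copies):
        # positions where the whole element fits in free space
        window_ok = np.convolve(free.astype(int), np.ones(length, dtype=int), "valid") == length
        candidates = np.nonzero(window_ok)[0]
        if candidates.size == 0:
            raise ValueError(
                f"no room for copy {copy_i + 1}/{n_copies}: element {length} bp, "
                f"{int(free.sum())} free bp in span ({lo}, {hi})"
            )
        start = int(rng.choice(candidates))
        out = overwrite_span(out, start, element)
        free[start : start + length] = False
    return out


def b2_like_element(pwm: PWM | None = None, seed: int = 7, length: int = 220) -> Sequence:
    """Synthetic retroelement-like sequence: a B-box promoter realization
    embedded in neutral, motif-null sequence.

    A constructed stand-in for a SINE B2 consensus (the real consensus is
    user-supplied); its only structured feature is a concrete realization of
    the B-box consensus RGTTCRNRTCC.  When a PWM is given, the flanks are
    scrubbed of motif-like windows so the element carries no occupancy
    signal — its motif content is nulled.
    """
    if pwm is None:
        base = random_sequence(length, seed=seed, id="b2_like_synthetic")
    else:
        base = motif_free_sequence(length, pwm, seed=seed, id="b2_like_synthetic")
    bbox = Sequence(id="bbox", bases="GGTTCGAGTCC")
    return overwrite_span(base, 100, bbox)
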