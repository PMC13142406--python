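"""PWM scanning with exact p-value thresholds, motif scores and span locking.

Scores are log2 odds of the motif probability over a background, with a tiny
pseudocount (1e-9) added to the motif probability so zero entries stay
finite.  The score threshold for a requested p-value is computed by exact
dynamic programming over integer-discretized per-position scores (the score
distribution under the background is the convolution of per-position score
distributions), the same construction FIMO-style scanners use.

Minus-strand hits score the reverse complement and are reported at their
forward-strand start coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import motifs as bio_motifs

from .seqcore import ALPHABET, Sequence

__all__ = [
    "PWM",
    "MotifHit",
    "MotifSet",
    "pwm_score_threshold",
    "scan_pwm",
    "motif_score",
    "aggregated_positive_score",
    "motif_jaccard",
    "locked_spans",
    "iupac_scan",
    "shuffle_hits",
    "packaged_ctcf_pwm",
]

UNIFORM_BACKGROUND = np.full(4, 0.25)
DEFAULT_PSEUDOCOUNT = 1e-9
DP_LEVELS_PER_POSITION = 1000  # discretization granularity for the p-value DP

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_IUPAC_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass
class PWM:
    """Position probability matrix with background and pseudocount."""

    probs: np.ndarray  # (W, 4), columns A C G T
    name: str = ""
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=np.float64)
        if p.ndim != 2 or p.shape[1] != 4 or p.shape[0] < 1:
            raise ValueError("PWM must be W x 4 with W >= 1")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM rows must sum to 1")
        bg = np.asarray(self.background, dtype=np.float64)
        if not np.isclose(bg.sum(), 1.0, atol=1e-6):
            raise ValueError("background must sum to 1")
        self.probs = p
        self.background = bg

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """(W, 4) matrix of log2((p + pseudocount) / background)."""
        return np.log2((self.probs + self.pseudocount) / self.background)

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in np.argmax(self.probs, axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(
            self.probs[::-1, ::-1].copy(),
            name=f"{self.name}_rc",
            background=self.background[::-1].copy(),
            pseudocount=self.pseudocount,
        )

    # -- IO ----------------------------------------------------------------

    @classmethod
    def from_meme(cls, path: str | Path, background: np.ndarray | None = None) -> "PWM":
        """Read the first motif of a MEME (minimal) motif file."""
        with open(path) as fh:
            records = bio_motifs.parse(fh, "minimal")
            motif = records[0]
        probs = np.array([[motif.pwm[b][i] for b in "ACGT"] for i in range(motif.length)])
        if background is None:
            bgd = getattr(motif, "background", None)
            if bgd:
                background = np.array([bgd[b] for b in "ACGT"])
        return cls(probs, name=motif.name or "motif", background=background
                   if background is not None else UNIFORM_BACKGROUND.copy())

    @classmethod
    def from_tsv(cls, path: str | Path, name: str = "motif") -> "PWM":
        """Read a plain 4-column (A C G T) probability matrix."""
        return cls(np.loadtxt(path), name=name)


@dataclass(frozen=True)
class MotifHit:
    start: int        # forward-strand start, 0-based
    strand: str       # '+' or '-'
    score: float      # log2 odds
    pvalue: float

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


@dataclass
class MotifSet:
    hits: list[MotifHit]
    sequence_length: int
    pwm_name: str = ""

    def __post_init__(self):
        self.hits = sorted(self.hits, key=lambda h: (h.start, h.strand))
        keys = [(h.start, h.strand) for h in self.hits]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (start, strand) hits")

    def keys(self) -> set[tuple[int, str]]:
        return {(h.start, h.strand) for h in self.hits}

    def __len__(self) -> int:
        return len(self.hits)


# ---------------------------------------------------------------------------
# exact score distribution and p-value threshold
# ---------------------------------------------------------------------------

def _discretized(pwm: PWM) -> tuple[np.ndarray, float, float]:
    """Integer per-position scores, the scale, and the summed offset."""
    lo = pwm.log_odds
    mins = lo.min(axis=1, keepdims=True)
    span = float((lo - mins).max())
    scale = DP_LEVELS_PER_POSITION / span if span > 0 else 1.0
    ints = np.rint((lo - mins) * scale).astype(np.int64)
    return ints, scale, float(mins.sum())


def _score_distribution(pwm: PWM) -> tuple[np.ndarray, np.ndarray, float, float]:
    """(support_tail, pmf, scale, offset): pmf over integer total scores."""
    cached = pwm.__dict__.get("_dist")
    if cached is not None:
        return cached
    ints, scale, offset = _discretized(pwm)
    pmf = np.array([1.0])
    for w in range(pwm.width):
        row = np.zeros(ints[w].max() + 1)
        for b in range(4):
            row[ints[w, b]] += pwm.background[b]
        pmf = np.convolve(pmf, row)
    tail = np.cumsum(pmf[::-1])[::-1]  # tail[s] = P(S >= s)
    pwm.__dict__["_dist"] = (tail, pmf, scale, offset)
    return tail, pmf, scale, offset


def pwm_score_threshold(pwm: PWM, pvalue: float) -> float:
    """Smallest attainable log2-odds score s with P(score >= s | background)
    <= pvalue (the FIMO-style score cut-off for a p-value threshold)."""
    if not 0 < pvalue <= 1:
        raise ValueError("p-value must be in (0, 1]")
    tail, pmf, scale, offset = _score_distribution(pwm)
    attained = np.nonzero((pmf > 0) & (tail <= pvalue))[0]
    if attained.size == 0:
        s_int = len(tail)  # no attainable score is significant enough
    else:
        s_int = int(attained[0])
    return s_int / scale + offset


def score_pvalue(pwm: PWM, score: float) -> float:
    """Exact-DP p-value of a log2-odds score (P(S >= score | background))."""
    tail, _pmf, scale, offset = _score_distribution(pwm)
    s_int = int(np.ceil((score - offset) * scale - 1e-9))
    if s_int <= 0:
        return 1.0
    if s_int >= len(tail):
        return float(tail[-1])
    return float(tail[s_int])


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def _window_scores(seq: Sequence, pwm: PWM) -> np.ndarray:
    """Forward-strand log2-odds score at every offset; NaN-free, -inf at N."""
    lo = pwm.log_odds
    w = pwm.width
    length = len(seq)
    if length < w:
        raise ValueError(f"sequence shorter than motif width {w}")
    idx = np.frombuffer(seq.bases.encode(), dtype=np.uint8)
    code = np.full(length, -1, dtype=np.int64)
    for b_i, b in enumerate(ALPHABET):
        code[idx == ord(b)] = b_i
    n_mask = code < 0
    # accumulate shifted lookups (cheap even for megabase sequences)
    n_off = length - w + 1
    scores = np.zeros(n_off)
    bad = np.zeros(n_off, dtype=bool)
    safe_code = np.where(n_mask, 0, code)
    for p in range(w):
        scores += lo[p][safe_code[p : p + n_off]]
        bad |= n_mask[p : p + n_off]
    scores[bad] = -np.inf
    return scores


def scan_pwm(
    seq: Sequence, pwm: PWM, pvalue_threshold: float = 1e-4
) -> MotifSet:
    """FIMO-style scan of both strands; hits pass the exact-DP p-value cut.

    Windows containing N score -inf and never hit.  Minus-strand hits are
    reported at forward-strand coordinates.
    """
    thr = pwm_score_threshold(pwm, pvalue_threshold)
    hits: list[MotifHit] = []
    for strand, p in (("+", pwm), ("-", pwm.reverse_complement())):
        scores = _window_scores(seq, p)
        for off in np.nonzero(scores >= thr - 1e-12)[0]:
            s = float(scores[off])
            hits.append(MotifHit(int(off), strand, s, score_pvalue(pwm, s)))
    return MotifSet(hits, len(seq), pwm.name)


def motif_score(subseq: Sequence, pwm: PWM) -> float:
    """Log2-odds similarity of a width-W site to the motif (pseudocounted)."""
    if len(subseq) != pwm.width:
        raise ValueError(f"site length {len(subseq)} != motif width {pwm.width}")
    return float(_window_scores(subseq, pwm)[0])


def aggregated_positive_score(seq: Sequence, pwm: PWM) -> float:
    """Sum of positive per-offset motif scores over both strands.

    A moving similarity track is computed along the sequence; only positive
    values (motif-like content above background) contribute.
    """
    total = 0.0
    for p in (pwm, pwm.reverse_complement()):
        s = _window_scores(seq, p)
        s = s[np.isfinite(s)]
        total += float(s[s > 0].sum())
    return total


def motif_jaccard(a: MotifSet, b: MotifSet) -> float:
    """Jaccard index over (position, orientation) pairs; two empty sets are
    considered identical patterns (index 1)."""
    if a.sequence_length != b.sequence_length:
        raise ValueError("motif sets from sequences of different lengths")
    ka, kb = a.keys(), b.keys()
    union = ka | kb
    if not union:
        return 1.0
    return len(ka & kb) / len(union)


def locked_spans(
    hits: MotifSet, width: int, flank_bp: int = 15
) -> list[tuple[int, int]]:
    """Per-hit spans [start - flank, start + width + flank), clipped to the
    sequence and merged where overlapping.  Edits are forbidden inside."""
    raw = sorted(
        (max(0, h.start - flank_bp), min(hits.sequence_length, h.start + width + flank_bp))
        for h in hits.hits
    )
    merged: list[list[int]] = []
    for lo, hi in raw:
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged]


def iupac_scan(
    seq: Sequence, consensus: str, max_mismatch: int = 0
) -> list[tuple[int, str, int]]:
    """All windows on both strands matching an IUPAC consensus with at most
    `max_mismatch` violating positions.  N in the sequence never matches."""
    consensus = consensus.upper()
    for c in consensus:
        if c not in IUPAC:
            raise ValueError(f"invalid IUPAC symbol {c!r}")
    w = len(consensus)
    out: list[tuple[int, str, int]] = []
    rc_consensus = consensus.translate(_IUPAC_COMP)[::-1]
    for strand, cons in (("+", consensus), ("-", rc_consensus)):
        allowed = np.zeros((w, 256), dtype=bool)
        for p, c in enumerate(cons):
            for b in IUPAC[c]:
                allowed[p, ord(b)] = True
        idx = np.frombuffer(seq.bases.encode(), dtype=np.uint8)
        n_off = len(seq) - w + 1
        mism = np.zeros(n_off, dtype=np.int64)
        for p in range(w):
            mism += ~allowed[p][idx[p : p + n_off]]
        for off in np.nonzero(mism <= max_mismatch)[0]:
            out.append((int(off), strand, int(mism[off])))
    return sorted(out)


def shuffle_hits(
    seq: Sequence, spans: list[tuple[int, int]], seed: int
) -> Sequence:
    """Independently permute the bases inside each span (seeded).

    Overlapping spans are merged first; base composition inside every span is
    preserved exactly and bases outside are untouched.
    """
    merged: list[list[int]] = []
    for lo, hi in sorted(spans):
        if lo < 0 or hi > len(seq):
            raise ValueError(f"span ({lo}, {hi}) outside sequence")
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    rng = np.random.default_rng(seed)
    bases = list(seq.bases)
    for lo, hi in merged:
        segment = bases[lo:hi]
        perm = rng.permutation(hi - lo)
        bases[lo:hi] = [segment[i] for i in perm]
    return Sequence(id=seq.id, bases="".join(bases), origin=seq.origin)


def packaged_ctcf_pwm() -> PWM:
    """The synthetic CTCF-like PWM shipped with the package (19 bp).

    A constructed stand-in with the canonical CTCF core consensus shape; real
    analyses should supply the JASPAR MA0139.1 matrix.
    """
    path = Path(__file__).parent / "data" / "ctcf_synthetic.meme"
    return PWM.from_meme(path)
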