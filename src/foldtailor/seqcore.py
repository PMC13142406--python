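"""DNA sequence containers, one-hot encoding, edit accounting and shuffles.

Coordinates are 0-based half-open throughout; strands are '+'/'-'.  The
one-hot column order is A, C, G, T; an ``N`` encodes as an all-zero row so
that real bases stay row-normalized and ambiguous positions carry no signal.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq as _BioSeq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

__all__ = [
    "Sequence",
    "OneHotSequence",
    "encode_one_hot",
    "decode_one_hot",
    "gc_fraction",
    "kmer_shuffle",
    "count_edits",
    "overwrite_span",
    "reverse_complement",
    "read_fasta",
    "write_fasta",
]


@dataclass(frozen=True)
class Sequence:
    """A named DNA string over {A, C, G, T, N} with optional genomic origin."""

    id: str
    bases: str
    origin: tuple[str, str, int, int] | None = None  # (assembly, chrom, start, end)

    def __post_init__(self):
        bases = self.bases.upper()
        object.__setattr__(self, "bases", bases)
        bad = set(bases) - set("ACGTN")
        if bad:
            pos = next(i for i, b in enumerate(bases) if b in bad)
            raise ValueError(
                f"invalid character {bases[pos]!r} at position {pos} in sequence {self.id!r}"
            )
        if self.origin is not None:
            _, _, start, end = self.origin
            if end - start != len(bases):
                raise ValueError(
                    f"origin span {end - start} != sequence length {len(bases)}"
                )

    def __len__(self) -> int:
        return len(self.bases)

    def fingerprint(self) -> str:
        return hashlib.sha256(self.bases.encode()).hexdigest()


@dataclass
class OneHotSequence:
    """L x 4 one-hot (or relaxed) encoding, columns in A, C, G, T order."""

    matrix: np.ndarray
    source_id: str = ""

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"one-hot matrix must be L x 4, got {self.matrix.shape}")

    def __len__(self) -> int:
        return self.matrix.shape[0]


def encode_one_hot(seq: Sequence) -> OneHotSequence:
    """Indicator encoding; ``N`` rows are all-zero."""
    idx = np.frombuffer(seq.bases.encode(), dtype=np.uint8)
    mat = np.zeros((len(seq), 4))
    for base, col in _BASE_INDEX.items():
        mat[idx == ord(base), col] = 1.0
    return OneHotSequence(mat, source_id=seq.id)


def decode_one_hot(oh: OneHotSequence, discretize: bool = False) -> Sequence:
    """Inverse of :func:`encode_one_hot`.

    Rows must be exact indicators or all-zero (decoded as 'N') unless
    ``discretize`` is set, in which case each row decodes to its argmax.
    """
    mat = oh.matrix
    if not discretize:
        is_indicator = np.all(np.isin(mat, (0.0, 1.0))) and np.all(
            np.isin(mat.sum(axis=1), (0.0, 1.0))
        )
        if not is_indicator:
            raise ValueError(
                "relaxed one-hot rows; pass discretize=True to decode by argmax"
            )
    zero = mat.sum(axis=1) == 0
    letters = np.array(list(ALPHABET))[np.argmax(mat, axis=1)]
    letters[zero] = "N"
    return Sequence(id=oh.source_id, bases="".join(letters))


def gc_fraction(seq: Sequence) -> float:
    """Fraction of G and C among non-N bases."""
    counts = {b: seq.bases.count(b) for b in ALPHABET}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("GC fraction undefined for an all-N sequence")
    return (counts["G"] + counts["C"]) / total


def count_edits(a: Sequence, b: Sequence) -> int:
    """Hamming distance between equal-length sequences (the input loss)."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a.bases, b.bases))


def overwrite_span(seq: Sequence, start: int, element: Sequence) -> Sequence:
    """Equal-length overwrite of `element` at `start` (keeps total length).

    Fixed-length model inputs cannot grow, so "inserting" an element is
    implemented as an overwrite of a same-length span.
    """
    if start < 0 or start + len(element) > len(seq):
        raise ValueError(
            f"span [{start}, {start + len(element)}) exceeds sequence length {len(seq)}"
        )
    bases = seq.bases[:start] + element.bases + seq.bases[start + len(element):]
    return Sequence(id=seq.id, bases=bases, origin=seq.origin)


def reverse_complement(seq: Sequence) -> Sequence:
    return Sequence(id=seq.id, bases=seq.bases.translate(_COMPLEMENT)[::-1])


def kmer_shuffle(seq: Sequence, k: int, seed: int) -> Sequence:
    """k-mer-preserving shuffle (Altschul–Erikson Eulerian-path shuffle).

    The returned sequence has exactly the same multiset of k-mers as the
    input: edges of the (k-1)-mer de Bruijn multigraph are re-ordered along a
    uniformly sampled Eulerian path with fixed endpoints.  Deterministic for
    a given seed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(seq) < k:
        raise ValueError(f"sequence shorter than k={k}")
    rng = np.random.default_rng(seed)
    if k == 1:
        perm = rng.permutation(len(seq))
        return Sequence(id=seq.id, bases="".join(seq.bases[i] for i in perm))

    s = seq.bases
    n_nodes = len(s) - k + 2  # number of (k-1)-mers
    nodes = [s[i : i + k - 1] for i in range(n_nodes)]
    # multigraph: node -> list of successor nodes (edge = k-mer)
    succ: dict[str, list[str]] = {}
    for i in range(n_nodes - 1):
        succ.setdefault(nodes[i], []).append(nodes[i + 1])
    first, last = nodes[0], nodes[-1]

    # Altschul–Erikson: fix, for every non-terminal node, a "last exit" edge
    # such that these edges form an arborescence into the terminal node.
    # Sample the arborescence with Wilson's loop-erased random walks, which
    # stays efficient on large de Bruijn graphs.
    last_edge: dict[str, str] = {}
    in_tree: set[str] = {last}
    for start in succ:
        if start in in_tree:
            continue
        path = [start]
        pos = {start: 0}
        cur = start
        while cur not in in_tree:
            nxt = succ[cur][rng.integers(len(succ[cur]))]
            if nxt in pos:  # erase the loop
                cut = pos[nxt]
                for node in path[cut + 1:]:
                    del pos[node]
                del path[cut + 1:]
            else:
                path.append(nxt)
                pos[nxt] = len(path) - 1
            cur = path[-1]
        for a, b in zip(path, path[1:]):
            last_edge[a] = b
            in_tree.add(a)

    remaining: dict[str, list[str]] = {}
    for node, targets in succ.items():
        pool = list(targets)
        if node in last_edge:
            pool.remove(last_edge[node])
        rng.shuffle(pool)
        if node in last_edge:
            pool.append(last_edge[node])
        remaining[node] = pool

    out = [first]
    ptr = {node: 0 for node in remaining}
    cur = first
    total_edges = n_nodes - 1
    for _ in range(total_edges):
        nxt = remaining[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    shuffled = out[0] + "".join(node[-1] for node in out[1:])
    return Sequence(id=seq.id, bases=shuffled)


def kmer_counts(seq: Sequence, k: int) -> dict[str, int]:
    """Multiset of k-mers (used to verify shuffle conservation)."""
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        w = seq.bases[i : i + k]
        counts[w] = counts.get(w, 0) + 1
    return counts


def read_fasta(path: str | Path) -> list[Sequence]:
    records = SeqIO.parse(str(path), "fasta")
    return [Sequence(id=r.id, bases=str(r.seq).upper()) for r in records]


def write_fasta(path: str | Path, seqs: list[Sequence]) -> None:
    records = [SeqRecord(_BioSeq(s.bases), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")
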