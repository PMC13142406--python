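"""Trunk/head contact-map predictor with a verifiable local receptive field.

The predictor follows the geometry of pooling convolutional genome-folding
models: a 1D convolutional tower pools one-hot DNA down to bin-level
embeddings (one embedding per `bin_size_bp` window), and a 2D head mixes all
bins into a cropped, symmetric contact map of log observed/expected values.

The property the activation cache depends on is *trunk locality*: an edit
confined to bin b changes trunk embeddings only within `affected_radius_bins`
of b.  The tower built here guarantees this analytically (the receptive-field
half-width equals 2^(n_stages+1) bp for kernel-5 stages, i.e. exactly two
bins) and :func:`measure_affected_radius` verifies it empirically; a model
whose measured radius exceeds its declared radius cannot be cached.

Weights are random (seeded): training on experimental Hi-C is out of scope,
so predictions are structured but arbitrary.  Cache-equivalence and geometry
contracts are independent of the weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concat
from .maps import ContactMap
from .seqcore import OneHotSequence, Sequence, encode_one_hot

__all__ = [
    "ModelGeometry",
    "ArchConfig",
    "BinEmbeddings",
    "ConvTowerModel",
    "GEOMETRY_PRESETS",
    "build_model",
    "predict_map",
    "trunk_embeddings",
    "measure_affected_radius",
    "layer_max_activations",
    "filter_group_contrast",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ModelGeometry:
    """Input/bin/map arithmetic shared by the predictor and the cache."""

    input_length_bp: int
    bin_size_bp: int
    n_bins: int
    crop_bins: int
    affected_radius_bins: int = 2
    context_radius_bins: int = 3
    diagonal_offset_bins: int = 2

    def __post_init__(self):
        if self.input_length_bp != self.bin_size_bp * self.n_bins:
            raise ValueError("input_length_bp must equal bin_size_bp * n_bins")
        if self.map_size <= 0:
            raise ValueError("cropping leaves no map bins")

    @property
    def map_size(self) -> int:
        return self.n_bins - 2 * self.crop_bins

    @property
    def cache_window_radius(self) -> int:
        return self.affected_radius_bins + self.context_radius_bins

    @property
    def central_map_bin(self) -> int:
        return self.map_size // 2

    def map_bin_to_seq_bin(self, map_bin: int) -> int:
        return map_bin + self.crop_bins

    def seq_bin_span_bp(self, seq_bin: int) -> tuple[int, int]:
        return seq_bin * self.bin_size_bp, (seq_bin + 1) * self.bin_size_bp


#: Reference geometry: 1.31 Mb of DNA pooled into 640 bins of 2,048 bp,
#: cropped by 64 bins per side to a 512 x 512 map (central map bin 256).
#: The test preset keeps the same structure at CPU-friendly size.
GEOMETRY_PRESETS: dict[str, ModelGeometry] = {
    "reference": ModelGeometry(1_310_720, 2048, 640, 64),
    "test": ModelGeometry(16_384, 256, 64, 8),
    "test_wide": ModelGeometry(32_768, 256, 128, 8),  # fits 50-bin dot spacing
}


@dataclass(frozen=True)
class ArchConfig:
    """Layer plan for the tower and head.

    `channels` has one entry per pooling stage; each stage is conv(kernel=
    `stage_kernel`, same padding) + ReLU + maxpool(2).  The number of stages
    must satisfy 2**n_stages == bin_size_bp, so the pooling schedule lands
    exactly on one embedding per bin.
    """

    channels: tuple[int, ...]
    stem_channels: int = 8
    stem_kernel: int = 5
    stage_kernel: int = 5
    head_channels: int = 16
    head_kernel: int = 3
    head_dilations: tuple[int, ...] = (1, 2)
    rc_equivariant: bool = False  # documented non-property: RC symmetry is
    # not enforced; reverse-complement inputs need not give reflected maps.

    @property
    def embed_dim(self) -> int:
        return self.channels[-1]


def default_arch(geometry: ModelGeometry) -> ArchConfig:
    n_stages = int(round(np.log2(geometry.bin_size_bp)))
    channels = tuple(min(32, 8 * 2 ** (s // 4)) for s in range(n_stages))
    return ArchConfig(channels=channels)


@dataclass
class BinEmbeddings:
    """Trunk output for a window of whole bins.

    `safe` flags bins whose receptive field lies entirely inside the window
    (or reaches a true sequence end); only safe bins may be spliced into a
    cache.
    """

    matrix: np.ndarray
    bin_offset: int
    safe: np.ndarray


def _receptive_halfwidth_bp(arch: ArchConfig, n_stages: int) -> int:
    # stem conv at 1 bp resolution + each stage conv at 2^(s) bp resolution
    hw = arch.stem_kernel // 2
    for s in range(n_stages):
        hw += (arch.stage_kernel // 2) * 2**s
    return hw


class ConvTowerModel:
    """Seeded random-weight pooling tower + dilated 2D head."""

    def __init__(self, geometry: ModelGeometry, arch: ArchConfig, seed: int):
        n_stages = int(round(np.log2(geometry.bin_size_bp)))
        if 2**n_stages != geometry.bin_size_bp:
            raise ValueError("bin_size_bp must be a power of two")
        if len(arch.channels) != n_stages:
            raise ValueError(
                f"pooling schedule inconsistent: {len(arch.channels)} stages "
                f"cannot pool to {geometry.bin_size_bp} bp per bin "
                f"(need {n_stages})"
            )
        rf_bins = int(np.ceil(_receptive_halfwidth_bp(arch, n_stages) / geometry.bin_size_bp))
        if rf_bins > geometry.affected_radius_bins:
            raise ValueError(
                f"architecture receptive field ({rf_bins} bins) exceeds the "
                f"declared affected radius ({geometry.affected_radius_bins})"
            )
        self.geometry = geometry
        self.arch = arch
        self.seed = seed
        self.n_stages = n_stages
        self.trunk_bins_processed = 0  # instrumentation for cache-cost checks
        rng = np.random.default_rng(seed)
        self.params: dict[str, Tensor] = {}

        def conv_init(name, c_out, c_in, *k):
            fan_in = c_in * int(np.prod(k))
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, *k))
            b = rng.normal(0.0, 0.1, size=c_out)
            self.params[f"{name}_w"] = Tensor(w)
            self.params[f"{name}_b"] = Tensor(b)

        conv_init("stem", arch.stem_channels, 4, arch.stem_kernel)
        c_prev = arch.stem_channels
        for s, c in enumerate(arch.channels):
            conv_init(f"stage{s + 1}", c, c_prev, arch.stage_kernel)
            c_prev = c
        conv_init("head0", arch.head_channels, 2 * arch.embed_dim,
                  arch.head_kernel, arch.head_kernel)
        for d_i in range(1, len(arch.head_dilations)):
            conv_init(f"head{d_i}", arch.head_channels, arch.head_channels,
                      arch.head_kernel, arch.head_kernel)
        conv_init("head_out", 1, arch.head_channels, 1, 1)

    # -- trunk -------------------------------------------------------------

    def layer_names(self) -> list[str]:
        return ["stem"] + [f"stage{s + 1}" for s in range(self.n_stages)]

    def _trunk(self, x: Tensor, capture: str | None = None):
        """x: (4, L) -> (n_window_bins, D) embeddings (L a multiple of bin size).

        With `capture`, returns the post-ReLU activation of the named layer
        instead (shape (C, positions)); pooling stops at that layer.
        """
        self.trunk_bins_processed += x.shape[1] // self.geometry.bin_size_bp
        h = x.conv1d(self.params["stem_w"], self.params["stem_b"]).relu()
        if capture == "stem":
            return h
        for s in range(self.n_stages):
            h = h.conv1d(self.params[f"stage{s + 1}_w"], self.params[f"stage{s + 1}_b"]).relu()
            if capture == f"stage{s + 1}":
                return h
            h = h.maxpool1d(2)
        if capture is not None:
            raise KeyError(
                f"unknown layer {capture!r}; valid layers: {self.layer_names()}"
            )
        return h.transpose(1, 0)  # (n_window_bins, D)

    # -- head --------------------------------------------------------------

    def _head(self, emb: Tensor) -> Tensor:
        """emb: (n_bins, D) -> (map_size, map_size) symmetric map tensor."""
        n = emb.shape[0]
        d = emb.shape[1]
        a = emb.reshape(n, 1, d)
        b = emb.reshape(1, n, d)
        avg = (a + b) * 0.5
        diff = (a - b).abs()
        feats = concat([avg, diff], axis=2).transpose(2, 0, 1)  # (2D, n, n)
        h = feats.conv2d(self.params["head0_w"], self.params["head0_b"],
                         dilation=self.arch.head_dilations[0]).relu()
        for d_i in range(1, len(self.arch.head_dilations)):
            h = h.conv2d(self.params[f"head{d_i}_w"], self.params[f"head{d_i}_b"],
                         dilation=self.arch.head_dilations[d_i]).relu()
        h = h.conv2d(self.params["head_out_w"], self.params["head_out_b"])
        c = self.geometry.crop_bins
        m = h.reshape(n, n)[c : n - c, c : n - c]
        return (m + m.transpose()) * 0.5

    # -- public ------------------------------------------------------------

    def predict_tensor(self, x: Tensor) -> Tensor:
        if x.shape != (4, self.geometry.input_length_bp):
            raise ValueError(
                f"expected (4, {self.geometry.input_length_bp}) input, got {x.shape}"
            )
        return self._head(self._trunk(x))

    def predict_map(self, oh: OneHotSequence) -> ContactMap:
        if len(oh) != self.geometry.input_length_bp:
            raise ValueError(
                f"input length {len(oh)} != model input {self.geometry.input_length_bp}"
            )
        out = self.predict_tensor(Tensor(oh.matrix.T))
        return ContactMap(out.data, self.geometry.diagonal_offset_bins)

    def trunk_embeddings(self, oh_window: OneHotSequence, bin_offset: int) -> BinEmbeddings:
        g = self.geometry
        if len(oh_window) % g.bin_size_bp:
            raise ValueError("window length must be a whole number of bins")
        emb = self._trunk(Tensor(oh_window.matrix.T))
        n_win = emb.shape[0]
        safe = np.ones(n_win, dtype=bool)
        cr = g.context_radius_bins
        if bin_offset > 0:
            safe[:cr] = False
        if bin_offset + n_win < g.n_bins:
            safe[max(0, n_win - cr):] = False
        return BinEmbeddings(emb.data, bin_offset, safe)


def build_model(
    geometry: ModelGeometry, arch_config: ArchConfig | None = None, seed: int = 0
) -> ConvTowerModel:
    """Deterministically build a predictor (same inputs -> same parameters)."""
    return ConvTowerModel(geometry, arch_config or default_arch(geometry), seed)


def predict_map(model, oh: OneHotSequence) -> ContactMap:
    return model.predict_map(oh)


def trunk_embeddings(model, oh_window: OneHotSequence, bin_offset: int) -> BinEmbeddings:
    return model.trunk_embeddings(oh_window, bin_offset)


def measure_affected_radius(model, n_probes: int = 10, seed: int = 0) -> int:
    """Empirical bin radius of trunk sensitivity to single-bin edits.

    Randomizes one interior bin at a time and records the farthest bin whose
    embedding moves by more than 1e-6.  Raises if the measured radius exceeds
    the declared `affected_radius_bins` — such a model must not be cached.
    """
    if n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    g = model.geometry
    rng = np.random.default_rng(seed)
    measured = 0
    for _ in range(n_probes):
        base = rng.integers(0, 4, size=g.input_length_bp)
        mat = np.eye(4)[base]
        emb0 = model.trunk_embeddings(OneHotSequence(mat), 0).matrix
        b = int(rng.integers(g.cache_window_radius, g.n_bins - g.cache_window_radius))
        mat2 = mat.copy()
        span = slice(b * g.bin_size_bp, (b + 1) * g.bin_size_bp)
        mat2[span] = np.eye(4)[rng.integers(0, 4, size=g.bin_size_bp)]
        emb1 = model.trunk_embeddings(OneHotSequence(mat2), 0).matrix
        delta = np.max(np.abs(emb0 - emb1), axis=1) > 1e-6
        idx = np.nonzero(delta)[0]
        if idx.size:
            measured = max(measured, int(np.max(np.abs(idx - b))))
    if measured > g.affected_radius_bins:
        raise RuntimeError(
            f"measured affected radius {measured} bins exceeds declared "
            f"{g.affected_radius_bins}; caching this model would be unsound"
        )
    return measured


def layer_max_activations(model, seqs: list[Sequence], layer_id: str) -> np.ndarray:
    """Per-sequence, per-filter maximum activation of a named trunk layer.

    Sequences are zero-padded up to the pooling granularity the layer
    requires; padding can only contribute the filters' bias response.
    Returns an (n_seqs, n_filters) matrix.
    """
    if layer_id not in model.layer_names():
        raise KeyError(f"unknown layer {layer_id!r}; valid layers: {model.layer_names()}")
    stage = 0 if layer_id == "stem" else int(layer_id.removeprefix("stage"))
    granularity = 2 ** max(0, stage - 1)  # pools applied before the layer
    rows = []
    for s in seqs:
        mat = encode_one_hot(s).matrix
        pad = (-len(s)) % granularity
        if pad:
            mat = np.vstack([mat, np.zeros((pad, 4))])
        act = model._trunk(Tensor(mat.T), capture=layer_id)
        rows.append(act.data.max(axis=1))
    return np.vstack(rows)


def filter_group_contrast(
    activations: np.ndarray, labels: list[str], group_a: str, group_b: str
) -> np.ndarray:
    """Per-filter specificity: mean activation difference between two groups."""
    labels = np.asarray(labels)
    if not (np.any(labels == group_a) and np.any(labels == group_b)):
        raise ValueError("both groups must be present in labels")
    return activations[labels == group_a].mean(axis=0) - activations[
        labels == group_b
    ].mean(axis=0)


# ---------------------------------------------------------------------------
# checkpoints: single .npz container with geometry/arch JSON + parameters
# ---------------------------------------------------------------------------

def save_model(model: ConvTowerModel, path: str | Path) -> None:
    meta = {
        "geometry": asdict(model.geometry),
        "arch": asdict(model.arch),
        "seed": model.seed,
    }
    arrays = {k: v.data for k, v in model.params.items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_model(path: str | Path) -> ConvTowerModel:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        geometry = ModelGeometry(**meta["geometry"])
        arch_d = meta["arch"]
        arch_d["channels"] = tuple(arch_d["channels"])
        arch_d["head_dilations"] = tuple(arch_d["head_dilations"])
        model = ConvTowerModel(geometry, ArchConfig(**arch_d), meta["seed"])
        for k in model.params:
            model.params[k] = Tensor(npz[k])
    return model
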