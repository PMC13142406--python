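import numpy as np
import pytest

import foldtailor as ft
from foldtailor.synth import MechanisticModel, motif_free_sequence


@pytest.fixture(scope="session")
def pwm():
    return ft.packaged_ctcf_pwm()


@pytest.fixture(scope="session")
def geom():
    return ft.GEOMETRY_PRESETS["test"]


@pytest.fixture(scope="session")
def tower(geom):
    return ft.build_model(geom, seed=3)


@pytest.fixture(scope="session")
def mech(geom, pwm):
    return MechanisticModel(geom, pwm)


@pytest.fixture(scope="session")
def flat_seq(geom, pwm):
    """Full-length background scrubbed of motif-like windows."""
    return motif_free_sequence(geom.input_length_bp, pwm, seed=100)


def bin_hits(result, geometry, pwm, map_bin):
    """Motif hits overlapping one map bin of a design result (with W-1 slop)."""
    sb = geometry.map_bin_to_seq_bin(map_bin)
    lo, hi = geometry.seq_bin_span_bp(sb)
    lo = max(0, lo - (pwm.width - 1))
    hi = min(len(result.optimized), hi + (pwm.width - 1))
    sub = ft.Sequence(id="bin", bases=result.optimized.bases[lo:hi])
    return ft.scan_pwm(sub, pwm)


def word_with_score(pwm, target_score):
    """Deterministically weaken the consensus to roughly `target_score`."""
    lo = pwm.log_odds
    word = list(pwm.consensus)

    def score(w):
        return sum(lo[i]["ACGT".index(b)] for i, b in enumerate(w))

    i = 0
    while score(word) > target_score and i < len(word):
        order = np.argsort(lo[i])[::-1]
        cand = word.copy()
        cand[i] = "ACGT"[order[1]]
        if score(cand) >= target_score - 1.5:
            word = cand
        i += 1
    return "".join(word), score(word)
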