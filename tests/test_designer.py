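import numpy as np
import pytest

import foldtailor as ft
from foldtailor.cache import build_cache
from foldtailor.designer import (
    EditableRegion,
    OptimizerConfig,
    design,
    noctcf_success,
    run_protocol,
    save_design_result,
)
from foldtailor.maps import boundary_target
from foldtailor.seqcore import encode_one_hot
from foldtailor.synth import motif_free_sequence

from conftest import bin_hits


def make_result(mech, geom, pwm, before_map, after_map, original, optimized):
    """Assemble a DesignResult by hand for success-criterion arithmetic."""
    from foldtailor.designer import DesignResult, EditTrace, LossBreakdown

    tm = boundary_target(before_map, -0.2)
    return DesignResult(
        original=original,
        optimized=optimized,
        map_before=before_map,
        map_after=after_map,
        loss=LossBreakdown(0, 0.0, 0.0, 0.01),
        trace=EditTrace(),
        config=OptimizerConfig(),
        target=tm,
        edited_bins=[],
    )


# ---------------------------------------------------------------------------
# composite loss
# ---------------------------------------------------------------------------

def test_compute_loss_examples():
    base = ft.ContactMap(np.zeros((48, 48)))
    target = boundary_target(base, -0.5)
    perfect = target.target
    cfg = OptimizerConfig(lambda_input=125.0)
    lb = ft.compute_loss(perfect, target, 0, cfg)
    assert lb.total == 0.0
    lb10 = ft.compute_loss(perfect, target, 10, cfg)
    assert lb10.total == pytest.approx(1250.0)


def test_single_score20_motif_penalty_under_noctcf_weights():
    """One scan hit of score 20 under the no-CTCF protocol's gamma=3000
    contributes a penalty of 60,000."""
    base = ft.ContactMap(np.zeros((48, 48)))
    target = boundary_target(base, -0.2)
    cfg = OptimizerConfig(lambda_input=0.01, gamma_motif=3000.0)
    lb = ft.compute_loss(target.target, target, 0, cfg, motif_scores_sum=20.0)
    assert lb.motif_penalty == pytest.approx(60_000.0)
    assert lb.total == pytest.approx(60_000.0)


def test_loss_breakdown_identity():
    from foldtailor.designer import LossBreakdown

    lb = LossBreakdown(7, 3.25, 12.0, 2.0)
    assert lb.total == 2.0 * 7 + 3.25 + 12.0


# ---------------------------------------------------------------------------
# optimizer behaviour
# ---------------------------------------------------------------------------

def test_huge_lambda_returns_original_sequence(mech, geom, pwm, flat_seq):
    res = run_protocol(
        "boundary", mech, flat_seq,
        overrides=dict(max_iter=40, seed=0, lambda_input=1e9),
    )
    assert res.n_edits == 0
    assert res.optimized.bases == res.original.bases
    assert not res.success


def test_fully_locked_region_yields_no_edits(mech, geom, flat_seq):
    center = geom.map_bin_to_seq_bin(geom.central_map_bin)
    span = geom.seq_bin_span_bp(center)
    cache = build_cache(mech, encode_one_hot(flat_seq))
    base_map = ft.predict_with_cache(mech, cache, encode_one_hot(flat_seq), [])
    target = boundary_target(base_map, -0.5)
    region = EditableRegion([span], locked_bp_spans=[span])
    res = design([(mech, cache, target)], flat_seq, region,
                 OptimizerConfig(max_iter=20, seed=1))
    assert res.n_edits == 0
    assert not res.success


def test_boundary_design_plants_motifs_on_surrogate(mech, geom, pwm):
    """Ground-truth recovery: the optimizer must create detectable motif
    hits in the edited bin to build the requested boundary."""
    for seed in range(5):
        seq = motif_free_sequence(geom.input_length_bp, pwm, seed=300 + seed)
        res = run_protocol(
            "boundary", mech, seq,
            overrides=dict(max_iter=400, seed=seed, learning_rate=0.3,
                           lambda_input=0.0),
            target_value=-0.5, pwm=pwm,
        )
        assert res.success
        hits = bin_hits(res, geom, pwm, geom.central_map_bin)
        assert len(hits) >= 1
        assert res.scores_after["boundary"] < res.scores_before["boundary"] - 0.3


def test_loss_accounting_matches_recomputation(mech, geom, pwm):
    seq = motif_free_sequence(geom.input_length_bp, pwm, seed=302)
    res = run_protocol(
        "boundary", mech, seq,
        overrides=dict(max_iter=200, seed=2, learning_rate=0.3, lambda_input=0.01),
        pwm=pwm,
    )
    lb = res.loss
    assert lb.input_loss == ft.count_edits(res.original, res.optimized)
    target = res.target
    mask = target.loss_mask & target.target.upper_mask()
    recomputed = np.abs(
        np.nan_to_num(res.map_after.matrix)[mask]
        - np.nan_to_num(target.target.matrix)[mask]
    ).sum()
    assert lb.output_loss == pytest.approx(recomputed, abs=1e-6)
    assert lb.total == pytest.approx(
        0.01 * lb.input_loss + lb.output_loss + lb.motif_penalty, abs=1e-6
    )


def test_design_is_reproducible(mech, geom, pwm):
    seq = motif_free_sequence(geom.input_length_bp, pwm, seed=303)
    kwargs = dict(max_iter=120, seed=5, learning_rate=0.3, lambda_input=0.0)
    r1 = run_protocol("boundary", mech, seq, overrides=kwargs, pwm=pwm)
    r2 = run_protocol("boundary", mech, seq, overrides=kwargs, pwm=pwm)
    assert r1.optimized.bases == r2.optimized.bases
    assert [lb.total for lb in r1.trace.losses] == [lb.total for lb in r2.trace.losses]
    assert r1.trace.best_iteration == r2.trace.best_iteration


def test_mean_edit_count_non_increasing_in_lambda(mech, geom, pwm):
    """Raising the edit-cost weight never increases the mean edit count
    (paired seeds), mirroring the reported many-to-few edits trend."""
    seq = motif_free_sequence(geom.input_length_bp, pwm, seed=304)
    means = []
    for lam in (0.0, 0.05, 1e9):
        edits = [
            run_protocol(
                "boundary", mech, seq,
                overrides=dict(max_iter=150, seed=s, learning_rate=0.3,
                               lambda_input=lam),
            ).n_edits
            for s in range(3)
        ]
        means.append(np.mean(edits))
    assert means[0] >= means[1] >= means[2]
    assert means[2] == 0.0


def test_locked_spans_are_never_edited_across_seeded_runs(mech, geom, pwm, flat_seq):
    """Constraint safety over 100 seeded designs with random locked spans."""
    center = geom.map_bin_to_seq_bin(geom.central_map_bin)
    lo, hi = geom.seq_bin_span_bp(center)
    cache = build_cache(mech, encode_one_hot(flat_seq))
    base_map = ft.predict_with_cache(mech, cache, encode_one_hot(flat_seq), [])
    target = boundary_target(base_map, -0.5)
    rng = np.random.default_rng(0)
    for run in range(100):
        a = int(rng.integers(lo, hi - 40))
        locked = [(a, a + int(rng.integers(10, 40)))]
        region = EditableRegion([(lo, hi)], locked_bp_spans=locked)
        res = design(
            [(mech, cache, target)], flat_seq, region,
            OptimizerConfig(max_iter=4, seed=run, learning_rate=0.5,
                            lambda_input=0.0),
        )
        for s0, s1 in locked:
            assert res.optimized.bases[s0:s1] == flat_seq.bases[s0:s1]


# ---------------------------------------------------------------------------
# success criteria
# ---------------------------------------------------------------------------

def test_is_success_requires_edits_and_map_change(mech, geom, flat_seq):
    from foldtailor.designer import is_success

    cm = ft.ContactMap(np.zeros((48, 48)))
    res = make_result(mech, geom, None, cm, cm, flat_seq, flat_seq)
    assert not is_success(res)  # zero edits
    edited = ft.overwrite_span(
        flat_seq, 0, ft.Sequence("m", "T" if flat_seq.bases[0] != "T" else "A")
    )
    res2 = make_result(mech, geom, None, cm, cm, flat_seq, edited)
    assert not is_success(res2)  # edits but identical maps
    bumped = ft.ContactMap(np.full((48, 48), 0.1))
    res3 = make_result(mech, geom, None, cm, bumped, flat_seq, edited)
    assert is_success(res3)


@pytest.mark.parametrize(
    "delta, expect", [(-0.005, True), (-0.0049, False), (-0.1, True)]
)
def test_noctcf_success_boundary_decrease_threshold(mech, geom, pwm, delta, expect):
    before = ft.ContactMap(np.full((48, 48), -0.1))
    after = ft.ContactMap(np.full((48, 48), -0.1 + delta))
    seq = motif_free_sequence(geom.input_length_bp, pwm, seed=42)
    res = make_result(mech, geom, pwm, before, after, seq, seq)
    center = geom.map_bin_to_seq_bin(geom.central_map_bin)
    assert noctcf_success(res, pwm, geom.seq_bin_span_bp(center)) == expect


def test_noctcf_success_vetoes_hits_in_edited_bin(mech, geom, pwm):
    before = ft.ContactMap(np.zeros((48, 48)))
    after = ft.ContactMap(np.full((48, 48), -0.1))
    seq = motif_free_sequence(geom.input_length_bp, pwm, seed=43)
    center = geom.map_bin_to_seq_bin(geom.central_map_bin)
    lo, _ = geom.seq_bin_span_bp(center)
    with_hit = ft.plant_motifs(seq, ft.Sequence("w", pwm.consensus), [(lo + 30, "+")])
    res = make_result(mech, geom, pwm, before, after, seq, with_hit)
    assert not noctcf_success(res, pwm, geom.seq_bin_span_bp(center))


def test_noctcf_protocol_builds_boundary_without_detectable_motifs(mech, geom, pwm):
    seq = motif_free_sequence(geom.input_length_bp, pwm, seed=300)
    res = run_protocol(
        "noctcf_boundary", mech, seq,
        overrides=dict(max_iter=400, seed=1, learning_rate=0.3),
        pwm=pwm,
    )
    assert res.config.gamma_motif == 3000.0
    center = geom.map_bin_to_seq_bin(geom.central_map_bin)
    span = geom.seq_bin_span_bp(center)
    assert noctcf_success(res, pwm, span)
    assert res.scores_after["boundary"] <= res.scores_before["boundary"] - 0.005


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------

def test_protocol_defaults_echoed(mech, geom, pwm, flat_seq):
    res = run_protocol("boundary", mech, flat_seq, overrides=dict(max_iter=1))
    assert res.config.lambda_input == 125.0
    assert res.config.epsilon == OptimizerConfig().epsilon
    center = geom.map_bin_to_seq_bin(geom.central_map_bin)
    assert res.edited_bins == [center]
    assert OptimizerConfig().max_iter == 2000  # published default, no early stop
    assert OptimizerConfig().early_stop is None


def test_dot_protocol_edits_anchor_bins(mech, geom, pwm, flat_seq):
    patch = ft.DotPatch(np.full((7, 7), 1.0))
    res = run_protocol(
        "dot", mech, flat_seq, overrides=dict(max_iter=1), dot_patch=patch,
        distance_bins=20,
    )
    assert res.config.lambda_input == 150.0
    a1, a2 = res.target.anchors
    assert a2 - a1 == 20
    assert res.edited_bins == [
        geom.map_bin_to_seq_bin(a1), geom.map_bin_to_seq_bin(a2)
    ]


def test_flame_and_fountain_protocol_wiring(mech, geom, flat_seq):
    res = run_protocol("flame", mech, flat_seq, overrides=dict(max_iter=1))
    assert res.config.lambda_input == 140.0
    assert res.target.feature_kind == "flame"
    res2 = run_protocol(
        "fountain", mech, flat_seq, overrides=dict(max_iter=1),
        fountain_center_bins=10,
    )
    assert res2.config.lambda_input == 0.01
    assert res2.target.feature_kind == "fountain"
    assert len(res2.edited_bins) == 10


def test_unknown_protocol_rejected(mech, flat_seq):
    with pytest.raises(ValueError, match="boundary"):
        run_protocol("loopify", mech, flat_seq)


def test_suppression_locks_motifs_and_unconstrained_arm_suppresses(geom, pwm):
    """Locked-motif suppression must leave every motif span untouched; the
    unconstrained arm should reach near-complete suppression (relative
    suppression ~1) by destroying the planted motifs."""
    from foldtailor.motifs import locked_spans
    from foldtailor.synth import MechanisticModel

    mech = MechanisticModel(geom, pwm)
    seq = motif_free_sequence(geom.input_length_bp, pwm, seed=305)
    prior = run_protocol(
        "boundary", mech, seq,
        overrides=dict(max_iter=400, seed=5, learning_rate=0.3, lambda_input=0.0),
        target_value=-0.5, pwm=pwm,
    )
    assert prior.success
    flat_score = ft.boundary_score(prior.map_before)
    locked = locked_spans(ft.scan_pwm(prior.optimized, pwm), pwm.width, 15)
    assert locked  # the designed boundary carries motifs to lock

    kept = run_protocol(
        "suppress_boundary", mech, prior.optimized,
        overrides=dict(max_iter=150, seed=6, learning_rate=0.3, lambda_input=0.0),
        pwm=pwm, flat_reference=prior.map_before,
    )
    assert kept.config.lambda_input == 0.0  # override logged in the echo
    for a, b in locked:
        assert kept.optimized.bases[a:b] == prior.optimized.bases[a:b]

    free = run_protocol(
        "suppress_boundary", mech, prior.optimized,
        overrides=dict(max_iter=300, seed=6, learning_rate=0.3, lambda_input=0.0),
        pwm=pwm, flat_reference=prior.map_before, lock_motifs=False,
    )
    rel = ft.relative_suppression(
        free.scores_before["boundary"], free.scores_after["boundary"], flat_score
    )
    assert rel > 0.8


def test_multi_model_design_sums_losses(geom, pwm):
    from foldtailor.synth import MechanisticModel

    m1 = MechanisticModel(geom, pwm, alpha=1.0)
    m2 = MechanisticModel(geom, pwm, alpha=0.5)
    seq = motif_free_sequence(geom.input_length_bp, pwm, seed=306)
    res = run_protocol(
        "fountain", [m1, m2], seq,
        overrides=dict(max_iter=3, seed=0), fountain_center_bins=4,
    )
    assert res.trace.losses  # ran with two predictors sharing a geometry


def test_design_result_serialization(tmp_path, mech, geom, pwm, flat_seq):
    res = run_protocol(
        "boundary", mech, flat_seq,
        overrides=dict(max_iter=10, seed=0, lambda_input=0.0), pwm=pwm,
    )
    save_design_result(res, tmp_path / "out")
    for name in (
        "original.fasta", "optimized.fasta", "map_before.tsv", "map_after.tsv",
        "map_target.tsv", "loss_trajectory.tsv", "edit_trace.tsv", "summary.json",
    ):
        assert (tmp_path / "out" / name).exists()
    import json

    summary = json.loads((tmp_path / "out" / "summary.json").read_text())
    assert summary["config"]["lambda_input"] == 0.0
    assert summary["n_edits"] == res.n_edits
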