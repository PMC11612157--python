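"""Closed-loop tic-tac-toe: rules, minimax, image analysis, full matches."""

import numpy as np
import pytest

from optopattern import calibration as cal
from optopattern import culture as cult
from optopattern import game as gm
from optopattern import projection as proj

FAST_CFG = gm.MatchConfig(dt_min=10.0)


class TestOutcome:
    def test_empty_board_ongoing(self):
        assert gm.check_outcome([gm.EMPTY] * 9) == "ongoing"

    @pytest.mark.parametrize("line", gm.LINES)
    def test_all_circle_lines_win(self, line):
        cells = [gm.EMPTY] * 9
        for i in line:
            cells[i] = gm.CIRCLE
        assert gm.check_outcome(cells) == "win_circle"

    def test_full_board_no_line_is_tie(self):
        cells = [gm.CIRCLE, gm.CROSS, gm.CIRCLE,
                 gm.CIRCLE, gm.CROSS, gm.CROSS,
                 gm.CROSS, gm.CIRCLE, gm.CIRCLE]
        assert gm.check_outcome(cells) == "tie"

    def test_double_winner_inconsistent(self):
        cells = [gm.CIRCLE] * 3 + [gm.CROSS] * 3 + [gm.EMPTY] * 3
        with pytest.raises(gm.InconsistentStateError):
            gm.check_outcome(cells)


class TestChooseMove:
    def test_perfect_completes_own_line(self):
        cells = [gm.CIRCLE, gm.CIRCLE, gm.EMPTY,
                 gm.CROSS, gm.CROSS, gm.EMPTY,
                 gm.EMPTY, gm.EMPTY, gm.EMPTY]
        assert gm.choose_move(cells, gm.CIRCLE, gm.PlayerPolicy("perfect")) == 2

    def test_perfect_blocks_opponent_threat(self):
        cells = [gm.CROSS, gm.CROSS, gm.EMPTY,
                 gm.CIRCLE, gm.EMPTY, gm.EMPTY,
                 gm.EMPTY, gm.EMPTY, gm.EMPTY]
        assert gm.choose_move(cells, gm.CIRCLE, gm.PlayerPolicy("perfect")) == 2

    def test_perfect_vs_perfect_all_openings_tie(self):
        """Brute-force game-tree check: every forced opening ends in a tie."""
        for opening in range(9):
            cells = [gm.EMPTY] * 9
            cells[opening] = gm.CIRCLE
            player = gm.CROSS
            while gm.check_outcome(cells) == "ongoing":
                mv = gm.choose_move(cells, player, gm.PlayerPolicy("perfect"))
                cells[mv] = player
                player = gm.CIRCLE if player == gm.CROSS else gm.CROSS
            assert gm.check_outcome(cells) == "tie"

    def test_scripted_illegal_move_rejected(self):
        cells = [gm.CIRCLE] + [gm.EMPTY] * 8
        pol = gm.PlayerPolicy("scripted", script=(0,))
        with pytest.raises(gm.InvalidScriptError):
            gm.choose_move(cells, gm.CROSS, pol)

    def test_random_policy_seeded(self):
        cells = [gm.EMPTY] * 9
        a = gm.choose_move(cells, gm.CIRCLE, gm.PlayerPolicy("random", seed=5))
        b = gm.choose_move(cells, gm.CIRCLE, gm.PlayerPolicy("random", seed=5))
        assert a == b


class TestAssignPosition:
    def test_highest_confluence_wins(self):
        mapping = {}
        confl = {i: v for i, v in enumerate((.5, .9, .4, .3, .2, .1, .6, .7, .8))}
        assert gm.assign_position(mapping, 4, confl) == 1
        assert mapping[4] == 1

    def test_tie_breaks_to_lowest_position(self):
        assert gm.assign_position({}, 0, {i: 0.5 for i in range(9)}) == 0

    def test_last_move_takes_remaining_position(self):
        mapping = {i: i for i in range(8)}
        assert gm.assign_position(mapping, 8, {8: 0.0}) == 8

    def test_exhausted_positions_raise(self):
        mapping = {i: i for i in range(9)}
        with pytest.raises(gm.InconsistentStateError):
            gm.assign_position(mapping, 9, {})


class TestConfluence:
    def test_blank_frame_zero(self):
        assert gm.estimate_confluence(np.zeros((64, 64))) == 0.0

    def test_dense_lawn_high_coverage(self):
        c = cult.init_culture(4000, fov_um=(554, 554), seed=1)
        frame = cult.render(c, "gfp", (256, 256), noise_rng=1,
                            params=cult.RenderParams(pixel_size_um=554 / 256))
        assert gm.estimate_confluence(frame) >= 0.9

    def test_monotone_in_seeding_density(self):
        vals = []
        for n in (50, 150, 400, 1000):
            c = cult.init_culture(n, fov_um=(554, 554), seed=2)
            frame = cult.render(c, "gfp", (192, 192), noise_rng=2,
                                params=cult.RenderParams(pixel_size_um=554 / 192))
            vals.append(gm.estimate_confluence(frame))
        assert all(b > a for a, b in zip(vals, vals[1:]))


def simulate_turn(symbol, seed, cfg=None, hours=5.0):
    """One projected turn on a fresh culture; returns (before, after) frames."""
    cfg = cfg or gm.MatchConfig()
    true_h = gm._true_homography(cfg)
    est = gm.calibrate_virtual(cfg, true_h)
    fov = (cfg.camera_shape[1] * cfg.pixel_size_um,
           cfg.camera_shape[0] * cfg.pixel_size_um)
    rp = cult.RenderParams(pixel_size_um=cfg.pixel_size_um,
                           blob_sigma_px=cfg.blob_sigma_px)
    c = cult.init_culture(400, fov_um=fov, seed=seed)
    before = cult.render(c, "sytox", cfg.camera_shape, c.rng, rp)
    if symbol is not None:
        pat = cal.correct_pattern(gm._symbol_target(symbol, cfg), est, cfg.dmd_shape)
        field = proj.render_irradiance(pat, true_h, cfg.max_irradiance,
                                       cfg.camera_shape,
                                       pixel_size_um=cfg.pixel_size_um)
    else:
        field = None
    for _ in range(int(hours * 60 / cfg.dt_min)):
        cult.step(c, field, cfg.dt_min)
    after = cult.render(c, "sytox", cfg.camera_shape, c.rng, rp)
    return before, after


class TestDetectMove:
    def test_identical_frames_none(self, rng):
        frame = rng.integers(180, 260, (128, 128)).astype(np.uint16)
        assert gm.detect_move(frame, frame).symbol == "none"

    def test_unilluminated_turn_detects_none(self):
        before, after = simulate_turn(None, seed=50)
        assert gm.detect_move(before, after).symbol == "none"

    @pytest.mark.parametrize("symbol,name",
                             [(gm.CIRCLE, "circle"), (gm.CROSS, "cross")])
    def test_projected_symbol_recovered(self, symbol, name):
        before, after = simulate_turn(symbol, seed=7 + symbol)
        det = gm.detect_move(before, after)
        assert det.symbol == name

    def test_mismatched_frames_rejected(self):
        with pytest.raises(ValueError):
            gm.detect_move(np.zeros((10, 10)), np.zeros((12, 12)))


class TestVirtualCalibration:
    def test_estimated_mapping_matches_true_optics(self):
        cfg = gm.MatchConfig()
        true_h = gm._true_homography(cfg)
        est = gm.calibrate_virtual(cfg, true_h)
        pts = np.array([[x, y] for x in (200, 960, 1700) for y in (100, 540, 980)],
                       dtype=float)
        err = np.linalg.norm(est.apply(pts) - true_h.apply(pts), axis=1)
        assert err.max() < 1.0
        assert est.residual_rms < 0.5


@pytest.fixture(scope="module")
def tie_log():
    return gm.run_match(gm.PlayerPolicy("perfect"), gm.PlayerPolicy("perfect"),
                        seed=7, config=FAST_CFG)


@pytest.fixture(scope="module")
def win_log():
    return gm.run_match(
        gm.PlayerPolicy("perfect"),
        gm.PlayerPolicy("scripted", script=gm.BLUNDER1_SCRIPT),
        seed=7, config=FAST_CFG,
    )


class TestRunMatch:
    def test_perfect_vs_perfect_ties_in_50_hours(self, tie_log):
        assert tie_log.outcome == "tie"
        assert tie_log.total_duration_h == 50.0
        assert len(tie_log.turns) == 9

    def test_blunder_script_loses_in_40_hours(self, win_log):
        assert win_log.outcome == "win_A"
        assert win_log.total_duration_h == 40.0
        assert len(win_log.turns) == 7

    def test_turn_cadence_exactly_five_hours(self, tie_log, win_log):
        for log in (tie_log, win_log):
            stamps = [t.timestamp_h for t in log.turns]
            assert all(b - a == 5.0 for a, b in zip(stamps, stamps[1:]))
            assert stamps[0] == 5.0

    def test_duration_law(self, tie_log, win_log):
        for log in (tie_log, win_log):
            assert log.total_duration_h == 5.0 * len(log.turns) + 5.0

    def test_all_moves_detected(self, tie_log, win_log):
        assert tie_log.detection_accuracy == 1.0
        assert win_log.detection_accuracy == 1.0

    def test_dynamic_mapping_tracks_confluence_order(self, tie_log):
        # Seeding densities decrease with position id, so early moves should
        # land on low-numbered (denser) positions: the assigned position
        # sequence must correlate positively with turn order.
        seq = [t.stage_position for t in tie_log.turns]
        assert len(set(seq)) == len(seq)
        from scipy.stats import spearmanr

        rho = spearmanr(range(len(seq)), seq).statistic
        assert rho > 0.5

    def test_gamelog_json_round_trip(self, tie_log):
        log2 = gm.GameLog.from_json(tie_log.to_json())
        assert log2.outcome == tie_log.outcome
        assert log2.total_duration_h == tie_log.total_duration_h
        assert [t.timestamp_h for t in log2.turns] == \
            [t.timestamp_h for t in tie_log.turns]
        # Duration law is re-checkable from the reloaded log.
        assert log2.total_duration_h == 5.0 * len(log2.turns) + 5.0

    def test_wrong_detection_changes_subsequent_play(self, tie_log):
        """Fault injection: players really decide from the images.

        Forcing one wrong symbol into the circle player's detection (with
        ground-truth arbitration off) must change its minimax choice relative
        to the honest match.
        """
        honest = tie_log
        calls = {"n": 0}

        def lying_detector(before, after, geometry=None, **kw):
            det = gm.detect_move(before, after, geometry, **kw)
            if det.symbol == "cross":
                calls["n"] += 1
                if calls["n"] == 1:  # first time A sees B's move: lie
                    return gm.MoveDetection("circle", det.confidence, det.area_px)
            return det

        cfg = gm.MatchConfig(dt_min=10.0, arbitrate=False)
        try:
            lied = gm.run_match(gm.PlayerPolicy("perfect"),
                                gm.PlayerPolicy("perfect"), seed=7,
                                config=cfg, detector=lying_detector)
            lied_moves = [t.grid_cell for t in lied.turns]
        except gm.InconsistentStateError:
            # The corrupted belief led the player into an impossible board —
            # equally proof that decisions flow from detection.
            return
        honest_moves = [t.grid_cell for t in honest.turns]
        assert lied_moves != honest_moves
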