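"""Closed-loop tic-tac-toe played on virtual light-inducible cell cultures.

Two computer players alternately draw circle and cross light patterns onto
nine independent culture positions (P1…P9).  A projected pattern kills the
illuminated cells, so after a 5 h turn the move is readable in the
dead-cell-stain (SYTOX) channel.  The defining closed-loop property: each
player learns the opponent's move *only* by image analysis of the SYTOX
frames, never from shared game state.  The game handler administers rules,
maps grid cells to stage positions by current confluence (densest position
first), projects calibration-corrected patterns, and arbitrates.

Timing: every executed move holds its pattern for ``turn_hours`` (default
5 h) of virtual time; after the last move one further ``final_wait_hours``
pass without illumination precedes the final acquisition, so a full 9-move
tie lasts 9·5 + 5 = 50 h and a 7-move win 40 h.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from functools import lru_cache

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import closing as _closing, disk

from . import calibration as cal
from . import culture as cult
from . import projection as proj

logger = logging.getLogger(__name__)

EMPTY, CIRCLE, CROSS = 0, 1, 2
_SYMBOL = {CIRCLE: "circle", CROSS: "cross", EMPTY: "empty"}

LINES = (
    (0, 1, 2), (3, 4, 5), (6, 7, 8),      # rows
    (0, 3, 6), (1, 4, 7), (2, 5, 8),      # columns
    (0, 4, 8), (2, 4, 6),                 # diagonals
)


class InconsistentStateError(RuntimeError):
    pass


class InvalidScriptError(ValueError):
    pass


# --------------------------------------------------------------------------
# Board, outcome, minimax
# --------------------------------------------------------------------------

def check_outcome(cells) -> str:
    """``ongoing`` | ``win_circle`` | ``win_cross`` | ``tie`` for a 9-cell board."""
    cells = tuple(cells)
    winners = set()
    for a, b, c in LINES:
        if cells[a] != EMPTY and cells[a] == cells[b] == cells[c]:
            winners.add(cells[a])
    if len(winners) > 1:
        raise InconsistentStateError("both players hold completed lines")
    if CIRCLE in winners:
        return "win_circle"
    if CROSS in winners:
        return "win_cross"
    return "tie" if all(c != EMPTY for c in cells) else "ongoing"


@lru_cache(maxsize=None)
def _minimax(cells: tuple, player: int) -> tuple[int, int, int]:
    """Return (score, depth, best_cell) from ``player``'s perspective.

    Score +1 win / 0 tie / −1 loss; among equal scores a shallower win and a
    deeper loss are preferred; final ties broken by lowest cell index.
    """
    outcome = check_outcome(cells)
    if outcome != "ongoing":
        if outcome == "tie":
            return 0, 0, -1
        won = (outcome == "win_circle") == (player == CIRCLE)
        return (1, 0, -1) if won else (-1, 0, -1)
    other = CIRCLE if player == CROSS else CROSS
    best = None
    for cell in range(9):
        if cells[cell] != EMPTY:
            continue
        nxt = list(cells)
        nxt[cell] = player
        s, d, _ = _minimax(tuple(nxt), other)
        cand = (-s, d + 1, cell)
        if best is None:
            best = cand
        else:
            # Higher score first; then shallower when winning, deeper when
            # not; then lowest index (implicit via iteration order).
            if cand[0] > best[0] or (
                cand[0] == best[0]
                and ((cand[0] > 0 and cand[1] < best[1])
                     or (cand[0] <= 0 and cand[1] > best[1]))
            ):
                best = cand
    assert best is not None
    return best[0], best[1], best[2]


@dataclass
class PlayerPolicy:
    """``perfect`` (deterministic minimax), ``random`` (seeded), or ``scripted``."""

    kind: str = "perfect"
    seed: int = 0
    script: tuple[int, ...] = ()
    _rng: np.random.Generator | None = field(default=None, repr=False)
    _script_pos: int = field(default=0, repr=False)

    def __post_init__(self) -> None:
        if self.kind not in ("perfect", "random", "scripted"):
            raise ValueError(f"unknown policy kind: {self.kind!r}")
        if self.kind == "random":
            self._rng = np.random.default_rng(self.seed)


#: A deliberately weak scripted line for the cross player.  Against the
#: deterministic perfect circle player it blocks the first immediate threat
#: but then concedes a fork, letting circle complete a line on the game's
#: 7th executed move (circle's 4th) — see the match tests.
BLUNDER1_SCRIPT = (1, 6, 2)

NAMED_SCRIPTS = {"blunder1": BLUNDER1_SCRIPT}


def choose_move(cells, symbol: int, policy: PlayerPolicy) -> int:
    """Pick the next grid cell for ``symbol`` on the private board ``cells``."""
    cells = tuple(cells)
    empties = [i for i in range(9) if cells[i] == EMPTY]
    if not empties or check_outcome(cells) != "ongoing":
        raise InconsistentStateError("no legal move available")
    if policy.kind == "perfect":
        return _minimax(cells, symbol)[2]
    if policy.kind == "random":
        assert policy._rng is not None
        return int(policy._rng.choice(empties))
    # scripted
    while policy._script_pos < len(policy.script):
        mv = policy.script[policy._script_pos]
        policy._script_pos += 1
        if mv in empties:
            return mv
        raise InvalidScriptError(f"scripted move {mv} is not legal")
    # Script exhausted: fall back to perfect play.
    return _minimax(cells, symbol)[2]


# --------------------------------------------------------------------------
# Image analysis: confluence and move detection
# --------------------------------------------------------------------------

def estimate_confluence(
    frame: np.ndarray,
    offset: float = 200.0,
    noise_sigma: float = 20.0,
    closing_radius: int = 3,
) -> float:
    """Fraction of the field covered by fluorescent (viable) cells.

    Pixels above offset + 5σ are foreground; morphological closing fills the
    gaps between adjacent cell blobs before measuring coverage.
    """
    frame = np.asarray(frame, dtype=float)
    fg = frame > offset + 5.0 * noise_sigma
    if not fg.any():
        return 0.0
    fg = _closing(fg, disk(closing_radius))
    return float(fg.mean())


def _shape_templates(shape: tuple[int, int], center: tuple[float, float],
                     geometry: "SymbolGeometry") -> dict[int, np.ndarray]:
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols].astype(float)
    cx, cy = center
    rr = np.hypot(xx - cx, yy - cy)
    ring = (rr <= geometry.outer_radius_px) & (
        rr >= geometry.outer_radius_px - geometry.stroke_px
    )
    half = geometry.stroke_px / 2.0
    arm = geometry.arm_length_px
    cross = ((np.abs(yy - cy) <= half) & (np.abs(xx - cx) <= arm)) | (
        (np.abs(xx - cx) <= half) & (np.abs(yy - cy) <= arm)
    )
    return {CIRCLE: ring, CROSS: cross}


@dataclass
class SymbolGeometry:
    """Pixel geometry of the projected circle/cross symbols in one position FOV."""

    outer_radius_px: float
    stroke_px: float
    arm_length_px: float

    @classmethod
    def for_fov(cls, camera_shape: tuple[int, int]) -> "SymbolGeometry":
        s = min(camera_shape)
        return cls(outer_radius_px=0.35 * s, stroke_px=0.15 * s, arm_length_px=0.35 * s)


@dataclass
class MoveDetection:
    symbol: str                  # circle | cross | none
    confidence: float
    area_px: int = 0


def detect_move(
    sytox_before: np.ndarray,
    sytox_after: np.ndarray,
    geometry: SymbolGeometry | None = None,
    min_component_px: int = 150,
    closing_radius: int = 3,
    smoothing_sigma_px: float = 4.0,
) -> MoveDetection:
    """Classify the newly appeared dead-cell pattern between two SYTOX frames.

    The positive difference image is smoothed into a dead-cell density map
    (individual stained nuclei are point-like; the drawn stroke is a region),
    Otsu-thresholded and morphologically closed to find the stained stroke;
    the stroke is then classified by normalized correlation of the density
    map against ideal ring and cross templates centred at the projection
    centre, with the mass fraction inside the would-be ring hole (empty for
    a circle, crossed by the arms of a cross) as a topological bias.
    Confidence is the winning normalized correlation.
    """
    before = np.asarray(sytox_before, dtype=float)
    after = np.asarray(sytox_after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("frames must share dimensions")
    diff = np.clip(after - before, 0, None)
    density = ndimage.gaussian_filter(diff, smoothing_sigma_px)
    # Noise guard: with no genuine signal Otsu would threshold pure noise.
    med = np.median(density)
    noise = np.median(np.abs(density - med)) * 1.4826 + 1e-9
    if density.max() < med + 20 * noise:
        return MoveDetection("none", 0.0)
    mask = density > threshold_otsu(density)
    mask = _closing(mask, disk(closing_radius))
    if not mask.any():
        return MoveDetection("none", 0.0)
    labels = cc_label(mask, connectivity=2)
    props = regionprops(labels)
    largest = max(props, key=lambda p: p.area)
    if largest.area < min_component_px:
        return MoveDetection("none", 0.0)
    # A sparsely stained stroke fragments into several arcs/segments; keep
    # every component of meaningful size, not just the largest.
    keep = [p.label for p in props
            if p.area >= max(min_component_px, 0.1 * largest.area)]
    comp = np.isin(labels, keep)

    geometry = geometry or SymbolGeometry.for_fov(comp.shape)
    # Symbols are always projected centred in the position FOV, so templates
    # are centred there too (a partially stained stroke would displace the
    # component centroid).
    center = ((comp.shape[1] - 1) / 2.0, (comp.shape[0] - 1) / 2.0)
    templates = _shape_templates(comp.shape, center, geometry)
    # Correlate the continuous density map (not the binarized mask) with the
    # ideal shapes: graded staining is evidence too, and binarization
    # artifacts (ring gaps, lumpy arms) cancel out.
    corr = {
        sym: float((density * t).sum()
                   / math.sqrt((density**2).sum() * max(t.sum(), 1)))
        for sym, t in templates.items()
    }
    # Topology as corroborating evidence: the ring's hole is empty of dead
    # cells, while cross arms pass straight through the centre.  The mass
    # fraction inside the hole is a robust continuous stand-in for the Euler
    # number of the ideal shapes and only biases the template score.
    yy, xx = np.mgrid[0: comp.shape[0], 0: comp.shape[1]].astype(float)
    hole = np.hypot(xx - center[0], yy - center[1]) < (
        geometry.outer_radius_px - geometry.stroke_px - 4.0
    )
    hole_frac = float(density[hole].sum() / max(density.sum(), 1e-9))
    score = dict(corr)
    score[CIRCLE] += 0.1 if hole_frac < 0.1 else -0.1
    score[CROSS] += 0.1 if hole_frac >= 0.1 else -0.1
    best = max(score, key=lambda s: score[s])
    det = MoveDetection(_SYMBOL[best], float(corr[best]), int(comp.sum()))
    if abs(corr[CIRCLE] - corr[CROSS]) < 0.05:
        logger.warning(
            "uncertain move detection (corr margin %.2f); reporting argmax",
            corr[CIRCLE] - corr[CROSS],
        )
    return det


# --------------------------------------------------------------------------
# Handler-side helpers
# --------------------------------------------------------------------------

def assign_position(mapping: dict[int, int], grid_cell: int,
                    confluences: dict[int, float]) -> int:
    """Bind ``grid_cell`` to the unassigned stage position of highest confluence.

    ``mapping`` is grid cell → position id (0-based); ties break toward the
    lowest position id.  Mutates and returns the chosen position id.
    """
    if grid_cell in mapping:
        raise InconsistentStateError(f"grid cell {grid_cell} already mapped")
    free = [p for p in range(9) if p not in mapping.values()]
    if not free:
        raise InconsistentStateError("no unassigned stage positions remain")
    best = max(free, key=lambda p: (confluences.get(p, 0.0), -p))
    mapping[grid_cell] = best
    return best


# --------------------------------------------------------------------------
# Closed-loop match
# --------------------------------------------------------------------------

@dataclass
class TurnRecord:
    turn: int
    player: str                 # "A" (circle) | "B" (cross)
    grid_cell: int
    stage_position: int
    timestamp_h: float          # virtual time at the end of the turn
    detected_symbol: str        # what this turn's player saw of the previous move
    detected_position: int
    detection_confidence: float
    detection_ok: bool


@dataclass
class GameLog:
    turns: list[TurnRecord]
    outcome: str
    total_duration_h: float
    mapping: dict[int, int]
    homography_residual_px: float
    detection_accuracy: float

    def to_json(self) -> str:
        d = {
            "turns": [asdict(t) for t in self.turns],
            "outcome": self.outcome,
            "total_duration_h": self.total_duration_h,
            "mapping": {str(k): v for k, v in self.mapping.items()},
            "homography_residual_px": self.homography_residual_px,
            "detection_accuracy": self.detection_accuracy,
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GameLog":
        d = json.loads(text)
        return cls(
            turns=[TurnRecord(**t) for t in d["turns"]],
            outcome=d["outcome"],
            total_duration_h=d["total_duration_h"],
            mapping={int(k): v for k, v in d["mapping"].items()},
            homography_residual_px=d["homography_residual_px"],
            detection_accuracy=d["detection_accuracy"],
        )


@dataclass
class MatchConfig:
    """Study conditions for one closed-loop match."""

    turn_hours: float = 5.0
    final_wait_hours: float = 5.0
    # Positions are imaged as 192-px views of the full ~2.2 mm field (the
    # physical FOV of the low-magnification objective), i.e. heavily binned:
    # pattern features stay large relative to cell migration, as they are on
    # the bench.
    camera_shape: tuple[int, int] = (192, 192)
    dmd_shape: tuple[int, int] = (1080, 1920)
    max_irradiance: float = 260.0       # μW/cm², match illumination
    pixel_size_um: float = 11.55
    blob_sigma_px: float = 2.0
    # Graded seeding densities (cells per position) for the dynamic
    # confluence mapping: early moves land on the densest positions.
    seeding: tuple[int, ...] = (480, 440, 400, 370, 340, 315, 290, 270, 250)
    dt_min: float = 5.0
    strict_detection: bool = False
    # When True (default) a detection mismatch is corrected from the
    # handler's ground truth so long matches stay robust; when False the
    # player's private board keeps whatever it detected — used to show that
    # decisions really flow from the images.
    arbitrate: bool = True


def _true_homography(cfg: MatchConfig) -> cal.Homography:
    """Ground-truth optics of the virtual microscope: the DMD footprint maps
    onto the position FOV with a small rotation, offset and mild projective
    distortion."""
    rows_c, cols_c = cfg.camera_shape
    rows_d, cols_d = cfg.dmd_shape
    # The DMD footprint must cover the whole camera FOV (with slack for the
    # rotation), so scale against the tighter axis.
    s = max(rows_c / rows_d, cols_c / cols_d) * 1.15
    th = math.radians(2.0)
    a = s * math.cos(th)
    b = -s * math.sin(th)
    m = np.array(
        [
            [a, b, 4.0],
            [-b, a, -6.0],
            [1e-6, -8e-7, 1.0],
        ]
    )
    # Centre the mapped DMD footprint on the camera frame.
    corners = np.array([[0, 0], [cols_d - 1, 0], [0, rows_d - 1], [cols_d - 1, rows_d - 1]])
    mapped = cal.Homography(m).apply(corners)
    shift = np.array([cols_c / 2, rows_c / 2]) - mapped.mean(axis=0)
    m[0, 2] += shift[0]
    m[1, 2] += shift[1]
    return cal.Homography(m)


def calibrate_virtual(cfg: MatchConfig, true_h: cal.Homography,
                      rows: int = 3, cols: int = 3,
                      spot_radius: float = 28.0) -> cal.Homography:
    """Run the full calibration loop against the virtual optics.

    Projects a fiducial disk grid through the (unknown to the caller) true
    homography, detects spot centroids in the rendered frame, and estimates
    the mapping by normalized DLT.
    """
    # Keep the grid within the camera's view of the DMD: the grid spans the
    # central region of the array (the FOV sees roughly the central square).
    rows_d, cols_d = cfg.dmd_shape
    pattern, centers = cal.generate_fiducial_pattern(
        rows, cols, spot_radius=spot_radius,
        margin=(0.18 * rows_d, 0.30 * cols_d),
        dmd_shape=cfg.dmd_shape,
    )
    field = proj.render_irradiance(
        pattern, true_h, cfg.max_irradiance, cfg.camera_shape,
        pixel_size_um=cfg.pixel_size_um,
    )
    frame = (field.irradiance / cfg.max_irradiance * 60000).astype(np.uint16)
    cam_pts = cal.detect_fiducial_centroids(frame, rows * cols,
                                            grid_shape=(rows, cols))
    return cal.estimate_homography(cal.FiducialSet(centers, cam_pts))


def _symbol_target(symbol: int, cfg: MatchConfig) -> np.ndarray:
    geo = SymbolGeometry.for_fov(cfg.camera_shape)
    rows, cols = cfg.camera_shape
    center = ((cols - 1) / 2.0, (rows - 1) / 2.0)
    return _shape_templates(cfg.camera_shape, center, geo)[symbol].astype(float)


def run_match(
    policy_a: PlayerPolicy,
    policy_b: PlayerPolicy,
    seed: int = 7,
    config: MatchConfig | None = None,
    detector=detect_move,
) -> GameLog:
    """Play one full closed-loop match on nine virtual culture positions.

    Per turn: acquire SYTOX frames at all 9 positions → the current player
    detects the opponent's previous move purely from the frame difference →
    updates its private board → chooses a move → the handler assigns the
    densest free stage position, pre-corrects the symbol pattern through the
    calibrated homography, and projects it for ``turn_hours`` while every
    culture advances.  After termination one final unilluminated wait and
    acquisition close the log.  ``detector`` is injectable for
    fault-injection tests of the information loop.
    """
    cfg = config or MatchConfig()
    rng = np.random.default_rng(seed)
    true_h = _true_homography(cfg)
    est_h = calibrate_virtual(cfg, true_h)

    fov_um = (cfg.camera_shape[1] * cfg.pixel_size_um,
              cfg.camera_shape[0] * cfg.pixel_size_um)
    cultures = [
        cult.init_culture(n, fov_um=fov_um, seed=int(rng.integers(2**31)))
        for n in cfg.seeding
    ]
    render_params = cult.RenderParams(
        pixel_size_um=cfg.pixel_size_um, blob_sigma_px=cfg.blob_sigma_px
    )

    def snap(channel: str) -> list[np.ndarray]:
        return [
            cult.render(c, channel, cfg.camera_shape, c.rng, render_params)
            for c in cultures
        ]

    def advance(hours: float, lit_position: int | None, field) -> None:
        n_steps = int(round(hours * 60.0 / cfg.dt_min))
        for _ in range(n_steps):
            for p, c in enumerate(cultures):
                cult.step(c, field if p == lit_position else None, cfg.dt_min)

    geometry = SymbolGeometry.for_fov(cfg.camera_shape)
    handler_board = [EMPTY] * 9
    boards = {CIRCLE: [EMPTY] * 9, CROSS: [EMPTY] * 9}   # private, detection-fed
    policies = {CIRCLE: policy_a, CROSS: policy_b}
    mapping: dict[int, int] = {}
    pos_to_cell: dict[int, int] = {}
    # Positions each player has already attributed to a move (its own, or a
    # previously detected opponent move).  Late SYTOX conversions keep adding
    # signal at old positions for one more turn, so players only scan
    # positions still unaccounted for on their private board.
    attributed: dict[int, set[int]] = {CIRCLE: set(), CROSS: set()}
    turns: list[TurnRecord] = []
    prev_frames = snap("sytox")
    last_move: tuple[int, int] | None = None   # (symbol, position), ground truth
    n_ok = 0
    n_det = 0
    clock = 0.0
    player = CIRCLE

    while check_outcome(handler_board) == "ongoing":
        frames = snap("sytox")
        det_symbol, det_pos, det_conf, det_ok = "none", -1, 0.0, True
        if last_move is not None:
            results = {
                p: detector(prev_frames[p], frames[p], geometry)
                for p in range(9)
                if p not in attributed[player]
            }
            found = {p: r for p, r in results.items() if r.symbol != "none"}
            if found:
                det_pos = max(found, key=lambda p: found[p].confidence)
                det_symbol = found[det_pos].symbol
                det_conf = found[det_pos].confidence
            n_det += 1
            truth_sym, truth_pos = last_move
            det_ok = (det_symbol == _SYMBOL[truth_sym]) and (det_pos == truth_pos)
            if det_ok:
                n_ok += 1
            else:
                msg = (
                    f"move detection mismatch: saw {det_symbol}@{det_pos}, "
                    f"truth {_SYMBOL[truth_sym]}@{truth_pos}"
                )
                if cfg.strict_detection:
                    raise InconsistentStateError(msg)
                if cfg.arbitrate:
                    logger.warning("%s; continuing on ground-truth arbitration", msg)
                    det_symbol, det_pos = _SYMBOL[truth_sym], truth_pos
                else:
                    logger.warning("%s; player keeps its detected belief", msg)
            # Update this player's private board from what it (now) believes.
            if det_pos in pos_to_cell and det_symbol in ("circle", "cross"):
                sym_code = CIRCLE if det_symbol == "circle" else CROSS
                boards[player][pos_to_cell[det_pos]] = sym_code
                attributed[player].add(det_pos)

        cell = choose_move(boards[player], player, policies[player])
        if handler_board[cell] != EMPTY:
            raise InconsistentStateError(
                f"player chose occupied cell {cell} (corrupted private board)"
            )
        confl = {
            p: estimate_confluence(f)
            for p, f in enumerate(snap("gfp"))
            if p not in mapping.values()
        }
        position = assign_position(mapping, cell, confl)
        pos_to_cell[position] = cell
        handler_board[cell] = player
        boards[player][cell] = player
        attributed[player].add(position)

        target = _symbol_target(player, cfg)
        pattern = cal.correct_pattern(target, est_h, cfg.dmd_shape)
        field = proj.render_irradiance(
            pattern, true_h, cfg.max_irradiance, cfg.camera_shape,
            pixel_size_um=cfg.pixel_size_um,
        )
        advance(cfg.turn_hours, position, field)
        clock += cfg.turn_hours
        turns.append(
            TurnRecord(
                turn=len(turns) + 1,
                player="A" if player == CIRCLE else "B",
                grid_cell=cell,
                stage_position=position,
                timestamp_h=clock,
                detected_symbol=det_symbol,
                detected_position=det_pos,
                detection_confidence=det_conf,
                detection_ok=det_ok,
            )
        )
        prev_frames = frames
        last_move = (player, position)
        player = CROSS if player == CIRCLE else CIRCLE

    advance(cfg.final_wait_hours, None, None)
    clock += cfg.final_wait_hours
    snap("sytox")  # final acquisition
    outcome = check_outcome(handler_board)
    return GameLog(
        turns=turns,
        outcome="win_A" if outcome == "win_circle"
        else "win_B" if outcome == "win_cross" else "tie",
        total_duration_h=clock,
        mapping=mapping,
        homography_residual_px=est_h.residual_rms,
        detection_accuracy=n_ok / n_det if n_det else 1.0,
    )
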