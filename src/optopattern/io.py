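"""Readers and writers for the framework's on-disk artifacts.

Patterns travel as 8-bit PNG (pixel/255 = duty), camera frames and label
masks as 16-bit (multi-page) TIFF with JSON-lines metadata sidecars,
homographies and game logs and classifiers as JSON, tracks and ground truth
as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .calibration import Homography
from .game import GameLog
from .projection import DMDPattern
from .segmentation import RegionClassifier
from .tracking import Track, tracks_to_frame


class FormatError(ValueError):
    pass


# --- DMD patterns: 8-bit PNG ------------------------------------------------

def save_pattern_png(pattern: DMDPattern, path: str | Path) -> None:
    iio.imwrite(Path(path), np.round(pattern.duties * 255).astype(np.uint8))


def load_pattern_png(path: str | Path) -> DMDPattern:
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    if arr.dtype != np.uint8:
        raise FormatError(f"{path}: expected 8-bit pattern PNG, got {arr.dtype}")
    return DMDPattern(arr.astype(float) / 255.0)


# --- Frame stacks: multi-page 16-bit TIFF + JSON-lines metadata -------------

def save_frame_stack(frames, metadata, path: str | Path) -> None:
    """``frames``: list of 2D uint16 arrays; ``metadata``: list of dicts."""
    path = Path(path)
    if len(frames) != len(metadata):
        raise ValueError("one metadata record per frame required")
    tifffile.imwrite(path, np.stack(frames).astype(np.uint16))
    side = path.with_suffix(path.suffix + ".jsonl")
    with open(side, "w") as fh:
        for m in metadata:
            fh.write(json.dumps(m) + "\n")


def load_frame_stack(path: str | Path):
    path = Path(path)
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    side = path.with_suffix(path.suffix + ".jsonl")
    metadata = []
    if side.exists():
        for i, line in enumerate(side.read_text().splitlines()):
            try:
                metadata.append(json.loads(line))
            except json.JSONDecodeError as exc:
                raise FormatError(f"{side}: bad JSON at line {i + 1}") from exc
    return [f for f in stack], metadata


# --- Label masks: 16-bit TIFF ------------------------------------------------

def save_mask_tiff(mask: np.ndarray, path: str | Path) -> None:
    if mask.max() > 65535:
        raise ValueError("more than 65535 labels cannot be stored as 16-bit")
    tifffile.imwrite(Path(path), mask.astype(np.uint16))


def load_mask_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.int32)


# --- JSON objects -------------------------------------------------------------

def save_homography(h: Homography, path: str | Path) -> None:
    Path(path).write_text(h.to_json())


def load_homography(path: str | Path) -> Homography:
    try:
        return Homography.from_json(Path(path).read_text())
    except (json.JSONDecodeError, KeyError) as exc:
        raise FormatError(f"{path}: not a homography file") from exc


def save_classifier(clf: RegionClassifier, path: str | Path) -> None:
    Path(path).write_text(clf.to_json())


def load_classifier(path: str | Path) -> RegionClassifier:
    try:
        return RegionClassifier.from_json(Path(path).read_text())
    except (json.JSONDecodeError, KeyError) as exc:
        raise FormatError(f"{path}: not a classifier file") from exc


def save_gamelog(log: GameLog, path: str | Path) -> None:
    Path(path).write_text(log.to_json())


def load_gamelog(path: str | Path) -> GameLog:
    try:
        return GameLog.from_json(Path(path).read_text())
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise FormatError(f"{path}: not a game log file") from exc


# --- Tracks: CSV --------------------------------------------------------------

def save_tracks_csv(tracks: list[Track], path: str | Path) -> None:
    tracks_to_frame(tracks).to_csv(Path(path), index=False)


def load_tracks_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))
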