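"""Shared fixtures and ground-truth matching helpers."""

from __future__ import annotations

import logging

import numpy as np
import pytest

from mompscreen import DetectionParams, SimulationConfig

logging.getLogger("mompscreen").setLevel(logging.ERROR)


@pytest.fixture
def default_config() -> SimulationConfig:
    return SimulationConfig()

@pytest.fixture
def small_config() -> SimulationConfig:
    """Quarter-size fields for fast unit tests; same optics otherwise."""
    return SimulationConfig(image_shape=(256, 256), cells_per_field=10.0)


@pytest.fixture
def params() -> DetectionParams:
    return DetectionParams()


def greedy_match(truth_pts: np.ndarray, detected_pts: np.ndarray, tol: float) -> int:
    """Number of truth points matched one-to-one to a detection within ``tol``."""
    truth_pts = np.asarray(truth_pts, dtype=float).reshape(-1, 2)
    detected_pts = np.asarray(detected_pts, dtype=float).reshape(-1, 2)
    used: set[int] = set()
    matched = 0
    for pt in truth_pts:
        if len(detected_pts) == 0:
            break
        d = np.hypot(detected_pts[:, 0] - pt[0], detected_pts[:, 1] - pt[1])
        order = np.argsort(d)
        for j in order:
            if d[j] > tol:
                break
            if j not in used:
                used.add(int(j))
                matched += 1
                break
    return matched


def granule_f1(truth_cells, granules, channel: str, tol: float = 3.0) -> tuple[float, int, int]:
    """(F1, n_true, n_detected) for one channel against generator ground truth."""
    truth_pts = np.array(
        [p.centroid for c in truth_cells for p in c.puncta.get(channel, [])]
    ).reshape(-1, 2)
    det_pts = np.array(
        [g.centroid for g in granules if g.channel == channel]
    ).reshape(-1, 2)
    tp = greedy_match(truth_pts, det_pts, tol)
    fn = len(truth_pts) - tp
    fp = len(det_pts) - tp
    if tp == 0:
        return 0.0, len(truth_pts), len(det_pts)
    prec = tp / (tp + fp)
    rec = tp / (tp + fn)
    return 2 * prec * rec / (prec + rec), len(truth_pts), len(det_pts)
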