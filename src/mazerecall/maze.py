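"""Y-maze skeleton geometry and return-path linearisation.

The maze has three symmetrical arms, 85 cm long and separated by 120
degrees, joined at a central platform (the choice point). The departure
(start) arm points south; the two goal arms point north-east ("right",
as seen by an animal heading up the start arm) and north-west ("left").

The linearised coordinate used throughout is the distance along the ITI
return path: chosen goal-arm end -> choice point -> start-arm end
(2 x 85 = 170 cm). Five equal-length sections partition this path;
section 1 is the goal-arm end and section 3 is centred on the choice
point.
"""

from __future__ import annotations

import numpy as np

ARM_LENGTH_CM = 85.0
ARM_WIDTH_CM = 8.0
N_SECTIONS = 5

_DEG = np.pi / 180.0
# unit vectors from the centre along each arm
_START_DIR = np.array([0.0, -1.0])
_RIGHT_DIR = np.array([np.cos(30 * _DEG), np.sin(30 * _DEG)])
_LEFT_DIR = np.array([np.cos(150 * _DEG), np.sin(150 * _DEG)])

CENTER = np.zeros(2)
START_END = ARM_LENGTH_CM * _START_DIR
ARM_ENDS = {
    "left": ARM_LENGTH_CM * _LEFT_DIR,
    "right": ARM_LENGTH_CM * _RIGHT_DIR,
}

RETURN_PATH_LENGTH_CM = 2 * ARM_LENGTH_CM


def return_path(arm: str) -> np.ndarray:
    """Polyline (3 x 2) of the return path for the given chosen arm."""
    if arm not in ARM_ENDS:
        raise ValueError(f"unknown arm {arm!r}")
    return np.vstack([ARM_ENDS[arm], CENTER, START_END])


def point_on_return_path(arm: str, distance: float | np.ndarray) -> np.ndarray:
    """(x, y) at the given arc distance(s) from the goal-arm end."""
    d = np.atleast_1d(np.asarray(distance, dtype=float))
    d = np.clip(d, 0.0, RETURN_PATH_LENGTH_CM)
    goal = ARM_ENDS[arm]
    pts = np.empty((d.size, 2))
    first = d <= ARM_LENGTH_CM
    f = (d[first] / ARM_LENGTH_CM)[:, None]
    pts[first] = goal * (1 - f) + CENTER * f
    f = ((d[~first] - ARM_LENGTH_CM) / ARM_LENGTH_CM)[:, None]
    pts[~first] = CENTER * (1 - f) + START_END * f
    return pts if np.ndim(distance) else pts[0]


def project_to_return_path(arm: str, x, y):
    """Project points onto the return path.

    Returns (arc distance from goal end, perpendicular distance to the
    nearest point of the path), both in cm, vectorised over samples.
    """
    pts = np.column_stack([np.asarray(x, float).ravel(),
                           np.asarray(y, float).ravel()])
    poly = return_path(arm)
    best_d2 = np.full(len(pts), np.inf)
    best_arc = np.zeros(len(pts))
    arc0 = 0.0
    for a, b in zip(poly[:-1], poly[1:]):
        ab = b - a
        seg_len = float(np.hypot(*ab))
        t = np.clip((pts - a) @ ab / (seg_len**2), 0.0, 1.0)
        proj = a + t[:, None] * ab
        d2 = np.sum((pts - proj) ** 2, axis=1)
        closer = d2 < best_d2
        best_d2[closer] = d2[closer]
        best_arc[closer] = arc0 + t[closer] * seg_len
        arc0 += seg_len
    return best_arc, np.sqrt(best_d2)


def section_of_arc(distance) -> np.ndarray:
    """Section id (1..5) for arc distances along the return path."""
    d = np.asarray(distance, dtype=float)
    sec = np.minimum(
        (d / (RETURN_PATH_LENGTH_CM / N_SECTIONS)).astype(int), N_SECTIONS - 1
    )
    return sec + 1
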