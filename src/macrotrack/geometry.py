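"""Planar geometry helpers shared by the generator and the analysis.

Image coordinates put ``x`` along columns and ``y`` along rows, with ``y``
increasing downwards.  All angles in this package are measured in the
conventional y-up Cartesian sense (counter-clockwise positive), so these
helpers negate the row axis when converting between the two frames.
"""

from __future__ import annotations

import math

import numpy as np

TWO_PI = 2.0 * math.pi


def wrap_angle(phi: float) -> float:
    """Wrap an angle to the interval (-pi, pi]."""
    phi = (phi + math.pi) % TWO_PI - math.pi
    if phi == -math.pi:
        phi = math.pi
    return phi


def unit_from_angle(phi: float) -> np.ndarray:
    """Unit vector in image coordinates for a y-up angle ``phi`` (radians)."""
    return np.array([math.cos(phi), -math.sin(phi)])


def angle_of(v) -> float:
    """y-up angle of an image-coordinate vector, in (-pi, pi]."""
    v = np.asarray(v, dtype=float)
    return wrap_angle(math.atan2(-v[1], v[0]))


def rotate(v, phi: float) -> np.ndarray:
    """Rotate image-coordinate vector(s) by ``phi`` counter-clockwise (y-up).

    Accepts a single 2-vector or an ``(n, 2)`` array of vectors.
    """
    c, s = math.cos(phi), math.sin(phi)
    v = np.asarray(v, dtype=float)
    x, y = v[..., 0], v[..., 1]
    return np.stack([c * x + s * y, -s * x + c * y], axis=-1)


def to_cartesian(points) -> np.ndarray:
    """Convert image-coordinate points to y-up Cartesian (negate rows)."""
    points = np.asarray(points, dtype=float)
    out = points.copy()
    out[..., 1] = -out[..., 1]
    return out


def signed_angle(u, w) -> float:
    """Signed angle from ``u`` to ``w`` in (-pi, pi].

    Both vectors are given in image coordinates; positive angles are
    counter-clockwise when the image is viewed with y pointing up.  An exact
    reversal maps to +pi.
    """
    u = np.asarray(u, dtype=float)
    w = np.asarray(w, dtype=float)
    # cross product in the y-up frame: rows are negated, flipping the sign
    cross = u[1] * w[0] - u[0] * w[1]
    dot = u[0] * w[0] + u[1] * w[1]
    theta = math.atan2(cross, dot)
    if theta == -math.pi:
        theta = math.pi
    return theta
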