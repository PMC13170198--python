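"""Circular helpers shared across modules.  All angles in degrees."""

from __future__ import annotations

import numpy as np

#: The eight mean motion directions used throughout: 22.5deg to 337.5deg in 45deg steps.
DIRECTION_SET = tuple(22.5 + 45.0 * k for k in range(8))

#: Directions whose horizontal component points rightward (the "right" category).
RIGHT_DIRECTIONS = frozenset((22.5, 67.5, 292.5, 337.5))

#: "Easy" directions far from the vertical boundary, "hard" directions near it.
EASY_DIRECTIONS = frozenset((22.5, 157.5, 202.5, 337.5))
HARD_DIRECTIONS = frozenset((67.5, 112.5, 247.5, 292.5))


def wrap360(theta):
    """Wrap angles to [0, 360)."""
    return np.asarray(theta, dtype=float) % 360.0


def wrap180(theta):
    """Wrap angular differences to [-180, 180)."""
    return (np.asarray(theta, dtype=float) + 180.0) % 360.0 - 180.0


def circmean_deg(theta):
    """Circular mean of angles in degrees, wrapped to [0, 360)."""
    rad = np.deg2rad(np.asarray(theta, dtype=float))
    return float(np.rad2deg(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean())) % 360.0)


def category_of(direction):
    """Category label for a mean direction: 'right' iff within 90deg of 0deg.

    The vertical axis (90deg / 270deg) is the learned category boundary; none of
    the eight stimulus directions lies on it.
    """
    d = wrap360(direction)
    scalar = np.isscalar(direction)
    right = (d < 90.0) | (d > 270.0)
    out = np.where(right, "right", "left")
    return str(out) if scalar else out


def signed_distance_from_boundary(direction):
    """Fold the circle onto [-90, +90] about the vertical category boundary.

    Positive values point into the right category (toward 0deg), negative into
    the left (toward 180deg); 0 is the boundary itself.
    """
    d = wrap360(direction)
    s = np.where(d < 180.0, 90.0 - d, d - 270.0)
    return float(s) if np.isscalar(direction) else s


def nearest_category_center(direction):
    """0deg for right-category directions, 180deg for left-category ones."""
    d = wrap360(direction)
    center = np.where((d < 90.0) | (d > 270.0), 0.0, 180.0)
    return float(center) if np.isscalar(direction) else center
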