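"""Wrapped-angle arithmetic shared across modules.

All dihedral angles in this package live on the circle and are reported in
degrees in the half-open interval (-180, 180].  Differences are always taken
along the shortest arc (modulo 360 deg).
"""

from __future__ import annotations

import numpy as np


def wrap_angle(a):
    """Wrap angle(s) in degrees into (-180, 180].

    Accepts scalars or arrays; -180 maps to +180 so the interval is
    half-open on the left.
    """
    w = -((-np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0)
    return float(w) if np.isscalar(a) else w


def signed_delta(a, b):
    """Signed shortest angular difference b - a in degrees, in (-180, 180]."""
    return wrap_angle(np.asarray(b, dtype=float) - np.asarray(a, dtype=float))


def abs_delta(a, b):
    """Absolute shortest angular difference in [0, 180]."""
    return np.abs(signed_delta(a, b))


def circular_mean(angles_deg, axis=0):
    """Mean direction of angles in degrees, computed on the unit circle."""
    rad = np.deg2rad(np.asarray(angles_deg, dtype=float))
    mean = np.arctan2(np.sin(rad).mean(axis=axis), np.cos(rad).mean(axis=axis))
    return wrap_angle(np.rad2deg(mean))
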