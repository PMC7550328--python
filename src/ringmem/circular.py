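"""Angular arithmetic on the ring.

All public functions work in degrees with the convention that 0° points
right, 90° points to the top of the screen, and angles increase
counterclockwise.  Every downstream measure (error, schema-consistency,
generalization) is a function of these primitives, so they accept scalars
or array-likes and broadcast like numpy ufuncs.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap",
    "angular_distance",
    "signed_angular_difference",
    "circular_mean",
    "DegenerateDirectionError",
]

#: resultant lengths below this are treated as directionless
_RESULTANT_TOL = 1e-12


class DegenerateDirectionError(ValueError):
    """Raised when a circular mean is requested for a directionless sample."""


def _validate_finite(*arrays):
    for a in arrays:
        if not np.all(np.isfinite(a)):
            raise ValueError("angles must be finite")


def wrap(a):
    """Wrap angle(s) into [0, 360).

    Idempotent; accepts any finite real input, scalar or array.
    """
    a = np.asarray(a, dtype=float)
    _validate_finite(a)
    out = np.mod(a, 360.0)
    # np.mod can return 360.0 for inputs like -1e-14
    out = np.where(out >= 360.0, out - 360.0, out)
    return out if out.ndim else float(out)


def signed_angular_difference(a, b):
    """Smallest signed rotation taking ``b`` to ``a``, in (-180, 180].

    Positive values mean ``a`` lies counterclockwise of ``b``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    _validate_finite(a, b)
    d = np.mod(a - b, 360.0)
    out = np.where(d > 180.0, d - 360.0, d)
    return out if out.ndim else float(out)


def angular_distance(a, b):
    """Absolute angular separation in [0, 180]."""
    d = signed_angular_difference(a, b)
    out = np.abs(d)
    return out if np.ndim(out) else float(out)


def circular_mean(angles):
    """Mean direction of a sample of angles, in [0, 360).

    Raises
    ------
    ValueError
        If the sample is empty.
    DegenerateDirectionError
        If the resultant vector length is (numerically) zero, i.e. the
        sample carries no directional information (e.g. two antipodal
        points); callers that can tolerate this should catch it rather
        than receive an arbitrary angle.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("circular_mean of empty sample")
    _validate_finite(angles)
    rad = np.deg2rad(angles)
    s, c = np.sin(rad).mean(), np.cos(rad).mean()
    if np.hypot(s, c) < _RESULTANT_TOL:
        raise DegenerateDirectionError("zero resultant: mean direction undefined")
    return wrap(np.rad2deg(np.arctan2(s, c)))
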