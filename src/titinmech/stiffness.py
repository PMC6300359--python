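"""Shared window-slope (stiffness) estimator.

"Average stiffness over a sarcomere-length window" is computed the same
way for per-molecule titin force curves and whole-muscle tension curves:
linearly interpolate the curve onto a fine grid restricted to the window
and take the least-squares slope.  For a linear curve this equals the
endpoint finite difference.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidInputError

#: Default sarcomere-length window (um) capturing most of the
#: physiological range of the studied muscles.
DEFAULT_WINDOW = (2.45, 2.75)


def window_slope(
    x: np.ndarray,
    y: np.ndarray,
    window: tuple[float, float] = DEFAULT_WINDOW,
    step: float = 0.01,
) -> float:
    """Least-squares slope of y vs x over ``window`` on a ``step`` grid.

    The curve must span the window; no extrapolation is performed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape or len(x) < 2:
        raise InvalidInputError("x and y must be 1-D arrays of equal length >= 2")
    if np.any(np.diff(x) <= 0):
        order = np.argsort(x)
        x, y = x[order], y[order]
        if np.any(np.diff(x) <= 0):
            raise InvalidInputError("x values must be distinct")
    lo, hi = window
    if not lo < hi:
        raise InvalidInputError(f"degenerate window {window}")
    if lo < x[0] - 1e-12 or hi > x[-1] + 1e-12:
        raise InvalidInputError(
            f"window {window} outside curve support [{x[0]:g}, {x[-1]:g}]"
        )
    grid = np.arange(lo, hi + 1e-9, step)
    if grid[-1] < hi - 1e-9:
        grid = np.append(grid, hi)
    vals = np.interp(grid, x, y)
    slope, _ = np.polyfit(grid, vals, 1)
    return float(slope)
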