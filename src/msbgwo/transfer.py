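"""Sigmoid transfer binarization.

The grey-wolf position updates produce unbounded continuous coordinates,
one per feature.  Feature selection needs 0/1 inclusion bits, so each
coordinate is squashed through the S-shaped transfer

    S(x) = 1 / (1 + exp(-10 * (x - 0.5)))

and thresholded: against a fresh uniform(0,1) draw per dimension in the
master-slave learning step, or against the fixed value 0.5 in the
whole-population update.  The slope 10 and midpoint 0.5 are fixed
constants of the method, not tunables.
"""

from __future__ import annotations

import numpy as np

#: threshold mode: compare S(x) against the constant 0.5 (deterministic).
FIXED_HALF = "fixed-half"
#: threshold mode: compare S(x) against an independent uniform(0,1) draw
#: per dimension (stochastic; requires an rng).
PER_DIM_RANDOM = "per-dim-random"

_SLOPE = 10.0
_MIDPOINT = 0.5


def sigmoid_transfer(x):
    """Map continuous coordinates to inclusion probabilities in (0, 1).

    Parameters
    ----------
    x : float or array-like
        Finite continuous coordinate(s).

    Returns
    -------
    float or ndarray
        ``1 / (1 + exp(-10 * (x - 0.5)))``, strictly increasing in ``x``
        and symmetric about (0.5, 0.5).

    Raises
    ------
    ValueError
        If any entry of ``x`` is NaN or infinite.
    """
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("sigmoid_transfer requires finite input")
    out = 1.0 / (1.0 + np.exp(-_SLOPE * (arr - _MIDPOINT)))
    if arr.ndim == 0:
        return float(out)
    return out


def binarize(position, threshold_mode=FIXED_HALF, rng=None):
    """Force a continuous position to a binary feature mask.

    Bit ``d`` is 1 iff ``S(position[d]) > threshold_d`` (strict, so an
    exact tie maps to 0).  Thresholds are independent uniform(0,1) draws
    in ``PER_DIM_RANDOM`` mode and the constant 0.5 in ``FIXED_HALF``
    mode, which makes the latter deterministic.

    Parameters
    ----------
    position : array-like of float
        Continuous wolf position, length D, all entries finite.
    threshold_mode : str
        ``FIXED_HALF`` or ``PER_DIM_RANDOM``.
    rng : numpy.random.Generator, optional
        Required in ``PER_DIM_RANDOM`` mode; one uniform draw is consumed
        per dimension.

    Returns
    -------
    ndarray of int8
        The 0/1 mask, same length as ``position``.
    """
    probs = np.atleast_1d(sigmoid_transfer(position))
    if threshold_mode == FIXED_HALF:
        threshold = 0.5
    elif threshold_mode == PER_DIM_RANDOM:
        if rng is None:
            raise ValueError("per-dim-random binarization requires an rng")
        threshold = rng.random(probs.shape[0])
    else:
        raise ValueError(
            f"unknown threshold_mode {threshold_mode!r}; "
            f"expected {FIXED_HALF!r} or {PER_DIM_RANDOM!r}"
        )
    return (probs > threshold).astype(np.int8)
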