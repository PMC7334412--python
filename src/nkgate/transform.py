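"""Intensity-scale transforms.

Raw fluorescence intensities are mapped to an approximately Gaussian scale
with the inverse hyperbolic sine, ``t = arcsinh(x / cofactor)``.  The map is
odd, strictly increasing and exactly invertible (``x = sinh(t) * cofactor``),
which is what gating thresholds need: order of events is preserved and a
cutoff on either scale translates to the other.
"""

from __future__ import annotations

import numpy as np

from .errors import NKGateError


def arcsinh_transform(values, cofactor: float):
    """Elementwise ``arcsinh(values / cofactor)``.

    Raises :class:`NKGateError` listing the offending indices if any value is
    non-finite.
    """
    if cofactor <= 0:
        raise ValueError("cofactor must be > 0")
    arr = np.asarray(values, dtype=float)
    bad = ~np.isfinite(arr)
    if bad.any():
        idx = np.flatnonzero(bad)[:20]
        raise NKGateError(f"non-finite values at indices {idx.tolist()}")
    return np.arcsinh(arr / cofactor)


def inverse_transform(values, cofactor: float):
    """Inverse of :func:`arcsinh_transform`: ``sinh(values) * cofactor``."""
    if cofactor <= 0:
        raise ValueError("cofactor must be > 0")
    return np.sinh(np.asarray(values, dtype=float)) * cofactor
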