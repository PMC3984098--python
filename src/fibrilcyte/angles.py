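"""Axial-angle arithmetic shared across the package.

Orientations of elongated objects are axial quantities: a major axis at
``theta`` and at ``theta + 180`` are the same physical direction. All public
angles are therefore wrapped into the half-open interval ``(-90, 90]``
degrees.
"""

from __future__ import annotations

import numpy as np

__all__ = ["wrap_axial"]


def wrap_axial(angle_deg):
    """Wrap angles (degrees) into the axial interval ``(-90, 90]``.

    Accepts scalars or arrays; returns the same shape. The wrap is exact for
    multiples of 90: ``wrap_axial(-90) == wrap_axial(270) == 90``.
    """
    a = np.asarray(angle_deg, dtype=float)
    w = a - 180.0 * np.round(a / 180.0)
    w = np.where(w <= -90.0, w + 180.0, w)
    if np.isscalar(angle_deg) or np.ndim(angle_deg) == 0:
        return float(w)
    return w
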