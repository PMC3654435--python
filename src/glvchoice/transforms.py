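"""Shared scalar transforms."""

from __future__ import annotations

import numpy as np

__all__ = ["display_transform"]


def display_transform(x):
    """Negative-reciprocal display of a positive ratio.

    Ratios >= 1 are returned unchanged; ratios < 1 become -1/ratio, so both
    isomer dominances scale symmetrically away from +-1 and the open
    interval (-1, 1) is never entered.  Strictly increasing on (0, inf).
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("display_transform requires positive ratios")
    out = np.where(arr >= 1.0, arr, -1.0 / arr)
    if np.isscalar(x) or arr.ndim == 0:
        return float(out)
    return out
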