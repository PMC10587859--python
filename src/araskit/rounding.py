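"""Display rounding used for report tables.

Published tables round half away from zero (so 0.565 prints as 0.57),
while Python's built-in ``round`` is banker's rounding.  All computation
stays at full float precision; this helper is presentation-only.
"""

from __future__ import annotations

import numpy as np

__all__ = ["round_half_away"]


def round_half_away(x, digits: int = 2):
    """Round half away from zero, element-wise on arrays."""
    arr = np.asarray(x, dtype=float)
    factor = 10.0**digits
    out = np.sign(arr) * np.floor(np.abs(arr) * factor + 0.5) / factor
    if np.isscalar(x) or arr.ndim == 0:
        return float(out)
    return out
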