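"""Kneedle knee/elbow detection for monotone curves.

Finds the point of maximum curvature ("knee") of a decreasing convex
curve such as within-cluster sum of squares versus k: the curve is
min-max normalized, the difference curve y_d = x_n - (1 - y_n) is formed
(for a decreasing curve), and local maxima of y_d that exceed the
sensitivity-scaled threshold are knees; the first one is returned.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np


def find_knee(
    x: Sequence[float],
    y: Sequence[float],
    sensitivity: float = 1.0,
) -> Optional[float]:
    """Knee x-location of a decreasing convex curve; None when absent."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3:
        return None
    xn = (x - x.min()) / (x.max() - x.min())
    rng = y.max() - y.min()
    if rng == 0:
        return None
    yn = (y - y.min()) / rng
    yd = (1.0 - yn) - xn  # distance above the diagonal for a decreasing curve
    # candidate knees: local maxima of the difference curve
    candidates = [
        i for i in range(1, len(yd) - 1) if yd[i] >= yd[i - 1] and yd[i] >= yd[i + 1]
    ]
    if not candidates:
        return None
    mean_gap = np.abs(np.diff(xn)).mean()
    for i in candidates:
        threshold = yd[i] - sensitivity * mean_gap
        # knee confirmed if the difference curve drops below the threshold
        # before the next local maximum
        j = i + 1
        while j < len(yd):
            if yd[j] > yd[i]:
                break
            if yd[j] < threshold:
                return float(x[i])
            j += 1
        else:
            return float(x[i])
    return None
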