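"""Small shared numerics."""

from __future__ import annotations

import numpy as np


def percentile_ci(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Classical percentile bootstrap interval from order statistics.

    Uses the (B+1)-based order-statistic convention: with B draws and
    level 0.95, the endpoints are the ⌊0.025(B+1)⌋-th and ⌈0.975(B+1)⌉-th
    order statistics (clipped to the sample), which is marginally wider —
    hence closer to nominal coverage — than interpolated quantiles.
    """
    draws = np.sort(np.asarray(draws, dtype=float))
    b = draws.size
    alpha = (1.0 - level) / 2.0
    k_lo = min(max(int(np.floor(alpha * (b + 1))), 1), b)
    k_hi = max(min(int(np.ceil((1.0 - alpha) * (b + 1))), b), 1)
    return float(draws[k_lo - 1]), float(draws[k_hi - 1])
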