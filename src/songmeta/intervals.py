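"""Highest-posterior-density intervals from MCMC draws."""

from __future__ import annotations

import math

import numpy as np

__all__ = ["hdi"]


def hdi(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous window of sorted draws containing ``ceil(mass*n)``.

    Ties between equally short windows are broken toward the earlier
    (lower) window.
    """
    if not 0.0 < mass < 1.0:
        raise ValueError(f"mass must be in (0, 1), got {mass}")
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n == 0:
        raise ValueError("empty sample")
    k = int(math.ceil(mass * n))
    if k < 1 or n - k < 0:
        raise ValueError(f"need at least {k} samples for mass={mass}, got {n}")
    if k == n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: n - k]
    i = int(np.argmin(widths))  # argmin takes the first minimum: earlier window
    return float(x[i]), float(x[i + k])
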