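"""Per-cell resource dynamics: logistic regrowth and scramble consumption.

The resource in a suitable cell is a single energy pool ``R`` (J) growing
logistically toward carrying capacity ``K`` once per day, with a
non-consumable floor ``E_nc`` (belowground tissue) that survives depletion
and seeds regrowth.  Competition is scramble: when the consumable pool
cannot cover all demands, every individual receives the same fraction of
its demand.
"""

from __future__ import annotations

import numpy as np

__all__ = ["logistic_update", "scramble_consume"]


def logistic_update(R, r: float, K: float):
    """One daily step of the discrete logistic map, capped at ``K``.

    ``R' = min(K, R + r * R * (1 - R/K))``.  ``R = K`` is a fixed point and
    the update never decreases ``R`` for ``r >= 0``.  Element-wise over
    arrays.
    """
    if r < 0:
        raise ValueError("growth rate must be non-negative")
    if K <= 0:
        raise ValueError("carrying capacity must be positive")
    R = np.asarray(R, dtype=float)
    out = np.minimum(K, R + r * R * (1.0 - R / K))
    return out if out.ndim else float(out)


def scramble_consume(R: float, e_nc: float, demands):
    """Split the consumable pool ``R - e_nc`` over per-individual demands.

    Returns ``(R_after, intakes)``.  Undersubscribed pools grant each
    demand in full; oversubscribed pools are shared proportionally to
    demand, so equal demands always receive equal intakes and the floor
    ``e_nc`` is never breached.  Energy is conserved exactly:
    ``R - R_after == intakes.sum()``.
    """
    demands = np.asarray(demands, dtype=float)
    if demands.size and np.any(demands < 0):
        raise ValueError("demands must be non-negative")
    pool = max(R - e_nc, 0.0)
    total = demands.sum()
    if total <= pool or total == 0.0:
        intakes = demands.copy()
    else:
        intakes = demands * (pool / total)
    return R - intakes.sum(), intakes
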