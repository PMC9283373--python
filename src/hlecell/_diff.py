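"""Finite-difference gradients with optional Richardson extrapolation.

Adaptive central differences: for each coordinate the second-order central
difference is evaluated on a shrinking sequence of steps and extrapolated by
a Richardson table; the returned entry is the one with the smallest estimated
error.  Falls back to one-sided differences when a stencil point is rejected
by the objective (e.g. an inadmissible microstate).
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["central_gradient", "richardson_gradient"]


def central_gradient(
    f: Callable[[np.ndarray], float],
    x: np.ndarray,
    h: float | Sequence[float] = 1e-6,
) -> np.ndarray:
    """Plain second-order central-difference gradient of ``f`` at ``x``."""
    x = np.asarray(x, dtype=float)
    hs = np.broadcast_to(np.asarray(h, dtype=float), x.shape)
    g = np.empty_like(x)
    for q in range(x.size):
        e = np.zeros_like(x)
        e.flat[q] = hs.flat[q]
        try:
            g.flat[q] = (f(x + e) - f(x - e)) / (2.0 * hs.flat[q])
        except Exception:
            # one-sided fallback when a stencil point is inadmissible
            f0 = f(x)
            try:
                g.flat[q] = (f(x + e) - f0) / hs.flat[q]
            except Exception:
                g.flat[q] = (f0 - f(x - e)) / hs.flat[q]
    return g


def _central(f, x, q, h):
    e = np.zeros_like(x)
    e.flat[q] = h
    return (f(x + e) - f(x - e)) / (2.0 * h)


def richardson_gradient(
    f: Callable[[np.ndarray], float],
    x: np.ndarray,
    h0: float = 1e-3,
    levels: int = 4,
    shrink: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Richardson-extrapolated central differences.

    Returns ``(gradient, error_estimate)``.  The central difference has error
    ``O(h^2)``; each Richardson stage removes the leading even power, so stage
    ``k`` of the table is accurate to ``O(h^(2k+2))``.
    """
    x = np.asarray(x, dtype=float)
    g = np.empty_like(x)
    err = np.empty_like(x)
    for q in range(x.size):
        hs = h0 / shrink ** np.arange(levels)
        try:
            D = [[_central(f, x, q, h) for h in hs]]
            for k in range(1, levels):
                fac = shrink ** (2 * k)
                D.append(
                    [
                        (fac * D[k - 1][i + 1] - D[k - 1][i]) / (fac - 1.0)
                        for i in range(levels - k)
                    ]
                )
            best, best_err = D[0][-1], np.inf
            for k in range(1, levels):
                e = abs(D[k][-1] - D[k - 1][-1])
                if e <= best_err:
                    best, best_err = D[k][-1], e
            g.flat[q], err.flat[q] = best, best_err
        except Exception:
            g.flat[q] = central_gradient(f, x, h0).flat[q]
            err.flat[q] = np.nan
    return g, err
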