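"""Minimal circular statistics: resultant, circular mean, Rayleigh test.

Angles are radians in (-pi, pi].
"""

from __future__ import annotations

import numpy as np


def wrap_angle(theta: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles into (-pi, pi]."""
    return -((-np.asarray(theta) + np.pi) % (2.0 * np.pi) - np.pi)


def resultant_length(theta: np.ndarray) -> float:
    """Mean resultant length R-bar of a sample of angles."""
    theta = np.asarray(theta, dtype=float)
    if theta.size == 0:
        raise ValueError("empty angle sample")
    return float(np.abs(np.exp(1j * theta).mean()))


def circular_mean(theta: np.ndarray) -> float:
    """Circular mean direction of a sample of angles."""
    theta = np.asarray(theta, dtype=float)
    if theta.size == 0:
        raise ValueError("empty angle sample")
    return float(np.angle(np.exp(1j * theta).mean()))


def rayleigh_test(theta: np.ndarray, n_eff: float | None = None) -> tuple[float, float]:
    """Rayleigh test of non-uniformity.

    Returns (z, p) where z = n * Rbar**2 and p uses the standard
    finite-sample correction (Zar, Biostatistical Analysis, eq. 27.4).
    ``n_eff`` substitutes an effective sample size when the angles are
    serially correlated (the test assumes independent draws).
    """
    theta = np.asarray(theta, dtype=float)
    if theta.size < 2:
        raise ValueError("Rayleigh test needs at least 2 angles")
    n = float(n_eff) if n_eff is not None else float(theta.size)
    n = max(n, 2.0)
    rbar = resultant_length(theta)
    z = n * rbar**2
    p = np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n**2 - (n * rbar) ** 2)) - (1.0 + 2.0 * n))
    return float(z), float(min(max(p, 0.0), 1.0))


def effective_sample_size(theta: np.ndarray) -> float:
    """AR(1)-style effective sample size for serially correlated angles.

    Uses the lag-1 correlation of sin(theta - mean direction); for a
    narrowband signal the per-cycle phase samples decorrelate only over
    the filter bandwidth, so treating them as independent overstates the
    evidence of any concentration test.
    """
    theta = np.asarray(theta, dtype=float)
    n = theta.size
    if n < 3:
        return float(n)
    dev = np.sin(theta - circular_mean(theta))
    if dev.std() == 0:
        return float(n)
    rho = float(np.corrcoef(dev[:-1], dev[1:])[0, 1])
    rho = min(max(rho, 0.0), 0.99)
    return float(n * (1.0 - rho) / (1.0 + rho))
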