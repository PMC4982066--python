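"""Simulation performance metrics: percent bias, rMSE, joint coverage."""

from __future__ import annotations

import numpy as np

__all__ = ["percent_bias", "signed_percent_bias", "rmse", "joint_coverage"]


def _as_matrix(estimates) -> np.ndarray:
    est = np.atleast_2d(np.asarray(estimates, dtype=float))
    if est.size == 0:
        raise ValueError("need at least one estimate")
    return est


def signed_percent_bias(estimates, truth) -> np.ndarray:
    """100 * (mean(estimate) - truth) / |truth| per component."""
    est = _as_matrix(estimates)
    truth = np.asarray(truth, dtype=float)
    if np.any(truth == 0):
        raise ValueError("percent bias undefined for zero truth components")
    return 100.0 * (est.mean(axis=0) - truth) / np.abs(truth)


def percent_bias(estimates, truth) -> np.ndarray:
    """Absolute relative bias of the mean estimate, in percent."""
    return np.abs(signed_percent_bias(estimates, truth))


def rmse(estimates, truth) -> np.ndarray:
    """Root mean squared error per component."""
    est = _as_matrix(estimates)
    if est.shape[0] < 2:
        raise ValueError("rmse needs at least 2 estimates")
    truth = np.asarray(truth, dtype=float)
    return np.sqrt(np.mean((est - truth) ** 2, axis=0))


def joint_coverage(flags) -> tuple[float, float]:
    """Fraction of replicates whose joint region contained the truth.

    Returns (coverage, binomial Monte-Carlo standard error).
    """
    flags = np.asarray(flags, dtype=bool)
    if flags.size == 0:
        raise ValueError("need at least one containment flag")
    p = float(flags.mean())
    se = float(np.sqrt(p * (1.0 - p) / flags.size))
    return p, se
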