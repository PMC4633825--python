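"""Circular statistics for spike- and pulse-phase analysis.

Descriptive statistics are the first trigonometric moment: mean direction
and resultant vector length R (0 = uniform, 1 = perfectly concentrated).
Tests: Rayleigh (uniformity), Watson–Williams (equality of mean directions
across groups), and a two-sample Watson U² with a permutation p-value.
All angles are degrees.
"""
from __future__ import annotations

import math
import warnings

import numpy as np
from scipy import stats

__all__ = [
    "resultant_length",
    "mean_phase_deg",
    "rayleigh_test",
    "circular_stats",
    "watson_williams",
    "watson_u2",
    "watson_u2_permutation",
    "vonmises_kappa_from_r",
]


def _rad(deg) -> np.ndarray:
    return np.deg2rad(np.asarray(deg, dtype=float))


def resultant_length(phases_deg) -> float:
    th = _rad(phases_deg)
    return float(np.abs(np.mean(np.exp(1j * th))))


def mean_phase_deg(phases_deg) -> float:
    th = _rad(phases_deg)
    return float(np.mod(np.degrees(np.angle(np.mean(np.exp(1j * th)))), 360.0))


def rayleigh_test(phases_deg) -> float:
    """Rayleigh p-value with the small-sample correction (Zar's formula).

    p = exp( sqrt(1 + 4n + 4(n^2 - Rn^2)) - (1 + 2n) ),  Rn = n*R.
    """
    th = np.asarray(phases_deg, dtype=float)
    n = th.size
    if n < 2:
        raise ValueError("Rayleigh test needs at least 2 phases")
    r = resultant_length(th)
    rn = n * r
    p = math.exp(math.sqrt(1.0 + 4.0 * n + 4.0 * (n * n - rn * rn))
                 - (1.0 + 2.0 * n))
    return min(p, 1.0)


def circular_stats(phases_deg) -> tuple[float, float, float]:
    """(resultant_length, mean_phase_deg, rayleigh_p) of a phase sample."""
    th = np.asarray(phases_deg, dtype=float)
    if th.size < 2:
        raise ValueError("circular statistics need at least 2 phases")
    return resultant_length(th), mean_phase_deg(th), rayleigh_test(th)


def vonmises_kappa_from_r(r: float) -> float:
    """Approximate ML inverse of r = I1(k)/I0(k) (Fisher 1993)."""
    if r < 0.53:
        return 2 * r + r**3 + 5 * r**5 / 6
    if r < 0.85:
        return -0.4 + 1.39 * r + 0.43 / (1 - r)
    return 1.0 / (r**3 - 4 * r**2 + 3 * r)


def watson_williams(*groups) -> tuple[float, float]:
    """Watson–Williams one-way test of equal mean directions.

    Returns (F, p).  Valid for reasonably concentrated samples; a warning
    is issued when the pooled resultant length is below 0.45, where the
    F approximation degrades.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size < 5 for g in groups):
        raise ValueError("each group needs at least 5 phases")
    k = len(groups)
    ns = np.array([g.size for g in groups])
    n = int(ns.sum())
    rws = np.array([g.size * resultant_length(g) for g in groups])
    all_ph = np.concatenate(groups)
    rw_tot = n * resultant_length(all_ph)
    rbar = float(rws.sum()) / n
    if rbar < 0.45:
        warnings.warn(
            "Watson-Williams: pooled resultant length {:.2f} < 0.45; the F "
            "approximation is unreliable at this concentration".format(rbar),
            stacklevel=2,
        )
    kappa = vonmises_kappa_from_r(rbar)
    corr = 1.0 + 3.0 / (8.0 * kappa) if kappa > 0 else 1.0
    num = (rws.sum() - rw_tot) / (k - 1)
    den = (n - rws.sum()) / (n - k)
    if den <= 0:
        return 0.0, 1.0
    f = corr * num / den
    f = max(f, 0.0)
    p = float(stats.f.sf(f, k - 1, n - k))
    return float(f), p


def watson_u2(a, b) -> float:
    """Two-sample Watson U^2 statistic."""
    a = np.mod(np.asarray(a, dtype=float), 360.0)
    b = np.mod(np.asarray(b, dtype=float), 360.0)
    n, m = a.size, b.size
    total = n + m
    vals = np.concatenate([a, b])
    order = np.argsort(vals, kind="stable")
    is_a = np.concatenate([np.ones(n, bool), np.zeros(m, bool)])[order]
    ca = np.cumsum(is_a) / n
    cb = np.cumsum(~is_a) / m
    d = ca - cb
    return float(n * m / total**2 * (np.sum(d**2) - np.sum(d) ** 2 / total))


def watson_u2_permutation(a, b, n_perm: int = 1000,
                          rng: np.random.Generator | None = None,
                          ) -> tuple[float, float]:
    """Watson U^2 with a label-permutation p-value.

    p = (1 + #{perm U^2 >= observed}) / (n_perm + 1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if n_perm < 200:
        raise ValueError("need at least 200 permutations")
    rng = np.random.default_rng() if rng is None else rng
    obs = watson_u2(a, b)
    pooled = np.concatenate([a, b])
    n = a.size
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if watson_u2(perm[:n], perm[n:]) >= obs - 1e-12:
            count += 1
    return obs, (1 + count) / (n_perm + 1)
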