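"""Independent reference implementations used only as test oracles.

These deliberately avoid the package's own code paths: a fixed-step
RK4 integrator for the co-culture model, closed-form logistic growth
and its time integral, a direct transcription of the weighted
plate-count formula, and a brute-force mean-rank computation for
Dunn's statistic.
"""

from __future__ import annotations

import math

import numpy as np


# ------------------------------------------------------------- logistic forms

def logistic_closed_form(t, r, K, S0):
    t = np.asarray(t, dtype=float)
    return K * S0 * np.exp(r * t) / (K + S0 * (np.exp(r * t) - 1.0))


def logistic_integral(T, r, K, S0):
    """Integral of the logistic curve from 0 to T (cells/mL * h)."""
    return (K / r) * math.log((K + S0 * (math.exp(r * T) - 1.0)) / K)


# --------------------------------------------------- fixed-step RK4 coculture

def rk4_coculture(params, t_grid, dt=1e-3):
    """Fixed-step RK4 solution of the S/I/R/P model on t_grid.

    Independent of the package's adaptive integrator; states are
    clamped at zero after each step.  Returns an array with rows
    S, I, R, P evaluated at the grid points.
    """
    r, K = params.r, params.K
    delta, tau, beta = params.delta, params.tau, params.beta
    lam, mu = params.lam, params.mu_res

    def f(y):
        S, I, R, P = np.maximum(y, 0.0)
        N = S + I + R
        g = r * (1.0 - N / K)
        return np.array([
            g * S - delta * S * P - mu * S,
            delta * S * P - I / tau,
            g * R + mu * S,
            (beta / tau) * I - delta * N * P - lam * P,
        ])

    t_grid = np.asarray(t_grid, dtype=float)
    y = np.array([params.S0, 0.0, 0.0, params.P0])
    out = np.empty((4, len(t_grid)))
    out[:, 0] = y
    t = t_grid[0]
    for k in range(1, len(t_grid)):
        target = t_grid[k]
        while t < target - 1e-12:
            h = min(dt, target - t)
            k1 = f(y)
            k2 = f(y + 0.5 * h * k1)
            k3 = f(y + 0.5 * h * k2)
            k4 = f(y + h * k3)
            y = np.maximum(y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4), 0.0)
            t += h
        out[:, k] = y
    return out


def trapezoid_auc(t, y):
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.sum((y[1:] + y[:-1]) / 2.0 * np.diff(t)))


# ------------------------------------------------ weighted plate-count oracle

def brute_force_titer(counts_by_exponent, plated_volume, lo=10, hi=300):
    """Direct transcription of the weighted plate-count formula.

    ``counts_by_exponent``: {exponent: [counts]}.  A dilution level
    enters iff any of its plates lies in [lo, hi]; all plates of the
    (at most two, adjacent, most dilute kept) selected levels then
    contribute.  Returns per-mL concentration, or None when no level
    qualifies.
    """
    levels = sorted(
        (e for e, cs in counts_by_exponent.items() if any(lo <= c <= hi for c in cs)),
        reverse=True,
    )
    if not levels:
        return None
    if len(levels) > 2:
        levels = levels[-2:]
    if len(levels) == 2 and levels[0] - levels[1] != 1:
        raise ValueError("non-adjacent countable levels")
    e_low = levels[0]
    total = sum(sum(counts_by_exponent[e]) for e in levels)
    n1 = len(counts_by_exponent[e_low])
    n2 = len(counts_by_exponent[levels[1]]) if len(levels) == 2 else 0
    per_aliquot = total / (n1 * 1.0 + n2 * 0.1)
    return per_aliquot / (10.0 ** e_low * plated_volume)


# ------------------------------------------------------- Dunn mean-rank oracle

def brute_force_mean_ranks(groups):
    """Mid-rank mean per group computed by explicit enumeration."""
    labelled = []
    for name, values in groups.items():
        labelled.extend((float(v), name) for v in values)
    values = sorted(v for v, _ in labelled)
    ranks = {}
    for v, _ in labelled:
        positions = [i + 1 for i, u in enumerate(values) if u == v]
        ranks.setdefault(v, sum(positions) / len(positions))
    out = {}
    for name, vals in groups.items():
        out[name] = sum(ranks[float(v)] for v in vals) / len(vals)
    return out
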