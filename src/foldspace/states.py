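"""Boltzmann state probabilities for the two- and three-state equilibria.

Folding is a two-state equilibrium between unfolded (u) and folded (f):
p_f = K_f / (1 + K_f) with K_f = exp(-dG_f / RT). Binding adds a third
state, folded-and-bound (fb), with the unfolded-and-bound state assumed
negligible: p_fb = K_f K_b c / (1 + K_f + K_f K_b c), where c is the
(dimensionless) ligand concentration.

Implementations work on the dimensionless energies dG/RT internally and
use numerically stable log-sum-exp forms so that extreme energies saturate
instead of overflowing.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, logsumexp

from .constants import RT


def fraction_folded(dg_f, rt: float = RT):
    """Fraction of folded molecules, p_f = K_f/(1+K_f), K_f = exp(-dG_f/RT).

    Strictly decreasing in ``dg_f`` (kcal/mol); 0.5 at dG_f = 0. Uses the
    branch-stable logistic (scipy's tanh-based expit loses ~4 digits in the
    deep tails, which matters against the enumeration oracle).
    """
    t = np.asarray(dg_f, dtype=float) / rt
    e_pos = np.exp(-np.clip(t, 0.0, 745.0))     # t >= 0: K_f <= 1
    e_neg = np.exp(np.clip(t, -745.0, 0.0))     # t < 0: 1/K_f < 1
    return np.where(t >= 0, e_pos / (1.0 + e_pos), 1.0 / (1.0 + e_neg))


def fraction_bound(dg_f, dg_b, c: float = 1.0, rt: float = RT):
    """Fraction folded-and-bound, p_fb = K_f K_b c / (1 + K_f + K_f K_b c).

    ``c`` is the dimensionless ligand concentration (> 0). Strictly
    decreasing in each free energy; 1/3 at dG_f = dG_b = 0, c = 1.
    """
    if c <= 0:
        raise ValueError(f"ligand concentration must be > 0, got {c}")
    tf = np.asarray(dg_f, dtype=float) / rt
    tb = np.asarray(dg_b, dtype=float) / rt
    # log-weights of states (uu, fu, fb): 0, -tf, -tf - tb + log c
    log_fb = -tf - tb + np.log(c)
    logz = logsumexp(np.stack(np.broadcast_arrays(
        np.zeros_like(log_fb), -tf, log_fb)), axis=0)
    return np.exp(log_fb - logz)


def state_probabilities(dg_f, dg_b=None, c: float = 1.0, rt: float = RT):
    """All state probabilities, summing to 1.

    Two-state: returns (p_u, p_f). Three-state (``dg_b`` given): returns
    (p_uu, p_fu, p_fb).
    """
    if dg_b is None:
        # p_u(dg) = p_f(-dg): evaluate both through the stable branch
        return fraction_folded(-np.asarray(dg_f, dtype=float), rt), \
            fraction_folded(dg_f, rt)
    tf = np.asarray(dg_f, dtype=float) / rt
    tb = np.asarray(dg_b, dtype=float) / rt
    log_w = np.stack(np.broadcast_arrays(
        np.zeros_like(tf + tb), -tf, -tf - tb + np.log(c)))
    logz = logsumexp(log_w, axis=0)
    p = np.exp(log_w - logz)
    return p[0], p[1], p[2]


def enumerate_partition(dg_f, dg_b=None, c: float = 1.0, rt: float = RT):
    """Brute-force Boltzmann enumeration oracle over explicit state weights.

    Computes the same probabilities as :func:`state_probabilities` by direct
    summation of weights 1, K_f (and K_f K_b c); intended for moderate
    energies where exp() does not overflow.
    """
    kf = np.exp(-np.asarray(dg_f, dtype=float) / rt)
    if dg_b is None:
        z = 1.0 + kf
        return 1.0 / z, kf / z
    kb = np.exp(-np.asarray(dg_b, dtype=float) / rt)
    z = 1.0 + kf + kf * kb * c
    return 1.0 / z, kf / z, kf * kb * c / z
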