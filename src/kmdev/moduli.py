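"""Conversions between (SWS, PR) and the complex shear modulus G*.

For an isotropic viscoelastic medium of density ρ with storage modulus G'
and loss modulus G'' (|G*| = √(G'² + G''²)):

    SWS = √( 2|G*|² / [ρ(|G*| + G')] )           (m/s)
    PR  = (1/2π)·√( 2|G*|² / [ρ(|G*| − G')] )    (m/s)

PR diverges in the lossless limit G'' → 0 (infinite penetration), which is
signalled explicitly rather than produced as ±inf arithmetic.  The inverse
map has a closed form: with A = ρ·SWS²/2 and B = ρ·(2π·PR)²/2,

    |G*| = 2AB/(A+B),  G' = |G*|·(B−A)/(A+B),  G'' = √(|G*|² − G'²),

which requires B ≥ A (equality is the purely viscous case G' = 0; the
elastic limit is B → ∞).
"""

from __future__ import annotations

import numpy as np

from .datamodel import ComplexModulus

__all__ = [
    "LosslessMaterialError",
    "sws_from_moduli",
    "pr_from_moduli",
    "moduli_from_sws_pr",
    "abs_modulus_elastic",
]


class LosslessMaterialError(ValueError):
    """Raised when PR is requested for a purely elastic medium (G'' = 0):
    the penetration rate is infinite there."""


def sws_from_moduli(m: ComplexModulus) -> np.ndarray | float:
    """Shear wave speed in m/s from the complex shear modulus."""
    gs = np.asarray(m.g_storage, dtype=np.float64)
    mag = np.asarray(m.magnitude, dtype=np.float64)
    out = np.sqrt(2.0 * mag**2 / (m.density * (mag + gs)))
    return float(out) if out.ndim == 0 else out

def pr_from_moduli(m: ComplexModulus) -> np.ndarray | float:
    """Penetration rate in m/s; raises :class:`LosslessMaterialError` if any
    G'' is zero (infinite penetration, elastic limit)."""
    gl = np.asarray(m.g_loss, dtype=np.float64)
    if np.any(gl == 0):
        raise LosslessMaterialError(
            "infinite penetration (elastic): G'' = 0 has no finite PR"
        )
    gs = np.asarray(m.g_storage, dtype=np.float64)
    mag = np.asarray(m.magnitude, dtype=np.float64)
    out = np.sqrt(2.0 * mag**2 / (m.density * (mag - gs))) / (2.0 * np.pi)
    return float(out) if out.ndim == 0 else out


def moduli_from_sws_pr(
    sws: np.ndarray | float,
    pr: np.ndarray | float,
    density: float = 1000.0,
) -> ComplexModulus:
    """Invert the (SWS, PR) pair back to (G', G'') exactly.

    ``pr = inf`` is the elastic limit and returns G'' = 0.  Pairs with
    2π·PR < SWS — i.e. B < A — have no solution with G' ≥ 0 and raise
    ``ValueError``.
    """
    sws = np.asarray(sws, dtype=np.float64)
    pr = np.asarray(pr, dtype=np.float64)
    if np.any(sws <= 0) or np.any(pr <= 0):
        raise ValueError("sws and pr must be strictly positive")
    if density <= 0:
        raise ValueError("density must be positive")
    A = density * sws**2 / 2.0
    B = density * (2.0 * np.pi * pr) ** 2 / 2.0
    with np.errstate(over="ignore", invalid="ignore"):
        elastic = np.isinf(B)
        Bc = np.where(elastic, 1.0, B)
        mag = np.where(elastic, 2.0 * A, 2.0 * A * Bc / (A + Bc))
        ratio = np.where(elastic, 1.0, (Bc - A) / (A + Bc))
    if np.any(ratio < -1e-12):
        raise ValueError(
            "no (G', G'') ≥ 0 reproduces this pair: requires 2π·PR ≥ SWS"
        )
    g_storage = mag * np.clip(ratio, 0.0, 1.0)
    g_loss = np.sqrt(np.maximum(mag**2 - g_storage**2, 0.0))
    return ComplexModulus(g_storage=g_storage, g_loss=g_loss, density=density)


def abs_modulus_elastic(
    sws: np.ndarray | float, density: float = 1000.0
) -> np.ndarray | float:
    """|G*| under the elastic model: ρ·SWS² in Pa (NaN-propagating)."""
    out = density * np.asarray(sws, dtype=np.float64) ** 2
    return float(out) if out.ndim == 0 else out
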