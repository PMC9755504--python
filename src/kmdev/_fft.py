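"""Boundary extension helpers for FFT-domain filtering.

Wave fields are not periodic over the field of view; filtering their raw
DFT lets the wrap discontinuity leak broadband energy into the passband
and corrupt phase-gradient estimates far into the interior.  Three
symmetric extensions (each doubling the axis) are provided:

``mirror``
    Plain reflection.  Amplitude-continuous, but the phase ramp of a
    travelling wave reverses at the junction (a kink of 2k' in the phase
    slope) and the extension holds a counter-propagating image wave.
``conj``
    Conjugated reflection.  Continues the phase ramp of a travelling wave
    but jumps by twice the boundary phase wherever that phase is nonzero.
``anchored``
    Conjugated reflection re-anchored by the squared boundary phase per
    boundary pixel.  For any locally plane wave a·exp(i k·r) this
    continues both the phase ramp and the amplitude envelope *exactly*
    through the face, for every axis and independently of the global
    phase.  The two single-sided continuations (beyond the end, before
    the start) are cross-faded where the reflected amplitude profile is
    smallest, closing the extended volume into a smoothly periodic one.

``anchored`` is the pipeline default; the others are kept for standalone
filtering and comparison.
"""

from __future__ import annotations

import numpy as np

PAD_MODES = ("none", "mirror", "conj", "anchored")


def _anchor(edge: np.ndarray) -> np.ndarray:
    """Unit phasor exp(2i·arg(edge)) per boundary pixel (1 where edge=0)."""
    mag = np.abs(edge)
    ph = np.where(mag > 0, edge / np.where(mag > 0, mag, 1.0), 1.0)
    return ph * ph


def _extend_axis(u: np.ndarray, mode: str) -> np.ndarray:
    """Extend axis 0 from n to 2n samples."""
    n = u.shape[0]
    flip = np.flip(u, axis=0)
    if mode == "mirror":
        ext = flip
    elif mode == "conj":
        ext = np.conj(flip) if np.iscomplexobj(u) else flip
    elif mode == "anchored":
        if not np.iscomplexobj(u):
            ext = flip
        else:
            cflip = np.conj(flip)
            fwd = cflip * _anchor(u[-1])[None]
            bwd = cflip * _anchor(u[0])[None]
            # hand over from the end-continuation to the start-continuation
            # where the reflected amplitude is smallest
            prof = np.abs(flip).reshape(n, -1).mean(axis=1)
            centre = int(np.argmin(prof))
            half = max(4, n // 4)
            t = np.arange(n)
            w = np.clip((t - (centre - half)) / (2.0 * half), 0.0, 1.0)
            w = 0.5 * (1.0 + np.cos(np.pi * w))
            ext = w[(slice(None),) + (None,) * (u.ndim - 1)] * fwd
            ext += (1.0 - w)[(slice(None),) + (None,) * (u.ndim - 1)] * bwd
    else:
        raise ValueError(f"pad mode must be one of {PAD_MODES}, got {mode!r}")
    return np.concatenate([u, ext], axis=0)


def extend(vol: np.ndarray, axes, mode: str = "anchored") -> np.ndarray:
    """Double the array along ``axes`` by symmetric extension."""
    if mode == "none":
        return vol
    if mode not in PAD_MODES:
        raise ValueError(f"pad mode must be one of {PAD_MODES}, got {mode!r}")
    for ax in axes:
        vol = np.moveaxis(_extend_axis(np.moveaxis(vol, ax, 0), mode), 0, ax)
    return vol


def padded_shape(shape, axes, mode: str) -> tuple[int, ...]:
    if mode == "none":
        return tuple(shape)
    return tuple(2 * n if ax in axes else n for ax, n in enumerate(shape))
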