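"""Temporal harmonic extraction and inter-slice phase correction.

The harmonic coefficient convention follows the container contract
(:mod:`kmdev.datamodel`): the returned complex field ũ satisfies
``u(r, t) = Re[ũ(r)·exp(−iωt)]``, so a plane wave travelling along +x
yields ũ ∝ exp(+ik'x) and its phase gradient points along the propagation
direction.
"""

from __future__ import annotations

import warnings

import numpy as np

from .datamodel import ComplexWaveField, TimeSeriesField

__all__ = ["extract_harmonic", "correct_slice_phase"]


def extract_harmonic(field: TimeSeriesField, harmonic: int = 1) -> ComplexWaveField:
    """Isolate one temporal harmonic of the phase-offset series.

    With T equally spaced samples over one vibration period, the
    coefficient is ``(2/T)·Σ_t u(t)·exp(+2πi·h·t/T)``: a pure tone of
    amplitude a is returned with magnitude a, the DC offset and all other
    harmonics are rejected exactly, and the operation is linear.

    Parameters
    ----------
    field
        Displacement series with T ≥ 2·harmonic + 1 (Nyquist).
    harmonic
        Index h ≥ 1 of the harmonic to keep; h = 1 is the drive frequency.
    """
    T = field.grid.n_timesteps
    if harmonic < 1 or T < 2 * harmonic + 1:
        raise ValueError(
            f"harmonic {harmonic} out of range for {T} phase offsets "
            f"(need T ≥ {2 * harmonic + 1})"
        )
    basis = np.exp(2j * np.pi * harmonic * np.arange(T) / T) * (2.0 / T)
    # contract over the timestep axis (axis 2 of (F, C, T, x, y, z))
    data = np.tensordot(basis, field.data, axes=([0], [2]))
    return ComplexWaveField(grid=field.grid, data=data)


def correct_slice_phase(field: ComplexWaveField) -> ComplexWaveField:
    """Remove constant per-slice phase offsets between adjacent slices.

    Multi-slice interleaved acquisitions can leave each slice with its own
    temporal phase origin, producing phase jumps along z that corrupt
    through-plane gradients.  For each slice z > 0 the offset relative to
    slice z−1 is estimated as the argument of the amplitude-weighted mean
    of ``u_z·conj(u_{z−1})`` over in-plane voxels and removed cumulatively;
    slice 0 and all amplitudes are left untouched.  The estimator is exact
    for constant per-slice offsets; note that for a single obliquely
    travelling wave it also absorbs the genuine mean through-plane phase
    advance (indistinguishable from an offset without a model of the
    field), which averages out in reverberant fields containing
    counter-propagating waves.

    Applied independently per (frequency, component).  A transition whose
    covariance vanishes (e.g. an all-zero slice) contributes a zero offset
    and a warning.
    """
    nz = field.grid.shape[2]
    if nz < 2:
        raise ValueError("slice phase correction requires at least 2 slices")
    data = field.data.copy()
    F, C = data.shape[:2]
    for fi in range(F):
        for c in range(C):
            u = data[fi, c]
            warned = False
            for z in range(1, nz):
                # slice z-1 is already corrected, so the argument of the
                # covariance is the full offset of slice z (cumulation is
                # implicit) and the pass is idempotent
                cov = np.sum(u[:, :, z] * np.conj(u[:, :, z - 1]))
                if cov == 0:
                    if not warned:
                        warnings.warn(
                            f"zero inter-slice covariance at slice {z} "
                            f"(frequency-index {fi}, component {c}); "
                            "offset(s) set to 0",
                            RuntimeWarning,
                            stacklevel=2,
                        )
                        warned = True
                    continue
                dphi = float(np.angle(cov))
                if dphi != 0.0:
                    u[:, :, z] *= np.exp(-1j * dphi)
    return ComplexWaveField(grid=field.grid, data=data)
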