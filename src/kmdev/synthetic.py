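"""Synthetic multifrequency shear-wave fields with known ground truth.

Every downstream stage of the inversion is tested against fields produced
here, because the generating viscoelastic parameters are known exactly.
A field is a superposition of attenuated plane shear waves

    u(r, t) = Re[ u0 · p̂ · exp(i(k*·n̂·r − ωt)) ],   k* = k' + i·k'',

with propagation direction n̂, transverse polarization p̂ ⟂ n̂,
k' = 2πf/SWS (rad/m) and k'' = f/PR (1/m).  The attenuation scaling
k'' = f/PR (not ω/PR) keeps the simulator self-consistent with the
penetration-rate definition PR_f = (ω/2π)/k'' used by the inversion.

Optionally the field carries a curl-free compression contaminant (the
gradient of a long-wavelength scalar plane wave), additive Gaussian noise
on the time-domain displacement samples, and constant per-slice phase
offsets emulating inter-slice timing discontinuities of interleaved
multi-slice acquisitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .datamodel import AcquisitionGrid, RegionMask, TimeSeriesField

__all__ = [
    "ShearSource",
    "CompressionWave",
    "Compartment",
    "PhantomSpec",
    "synthesize",
    "brain_like_phantom",
]


def _unit(v: Sequence[float]) -> np.ndarray:
    v = np.asarray(v, dtype=np.float64)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector cannot be normalized")
    return v / n


@dataclass(frozen=True)
class ShearSource:
    """One plane shear-wave source.

    ``propagation`` and ``polarization`` are unit 3-vectors with
    polarization ⟂ propagation (transverse wave); ``amplitude`` is the
    displacement amplitude in µm and ``phase`` a temporal phase in rad.
    """

    propagation: tuple[float, float, float]
    polarization: tuple[float, float, float]
    amplitude: float
    phase: float = 0.0

    def __post_init__(self) -> None:
        n = _unit(self.propagation)
        p = _unit(self.polarization)
        if abs(float(n @ p)) > 1e-9:
            raise ValueError(
                "polarization must be orthogonal to propagation (tol 1e-9)"
            )
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        object.__setattr__(self, "propagation", tuple(n))
        object.__setattr__(self, "polarization", tuple(p))


@dataclass(frozen=True)
class CompressionWave:
    """Curl-free longitudinal contaminant: gradient of a scalar plane wave.

    ``amplitude`` is the displacement amplitude in µm, ``wavelength`` in m.
    The displacement is u = amplitude · m̂ · exp(i(k_c m̂·r − ωt)), which is
    the gradient of (amplitude/k_c)·(−i)·exp(i k_c m̂·r) and hence exactly
    curl-free.
    """

    amplitude: float
    wavelength: float
    direction: tuple[float, float, float] = (1.0, 1.0, 0.5)
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        object.__setattr__(self, "direction", tuple(_unit(self.direction)))


def _per_frequency(value: float | Mapping[float, float], f: float, what: str) -> float:
    if isinstance(value, Mapping):
        if f not in value:
            raise ValueError(f"{what} has no entry for frequency {f} Hz")
        out = float(value[f])
    else:
        out = float(value)
    if not out > 0:
        raise ValueError(f"{what} must be positive, got {out} at {f} Hz")
    return out


@dataclass(frozen=True)
class Compartment:
    """Homogeneous region of the phantom.

    ``sws``/``pr`` are in m/s, either scalars (non-dispersive) or mappings
    frequency→value; ``pr`` may be ``inf`` for a lossless medium.
    ``amplitude_scale`` multiplies every shear source inside the region
    (≈0 models fluid with near-zero shear support).
    """

    mask: np.ndarray
    sws: float | Mapping[float, float]
    pr: float | Mapping[float, float] = np.inf
    amplitude_scale: float = 1.0
    name: str = ""

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 3:
            raise ValueError("compartment mask must be a 3-D boolean volume")
        if self.amplitude_scale < 0:
            raise ValueError("amplitude_scale must be non-negative")
        object.__setattr__(self, "mask", mask)


@dataclass(frozen=True)
class PhantomSpec:
    """Complete description of a synthetic acquisition.

    ``smooth_sigma_vox`` Gaussian-smooths the material fields (slowness,
    attenuation, shear amplitude support) across compartment interfaces,
    in voxels; 0 keeps them piecewise constant.
    """

    grid: AcquisitionGrid
    compartments: tuple[Compartment, ...]
    sources: tuple[ShearSource, ...]
    compression: CompressionWave | None = None
    noise_sigma: float = 0.0
    slice_phase_offsets: np.ndarray | None = None
    smooth_sigma_vox: float = 0.0
    support_smooth_sigma_vox: float | None = None  # default: smooth_sigma_vox
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "compartments", tuple(self.compartments))
        object.__setattr__(self, "sources", tuple(self.sources))
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        for comp in self.compartments:
            if comp.mask.shape != self.grid.shape:
                raise ValueError(
                    f"compartment mask shape {comp.mask.shape} does not match "
                    f"grid {self.grid.shape}"
                )
        if self.slice_phase_offsets is not None:
            off = np.asarray(self.slice_phase_offsets, dtype=np.float64)
            if off.shape != (self.grid.shape[2],):
                raise ValueError("slice_phase_offsets must have one entry per slice")
            object.__setattr__(self, "slice_phase_offsets", off)
        if self.compression is not None and self.sources:
            lam_shear = max(
                _per_frequency(comp.sws, f, "SWS") / f
                for comp in self.compartments
                for f in self.grid.frequencies
            )
            if self.compression.wavelength < 10.0 * lam_shear:
                raise ValueError(
                    "compression wavelength must be ≥ 10× the largest shear "
                    f"wavelength ({lam_shear:.3f} m) to model a long-wavelength "
                    "contaminant"
                )


def _material_fields(
    spec: PhantomSpec, f: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxelwise slowness (s/m), attenuation k'' (1/m) and shear-amplitude
    support for one frequency, optionally smoothed across interfaces."""
    g = spec.grid
    slowness = np.zeros(g.shape)
    kdp = np.zeros(g.shape)
    support = np.zeros(g.shape)
    for comp in spec.compartments:
        if not comp.mask.any():
            continue
        sws = _per_frequency(comp.sws, f, "SWS")
        pr = _per_frequency(comp.pr, f, "PR")
        slowness[comp.mask] = 1.0 / sws
        kdp[comp.mask] = 0.0 if np.isinf(pr) else f / pr
        support[comp.mask] = comp.amplitude_scale
    if spec.smooth_sigma_vox > 0:
        s = spec.smooth_sigma_vox
        # smooth inside-values outward-consistently: fill background with the
        # nearest compartment values before smoothing, then re-apply support
        inside = slowness > 0
        if inside.any() and not inside.all():
            _, idx = ndimage.distance_transform_edt(
                ~inside, return_indices=True, sampling=g.spacing
            )
            slowness = slowness[tuple(idx)]
            kdp = kdp[tuple(idx)]
        slowness = ndimage.gaussian_filter(slowness, s)
        kdp = ndimage.gaussian_filter(kdp, s)
    s_sup = (
        spec.support_smooth_sigma_vox
        if spec.support_smooth_sigma_vox is not None
        else spec.smooth_sigma_vox
    )
    if s_sup > 0:
        support = ndimage.gaussian_filter(support, s_sup)
    return slowness, kdp, support


def _ray_phase_and_decay(
    slowness: np.ndarray,
    kdp: np.ndarray,
    spec: PhantomSpec,
    n_hat: np.ndarray,
    f: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Accumulated phase (rad) and log-amplitude along straight rays.

    For axis-aligned propagation the integrals are evaluated exactly by
    trapezoidal accumulation along the axis (the eikonal for straight
    rays), so the local phase gradient equals 2πf·slowness(r) even across
    material gradients.  For oblique directions the integrals fall back to
    the homogeneous projection k*·(n̂·r) per voxel, which is exact only in
    uniform media (the interfaces then carry phase discontinuities).
    """
    g = spec.grid
    axis = int(np.argmax(np.abs(n_hat)))
    if abs(abs(n_hat[axis]) - 1.0) < 1e-12:
        h = g.spacing_m[axis]
        sl = np.moveaxis(slowness, axis, 0)
        at = np.moveaxis(kdp, axis, 0)
        if n_hat[axis] < 0:
            sl = sl[::-1]
            at = at[::-1]
        mid_s = 0.5 * (sl[1:] + sl[:-1])
        mid_a = 0.5 * (at[1:] + at[:-1])
        phase = np.concatenate(
            [np.zeros((1,) + sl.shape[1:]), np.cumsum(mid_s * h, axis=0)], axis=0
        ) * (2.0 * np.pi * f)
        decay = -np.concatenate(
            [np.zeros((1,) + at.shape[1:]), np.cumsum(mid_a * h, axis=0)], axis=0
        )
        if n_hat[axis] < 0:
            phase = phase[::-1]
            decay = decay[::-1]
        return np.moveaxis(phase, 0, axis), np.moveaxis(decay, 0, axis)
    X, Y, Z = g.coords_m(sparse=False)
    proj = n_hat[0] * X + n_hat[1] * Y + n_hat[2] * Z
    travel = proj - proj.min()
    return 2.0 * np.pi * f * slowness * proj, -kdp * travel


def synthesize(spec: PhantomSpec) -> TimeSeriesField:
    """Evaluate the phantom into a displacement phase-offset series.

    Deterministic given ``spec.seed``.  Each shear source contributes
    ``support·amplitude·p̂·exp(decay)·exp(i(phase + φ₀))`` with phase and
    decay accumulated along straight rays through the (possibly smoothed)
    material fields, so the local complex wavenumber is k* = 2πf/SWS(r) +
    i·f/PR(r) everywhere the material is smooth.  The curl-free
    compression contaminant and per-slice phase factors are applied to the
    complex phasor before the real part is taken at each timestep;
    Gaussian noise is added independently per displacement sample.
    """
    g = spec.grid
    rng = np.random.default_rng(spec.seed)
    T = g.n_timesteps
    data = np.zeros((g.n_frequencies, 3, T) + g.shape, dtype=np.float64)

    for fi, f in enumerate(g.frequencies):
        phasor = np.zeros((3,) + g.shape, dtype=np.complex128)
        if spec.sources and spec.compartments:
            slowness, kdp, support = _material_fields(spec, f)
            for src in spec.sources:
                n_hat = np.asarray(src.propagation)
                p_hat = np.asarray(src.polarization)
                phase, decay = _ray_phase_and_decay(slowness, kdp, spec, n_hat, f)
                wave = (
                    src.amplitude
                    * support
                    * np.exp(decay)
                    * np.exp(1j * (phase + src.phase))
                )
                for c in range(3):
                    if p_hat[c] != 0.0:
                        phasor[c] += p_hat[c] * wave
        if spec.compression is not None:
            cw = spec.compression
            m_hat = np.asarray(cw.direction)
            k_c = 2.0 * np.pi / cw.wavelength
            X, Y, Z = g.coords_m(sparse=False)
            proj = m_hat[0] * X + m_hat[1] * Y + m_hat[2] * Z
            wave = cw.amplitude * np.exp(1j * cw.phase) * np.exp(1j * k_c * proj)
            for c in range(3):
                phasor[c] += m_hat[c] * wave
        if spec.slice_phase_offsets is not None:
            phasor = phasor * np.exp(1j * spec.slice_phase_offsets)[None, None, None, :]

        omega_t = 2.0 * np.pi * np.arange(T) / T
        for j in range(T):
            data[fi, :, j] = np.real(phasor * np.exp(-1j * omega_t[j]))

    if spec.noise_sigma > 0:
        data += rng.normal(0.0, spec.noise_sigma, size=data.shape)
    return TimeSeriesField(grid=g, data=data)


# Ground-truth shear wave speeds (m/s) for the brain-like phantom
# compartments, chosen at the reported 2D group means for white matter,
# cortical gray matter, and deep gray matter.
BRAIN_SWS = {"WM": 1.28, "CGM": 1.21, "DGM": 1.42}
# Penetration rates (m/s) in the physiological range of the compounded maps.
BRAIN_PR = {"WM": 0.85, "CGM": 0.80, "DGM": 0.90}
BRAIN_LABELS = {1: "WM", 2: "CGM", 3: "DGM", 4: "CSF"}


def reverberant_slab_phantom(
    grid: AcquisitionGrid,
    tilt_deg: float = 30.0,
    sws: float = 1.28,
    pr: float = 0.85,
    seed: int = 0,
) -> tuple[PhantomSpec, RegionMask]:
    """Homogeneous slab filled by obliquely interfering shear waves.

    Eight plane waves enter from four azimuths, each as a pair tilted
    ±``tilt_deg`` out of the slice plane with equal amplitude and phase —
    a symmetric reverberant field such as builds up between the top and
    bottom of the skull.  The balanced through-plane content gives the
    field genuine z-structure (through-plane wavelength λ/sin(tilt))
    while keeping the inter-slice phase-offset estimator neutral.  Used
    for slab-thickness studies; the analysis region (label 1) is a
    central in-plane ellipse through all slices.
    """
    rng = np.random.default_rng(seed)
    comp = Compartment(mask=np.ones(grid.shape, bool), sws=sws, pr=pr)
    tilt = np.deg2rad(tilt_deg)
    sources = []
    for i, az in enumerate(np.deg2rad([0.0, 90.0, 180.0, 270.0])):
        amp = float(np.clip(rng.normal(10.8, 2.5), 6.0, 16.0))
        phase = float(rng.uniform(0, 2 * np.pi))
        for sgn in (+1.0, -1.0):
            n_hat = np.array(
                [
                    np.cos(az) * np.cos(tilt),
                    np.sin(az) * np.cos(tilt),
                    sgn * np.sin(tilt),
                ]
            )
            ref = np.array([0.0, 0.0, 1.0]) if i % 2 == 0 else np.cross(n_hat, [0, 0, 1.0])
            p_hat = ref - (ref @ n_hat) * n_hat
            p_hat /= np.linalg.norm(p_hat)
            sources.append(
                ShearSource(
                    propagation=tuple(n_hat),
                    polarization=tuple(p_hat),
                    amplitude=amp,
                    phase=phase,
                )
            )
    spec = PhantomSpec(
        grid=grid, compartments=(comp,), sources=tuple(sources), seed=seed
    )
    X, Y, _ = grid.coords_m(sparse=False)
    cx, cy = grid.extent_m[0] / 2, grid.extent_m[1] / 2
    rho = np.sqrt(
        ((X - cx) / (0.35 * grid.extent_m[0])) ** 2
        + ((Y - cy) / (0.35 * grid.extent_m[1])) ** 2
    )
    mask = RegionMask(labels=(rho < 1.0).astype(np.int32), names={1: "WM"})
    return spec, mask


def brain_like_phantom(
    grid: AcquisitionGrid | None = None,
    seed: int = 0,
    noise_sigma: float = 0.0,
    compression: CompressionWave | None = None,
    slice_phase_offsets: np.ndarray | None = None,
) -> tuple[PhantomSpec, RegionMask]:
    """Nested-ellipsoid head phantom with four compartments.

    Outer shell mimics cortical gray matter, the bulk is white matter, a
    central deep-gray nucleus is stiffer, and a small fluid cavity carries
    near-zero shear amplitude.  The wave field is reverberant-like: plane
    sources enter from four azimuths in counter-propagating pairs tilted
    slightly out of plane, with amplitudes drawn around the ~10 µm scale
    typical of in-vivo brain fields.  Deterministic given ``seed``.
    """
    if grid is None:
        grid = AcquisitionGrid(
            shape=(64, 64, 24),
            spacing=(1.6, 1.6, 2.0),
            n_timesteps=8,
            frequencies=(20.0, 25.0, 30.0, 35.0),
        )
    if grid.shape[2] < 24:
        raise ValueError("brain-like phantom requires a grid with ≥ 24 slices")

    rng = np.random.default_rng(seed)
    X, Y, Z = grid.coords_m(sparse=False)
    cx, cy, cz = (e / 2.0 for e in grid.extent_m)
    ax_ = 0.46 * grid.extent_m[0]
    ay_ = 0.46 * grid.extent_m[1]
    az_ = 0.48 * grid.extent_m[2]
    rho = np.sqrt(
        ((X - cx) / ax_) ** 2 + ((Y - cy) / ay_) ** 2 + ((Z - cz) / az_) ** 2
    )
    labels = np.zeros(grid.shape, dtype=np.int32)
    labels[rho <= 1.0] = 2  # cortical shell
    labels[rho < 0.82] = 1  # white matter bulk
    labels[rho < 0.34] = 3  # deep gray nucleus
    labels[rho < 0.12] = 4  # central fluid cavity
    mask = RegionMask(labels=labels, names=BRAIN_LABELS)

    # the head is embedded in a tissue-mimicking gel so that the wave field
    # carries no amplitude edge at the object boundary (as in a phantom
    # scanned in a coupling medium); the fluid cavity keeps near-zero
    # shear support
    compartments = [
        Compartment(mask=labels == 1, sws=BRAIN_SWS["WM"], pr=BRAIN_PR["WM"], name="WM"),
        Compartment(mask=labels == 2, sws=BRAIN_SWS["CGM"], pr=BRAIN_PR["CGM"], name="CGM"),
        Compartment(mask=labels == 3, sws=BRAIN_SWS["DGM"], pr=BRAIN_PR["DGM"], name="DGM"),
        Compartment(mask=labels == 4, sws=1.0, pr=0.5, amplitude_scale=0.02, name="CSF"),
        Compartment(mask=labels == 0, sws=1.25, pr=0.85, name="gel"),
    ]

    # Waves entering from the four in-plane faces, as produced by
    # skull-borne excitation; amplitudes around the in-vivo ~10 µm scale.
    # Axis-aligned propagation keeps the ray-integral phase exact across
    # the stiffness interfaces; alternating SV-like (through-plane) and
    # SH-like (in-plane transverse) polarizations exercise all three
    # encoding components.
    sources = []
    for i, n_hat in enumerate(
        np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0]], dtype=float)
    ):
        ref = np.array([0.0, 0.0, 1.0]) if i % 2 == 0 else np.cross(n_hat, [0, 0, 1.0])
        p_hat = ref - (ref @ n_hat) * n_hat
        p_hat /= np.linalg.norm(p_hat)
        amp = float(np.clip(rng.normal(10.8, 2.5), 6.0, 16.0))
        sources.append(
            ShearSource(
                propagation=tuple(n_hat),
                polarization=tuple(p_hat),
                amplitude=amp,
                phase=float(rng.uniform(0, 2 * np.pi)),
            )
        )

    spec = PhantomSpec(
        grid=grid,
        compartments=tuple(compartments),
        sources=tuple(sources),
        compression=compression,
        noise_sigma=noise_sigma,
        slice_phase_offsets=slice_phase_offsets,
        smooth_sigma_vox=1.5,
        seed=seed,
    )
    return spec, mask
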