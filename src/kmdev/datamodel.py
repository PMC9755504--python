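"""Typed containers, units, and coordinate conventions shared by all stages.

Conventions
-----------
* Axis order is ``(x, y, z)`` and matches NIfTI ``(i, j, k)``; the slice
  axis is ``z``.  Voxel indices are 0-based.
* Voxel spacing is stored in millimetres.  All wavenumber arithmetic
  converts to metres.
* Displacements are in micrometres (µm).
* Real wavenumbers ``k'`` are carried in rad/m, imaginary wavenumbers
  ``k''`` in 1/m (nepers per metre).  Keeping both flavours explicit avoids
  factor-of-2π mistakes between the angular frequency ω (rad/s) used for
  shear-wave speed and the ordinary frequency ω/2π (Hz) used for the
  penetration rate.
* A complex harmonic field ``ũ`` represents the time series
  ``u(r, t) = Re[ũ(r)·exp(−iωt)]``; a wave travelling along the unit
  vector ``n̂`` therefore has phasor ``exp(+i k n̂·r)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

MM_PER_M = 1000.0

__all__ = [
    "AcquisitionGrid",
    "TimeSeriesField",
    "ComplexWaveField",
    "DecomposedField",
    "WavenumberMaps",
    "ParameterMap",
    "ComplexModulus",
    "RegionMask",
    "validate_field",
]


@dataclass(frozen=True)
class AcquisitionGrid:
    """Spatial and temporal sampling of a multifrequency acquisition.

    Parameters
    ----------
    shape
        Grid size ``(nx, ny, nz)`` in voxels.
    spacing
        Voxel size in millimetres per axis.
    n_timesteps
        Number of phase offsets sampled over one vibration period.
    frequencies
        Vibration frequencies in Hz, strictly increasing.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    n_timesteps: int
    frequencies: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(
            self, "frequencies", tuple(float(f) for f in self.frequencies)
        )
        if len(self.shape) != 3 or any(n < 1 for n in self.shape):
            raise ValueError(f"shape must be a positive integer triple, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if self.n_timesteps < 3:
            raise ValueError(
                "at least 3 phase offsets are required to isolate the first harmonic"
            )
        f = self.frequencies
        if len(f) == 0 or any(v <= 0 for v in f):
            raise ValueError("frequencies must be strictly positive")
        if any(f[i + 1] <= f[i] for i in range(len(f) - 1)):
            raise ValueError("frequencies must be strictly increasing with no duplicates")

    @property
    def n_frequencies(self) -> int:
        return len(self.frequencies)

    @property
    def spacing_m(self) -> tuple[float, float, float]:
        """Voxel spacing converted to metres."""
        return tuple(s / MM_PER_M for s in self.spacing)

    @property
    def extent_m(self) -> tuple[float, float, float]:
        """Physical field-of-view extent per axis in metres."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing_m))

    @property
    def omega(self) -> np.ndarray:
        """Angular frequencies 2πf in rad/s, one per vibration frequency."""
        return 2.0 * np.pi * np.asarray(self.frequencies)

    def coords_m(self, sparse: bool = True) -> tuple[np.ndarray, ...]:
        """Voxel-centre coordinates in metres as a (sparse) meshgrid."""
        axes = [np.arange(n) * d for n, d in zip(self.shape, self.spacing_m)]
        return tuple(np.meshgrid(*axes, indexing="ij", sparse=sparse))


def _require_shape(name: str, arr: np.ndarray, expected: tuple[int, ...]) -> None:
    if arr.shape != expected:
        raise ValueError(f"{name} has shape {arr.shape}, expected {expected}")


@dataclass(frozen=True)
class TimeSeriesField:
    """Real displacement phase-offset series, in µm.

    ``data`` is indexed ``(frequency, component, timestep, x, y, z)`` with
    exactly three orthogonal motion-encoding components.
    """

    grid: AcquisitionGrid
    data: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        object.__setattr__(self, "data", data)
        g = self.grid
        _require_shape(
            "TimeSeriesField.data",
            data,
            (g.n_frequencies, 3, g.n_timesteps) + g.shape,
        )


@dataclass(frozen=True)
class ComplexWaveField:
    """Complex harmonic field ũ after temporal Fourier transform, in µm.

    ``data`` is indexed ``(frequency, component, x, y, z)``.  The physical
    field is ``u(r, t) = Re[ũ(r)·exp(−iωt)]``.
    """

    grid: AcquisitionGrid
    data: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.complex128)
        object.__setattr__(self, "data", data)
        g = self.grid
        _require_shape("ComplexWaveField.data", data, (g.n_frequencies, 3) + g.shape)

    @property
    def omega_per_frequency(self) -> np.ndarray:
        return self.grid.omega


@dataclass(frozen=True)
class DecomposedField:
    """Scalar complex wave fields u_dcf after directional decomposition.

    ``data`` is indexed ``(direction, component, frequency, x, y, z)``.
    ``directions`` holds the unit propagation vectors as rows; in 2D mode
    they lie in the slice plane (z component zero).
    """

    grid: AcquisitionGrid
    data: np.ndarray
    directions: np.ndarray
    mode: str  # "2d" or "3d"

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.complex128)
        directions = np.asarray(self.directions, dtype=np.float64)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "directions", directions)
        if self.mode not in ("2d", "3d"):
            raise ValueError(f"mode must be '2d' or '3d', got {self.mode!r}")
        g = self.grid
        n_dir = directions.shape[0]
        if directions.ndim != 2 or directions.shape[1] != 3:
            raise ValueError("directions must be an (n, 3) array of unit vectors")
        norms = np.linalg.norm(directions, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-12):
            raise ValueError("direction vectors must have unit norm (tol 1e-12)")
        _require_shape(
            "DecomposedField.data", data, (n_dir, 3, g.n_frequencies) + g.shape
        )

    @property
    def n_directions(self) -> int:
        return self.directions.shape[0]


@dataclass(frozen=True)
class WavenumberMaps:
    """Voxelwise wavenumber estimates with amplitude weights w = |u_dcf|².

    All arrays are indexed ``(direction, component, frequency, x, y, z)``.
    Voxels where the estimate is unusable carry weight 0 (and wavenumber 0),
    so multifrequency compounding is a pure weighted reduction.
    """

    grid: AcquisitionGrid
    k_prime: np.ndarray  # rad/m
    k_doubleprime: np.ndarray  # 1/m
    weights: np.ndarray  # µm², dimensionless up to a common scale

    def __post_init__(self) -> None:
        kp = np.asarray(self.k_prime, dtype=np.float64)
        kpp = np.asarray(self.k_doubleprime, dtype=np.float64)
        w = np.asarray(self.weights, dtype=np.float64)
        for name, arr in (("k_prime", kp), ("k_doubleprime", kpp), ("weights", w)):
            if arr.shape != kp.shape:
                raise ValueError("wavenumber map arrays must share one shape")
            if np.any(arr < 0):
                raise ValueError(f"{name} must be non-negative everywhere")
        object.__setattr__(self, "k_prime", kp)
        object.__setattr__(self, "k_doubleprime", kpp)
        object.__setattr__(self, "weights", w)


@dataclass(frozen=True)
class ParameterMap:
    """Compounded shear-wave-speed and penetration-rate volumes in m/s.

    Invalid voxels (trimmed edge slices, vanishing wave energy) are NaN in
    ``sws``/``pr`` and False in ``valid_mask``.
    """

    grid: AcquisitionGrid
    sws: np.ndarray
    pr: np.ndarray
    valid_mask: np.ndarray
    mode: str  # "2d" or "3d" provenance tag

    def __post_init__(self) -> None:
        sws = np.asarray(self.sws, dtype=np.float64)
        pr = np.asarray(self.pr, dtype=np.float64)
        valid = np.asarray(self.valid_mask, dtype=bool)
        g = self.grid
        _require_shape("ParameterMap.sws", sws, g.shape)
        _require_shape("ParameterMap.pr", pr, g.shape)
        _require_shape("ParameterMap.valid_mask", valid, g.shape)
        if self.mode not in ("2d", "3d"):
            raise ValueError(f"mode must be '2d' or '3d', got {self.mode!r}")
        if np.any(~(sws[valid] > 0)) or np.any(~(pr[valid] > 0)):
            raise ValueError("sws and pr must be strictly positive on valid voxels")
        object.__setattr__(self, "sws", sws)
        object.__setattr__(self, "pr", pr)
        object.__setattr__(self, "valid_mask", valid)

    @property
    def n_valid_slices(self) -> int:
        """Number of slices containing at least one valid voxel."""
        return int(np.sum(self.valid_mask.any(axis=(0, 1))))


@dataclass(frozen=True)
class ComplexModulus:
    """Storage/loss modulus pair G', G'' in Pa with material density ρ."""

    g_storage: np.ndarray | float
    g_loss: np.ndarray | float
    density: float = 1000.0

    def __post_init__(self) -> None:
        gs = np.asarray(self.g_storage, dtype=np.float64)
        gl = np.asarray(self.g_loss, dtype=np.float64)
        if np.any(gs < 0) or np.any(gl < 0):
            raise ValueError("moduli must be non-negative")
        if self.density <= 0:
            raise ValueError("density must be positive")
        if np.any((gs == 0) & (gl == 0)):
            raise ValueError("G' and G'' must not both be zero")
        object.__setattr__(self, "g_storage", gs)
        object.__setattr__(self, "g_loss", gl)

    @property
    def magnitude(self) -> np.ndarray:
        """|G*| = √(G'² + G''²) in Pa."""
        return np.hypot(np.asarray(self.g_storage), np.asarray(self.g_loss))


@dataclass(frozen=True)
class RegionMask:
    """Integer label volume aligned to the acquisition grid."""

    labels: np.ndarray
    names: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError("labels must be an integer volume")
        if labels.ndim != 3:
            raise ValueError("labels must be a 3-D volume")
        if np.any(labels < 0):
            raise ValueError("labels must be non-negative")
        present = set(np.unique(labels).tolist()) - {0}
        missing = present - set(self.names)
        if missing:
            raise ValueError(f"labels without a region name: {sorted(missing)}")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "names", dict(self.names))

    def region(self, label: int) -> np.ndarray:
        """Boolean mask of one region."""
        return self.labels == label


def validate_field(field: TimeSeriesField) -> list[str]:
    """Report invariant violations of a displacement time series.

    Returns an empty list iff the field is well formed.  Violations carry
    voxel/axis context where available.  Construction already enforces the
    shape contract; this reports data-level defects (useful on fields
    assembled from external files).
    """
    violations: list[str] = []
    g = field.grid
    data = field.data
    if data.shape[1] != 3:
        violations.append(
            f"expected 3 motion-encoding components, found {data.shape[1]}"
        )
    if not np.all(np.isfinite(data)):
        bad = np.argwhere(~np.isfinite(data))
        f, c, t, x, y, z = bad[0]
        violations.append(
            f"non-finite displacement at frequency-index {f}, component {c}, "
            f"timestep {t}, voxel ({x}, {y}, {z}) "
            f"({len(bad)} non-finite samples in total)"
        )
    freqs = g.frequencies
    if any(freqs[i + 1] <= freqs[i] for i in range(len(freqs) - 1)):
        violations.append("frequencies not increasing")
    if any(s <= 0 for s in g.spacing):
        violations.append(f"non-positive voxel spacing {g.spacing}")
    return violations
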