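"""NIfTI readers/writers and run configuration.

Two input dialects are supported, because public MRE datasets ship both:

``volume5d``
    One 5-D NIfTI per vibration frequency, shape (nx, ny, nz, T, 3) with
    T phase offsets and 3 motion-encoding components; default filename
    template ``wave_{freq:g}Hz.nii.gz``.
``fileset``
    One 3-D NIfTI per (frequency, component, timestep); default template
    ``wave_{freq:g}Hz_{comp}_t{t:02d}.nii.gz`` with ``comp`` ∈ x, y, z.

Voxel spacing is taken from the NIfTI header (mm).  Parameter maps are
written as float32 with NaN marking invalid voxels (0 m/s would be a
physically meaningful, wrong value), together with a YAML manifest
recording all parameters, the package version, and input checksums.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .datamodel import AcquisitionGrid, ParameterMap, RegionMask, TimeSeriesField
from .decomp2d import Bandpass2DConfig
from .decomp3d import Curl3DConfig
from .inversion import CompoundConfig

__all__ = [
    "RunConfig",
    "read_wavefield",
    "write_wavefield",
    "write_maps",
    "read_parameter_map",
    "write_mask",
    "read_mask",
]

DEFAULT_5D_TEMPLATE = "wave_{freq:g}Hz.nii.gz"
DEFAULT_FILESET_TEMPLATE = "wave_{freq:g}Hz_{comp}_t{t:02d}.nii.gz"
COMPONENTS = ("x", "y", "z")


@dataclass
class RunConfig:
    """Structured run configuration; defaults reproduce the reference
    brain protocol (8 directions / order 3 / 15–250 cycles/m bandpass in
    2D; order 1 / 200 cycles/m lowpass and 20 sphere directions in 3D;
    4 trimmed slices per side)."""

    mode: str = "2d"
    layout: str = "volume5d"
    input_dir: str = "."
    template: str | None = None
    frequencies: tuple[float, ...] = (20.0, 25.0, 30.0, 35.0)
    n_timesteps: int = 8
    bandpass2d: Bandpass2DConfig = field(default_factory=Bandpass2DConfig)
    curl3d: Curl3DConfig = field(default_factory=Curl3DConfig)
    trim_slices: int = 4
    min_cycles_per_fov: float = 1.0
    output_dir: str = "out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("2d", "3d"):
            raise ValueError("mode must be '2d' or '3d'")
        if self.layout not in ("volume5d", "fileset"):
            raise ValueError("layout must be 'volume5d' or 'fileset'")
        if isinstance(self.bandpass2d, dict):
            self.bandpass2d = Bandpass2DConfig(**self.bandpass2d)
        if isinstance(self.curl3d, dict):
            self.curl3d = Curl3DConfig(**self.curl3d)
        self.frequencies = tuple(float(f) for f in self.frequencies)

    @property
    def compound(self) -> CompoundConfig:
        return CompoundConfig(
            trim_slices=self.trim_slices, min_cycles_per_fov=self.min_cycles_per_fov
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_plain(self.to_dict()), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _plain(obj):
    """Recursively convert tuples/numpy scalars for clean YAML output."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _affine(spacing_mm) -> np.ndarray:
    return np.diag(list(spacing_mm) + [1.0])


def _load(path: Path) -> tuple[np.ndarray, tuple[float, ...]]:
    img = nib.load(str(path))
    # zooms are stored as float32 in the header; round to their printable
    # precision so written spacings survive the round trip exactly
    zooms = tuple(float(f"{z:.7g}") for z in img.header.get_zooms()[:3])
    return np.asanyarray(img.dataobj), zooms


def read_wavefield(
    input_dir: str | Path,
    frequencies,
    layout: str = "volume5d",
    template: str | None = None,
    n_timesteps: int | None = None,
) -> TimeSeriesField:
    """Assemble the 5-D displacement series from NIfTI files.

    All headers must agree on shape and voxel spacing and all data must be
    finite; every inconsistent or missing file is reported in one error.
    """
    input_dir = Path(input_dir)
    frequencies = tuple(float(f) for f in frequencies)
    errors: list[str] = []
    volumes: dict = {}
    spacing = None
    shape = None

    def check(path: Path, data, zooms):
        nonlocal spacing, shape
        if not np.all(np.isfinite(data)):
            errors.append(f"{path.name}: non-finite data")
        if spacing is None:
            spacing = zooms
        elif not np.allclose(zooms, spacing):
            errors.append(f"{path.name}: spacing {zooms} != {spacing}")
        if shape is None:
            shape = data.shape[:3]
        elif data.shape[:3] != shape:
            errors.append(f"{path.name}: shape {data.shape[:3]} != {shape}")

    if layout == "volume5d":
        template = template or DEFAULT_5D_TEMPLATE
        for f in frequencies:
            path = input_dir / template.format(freq=f)
            if not path.exists():
                errors.append(f"missing file: {path.name}")
                continue
            data, zooms = _load(path)
            if data.ndim != 5 or data.shape[4] != 3:
                errors.append(
                    f"{path.name}: expected 5-D (nx,ny,nz,T,3), got {data.shape}"
                )
                continue
            check(path, data, zooms)
            volumes[f] = data
        if not errors:
            T = next(iter(volumes.values())).shape[3]
            if any(v.shape[3] != T for v in volumes.values()):
                errors.append("inconsistent number of timesteps across frequencies")
    elif layout == "fileset":
        template = template or DEFAULT_FILESET_TEMPLATE
        if n_timesteps is None:
            raise ValueError("fileset layout requires n_timesteps")
        T = n_timesteps
        for f in frequencies:
            for ci, comp in enumerate(COMPONENTS):
                for t in range(T):
                    path = input_dir / template.format(freq=f, comp=comp, t=t)
                    if not path.exists():
                        errors.append(f"missing file: {path.name}")
                        continue
                    data, zooms = _load(path)
                    if data.ndim != 3:
                        errors.append(f"{path.name}: expected 3-D, got {data.shape}")
                        continue
                    check(path, data, zooms)
                    volumes[(f, ci, t)] = data
    else:
        raise ValueError("layout must be 'volume5d' or 'fileset'")

    if errors:
        raise ValueError("wavefield input errors:\n  " + "\n  ".join(errors))

    if layout == "volume5d":
        T = next(iter(volumes.values())).shape[3]
        grid = AcquisitionGrid(shape, spacing, T, frequencies)
        data = np.empty((len(frequencies), 3, T) + shape)
        for fi, f in enumerate(frequencies):
            # file layout (nx, ny, nz, T, comp) -> (comp, T, nx, ny, nz)
            data[fi] = np.moveaxis(volumes[f], (3, 4), (1, 0))
    else:
        grid = AcquisitionGrid(shape, spacing, T, frequencies)
        data = np.empty((len(frequencies), 3, T) + shape)
        for fi, f in enumerate(frequencies):
            for ci in range(3):
                for t in range(T):
                    data[fi, ci, t] = volumes[(f, ci, t)]
    return TimeSeriesField(grid=grid, data=data)


def write_wavefield(
    field: TimeSeriesField,
    outdir: str | Path,
    layout: str = "volume5d",
    template: str | None = None,
) -> list[Path]:
    """Write a displacement series in one of the two supported dialects
    (float32)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    g = field.grid
    aff = _affine(g.spacing)
    written: list[Path] = []
    if layout == "volume5d":
        template = template or DEFAULT_5D_TEMPLATE
        for fi, f in enumerate(g.frequencies):
            # (comp, T, nx, ny, nz) -> (nx, ny, nz, T, comp)
            vol = np.moveaxis(field.data[fi], (0, 1), (4, 3)).astype(np.float32)
            path = outdir / template.format(freq=f)
            nib.save(nib.Nifti1Image(vol, aff), str(path))
            written.append(path)
    elif layout == "fileset":
        template = template or DEFAULT_FILESET_TEMPLATE
        for fi, f in enumerate(g.frequencies):
            for ci, comp in enumerate(COMPONENTS):
                for t in range(g.n_timesteps):
                    path = outdir / template.format(freq=f, comp=comp, t=t)
                    nib.save(
                        nib.Nifti1Image(
                            field.data[fi, ci, t].astype(np.float32), aff
                        ),
                        str(path),
                    )
                    written.append(path)
    else:
        raise ValueError("layout must be 'volume5d' or 'fileset'")
    return written


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_maps(
    pmap: ParameterMap,
    outdir: str | Path,
    config: RunConfig | None = None,
    input_files: list[str | Path] | None = None,
) -> dict[str, Path]:
    """Write sws.nii.gz, pr.nii.gz (float32, NaN = invalid) and a manifest."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aff = _affine(pmap.grid.spacing)
    paths = {}
    for name, vol in (("sws", pmap.sws), ("pr", pmap.pr)):
        data = np.where(pmap.valid_mask, vol, np.nan).astype(np.float32)
        path = outdir / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(data, aff), str(path))
        paths[name] = path
    manifest = {
        "software": {"name": "kmdev", "version": __version__},
        "mode": pmap.mode,
        "grid": {
            "shape": list(pmap.grid.shape),
            "spacing_mm": list(pmap.grid.spacing),
            "n_timesteps": pmap.grid.n_timesteps,
            "frequencies_hz": list(pmap.grid.frequencies),
        },
        "n_valid_slices": pmap.n_valid_slices,
        "parameters": _plain(config.to_dict()) if config is not None else None,
        "input_checksums": {
            Path(p).name: _sha256(Path(p)) for p in (input_files or [])
        },
    }
    manifest_path = outdir / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(_plain(manifest), sort_keys=True))
    paths["manifest"] = manifest_path
    return paths


def read_parameter_map(
    sws_path: str | Path,
    pr_path: str | Path | None = None,
    mode: str = "2d",
    frequencies=(20.0, 25.0, 30.0, 35.0),
    n_timesteps: int = 8,
) -> ParameterMap:
    """Re-load written maps; NaN voxels become invalid."""
    sws, spacing = _load(Path(sws_path))
    pr = np.full_like(sws, np.nan) if pr_path is None else _load(Path(pr_path))[0]
    valid = np.isfinite(sws) if pr_path is None else np.isfinite(sws) & np.isfinite(pr)
    if pr_path is None:
        pr = np.where(valid, 1.0, np.nan)  # placeholder for SWS-only analyses
    grid = AcquisitionGrid(sws.shape, spacing, n_timesteps, tuple(frequencies))
    return ParameterMap(
        grid=grid,
        sws=np.asarray(sws, dtype=np.float64),
        pr=np.asarray(pr, dtype=np.float64),
        valid_mask=valid,
        mode=mode,
    )


def write_mask(mask: RegionMask, path: str | Path, spacing_mm) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(mask.labels.astype(np.int16), _affine(spacing_mm))
    nib.save(img, str(path))
    names_path = path.parent / (path.name.split(".")[0] + "_labels.yaml")
    names_path.write_text(yaml.safe_dump({int(k): v for k, v in mask.names.items()}))
    return path


def read_mask(path: str | Path) -> RegionMask:
    path = Path(path)
    labels, _ = _load(path)
    names_path = path.parent / (path.name.split(".")[0] + "_labels.yaml")
    names = {}
    if names_path.exists():
        names = {int(k): str(v) for k, v in yaml.safe_load(names_path.read_text()).items()}
    else:
        names = {int(l): f"region_{int(l)}" for l in np.unique(labels) if l != 0}
    return RegionMask(labels=np.asarray(labels).astype(np.int32), names=names)
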