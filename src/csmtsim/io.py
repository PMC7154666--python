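"""Configuration schema, NIfTI exchange, manifests and logging setup.

Volumes are exchanged as NIfTI-1 (.nii.gz) on a 1-mm isotropic RAS grid with
one JSON metadata sidecar per volume; a run manifest records the config hash,
per-file content hashes and all seeds, so a rerun with the same config is
byte-identical (timestamps are confined to logs).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .jsr import FitConfig
from .phantom import (AcquisitionSet, FieldMaps, PhantomVolume, VendorProfile,
                      VolumeRecord, default_vendors)
from .pulse_design import CsmtDesign
from .variability import SubsetSpec, default_subsets

__all__ = ["StudyConfig", "load_config", "config_hash", "setup_logging",
           "save_acquisition", "load_acquisition", "save_maps", "load_maps",
           "write_manifest", "affine_1mm"]

log = logging.getLogger("csmtsim")


def setup_logging(level: str = "INFO") -> None:
    """Route package logs to stderr with levels."""
    h = logging.StreamHandler(sys.stderr)
    h.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("csmtsim")
    root.handlers[:] = [h]
    root.setLevel(level)


# ---------------------------------------------------------------------------
# study configuration
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Everything the end-to-end study needs; every random stage is seeded."""

    seed: int
    shape: tuple = (64, 64, 64)
    voxel_mm: float = 1.0
    tr: float = 7.0
    te: float = 3.5
    snr: float = 100.0
    b1_range: tuple = (0.85, 1.15)
    b0_range_hz: tuple = (-60.0, 60.0)
    erosion_radius_mm: float = 2.0
    fit_subsample: int = 3000
    n_replicates: int = 1
    conditions: tuple = ("native", "harmonized_spoiling", "csmt")
    vendors: tuple = field(default_factory=default_vendors)
    subsets: tuple = field(default_factory=default_subsets)
    csmt_design: CsmtDesign = field(default_factory=CsmtDesign)
    fit_config: FitConfig = field(default_factory=FitConfig)

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("config must carry an explicit seed")
        self.shape = tuple(int(s) for s in self.shape)
        from .variability import CONDITIONS
        for c in self.conditions:
            if c not in CONDITIONS:
                raise ValueError(f"unknown condition {c!r}")


def load_config(path) -> StudyConfig:
    """Read a YAML/JSON study configuration; schema-validated field names."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    if "seed" not in raw:
        raise ValueError("config is missing required field 'seed'")
    known = {f.name for f in dataclasses.fields(StudyConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    kw = dict(raw)
    if "vendors" in kw:
        kw["vendors"] = tuple(VendorProfile(**v) for v in kw["vendors"])
    if "subsets" in kw:
        kw["subsets"] = tuple(
            SubsetSpec(name=s["name"], spgr_fas=tuple(s["spgr_fas"]),
                       bssfp_fas_180=tuple(s["bssfp_fas_180"]),
                       include_bssfp_0=bool(s.get("include_bssfp_0", True)))
            for s in kw["subsets"])
    if "csmt_design" in kw:
        kw["csmt_design"] = CsmtDesign(**kw["csmt_design"])
    if "fit_config" in kw:
        fc = dict(kw["fit_config"])
        for key in ("t1_bounds", "t2_bounds"):
            if key in fc:
                fc[key] = tuple(fc[key])
        kw["fit_config"] = FitConfig(**fc)
    for key in ("shape", "b1_range", "b0_range_hz", "conditions"):
        if key in kw:
            kw[key] = tuple(kw[key])
    return StudyConfig(**kw)


def config_hash(config: StudyConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# NIfTI exchange
# ---------------------------------------------------------------------------

def affine_1mm(voxel_mm: float = 1.0) -> np.ndarray:
    """RAS affine with isotropic voxels, origin at the corner voxel."""
    return np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])


def _write_nifti(data, path, voxel_mm=1.0, dtype=np.float64):
    img = nib.Nifti1Image(np.asarray(data, dtype), affine_1mm(voxel_mm))
    img.to_filename(str(path))


def _read_nifti(path) -> np.ndarray:
    try:
        return np.asarray(nib.load(str(path)).dataobj)
    except Exception as exc:
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def save_acquisition(acq: AcquisitionSet, out_dir, tag: str = "acq") -> Path:
    """Write one AcquisitionSet: image volumes + sidecars + truth + fields."""
    out = Path(out_dir) / tag
    out.mkdir(parents=True, exist_ok=True)
    vm = acq.truth.voxel_size
    names = []
    for i, v in enumerate(acq.volumes):
        name = f"vol{i:02d}_{v.meta['sequence']}_fa{v.meta['fa']:g}"
        _write_nifti(v.data, out / f"{name}.nii.gz", vm)
        (out / f"{name}.json").write_text(json.dumps(v.meta, indent=1))
        names.append(name)
    _write_nifti(acq.truth.labels, out / "labels.nii.gz", vm, dtype=np.int16)
    _write_nifti(acq.fields.b1_scale, out / "b1_scale.nii.gz", vm)
    _write_nifti(acq.fields.b0_hz, out / "b0_hz.nii.gz", vm)
    tissue = {str(k): dataclasses.asdict(t) for k, t in acq.truth.tissue_params.items()}
    (out / "tissue_params.json").write_text(json.dumps(tissue, indent=1))
    (out / "set_meta.json").write_text(json.dumps(
        {**acq.meta, "volumes": names, "voxel_mm": vm}, indent=1))
    return out


def load_acquisition(acq_dir) -> AcquisitionSet:
    acq_dir = Path(acq_dir)
    meta_path = acq_dir / "set_meta.json"
    if not meta_path.exists():
        raise IOError(f"no acquisition manifest (set_meta.json) in {acq_dir}")
    set_meta = json.loads(meta_path.read_text())
    volumes = []
    for name in set_meta["volumes"]:
        data = _read_nifti(acq_dir / f"{name}.nii.gz")
        meta = json.loads((acq_dir / f"{name}.json").read_text())
        volumes.append(VolumeRecord(data=data, meta=meta))
    from .signal_models import TwoPoolTissue
    tissue_raw = json.loads((acq_dir / "tissue_params.json").read_text())
    tissue = {int(k): TwoPoolTissue(**v) for k, v in tissue_raw.items()}
    truth = PhantomVolume(labels=_read_nifti(acq_dir / "labels.nii.gz").astype(np.int16),
                          tissue_params=tissue,
                          voxel_size=set_meta.get("voxel_mm", 1.0))
    fields = FieldMaps(b1_scale=_read_nifti(acq_dir / "b1_scale.nii.gz"),
                       b0_hz=_read_nifti(acq_dir / "b0_hz.nii.gz"))
    return AcquisitionSet(volumes=volumes, fields=fields, truth=truth,
                          meta={k: v for k, v in set_meta.items()
                                if k != "volumes"})


def save_maps(maps: dict, meta: dict, out_dir, tag: str) -> Path:
    """Write fitted parameter maps plus fit-provenance JSON."""
    out = Path(out_dir) / tag
    out.mkdir(parents=True, exist_ok=True)
    for name in ("t1", "t2", "m0", "delta_f", "residual"):
        _write_nifti(maps[name], out / f"{name}.nii.gz", meta.get("voxel_mm", 1.0))
    _write_nifti(maps["converged"].astype(np.uint8), out / "converged.nii.gz",
                 meta.get("voxel_mm", 1.0), dtype=np.uint8)
    _write_nifti(maps["mask"].astype(np.uint8), out / "mask.nii.gz",
                 meta.get("voxel_mm", 1.0), dtype=np.uint8)
    (out / "fit_meta.json").write_text(json.dumps(meta, indent=1))
    return out


def load_maps(map_dir) -> tuple:
    map_dir = Path(map_dir)
    meta = json.loads((map_dir / "fit_meta.json").read_text())
    maps = {name: _read_nifti(map_dir / f"{name}.nii.gz")
            for name in ("t1", "t2", "m0", "delta_f", "residual")}
    maps["converged"] = _read_nifti(map_dir / "converged.nii.gz").astype(bool)
    maps["mask"] = _read_nifti(map_dir / "mask.nii.gz").astype(bool)
    return maps, meta


def write_manifest(out_dir, entries: dict, extra: dict | None = None) -> Path:
    """Manifest with content hashes of every artifact path in ``entries``."""
    out_dir = Path(out_dir)
    manifest = {"files": {}, **(extra or {})}
    for key, path in entries.items():
        p = Path(path)
        if p.is_dir():
            manifest["files"][key] = {
                str(f.relative_to(p)): _sha256(f)
                for f in sorted(p.rglob("*")) if f.is_file()}
        else:
            manifest["files"][key] = _sha256(p)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path
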