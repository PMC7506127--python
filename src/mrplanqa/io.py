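"""File formats, run configuration and artifact manifests.

Grids travel as NIfTI (spacing/origin in the affine; doses as float32
Gy, masks as uint8); tables as CSV; configuration as YAML; the manifest
as JSON with SHA-256 checksums so a re-run with the same seed can be
verified bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional

import nibabel as nib
import numpy as np
import yaml

from . import __version__
from .grid import DoseGrid, StructureMask, StructureSet, VoxelGrid
from .phantom import (
    PerturbationParams,
    PhantomSpec,
    default_perturbations,
    default_spec,
)
from .pqm import PQMTable, default_table, load_table

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "save_config",
    "save_dose",
    "load_dose",
    "save_mask",
    "load_mask",
    "save_structure_set",
    "load_structure_set",
    "Manifest",
    "sha256_of",
]


class ConfigError(ValueError):
    """Aggregated configuration-validation failure."""


# ---------------------------------------------------------------------------
# NIfTI volumes


def _grid_from_nifti(img) -> VoxelGrid:
    aff = img.affine
    spacing = tuple(float(s) for s in np.abs(np.diag(aff)[:3]))
    origin = tuple(float(o) for o in aff[:3, 3])
    return VoxelGrid(tuple(img.shape), spacing, origin)


def save_dose(dose: DoseGrid, path: str | Path) -> None:
    img = nib.Nifti1Image(dose.values.astype(np.float32), dose.grid.affine())
    nib.save(img, str(path))


def load_dose(path: str | Path) -> DoseGrid:
    img = nib.load(str(path))
    return DoseGrid(_grid_from_nifti(img), np.asarray(img.dataobj, dtype=np.float64))


def save_mask(mask: StructureMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), mask.grid.affine())
    nib.save(img, str(path))


def load_mask(path: str | Path, name: Optional[str] = None) -> StructureMask:
    path = Path(path)
    img = nib.load(str(path))
    if name is None:
        name = path.name.split(".")[0]
    voxels = np.asarray(img.dataobj) > 0
    return StructureMask(name, _grid_from_nifti(img), voxels)


def save_structure_set(structs: StructureSet, out_dir: str | Path) -> List[Path]:
    """One NIfTI per structure, named ``<structure>.nii.gz``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in structs:
        p = out_dir / f"{name}.nii.gz"
        save_mask(structs[name], p)
        paths.append(p)
    return paths


def load_structure_set(in_dir: str | Path) -> StructureSet:
    in_dir = Path(in_dir)
    paths = sorted(in_dir.glob("*.nii*"))
    if not paths:
        raise FileNotFoundError(f"no NIfTI masks found in {in_dir}")
    first = load_mask(paths[0])
    structs = StructureSet(first.grid)
    for p in paths:
        structs.add(load_mask(p))
    return structs


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Validated configuration of one end-to-end pipeline run."""

    n_patients: int = 1
    master_seed: int = 0
    output_dir: str = "mrplanqa_out"
    log_level: str = "INFO"
    phantom: PhantomSpec = field(default_factory=default_spec)
    perturbations: Dict[str, PerturbationParams] = field(
        default_factory=default_perturbations
    )
    pqm_table: PQMTable = field(default_factory=default_table)
    pqm_table_path: Optional[str] = None
    render_png: bool = False


_TOP_KEYS = {
    "n_patients",
    "master_seed",
    "output_dir",
    "log_level",
    "phantom",
    "perturbations",
    "pqm_table_path",
    "render_png",
}
_PHANTOM_KEYS = {
    "grid_shape",
    "spacing_mm",
    "body_radius_mm",
    "body_center_xy_mm",
    "ptv_margin_mm",
}
_LOG_LEVELS = {"DEBUG", "INFO", "WARNING", "ERROR"}


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    Missing keys fall back to package defaults (default phantom and
    perturbations, default 15-row PQM table, standard prescriptions).
    Every violated field is reported in one aggregated error.
    """
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")

    errors: List[str] = []
    config = RunConfig()

    for key in raw:
        if key not in _TOP_KEYS:
            errors.append(f"unknown configuration key: {key!r}")

    n_patients = raw.get("n_patients", config.n_patients)
    if not isinstance(n_patients, int) or n_patients < 1:
        errors.append(f"n_patients must be an integer >= 1, got {n_patients!r}")
    else:
        config.n_patients = n_patients

    master_seed = raw.get("master_seed", config.master_seed)
    if not isinstance(master_seed, int):
        errors.append(f"master_seed must be an integer, got {master_seed!r}")
    else:
        config.master_seed = master_seed

    config.output_dir = str(raw.get("output_dir", config.output_dir))
    config.render_png = bool(raw.get("render_png", config.render_png))

    log_level = str(raw.get("log_level", config.log_level)).upper()
    if log_level not in _LOG_LEVELS:
        errors.append(f"log_level must be one of {sorted(_LOG_LEVELS)}, got {log_level!r}")
    else:
        config.log_level = log_level

    phantom_raw = raw.get("phantom", {})
    if not isinstance(phantom_raw, dict):
        errors.append("phantom must be a mapping of phantom overrides")
    else:
        overrides = {}
        for key, value in phantom_raw.items():
            if key not in _PHANTOM_KEYS:
                errors.append(f"unknown phantom key: {key!r}")
            elif key in ("grid_shape", "spacing_mm"):
                overrides[key] = tuple(value)
            elif key == "body_center_xy_mm":
                overrides[key] = tuple(float(v) for v in value)
            else:
                overrides[key] = float(value)
        try:
            config.phantom = replace(default_spec(), **overrides)
        except Exception as exc:  # invalid combination
            errors.append(f"invalid phantom specification: {exc}")

    pert_raw = raw.get("perturbations", {})
    if not isinstance(pert_raw, dict):
        errors.append("perturbations must map condition label -> parameter overrides")
    else:
        perts = default_perturbations()
        pert_fields = {f.name for f in dataclasses.fields(PerturbationParams)}
        for label, params_raw in pert_raw.items():
            if label not in perts:
                errors.append(f"unknown plan condition in perturbations: {label!r}")
                continue
            bad = set(params_raw) - pert_fields
            if bad:
                errors.append(f"unknown perturbation fields for {label}: {sorted(bad)}")
                continue
            if "cavity_shift_direction" in params_raw:
                params_raw = dict(params_raw)
                params_raw["cavity_shift_direction"] = tuple(
                    params_raw["cavity_shift_direction"]
                )
            try:
                perts[label] = replace(perts[label], **params_raw)
            except ValueError as exc:
                errors.append(f"invalid perturbation for {label}: {exc}")
        config.perturbations = perts

    table_path = raw.get("pqm_table_path")
    if table_path is not None:
        config.pqm_table_path = str(table_path)
        resolved = Path(table_path)
        if not resolved.is_absolute():
            resolved = path.parent / resolved
        if not resolved.exists():
            errors.append(f"pqm_table_path does not exist: {table_path}")
        else:
            try:
                config.pqm_table = load_table(resolved)
            except ValueError as exc:
                errors.append(f"invalid PQM table: {exc}")

    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(errors))
    return config


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a configuration back to YAML (round-trips with load_config)."""
    phantom_defaults = default_spec()
    phantom = {}
    for key in sorted(_PHANTOM_KEYS):
        value = getattr(config.phantom, key)
        if value != getattr(phantom_defaults, key):
            phantom[key] = list(value) if isinstance(value, tuple) else value
    perts = {}
    defaults = default_perturbations()
    for label, params in config.perturbations.items():
        diff = {}
        for f in dataclasses.fields(PerturbationParams):
            value = getattr(params, f.name)
            if value != getattr(defaults[label], f.name):
                diff[f.name] = list(value) if isinstance(value, tuple) else value
        if diff:
            perts[label] = diff
    data = {
        "n_patients": config.n_patients,
        "master_seed": config.master_seed,
        "output_dir": config.output_dir,
        "log_level": config.log_level,
        "render_png": config.render_png,
    }
    if phantom:
        data["phantom"] = phantom
    if perts:
        data["perturbations"] = perts
    if config.pqm_table_path is not None:
        data["pqm_table_path"] = config.pqm_table_path
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


# ---------------------------------------------------------------------------
# manifest


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class Manifest:
    """Record of every artifact a pipeline run produced."""

    master_seed: int
    software_version: str = __version__
    records: List[dict] = field(default_factory=list)

    def add(
        self,
        path: Path,
        base_dir: Path,
        kind: str,
        patient: Optional[int] = None,
        condition: Optional[str] = None,
        seed: Optional[int] = None,
    ) -> None:
        self.records.append(
            {
                "path": str(path.relative_to(base_dir)),
                "kind": kind,
                "patient": patient,
                "condition": condition,
                "seed": seed,
                "sha256": sha256_of(path),
            }
        )

    def write(self, path: str | Path) -> None:
        payload = {
            "software_version": self.software_version,
            "master_seed": self.master_seed,
            "records": self.records,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def read(cls, path: str | Path) -> "Manifest":
        payload = json.loads(Path(path).read_text())
        return cls(
            master_seed=payload["master_seed"],
            software_version=payload["software_version"],
            records=payload["records"],
        )

    def verify(self, base_dir: str | Path) -> List[str]:
        """Return a list of problems (missing files, checksum mismatches)."""
        base_dir = Path(base_dir)
        problems = []
        for rec in self.records:
            p = base_dir / rec["path"]
            if not p.exists():
                problems.append(f"missing: {rec['path']}")
            elif sha256_of(p) != rec["sha256"]:
                problems.append(f"checksum mismatch: {rec['path']}")
        return problems
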