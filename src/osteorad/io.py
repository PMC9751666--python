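"""File I/O: voxel volumes (TIFF/NIfTI), YAML dose-model configs, and
atomic table/report writes."""

from __future__ import annotations

import json
import os
import tempfile
from contextlib import contextmanager
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .dosimetry import (
    CA45,
    SR89,
    BetaNuclide,
    DoseModel,
    DosimetryError,
    InjectionEvent,
)
from .morphometry import BinaryVolume, GrayVolume

__all__ = [
    "read_volume",
    "write_volume",
    "load_dose_model",
    "atomic_write_text",
    "write_json",
    "write_csv",
]

_NUCLIDE_PRESETS = {"Ca-45": CA45, "Sr-89": SR89}


@contextmanager
def _atomic_path(path: str | Path):
    """Write-then-rename so partial outputs never masquerade as complete."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    try:
        yield Path(tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def atomic_write_text(path: str | Path, text: str) -> None:
    with _atomic_path(path) as tmp:
        tmp.write_text(text)


def write_json(path: str | Path, obj: Any) -> None:
    atomic_write_text(path, json.dumps(obj, indent=2, default=float) + "\n")


def write_csv(path: str | Path, df) -> None:
    with _atomic_path(path) as tmp:
        df.to_csv(tmp, index=False)


def read_volume(path: str | Path, voxel_size_um: float | None = None) -> GrayVolume:
    """Read a 3D volume from multi-page TIFF or NIfTI.

    ``voxel_size_um`` overrides any metadata; TIFF files carry no reliable
    voxel-size tag in this pipeline, so the flag is required for them.
    """
    path = Path(path)
    suffix = "".join(path.suffixes).lower()
    if suffix.endswith((".tif", ".tiff")):
        import tifffile

        data = np.asarray(tifffile.imread(path))
        if voxel_size_um is None:
            raise DosimetryError(
                "TIFF input requires an explicit voxel size (--voxel-um)"
            )
    elif suffix.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        if voxel_size_um is None:
            zooms = img.header.get_zooms()[:3]
            if len(set(np.round(zooms, 6))) != 1:
                raise DosimetryError("anisotropic NIfTI voxels; pass --voxel-um")
            voxel_size_um = float(zooms[0]) * 1000.0  # NIfTI zooms are mm
    else:
        raise DosimetryError(f"unsupported volume format: {path.name}")
    if data.ndim != 3:
        raise DosimetryError(f"expected a 3D volume, got shape {data.shape}")
    return GrayVolume(data.astype(float), voxel_size_um)


def write_volume(path: str | Path, volume: GrayVolume | BinaryVolume) -> None:
    """Write a volume as multi-page TIFF (masks as uint8 0/255)."""
    import tifffile

    path = Path(path)
    if isinstance(volume, BinaryVolume):
        data = (volume.mask.astype(np.uint8)) * 255
    else:
        data = volume.voxels.astype(np.float32)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, data)


def _build_nuclide(block: dict[str, Any]) -> BetaNuclide:
    if isinstance(block, str):
        try:
            return _NUCLIDE_PRESETS[block]
        except KeyError:
            raise DosimetryError(f"unknown nuclide preset {block!r}") from None
    name = block.get("name", "custom")
    if set(block) <= {"name"} and name in _NUCLIDE_PRESETS:
        return _NUCLIDE_PRESETS[name]
    return BetaNuclide(
        name=name,
        physical_half_life_days=block["half_life_days"],
        mean_beta_energy_MeV=block["mean_beta_energy_MeV"],
        max_beta_energy_MeV=block["max_beta_energy_MeV"],
        beta_yield_per_decay=block.get("beta_yield_per_decay", 1.0),
    )


def load_dose_model(path: str | Path) -> DoseModel:
    """Build a DoseModel from a YAML config.

    Schema::

        nuclide: Ca-45            # preset name, or a block with constants
        schedule:
          - {age_weeks: 4, activity_concentration_Bq_per_g: 37000, body_mass_g: 20}
          - {age_weeks: 7, activity_concentration_Bq_per_g: 37000, body_mass_g: 20}
        calibration_mode: pinned_peak_rate
        peak_dose_rate_mGy_per_day: 29
        absorbed_fraction: 0.9
        retention_fraction: 0.879
        ddref: 1
    """
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise DosimetryError("dose config must be a YAML mapping")
    try:
        nuclide = _build_nuclide(cfg["nuclide"])
        schedule = [
            InjectionEvent(
                age_at_injection_weeks=ev["age_weeks"],
                activity_concentration_Bq_per_g=ev["activity_concentration_Bq_per_g"],
                body_mass_g=ev["body_mass_g"],
            )
            for ev in cfg["schedule"]
        ]
    except KeyError as exc:
        raise DosimetryError(f"dose config missing field {exc}") from None
    kwargs: dict[str, Any] = {}
    for key in (
        "absorbed_fraction",
        "retention_fraction",
        "calibration_mode",
        "source_mass_kg",
        "peak_dose_rate_mGy_per_day",
        "ddref",
    ):
        if key in cfg:
            kwargs[key] = cfg[key]
    if "equilibrium_dose_constant" in cfg:
        kwargs["equilibrium_dose_constant_Gy_kg_per_Bq_s"] = cfg[
            "equilibrium_dose_constant"
        ]
    return DoseModel(nuclide=nuclide, schedule=schedule, **kwargs)
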