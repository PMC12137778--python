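"""Configuration, NIfTI/CSV input-output and provenance plumbing.

NIfTI is the sole volumetric format; voxel sizes travel in the affine/header
(axis order RL x AP x FH) and every simulated output is accompanied by a
JSON provenance sidecar echoing the resolved configuration and seed, so any
seeded run can be reproduced bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from importlib import resources
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .signal_model import SequenceProtocol, TissueParams
from .phantom import ParameterMaps, PARAMETER_NAMES

__all__ = [
    "Presets",
    "RunConfig",
    "load_presets",
    "load_config",
    "make_interleaved_order",
    "read_nifti",
    "write_nifti",
    "write_csv",
    "write_parameter_maps",
    "read_parameter_maps",
    "write_provenance",
]


@dataclass(frozen=True)
class Presets:
    tissues: dict[str, TissueParams]
    protocol: SequenceProtocol


@dataclass
class RunConfig:
    """Resolved run configuration; round-trips losslessly through YAML."""

    tissues: dict[str, TissueParams]
    protocol: SequenceProtocol
    seed: int = 0
    n_coils: int = 8
    noise_sigma: float = 0.0
    b1_scale: float = 1.0
    output_dir: str = "."
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "tissues": {
                name: _tissue_to_dict(t) for name, t in self.tissues.items()
            },
            "protocol": _protocol_to_dict(self.protocol),
            "seed": self.seed,
            "n_coils": self.n_coils,
            "noise_sigma": self.noise_sigma,
            "b1_scale": self.b1_scale,
            "output_dir": str(self.output_dir),
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        tissues = {
            name: _tissue_from_dict(name, td) for name, td in d.get("tissues", {}).items()
        }
        protocol = _protocol_from_dict(d.get("protocol", {}))
        return cls(
            tissues=tissues,
            protocol=protocol,
            seed=int(d.get("seed", 0)),
            n_coils=int(d.get("n_coils", 8)),
            noise_sigma=float(d.get("noise_sigma", 0.0)),
            b1_scale=float(d.get("b1_scale", 1.0)),
            output_dir=str(d.get("output_dir", ".")),
            log_level=str(d.get("log_level", "INFO")),
        )


def _tissue_to_dict(t: TissueParams) -> dict:
    return {
        "t1_free": t.t1_free,
        "t2_free": t.t2_free,
        "bound_fraction": t.bound_fraction,
        "exchange_rate": t.exchange_rate,
        "t1_bound": t.t1_bound,
        "t2_bound": t.t2_bound,
        "lineshape": t.lineshape.value,
        "proton_density": t.proton_density,
    }


def _tissue_from_dict(name: str, d: dict) -> TissueParams:
    known = {
        "t1_free",
        "t2_free",
        "bound_fraction",
        "exchange_rate",
        "t1_bound",
        "t2_bound",
        "lineshape",
        "proton_density",
    }
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"tissue {name!r}: unknown field(s) {sorted(unknown)}")
    try:
        return TissueParams(label=name, **d)
    except (TypeError, ValueError) as err:
        raise ValueError(f"tissue {name!r}: {err}") from err


def _protocol_to_dict(p: SequenceProtocol) -> dict:
    return {
        "tr": p.tr,
        "flip_angle": p.flip_angle,
        "pulse_width": p.pulse_width,
        "sequence": p.sequence.value,
        "fov": list(p.fov),
        "voxel": list(p.voxel),
        "bandwidth_khz": p.bandwidth_khz,
        "n_epg_states": p.n_epg_states,
    }


def _protocol_from_dict(d: dict) -> SequenceProtocol:
    d = dict(d)
    for key in ("fov", "voxel"):
        if key in d:
            d[key] = tuple(float(v) for v in d[key])
    try:
        return SequenceProtocol(**d)
    except (TypeError, ValueError) as err:
        raise ValueError(f"protocol: {err}") from err


def load_presets(path: str | Path | None = None) -> Presets:
    """Load tissue/protocol presets; the bundled 64 mT file by default."""
    if path is None:
        text = resources.files("ulfmt.data").joinpath("presets_64mT.yaml").read_text()
        raw = yaml.safe_load(text)
    else:
        raw = yaml.safe_load(Path(path).read_text())
    tissues = {name: _tissue_from_dict(name, td) for name, td in raw["tissues"].items()}
    protocol = _protocol_from_dict(raw.get("protocol", {}))
    return Presets(tissues=tissues, protocol=protocol)


def load_config(path: str | Path) -> RunConfig:
    """Load a run configuration, filling tissues/protocol from the presets."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    presets = load_presets()
    if "tissues" not in raw:
        raw["tissues"] = {n: _tissue_to_dict(t) for n, t in presets.tissues.items()}
    if "protocol" not in raw:
        raw["protocol"] = _protocol_to_dict(presets.protocol)
    return RunConfig.from_dict(raw)


def make_interleaved_order(angles: Sequence[float]) -> list[float]:
    """Acquisition ordering alternating lowest-remaining, highest-remaining.

    The flip-angle sweep was acquired interleaved (1, 420, 10, 410, ...) so
    that slow drifts spread evenly over the angle range; this reproduces that
    ordering for any sorted angle list. The output is a permutation of the
    input.
    """
    remaining = sorted(float(a) for a in angles)
    if not remaining:
        raise ValueError("angles must be non-empty")
    order = []
    lo, hi = 0, len(remaining) - 1
    take_low = True
    while lo <= hi:
        if take_low:
            order.append(remaining[lo])
            lo += 1
        else:
            order.append(remaining[hi])
            hi -= 1
        take_low = not take_low
    return order


# ---------------------------------------------------------------------------
# Volumes and tables
# ---------------------------------------------------------------------------


def write_nifti(path: str | Path, data: np.ndarray, voxel: Sequence[float]) -> None:
    """Write a volume (3D or 4D) with voxel sizes (mm) on the affine diagonal."""
    affine = np.diag(list(voxel[:3]) + [1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    img.header.set_zooms(tuple(voxel[:3]) + ((1.0,) if np.asarray(data).ndim == 4 else ()))
    nib.save(img, str(path))


def read_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, ...]]:
    """Read a NIfTI volume; returns (data, voxel sizes in mm)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    voxel = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, voxel


def write_csv(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def write_provenance(path: str | Path, provenance: dict) -> None:
    Path(path).write_text(json.dumps(provenance, indent=2, sort_keys=True) + "\n")


def write_parameter_maps(directory: str | Path, maps: ParameterMaps) -> None:
    """Write one NIfTI per tissue parameter plus the integer label map and sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in PARAMETER_NAMES:
        write_nifti(directory / f"{name}.nii.gz", maps.maps[name], maps.voxel)
    write_nifti(directory / "labels.nii.gz", maps.labels.astype(np.int16), maps.voxel)
    sidecar = {
        "voxel_mm": list(maps.voxel),
        "label_names": maps.label_names,
        "tissues": [_tissue_to_dict(t) for t in maps.tissues],
    }
    write_provenance(directory / "phantom.json", sidecar)


def read_parameter_maps(directory: str | Path) -> ParameterMaps:
    directory = Path(directory)
    sidecar = json.loads((directory / "phantom.json").read_text())
    maps = {}
    for name in PARAMETER_NAMES:
        maps[name], voxel = read_nifti(directory / f"{name}.nii.gz")
    labels, voxel = read_nifti(directory / "labels.nii.gz")
    tissues = [
        _tissue_from_dict(name, td)
        for name, td in zip(sidecar["label_names"], sidecar["tissues"])
    ]
    return ParameterMaps(
        maps=maps,
        labels=np.asarray(labels, dtype=np.int16),
        label_names=list(sidecar["label_names"]),
        tissues=tissues,
        voxel=tuple(sidecar["voxel_mm"]),
    )
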