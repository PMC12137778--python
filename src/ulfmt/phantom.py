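"""Digital phantoms and noisy multi-coil acquisition simulation.

Phantoms are defined as labelled geometric compartments (cylinders, spheres,
boxes) rasterized onto a regular voxel grid into per-parameter volumes. Two
ready-made layouts emulate bench experiments used to develop the protocol:

* a six-vial MT phantom — two vials each of water, a dairy-cream-like
  material and a hair-conditioner-like material, spanning bound-pool
  fractions from zero upward;
* a relaxometry array — vials of varying T1/T2 with no bound pool at all,
  used to show that T1/T2 variation alone produces no apparent MT effect.

Acquisition simulation evaluates the steady-state signal once per distinct
tissue class (voxels in a compartment are homogeneous), modulates it by
smooth complex coil sensitivities and adds i.i.d. complex Gaussian noise per
receive channel in the image domain.

Coordinate convention: 0-based voxel indices; world coordinates in mm at
voxel centers, origin at the corner of the field of view; axis order
RL x AP x FH.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .signal_model import (
    ConvergenceError,
    FieldConditions,
    SequenceProtocol,
    TissueParams,
    default_flip_angles,
    ssfp_steady_state,
)
from .image_ops import rss_combine

__all__ = [
    "Geometry",
    "Compartment",
    "PhantomDefinition",
    "ParameterMaps",
    "AcquisitionSim",
    "build_vial_phantom",
    "default_vial_phantom",
    "build_relaxometry_array",
    "simulate_coil_sensitivities",
    "simulate_acquisition",
    "simulate_sweep_dataset",
]

PARAMETER_NAMES = (
    "t1_free",
    "t2_free",
    "bound_fraction",
    "exchange_rate",
    "t1_bound",
    "t2_bound",
    "proton_density",
)


@dataclass(frozen=True)
class Geometry:
    """Axis-aligned primitive in world mm: cylinder (FH axis), sphere or box.

    ``size`` means (radius, height) for a cylinder, (radius,) for a sphere
    and full extents (sx, sy, sz) for a box.
    """

    kind: str
    center: tuple[float, float, float]
    size: tuple[float, ...]

    def __post_init__(self):
        if self.kind not in ("cylinder", "sphere", "box"):
            raise ValueError(f"unknown geometry kind {self.kind!r}")

    def contains(self, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        cx, cy, cz = self.center
        if self.kind == "cylinder":
            r, h = self.size
            return ((x - cx) ** 2 + (y - cy) ** 2 <= r**2) & (np.abs(z - cz) <= h / 2.0)
        if self.kind == "sphere":
            (r,) = self.size
            return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= r**2
        sx, sy, sz = self.size
        return (
            (np.abs(x - cx) <= sx / 2.0)
            & (np.abs(y - cy) <= sy / 2.0)
            & (np.abs(z - cz) <= sz / 2.0)
        )

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.center)
        if self.kind == "cylinder":
            r, h = self.size
            half = np.array([r, r, h / 2.0])
        elif self.kind == "sphere":
            half = np.full(3, self.size[0])
        else:
            half = np.asarray(self.size) / 2.0
        return c - half, c + half


@dataclass(frozen=True)
class Compartment:
    label: str
    geometry: Geometry
    tissue: TissueParams


@dataclass(frozen=True)
class PhantomDefinition:
    """Voxel grid plus labelled compartments; everything else is background."""

    grid: tuple[int, int, int]
    voxel: tuple[float, float, float]
    compartments: tuple[Compartment, ...]
    background_label: str = "background"

    def __post_init__(self):
        if any(n < 1 for n in self.grid) or any(v <= 0 for v in self.voxel):
            raise ValueError("grid dims must be >= 1 and voxel sizes positive")
        names = [c.label for c in self.compartments]
        if len(set(names)) != len(names):
            raise ValueError("compartment labels must be unique")
        fov = np.asarray(self.grid) * np.asarray(self.voxel)
        for comp in self.compartments:
            lo, hi = comp.geometry.bounds()
            if np.any(lo < -1e-9) or np.any(hi > fov + 1e-9):
                raise ValueError(f"compartment {comp.label!r} lies outside the grid")

    @property
    def fov(self) -> tuple[float, float, float]:
        return tuple(n * v for n, v in zip(self.grid, self.voxel))


@dataclass
class ParameterMaps:
    """Voxelwise tissue-parameter volumes plus an integer label map.

    ``labels == 0`` is background; label ``i >= 1`` corresponds to
    ``label_names[i - 1]`` and ``tissues[i - 1]``.
    """

    maps: dict[str, np.ndarray]
    labels: np.ndarray
    label_names: list[str]
    tissues: list[TissueParams]
    voxel: tuple[float, float, float]

    def __post_init__(self):
        shape = self.labels.shape
        for name, vol in self.maps.items():
            if vol.shape != shape:
                raise ValueError(f"map {name!r} shape {vol.shape} != label shape {shape}")

    @property
    def grid(self) -> tuple[int, int, int]:
        return self.labels.shape


@dataclass(frozen=True)
class AcquisitionSim:
    """Receive-chain description: coil count, complex noise level, seed."""

    n_coils: int = 8
    noise_sigma: float = 0.0
    seed: int = 0
    coil_mode: str = "gaussian"  # "gaussian" lobes or "uniform"
    coil_profile_scale: float = 0.7  # lobe width as a fraction of FOV diagonal

    def __post_init__(self):
        if self.n_coils < 1:
            raise ValueError("n_coils must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.coil_mode not in ("gaussian", "uniform"):
            raise ValueError(f"unknown coil_mode {self.coil_mode!r}")


# ---------------------------------------------------------------------------
# Phantom construction
# ---------------------------------------------------------------------------


def _voxel_centers(grid, voxel):
    axes = [(np.arange(n) + 0.5) * v for n, v in zip(grid, voxel)]
    return np.meshgrid(*axes, indexing="ij")


def build_vial_phantom(spec: PhantomDefinition) -> ParameterMaps:
    """Rasterize a phantom definition into parameter maps.

    A voxel belongs to a compartment iff its center lies inside the geometry;
    overlapping compartments are rejected. Background voxels carry zero
    proton density and nominal relaxation times.
    """
    x, y, z = _voxel_centers(spec.grid, spec.voxel)
    labels = np.zeros(spec.grid, dtype=np.int16)
    for i, comp in enumerate(spec.compartments, start=1):
        mask = comp.geometry.contains(x, y, z)
        if np.any(labels[mask] != 0):
            raise ValueError(f"compartment {comp.label!r} overlaps an earlier compartment")
        labels[mask] = i

    maps = {name: np.zeros(spec.grid) for name in PARAMETER_NAMES}
    # background: unit times to keep the volumes physically interpretable
    maps["t1_free"][:] = 1.0
    maps["t2_free"][:] = 1.0
    maps["t1_bound"][:] = 1.0
    maps["t2_bound"][:] = 1.0
    for i, comp in enumerate(spec.compartments, start=1):
        sel = labels == i
        for name in PARAMETER_NAMES:
            maps[name][sel] = getattr(comp.tissue, name)
    return ParameterMaps(
        maps=maps,
        labels=labels,
        label_names=[c.label for c in spec.compartments],
        tissues=[c.tissue for c in spec.compartments],
        voxel=spec.voxel,
    )


def default_vial_phantom(
    tissues: dict[str, TissueParams] | None = None,
    grid: tuple[int, int, int] = (90, 110, 40),
    voxel: tuple[float, float, float] = (2.0, 2.0, 5.0),
    vial_radius_mm: float = 18.0,
    vial_height_mm: float = 120.0,
) -> ParameterMaps:
    """Six-vial MT phantom: 2x water, 2x cream-like, 2x conditioner-like.

    Vials are parallel cylinders (FH axis) arranged in a 2 x 3 pattern in the
    RL-AP plane, mimicking a bundle of sample tubes in the head coil.
    """
    if tissues is None:
        from .io import load_presets

        presets = load_presets()
        tissues = presets.tissues
    required = ("water", "cream_like", "conditioner_like")
    for name in required:
        if name not in tissues:
            raise ValueError(f"tissue preset {name!r} missing")

    fov = np.asarray(grid) * np.asarray(voxel)
    cz = fov[2] / 2.0
    xs = (fov[0] / 2.0 - 22.0, fov[0] / 2.0 + 22.0)
    ys = (fov[1] / 2.0 - 44.0, fov[1] / 2.0, fov[1] / 2.0 + 44.0)
    layout = [
        ("water_1", xs[0], ys[0], "water"),
        ("water_2", xs[1], ys[0], "water"),
        ("cream_1", xs[0], ys[1], "cream_like"),
        ("cream_2", xs[1], ys[1], "cream_like"),
        ("conditioner_1", xs[0], ys[2], "conditioner_like"),
        ("conditioner_2", xs[1], ys[2], "conditioner_like"),
    ]
    comps = tuple(
        Compartment(
            label=name,
            geometry=Geometry("cylinder", (cx, cy, cz), (vial_radius_mm, vial_height_mm)),
            tissue=tissues[key],
        )
        for name, cx, cy, key in layout
    )
    return build_vial_phantom(PhantomDefinition(grid=grid, voxel=tuple(voxel), compartments=comps))


def build_relaxometry_array(
    t1_list: Sequence[float],
    t2_list: Sequence[float],
    grid: tuple[int, int, int] = (90, 110, 40),
    voxel: tuple[float, float, float] = (2.0, 2.0, 5.0),
    vial_radius_mm: float = 8.0,
    n_per_layer: int = 14,
) -> ParameterMaps:
    """Relaxometry array phantom: one vial per (T1, T2) pair, no bound pool.

    Vials are placed on a circle, ``n_per_layer`` per FH layer, emulating a
    multi-compartment quantitative relaxometry phantom. All compartments have
    ``bound_fraction = 0``, so any apparent MT weighting in this phantom
    would be a pure T1/T2 effect.
    """
    t1_list = list(t1_list)
    t2_list = list(t2_list)
    if not t1_list or len(t1_list) != len(t2_list):
        raise ValueError("t1_list and t2_list must be non-empty and of equal length")
    if min(t1_list) <= 0 or min(t2_list) <= 0:
        raise ValueError("relaxation times must be positive")

    fov = np.asarray(grid) * np.asarray(voxel)
    ring_r = 0.5 * min(fov[0], fov[1]) - vial_radius_mm - 2.0
    n_layers = math.ceil(len(t1_list) / n_per_layer)
    layer_h = fov[2] / n_layers
    comps = []
    for idx, (t1, t2) in enumerate(zip(t1_list, t2_list)):
        layer, pos = divmod(idx, n_per_layer)
        theta = 2.0 * math.pi * pos / n_per_layer
        cx = fov[0] / 2.0 + ring_r * math.cos(theta)
        cy = fov[1] / 2.0 + ring_r * math.sin(theta)
        cz = (layer + 0.5) * layer_h
        comps.append(
            Compartment(
                label=f"vial_{idx:02d}",
                geometry=Geometry(
                    "cylinder", (cx, cy, cz), (vial_radius_mm, 0.8 * layer_h)
                ),
                tissue=TissueParams(
                    t1_free=t1, t2_free=t2, bound_fraction=0.0, label=f"vial_{idx:02d}"
                ),
            )
        )
    return build_vial_phantom(
        PhantomDefinition(grid=grid, voxel=tuple(voxel), compartments=tuple(comps))
    )


# ---------------------------------------------------------------------------
# Acquisition simulation
# ---------------------------------------------------------------------------


def simulate_coil_sensitivities(
    grid: tuple[int, int, int],
    n_coils: int,
    seed: int = 0,
    mode: str = "gaussian",
    profile_scale: float = 0.7,
) -> np.ndarray:
    """Smooth complex coil sensitivity volumes, shape (n_coils, *grid).

    ``mode='uniform'`` returns all-ones maps. Otherwise each coil is a
    Gaussian lobe centered on the FOV perimeter (angular position jittered by
    the seeded generator) with a slowly varying phase; magnitudes are
    strictly positive everywhere so the sum-of-squares is bounded away from
    zero inside the object.
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    if mode == "uniform":
        return np.ones((n_coils,) + tuple(grid), dtype=complex)
    rng = np.random.default_rng(seed)
    nx, ny, nz = grid
    x, y, z = np.meshgrid(
        np.linspace(-1, 1, nx), np.linspace(-1, 1, ny), np.linspace(-1, 1, nz), indexing="ij"
    )
    sens = np.empty((n_coils,) + tuple(grid), dtype=complex)
    width = profile_scale * 2.0
    for c in range(n_coils):
        theta = 2.0 * math.pi * (c + 0.15 * rng.standard_normal()) / n_coils
        cx, cy = 1.1 * math.cos(theta), 1.1 * math.sin(theta)
        r2 = (x - cx) ** 2 + (y - cy) ** 2 + 0.5 * z**2
        mag = 0.05 + np.exp(-r2 / (2.0 * width**2))
        phase = 0.5 * (x * math.sin(theta) - y * math.cos(theta)) + 0.1 * rng.standard_normal()
        sens[c] = mag * np.exp(1j * phase)
    return sens


def _signal_lookup(
    maps: ParameterMaps,
    protocol: SequenceProtocol,
    field: FieldConditions,
) -> np.ndarray:
    """Noise-free signal volume: one steady-state solve per tissue class."""
    signal = np.zeros(maps.grid)
    for i, tissue in enumerate(maps.tissues, start=1):
        sel = maps.labels == i
        if not np.any(sel):
            continue
        try:
            sig = ssfp_steady_state(protocol, tissue, field)
        except ConvergenceError as err:
            raise ConvergenceError(
                f"steady state failed for tissue {maps.label_names[i - 1]!r}: {err}",
                err.n_iterations,
                err.last_change,
            ) from err
        signal[sel] = sig.observable(protocol.sequence)
    return signal


def simulate_acquisition(
    maps: ParameterMaps,
    protocol: SequenceProtocol,
    field: FieldConditions = FieldConditions(),
    acq: AcquisitionSim = AcquisitionSim(),
    sensitivities: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-coil complex image stack, shape (n_coils, *grid).

    Voxelwise steady-state signal (cached per tissue class) times coil
    sensitivity plus i.i.d. complex Gaussian noise per channel. Passing the
    same seed and configuration reproduces the output bit for bit.
    """
    if sensitivities is None:
        sensitivities = simulate_coil_sensitivities(
            maps.grid, acq.n_coils, acq.seed, acq.coil_mode, acq.coil_profile_scale
        )
    if sensitivities.shape != (acq.n_coils,) + tuple(maps.grid):
        raise ValueError("sensitivity stack shape does not match n_coils and grid")
    if rng is None:
        rng = np.random.default_rng(acq.seed)
    signal = _signal_lookup(maps, protocol, field)
    data = sensitivities * signal[None]
    if acq.noise_sigma > 0:
        noise = acq.noise_sigma * (
            rng.standard_normal(data.shape) + 1j * rng.standard_normal(data.shape)
        )
        data = data + noise
    return data


def simulate_sweep_dataset(
    maps: ParameterMaps,
    protocol: SequenceProtocol,
    angle_list: Sequence[float] | None = None,
    acq: AcquisitionSim = AcquisitionSim(),
    field: FieldConditions = FieldConditions(),
) -> tuple[np.ndarray, dict]:
    """Coil-combined magnitude stack over a flip-angle sweep, plus provenance.

    One acquisition per angle, combined by root-sum-of-squares and stacked
    along a fourth axis in ascending-angle order. The provenance dict records
    the seed, protocol, angles and the interleaved acquisition order actually
    used on the scanner side (alternating lowest/highest remaining angle).
    """
    from .io import make_interleaved_order

    angles = default_flip_angles() if angle_list is None else np.sort(
        np.asarray(angle_list, dtype=float)
    )
    sens = simulate_coil_sensitivities(
        maps.grid, acq.n_coils, acq.seed, acq.coil_mode, acq.coil_profile_scale
    )
    rng = np.random.default_rng(acq.seed)
    stack = np.empty(tuple(maps.grid) + (angles.size,))
    for i, alpha in enumerate(angles):
        from dataclasses import replace

        coil_images = simulate_acquisition(
            maps,
            replace(protocol, flip_angle=float(alpha)),
            field,
            acq,
            sensitivities=sens,
            rng=rng,
        )
        stack[..., i] = rss_combine(coil_images)
    provenance = {
        "seed": acq.seed,
        "n_coils": acq.n_coils,
        "noise_sigma": acq.noise_sigma,
        "angles_deg": angles.tolist(),
        "acquisition_order_deg": make_interleaved_order(angles.tolist()),
        "tr_ms": protocol.tr,
        "pulse_width_us": protocol.pulse_width,
        "sequence": str(protocol.sequence.value),
        "b1_scale": field.b1_scale,
        "voxel_mm": list(maps.voxel),
        "tissue_labels": maps.label_names,
    }
    return stack, provenance
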