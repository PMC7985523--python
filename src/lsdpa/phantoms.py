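"""Seeded generators for the three synthetic tissue domains.

Three phantom families are produced, each a 2D imaging-plane cross section
(depth along the last axis, surface at z = 0):

* ``generic`` - randomly placed tubular vessels (100% blood volume) in a
  homogeneous background with 0.5% blood volume fraction and mu_s' of
  10 cm^-1; every structure shares one sO2 value drawn uniformly on [0, 1].
* ``flow`` - a single blood-filled tube (150 g/L hemoglobin, sO2 uniform on
  [0, 1], radius uniform on [0.5, 2.5] mm) in an agar background with
  mu_s' = 5 cm^-1 and water content uniform on [50, 100]%; pencil-beam
  illumination.
* ``forearm`` - layered gel pad / epidermis / dermis / muscle geometry with
  embedded vessels, one artery, one vein, and a bone; per-tissue parameters
  sampled from the uniform/Gaussian laws given in
  ``FOREARM_SAMPLING`` (Gaussian draws clipped to [0, 1]).

All sampling is driven by a caller-supplied ``numpy.random.Generator``, so
generation is bit-reproducible given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Optional, Set, Tuple

import numpy as np

from .chromophores import ChromophoreTable, TissueComposition, \
    tissue_absorption, tissue_scattering
from .errors import GenerationError, ValidationError

MM_PER_CM = 10.0

#: forearm per-tissue sampling laws: (kind, lo/mean, hi/sd) on the unit scale
FOREARM_SAMPLING = {
    "dermis_oxy": ("gauss", 0.80, 0.10),
    "muscle_oxy": ("gauss", 0.80, 0.10),
    "artery_oxy": ("gauss", 0.95, 0.05),
    "vein_oxy": ("gauss", 0.70, 0.10),
    "vessel_oxy": ("uniform", 0.0, 1.0),
    "epidermis_melanin": ("gauss", 0.022, 0.01),
    "bone_water": ("gauss", 0.19, 0.01),
}
FOREARM_FIXED = {
    "dermis_bvf": 0.01, "muscle_bvf": 0.01,
    "dermis_water": 0.58, "muscle_water": 0.68,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters for one phantom family."""

    dataset_kind: str
    grid_shape: Tuple[int, int] = (256, 128)   # (ny, nz) voxels
    voxel_size_mm: float = 0.1
    seed: Optional[int] = None
    vessel_count_range: Tuple[int, int] = (1, 5)
    vessel_radius_range_mm: Tuple[float, float] = (0.5, 2.5)
    tube_radius_range_mm: Tuple[float, float] = (0.5, 2.5)
    #: flow-phantom tube center depth; the emulated flow setup has a fixed
    #: geometry and randomizes only radius, water content, and sO2
    tube_depth_mm: float = 6.0
    max_placement_retries: int = 200

    def __post_init__(self) -> None:
        if self.dataset_kind not in ("generic", "flow", "forearm"):
            raise ValidationError(f"unknown dataset kind {self.dataset_kind!r}")
        if min(self.grid_shape) < 4:
            raise ValidationError("grid_shape too small")
        if self.voxel_size_mm <= 0:
            raise ValidationError("voxel_size must be > 0")


@dataclass
class LabeledVolume:
    """Voxel label grid with per-label composition and ground-truth sO2."""

    labels: np.ndarray
    compositions: Dict[int, TissueComposition]
    ground_truth_so2: Dict[int, float]
    label_names: Dict[int, str]
    vessel_labels: Set[int]
    illumination: str
    voxel_size_mm: float
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.compositions)
        if missing:
            raise ValidationError(f"labels without composition: {missing}")
        for lab in self.vessel_labels:
            if self.compositions[lab].blood_volume_fraction != 1.0:
                raise ValidationError("vessel-class label without bvf = 1")
        for so2 in self.ground_truth_so2.values():
            if not 0.0 <= so2 <= 1.0:
                raise ValidationError("ground-truth sO2 outside [0, 1]")

    def so2_map(self) -> np.ndarray:
        """Per-voxel ground-truth sO2 (NaN for labels with no blood)."""
        out = np.full(self.labels.shape, np.nan)
        for lab, so2 in self.ground_truth_so2.items():
            out[self.labels == lab] = so2
        return out

    def vessel_mask(self) -> np.ndarray:
        mask = np.zeros(self.labels.shape, dtype=bool)
        for lab in self.vessel_labels:
            mask |= self.labels == lab
        return mask

    def depth_map_mm(self) -> np.ndarray:
        nz = self.labels.shape[-1]
        depth = (np.arange(nz) + 0.5) * self.voxel_size_mm
        return np.broadcast_to(depth, self.labels.shape)


def _disk_mask(shape: Tuple[int, int], cy: float, cz: float,
               radius_vox: float) -> np.ndarray:
    yy, zz = np.ogrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (zz - cz) ** 2 <= radius_vox ** 2


def _clipped_gauss(rng: np.random.Generator, mean: float, sd: float) -> float:
    return float(np.clip(rng.normal(mean, sd), 0.0, 1.0))


def sample_forearm_tissue_params(rng: np.random.Generator) -> Dict[str, float]:
    """Draw one set of per-tissue forearm parameters (unit fractions)."""
    out = dict(FOREARM_FIXED)
    for key, (kind, a, b) in FOREARM_SAMPLING.items():
        if kind == "uniform":
            out[key] = float(rng.uniform(a, b))
        else:
            out[key] = _clipped_gauss(rng, a, b)
    return out


def sample_generic(spec: PhantomSpec, rng: np.random.Generator
                   ) -> LabeledVolume:
    """Generic tissue phantom: random vessels in a blood-tinted background."""
    ny, nz = spec.grid_shape
    labels = np.zeros((ny, nz), dtype=np.int32)
    so2 = float(rng.uniform(0.0, 1.0))  # shared by every structure
    comps = {0: TissueComposition(blood_volume_fraction=0.005,
                                  oxygenation=so2, mus_prime_ref=10.0)}
    gt = {0: so2}
    names = {0: "background"}
    vessel_labels: Set[int] = set()

    n_vessels = int(rng.integers(spec.vessel_count_range[0],
                                 spec.vessel_count_range[1] + 1))
    for k in range(n_vessels):
        lab = k + 1
        r_mm = float(rng.uniform(*spec.vessel_radius_range_mm))
        r = r_mm / spec.voxel_size_mm
        placed = False
        for _ in range(spec.max_placement_retries):
            cy = rng.uniform(r, ny - r)
            cz = rng.uniform(r + 2.0 / spec.voxel_size_mm, nz - r)
            disk = _disk_mask((ny, nz), cy, cz, r)
            if disk.any():
                placed = True
                break
        if not placed:
            raise GenerationError("vessel placement failed")
        labels[disk] = lab
        comps[lab] = TissueComposition(blood_volume_fraction=1.0,
                                       oxygenation=so2, mus_prime_ref=10.0)
        gt[lab] = so2
        names[lab] = "vessel"
        vessel_labels.add(lab)
    return LabeledVolume(labels, comps, gt, names, vessel_labels,
                         "slab", spec.voxel_size_mm, spec.seed)


def sample_flow(spec: PhantomSpec, rng: np.random.Generator) -> LabeledVolume:
    """Flow-phantom cross section: one blood tube in scattering agar."""
    ny, nz = spec.grid_shape
    r_mm = float(rng.uniform(*spec.tube_radius_range_mm))
    r = r_mm / spec.voxel_size_mm
    if 2 * r >= min(ny, nz):
        raise GenerationError("tube radius exceeds the grid")
    water = float(rng.uniform(0.5, 1.0))
    so2 = float(rng.uniform(0.0, 1.0))
    cy = ny / 2.0
    cz = spec.tube_depth_mm / spec.voxel_size_mm
    if cz - r < 0 or cz + r >= nz:
        raise GenerationError("tube radius exceeds the grid depth")

    labels = np.zeros((ny, nz), dtype=np.int32)
    disk = _disk_mask((ny, nz), cy, cz, r)
    labels[disk] = 1
    comps = {
        0: TissueComposition(water_fraction=water, mus_prime_ref=5.0),
        1: TissueComposition(blood_volume_fraction=1.0, oxygenation=so2,
                             mus_prime_ref=5.0),
    }
    gt = {0: 0.0, 1: so2}
    names = {0: "agar", 1: "tube"}
    return LabeledVolume(labels, comps, gt, names, {1}, "pencil",
                         spec.voxel_size_mm, spec.seed)


def sample_forearm(spec: PhantomSpec, rng: np.random.Generator
                   ) -> LabeledVolume:
    """Layered forearm phantom with vessels, artery, vein, and bone."""
    ny, nz = spec.grid_shape
    vx = spec.voxel_size_mm
    params = sample_forearm_tissue_params(rng)

    # layer boundaries (mm below the probe surface)
    gel_mm, epi_mm, dermis_mm = 1.0, 0.15, 1.5
    z_mm = (np.arange(nz) + 0.5) * vx
    labels = np.zeros((ny, nz), dtype=np.int32)
    labels[:, z_mm >= gel_mm] = 1                                  # epidermis
    labels[:, z_mm >= gel_mm + epi_mm] = 2                         # dermis
    labels[:, z_mm >= gel_mm + epi_mm + dermis_mm] = 3             # muscle

    comps = {
        0: TissueComposition(mus_prime_ref=1.0),                   # gel pad
        1: TissueComposition(melanin_fraction=params["epidermis_melanin"],
                             mus_prime_ref=20.0, scatter_power=1.5),
        2: TissueComposition(blood_volume_fraction=params["dermis_bvf"],
                             oxygenation=params["dermis_oxy"],
                             water_fraction=params["dermis_water"],
                             mus_prime_ref=20.0, scatter_power=1.5),
        3: TissueComposition(blood_volume_fraction=params["muscle_bvf"],
                             oxygenation=params["muscle_oxy"],
                             water_fraction=params["muscle_water"],
                             mus_prime_ref=8.0, scatter_power=0.5),
    }
    gt = {0: 0.0, 1: 0.0, 2: params["dermis_oxy"], 3: params["muscle_oxy"]}
    names = {0: "gel_pad", 1: "epidermis", 2: "dermis", 3: "muscle"}
    vessel_labels: Set[int] = set()

    tissue_top = gel_mm + epi_mm
    next_label = 4

    def place_tube(radius_mm: float, z_range_mm: Tuple[float, float],
                   name: str, oxy: float, water: float = 0.0,
                   is_vessel: bool = True,
                   mus_prime: float = 10.0, power: float = 0.5) -> None:
        nonlocal next_label
        r = radius_mm / vx
        for _ in range(spec.max_placement_retries):
            cy = rng.uniform(r, ny - r)
            cz = rng.uniform(max(z_range_mm[0] / vx, r),
                             min(z_range_mm[1] / vx, nz - 1))
            disk = _disk_mask((ny, nz), cy, cz, r)
            # keep structures inside dermis/muscle (never the gel/epidermis)
            if disk.any() and z_mm[np.where(disk)[1]].min() > tissue_top:
                labels[disk] = next_label
                break
        else:
            raise GenerationError(f"{name} placement failed")
        if is_vessel:
            comps[next_label] = TissueComposition(
                blood_volume_fraction=1.0, oxygenation=oxy,
                mus_prime_ref=mus_prime, scatter_power=power)
            vessel_labels.add(next_label)
            gt[next_label] = oxy
        else:  # bone
            comps[next_label] = TissueComposition(
                water_fraction=water, mus_prime_ref=20.0, scatter_power=0.65)
            gt[next_label] = 0.0
        names[next_label] = name
        next_label += 1

    depth_mm = nz * vx
    place_tube(float(rng.uniform(2.0, 4.0)),
               (0.6 * depth_mm, 0.95 * depth_mm), "bone", 0.0,
               water=params["bone_water"], is_vessel=False)
    n_vessels = int(rng.integers(spec.vessel_count_range[0],
                                 spec.vessel_count_range[1] + 1))
    for _ in range(n_vessels):
        place_tube(float(rng.uniform(*spec.vessel_radius_range_mm)),
                   (tissue_top + 0.3, 0.8 * depth_mm), "vessel",
                   float(rng.uniform(0.0, 1.0)))
    place_tube(float(rng.uniform(0.8, 1.8)),
               (tissue_top + 0.5, 0.6 * depth_mm), "artery",
               params["artery_oxy"])
    place_tube(float(rng.uniform(0.8, 2.2)),
               (tissue_top + 0.3, 0.5 * depth_mm), "vein",
               params["vein_oxy"])
    return LabeledVolume(labels, comps, gt, names, vessel_labels,
                         "slab", vx, spec.seed)


_SAMPLERS: Dict[str, Callable] = {
    "generic": sample_generic,
    "flow": sample_flow,
    "forearm": sample_forearm,
}


def sample_phantom(spec: PhantomSpec, rng: np.random.Generator
                   ) -> LabeledVolume:
    """Dispatch to the family-specific generator."""
    return _SAMPLERS[spec.dataset_kind](spec, rng)


def optical_volume(vol: LabeledVolume, wavelength_nm: float,
                   table: ChromophoreTable):
    """Per-voxel (mu_a, mu_s, g) grids at one wavelength."""
    mu_a = np.zeros(vol.labels.shape)
    mu_s = np.zeros(vol.labels.shape)
    g = np.zeros(vol.labels.shape)
    for lab in np.unique(vol.labels):
        comp = vol.compositions.get(int(lab))
        if comp is None:
            raise ValidationError(f"label {lab} has no composition")
        where = vol.labels == lab
        mu_a[where] = tissue_absorption(comp, wavelength_nm, table)
        ms, ga = tissue_scattering(comp, wavelength_nm)
        mu_s[where] = ms
        g[where] = ga
    return mu_a, mu_s, g


def save_phantom_hdf5(vol: LabeledVolume, group) -> None:
    """Serialize a labeled volume into an open HDF5 group."""
    group.create_dataset("labels", data=vol.labels)
    labs = sorted(vol.compositions)
    group.create_dataset("label_ids", data=np.array(labs))
    group.create_dataset(
        "so2", data=np.array([vol.ground_truth_so2[k] for k in labs]))
    group.attrs["voxel_size_mm"] = vol.voxel_size_mm
    group.attrs["illumination"] = vol.illumination
    if vol.seed is not None:
        group.attrs["seed"] = vol.seed
    group.attrs["vessel_labels"] = sorted(vol.vessel_labels)
    for k in labs:
        c = vol.compositions[k]
        group.attrs[f"comp_{k}"] = [
            c.blood_volume_fraction, c.oxygenation, c.melanin_fraction,
            c.water_fraction, c.hemoglobin_concentration, c.mus_prime_ref,
            c.scatter_power, c.anisotropy]
        group.attrs[f"name_{k}"] = vol.label_names.get(k, str(k))


def load_phantom_hdf5(group) -> LabeledVolume:
    labs = [int(k) for k in group["label_ids"][()]]
    so2 = group["so2"][()]
    comps, names = {}, {}
    for i, k in enumerate(labs):
        v = group.attrs[f"comp_{k}"]
        comps[k] = TissueComposition(*[float(x) for x in v])
        names[k] = str(group.attrs[f"name_{k}"])
    return LabeledVolume(
        labels=group["labels"][()],
        compositions=comps,
        ground_truth_so2={k: float(so2[i]) for i, k in enumerate(labs)},
        label_names=names,
        vessel_labels=set(int(x) for x in group.attrs["vessel_labels"]),
        illumination=str(group.attrs["illumination"]),
        voxel_size_mm=float(group.attrs["voxel_size_mm"]),
        seed=int(group.attrs["seed"]) if "seed" in group.attrs else None,
    )
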