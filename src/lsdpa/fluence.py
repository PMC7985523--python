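"""Optical forward models: light fluence and initial pressure.

Two fluence models are provided.  ``fluence_layered`` is a fast
deterministic column-wise model: along the beam axis the fluence decays as
exp(-integral of mu_eff), with mu_eff = sqrt(3*mu_a*(mu_a+mu_s')) in
scattering media (diffusion approximation) and mu_eff = mu_a (Beer-Lambert)
where mu_s' = 0.  ``fluence_mc`` is a seeded voxel Monte Carlo random walk
(hop/drop/spin with a Henyey-Greenstein phase function, continuous
absorption along voxel-clipped path segments, Russian-roulette termination)
in full 3D.

The initial pressure is p0 = Gamma * mu_a * phi, with a wavelength-
independent Grueneisen parameter Gamma (default 1; the absolute scale is
discarded later by sum-to-one spectrum normalization).

Conventions: depth axis is the last array axis, tissue surface at z = 0,
voxel centers at (i + 0.5) * voxel size.  Fluence maps are normalized so
that the surface-incident fluence is 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ValidationError

MM_PER_CM = 10.0


@dataclass
class FluenceMap:
    """Wavelength-resolved fluence grid (dimensionless, surface = 1)."""

    values: np.ndarray
    wavelength: float
    illumination: str
    voxel_size_mm: float
    #: MC energy bookkeeping (absorbed/escaped/roulette_net/injected);
    #: empty for deterministic models
    energy_ledger: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise ValidationError("fluence must be finite and >= 0")
        self.values = v


@dataclass
class InitialPressureImage:
    """Single-wavelength initial-pressure grid, p0 = Gamma*mu_a*phi."""

    values: np.ndarray
    wavelength: float
    gruneisen: float = 1.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise ValidationError("p0 must be finite and >= 0")
        self.values = v


@dataclass
class MultispectralStack:
    """Stack of p0 images over a wavelength grid, shape (n_lambda, ny, nz)."""

    values: np.ndarray
    wavelengths_nm: np.ndarray
    voxel_size_mm: float
    model: str = "layered"
    gruneisen: float = 1.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.values.shape[0] != self.wavelengths_nm.size:
            raise ValidationError("stack/wavelength length mismatch")

    def to_hdf5(self, group) -> None:
        group.create_dataset("p0", data=self.values)
        group.create_dataset("wavelengths_nm", data=self.wavelengths_nm)
        group.attrs["voxel_size_mm"] = self.voxel_size_mm
        group.attrs["model"] = self.model
        group.attrs["gruneisen"] = self.gruneisen
        if self.seed is not None:
            group.attrs["seed"] = self.seed

    @classmethod
    def from_hdf5(cls, group) -> "MultispectralStack":
        return cls(
            values=group["p0"][()],
            wavelengths_nm=group["wavelengths_nm"][()],
            voxel_size_mm=float(group.attrs["voxel_size_mm"]),
            model=str(group.attrs.get("model", "layered")),
            gruneisen=float(group.attrs.get("gruneisen", 1.0)),
            seed=int(group.attrs["seed"]) if "seed" in group.attrs else None,
        )


@dataclass(frozen=True)
class MCConfig:
    """Monte Carlo run parameters."""

    photon_count: int = 100_000
    seed: int = 0
    boundary: str = "absorbing"
    roulette_threshold: float = 1e-4
    roulette_survival: float = 0.1
    max_steps: int = 200_000

    def __post_init__(self) -> None:
        if self.photon_count < 1:
            raise ValidationError("photon_count must be >= 1")
        if self.boundary != "absorbing":
            raise ValidationError("only absorbing boundaries are implemented")


def fluence_layered(mu_a_grid, mu_s_prime_grid, voxel_size_mm: float,
                    illumination: str = "slab",
                    wavelength: float = float("nan")) -> FluenceMap:
    """Deterministic column-wise fluence along the depth (last) axis.

    phi at a voxel center integrates mu_eff over the half voxel plus all
    voxels above it in the same column.
    """
    mu_a = np.asarray(mu_a_grid, dtype=float)
    mu_sp = np.asarray(mu_s_prime_grid, dtype=float)
    if mu_a.shape != mu_sp.shape:
        raise ValidationError("mu_a and mu_s' grids must share a shape")
    if np.any(mu_a < 0) or np.any(mu_sp < 0):
        raise ValidationError("optical coefficients must be >= 0")
    mu_eff = np.where(mu_sp > 0, np.sqrt(3.0 * mu_a * (mu_a + mu_sp)), mu_a)
    dz_cm = voxel_size_mm / MM_PER_CM
    tau = np.cumsum(mu_eff, axis=-1) * dz_cm - 0.5 * mu_eff * dz_cm
    return FluenceMap(np.exp(-tau), wavelength, illumination, voxel_size_mm)


# ---------------------------------------------------------------------------
# Monte Carlo
# ---------------------------------------------------------------------------

def _hg_scatter(direction: np.ndarray, g: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    """Henyey-Greenstein redirection of unit vectors (vectorized)."""
    n = direction.shape[0]
    u = rng.random(n)
    cos_t = np.empty(n)
    iso = np.abs(g) < 1e-8
    cos_t[iso] = 1.0 - 2.0 * u[iso]
    ga = g[~iso]
    tmp = (1.0 - ga * ga) / (1.0 - ga + 2.0 * ga * u[~iso])
    cos_t[~iso] = (1.0 + ga * ga - tmp * tmp) / (2.0 * ga)
    np.clip(cos_t, -1.0, 1.0, out=cos_t)
    sin_t = np.sqrt(1.0 - cos_t * cos_t)
    phi = 2.0 * np.pi * rng.random(n)
    cos_p, sin_p = np.cos(phi), np.sin(phi)

    ux, uy, uz = direction[:, 0], direction[:, 1], direction[:, 2]
    near_pole = np.abs(uz) > 0.99999
    denom = np.sqrt(np.maximum(1.0 - uz * uz, 1e-30))
    new = np.empty_like(direction)
    new[:, 0] = (sin_t * (ux * uz * cos_p - uy * sin_p) / denom + ux * cos_t)
    new[:, 1] = (sin_t * (uy * uz * cos_p + ux * sin_p) / denom + uy * cos_t)
    new[:, 2] = -sin_t * cos_p * denom + uz * cos_t
    # photons traveling (anti)parallel to z need the degenerate formula
    new[near_pole, 0] = sin_t[near_pole] * cos_p[near_pole]
    new[near_pole, 1] = sin_t[near_pole] * sin_p[near_pole]
    new[near_pole, 2] = cos_t[near_pole] * np.sign(uz[near_pole])
    new /= np.linalg.norm(new, axis=1, keepdims=True)
    return new


def fluence_mc(mu_a_grid, mu_s_grid, g_grid, voxel_size_mm: float,
               illumination: str = "pencil",
               cfg: Optional[MCConfig] = None,
               wavelength: float = float("nan")) -> FluenceMap:
    """Voxel Monte Carlo fluence on a 3D grid (x, y, z), beam along +z.

    Uses a track-length fluence estimator with continuous absorption:
    photon weight decays by exp(-mu_a*ds) along each voxel-clipped segment,
    and each voxel accumulates the path integral of the weight.  This gives
    the exact Beer-Lambert profile in non-scattering media and a finite
    fluence estimate in mu_a = 0 voxels.  The energy ledger satisfies
    absorbed + escaped + roulette_net + residual = injected, where
    roulette_net is killed-minus-gained roulette weight.
    """
    cfg = cfg or MCConfig()
    mu_a = np.ascontiguousarray(mu_a_grid, dtype=float)
    mu_s = np.ascontiguousarray(mu_s_grid, dtype=float)
    g = np.ascontiguousarray(g_grid, dtype=float)
    if mu_a.ndim != 3 or mu_a.shape != mu_s.shape or mu_a.shape != g.shape:
        raise ValidationError("MC grids must be 3D and share a shape")
    if np.any(mu_a < 0) or np.any(mu_s < 0):
        raise ValidationError("optical coefficients must be >= 0")
    if np.any(np.abs(g) >= 1.0):
        raise ValidationError("anisotropy |g| must be < 1")
    if illumination not in ("pencil", "slab"):
        raise ValidationError(f"unknown illumination {illumination!r}")

    nx, ny, nz = mu_a.shape
    dv = voxel_size_mm / MM_PER_CM  # voxel edge, cm
    extent = np.array([nx, ny, nz], dtype=float) * dv
    rng = np.random.default_rng(cfg.seed)
    n = int(cfg.photon_count)

    pos = np.zeros((n, 3))
    if illumination == "pencil":
        pos[:, 0] = (nx / 2.0) * dv
        pos[:, 1] = (ny / 2.0) * dv
        beam_area = dv * dv
    else:
        pos[:, 0] = rng.random(n) * extent[0]
        pos[:, 1] = rng.random(n) * extent[1]
        beam_area = extent[0] * extent[1]
    pos[:, 2] = 1e-12
    direction = np.zeros((n, 3))
    direction[:, 2] = 1.0
    weight = np.ones(n)
    tau = -np.log(rng.random(n))  # scattering optical depth to next event

    track = np.zeros(mu_a.size)
    flat_a = mu_a.ravel()
    flat_s = mu_s.ravel()
    flat_g = g.ravel()
    absorbed = 0.0
    escaped = 0.0
    roulette_net = 0.0
    eps_push = 1e-9 * dv

    for _ in range(cfg.max_steps):
        if pos.shape[0] == 0:
            break
        iv = np.floor(pos / dv).astype(np.int64)
        np.clip(iv, 0, [nx - 1, ny - 1, nz - 1], out=iv)
        flat = (iv[:, 0] * ny + iv[:, 1]) * nz + iv[:, 2]
        va, vs, vg = flat_a[flat], flat_s[flat], flat_g[flat]

        # distance to the nearest voxel face along the flight direction
        with np.errstate(divide="ignore", invalid="ignore"):
            step_up = ((iv + 1) * dv - pos) / direction
            step_dn = (iv * dv - pos) / direction
        t_face = np.where(direction > 0, step_up,
                          np.where(direction < 0, step_dn, np.inf))
        t_bound = np.maximum(t_face.min(axis=1), 0.0)
        with np.errstate(divide="ignore"):
            t_scat = np.where(vs > 0, tau / vs, np.inf)
        ds = np.minimum(t_bound, t_scat)

        att = np.exp(-va * ds)
        with np.errstate(divide="ignore", invalid="ignore"):
            seg = np.where(va > 0, weight * (1.0 - att) / va, weight * ds)
        np.add.at(track, flat, seg)
        absorbed += float(np.sum(weight * (1.0 - att)))
        weight = weight * att
        tau = tau - vs * ds
        pos = pos + direction * ds[:, None]

        scattered = t_scat <= t_bound
        if np.any(scattered):
            direction[scattered] = _hg_scatter(
                direction[scattered], vg[scattered], rng)
            tau[scattered] = -np.log(rng.random(int(scattered.sum())))
        pos[~scattered] += direction[~scattered] * eps_push

        out = np.any((pos <= 0) | (pos >= extent), axis=1)
        # absorbing z=0 top surface too; photons exactly on a lateral/bottom
        # face count as escaped
        escaped += float(np.sum(weight[out]))
        alive = ~out

        low = alive & (weight < cfg.roulette_threshold)
        if np.any(low):
            survive = rng.random(int(low.sum())) < cfg.roulette_survival
            idx = np.flatnonzero(low)
            killed_idx = idx[~survive]
            grown_idx = idx[survive]
            roulette_net += float(np.sum(weight[killed_idx]))
            roulette_net -= float(np.sum(
                weight[grown_idx] * (1.0 / cfg.roulette_survival - 1.0)))
            weight[grown_idx] /= cfg.roulette_survival
            alive[killed_idx] = False

        pos, direction, weight, tau = (
            pos[alive], direction[alive], weight[alive], tau[alive])

    residual = float(np.sum(weight))
    fluence = track.reshape(mu_a.shape) * beam_area / (dv ** 3 * n)
    ledger = {
        "injected": float(n),
        "absorbed": absorbed,
        "escaped": escaped,
        "roulette_net": roulette_net,
        "residual": residual,
    }
    return FluenceMap(fluence, wavelength, illumination, voxel_size_mm,
                      energy_ledger=ledger)


def initial_pressure(mu_a_grid, fluence: FluenceMap,
                     gruneisen: float = 1.0) -> InitialPressureImage:
    """p0 = Gamma * mu_a * phi, elementwise."""
    mu_a = np.asarray(mu_a_grid, dtype=float)
    if mu_a.shape != fluence.values.shape:
        raise ValidationError("mu_a and fluence shapes differ")
    return InitialPressureImage(gruneisen * mu_a * fluence.values,
                                fluence.wavelength, gruneisen)


def simulate_multispectral(vol, wavelengths_nm, table, model: str = "layered",
                           mc_config: Optional[MCConfig] = None,
                           gruneisen: float = 1.0,
                           slab_thickness_voxels: int = 15
                           ) -> MultispectralStack:
    """Simulate one p0 image per wavelength for a labeled 2D volume.

    ``model="layered"`` runs the deterministic column model on the imaging
    plane; ``model="mc"`` extrudes the plane into a thin 3D slab, runs the
    voxel Monte Carlo per wavelength (seed offset by the wavelength index),
    and returns the central sheet.
    """
    from .phantoms import optical_volume  # deferred: avoids import cycle

    wavelengths = np.asarray(wavelengths_nm, dtype=float)
    maps = []
    for k, wl in enumerate(wavelengths):
        mu_a, mu_s, g = optical_volume(vol, wl, table)
        if model == "layered":
            mu_sp = mu_s * (1.0 - g)
            phi = fluence_layered(mu_a, mu_sp, vol.voxel_size_mm,
                                  vol.illumination, wavelength=wl)
            p0 = initial_pressure(mu_a, phi, gruneisen)
        elif model == "mc":
            cfg = mc_config or MCConfig()
            cfg_k = MCConfig(photon_count=cfg.photon_count,
                             seed=cfg.seed + k, boundary=cfg.boundary,
                             roulette_threshold=cfg.roulette_threshold,
                             roulette_survival=cfg.roulette_survival,
                             max_steps=cfg.max_steps)
            nxt = slab_thickness_voxels
            ext = lambda a: np.broadcast_to(a, (nxt,) + a.shape).copy()
            phi3 = fluence_mc(ext(mu_a), ext(mu_s), ext(g),
                              vol.voxel_size_mm, vol.illumination, cfg_k,
                              wavelength=wl)
            phi = FluenceMap(phi3.values[nxt // 2], wl, vol.illumination,
                             vol.voxel_size_mm)
            p0 = initial_pressure(mu_a, phi, gruneisen)
        else:
            raise ValidationError(f"unknown fluence model {model!r}")
        maps.append(p0.values)
    seed = mc_config.seed if (model == "mc" and mc_config) else None
    return MultispectralStack(np.stack(maps), wavelengths, vol.voxel_size_mm,
                              model=model, gruneisen=gruneisen, seed=seed)
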