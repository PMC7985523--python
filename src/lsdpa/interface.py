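"""Configuration, wavelength plumbing, and the end-to-end pipeline.

``run_in_silico_experiment`` is the core driver: it generates phantoms of
one family, simulates multispectral initial-pressure stacks, extracts a
labeled spectra dataset, trains the LSD regressor, and evaluates both LSD
and the linear-unmixing baseline on the held-out test split.
``run_pipeline`` wraps it with file outputs and a reproducibility manifest.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from . import evaluation, lsd_model, phantoms, spectra, unmixing
from .chromophores import ChromophoreTable, load_chromophore_table
from .errors import ConfigError, DataError
from .fluence import MCConfig, simulate_multispectral

#: the 17 acquisition wavelengths of the flow-phantom setup (nm)
FLOW_WAVELENGTHS = (660, 664, 680, 684, 694, 700, 708, 715, 730, 735,
                    760, 770, 775, 779, 800, 850, 950)

_PRESET_GRIDS = {
    "generic": {"start": 700, "stop": 950, "step": 10},
    "forearm": {"start": 700, "stop": 950, "step": 10},
    "flow": list(FLOW_WAVELENGTHS),
}


def resolve_wavelengths(spec) -> np.ndarray:
    """Resolve a wavelength specification to an explicit sorted nm grid.

    Accepts a preset name ("generic" | "flow" | "forearm"), an explicit
    sequence, or a dict with start/stop/step.
    """
    if isinstance(spec, str):
        if spec not in _PRESET_GRIDS:
            raise ConfigError(f"unknown wavelength preset {spec!r}")
        spec = _PRESET_GRIDS[spec]
    if isinstance(spec, dict):
        try:
            start, stop, step = (float(spec["start"]), float(spec["stop"]),
                                 float(spec["step"]))
        except KeyError as exc:
            raise ConfigError("wavelength dict needs start/stop/step") from exc
        if step <= 0 or stop < start:
            raise ConfigError("descending or empty wavelength spec")
        grid = np.arange(start, stop + 0.5 * step, step)
    else:
        grid = np.asarray(sorted(float(x) for x in spec))
    if grid.size < 2:
        raise ConfigError("need at least 2 wavelengths (unmixing requires 2)")
    if np.any(np.diff(grid) <= 0):
        raise ConfigError("wavelength grid must be strictly increasing")
    return grid


@dataclass
class PipelineConfig:
    """Validated configuration of one end-to-end run."""

    dataset_kind: str
    wavelengths: object = None          # None -> family preset grid
    n_spectra: int = 100_000
    max_phantoms: int = 1000
    #: SLSQP is the LU cost driver; the baseline is evaluated on a seeded
    #: subsample of the test split of at most this many rows
    lu_max_rows: int = 2500
    grid_shape: Tuple[int, int] = (256, 128)
    voxel_size_mm: float = 0.1
    fluence_model: str = "layered"
    mc_photons: int = 100_000
    noise_sigma_frac: float = 0.003
    cnr_threshold: float = 2.0
    lsd_profile: str = "desk"           # "desk" | "full"
    #: per-field overrides of the LSD training config (e.g. {"epochs": 4})
    lsd_overrides: Optional[dict] = None
    evaluate_lu: bool = True
    seed: int = 0
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.dataset_kind not in ("generic", "flow", "forearm"):
            raise ConfigError(f"unknown dataset kind {self.dataset_kind!r}")
        if self.wavelengths is None:
            self.wavelengths = self.dataset_kind
        self.wavelength_grid = resolve_wavelengths(self.wavelengths)
        if self.n_spectra < 1 or self.max_phantoms < 1:
            raise ConfigError("n_spectra and max_phantoms must be positive")
        if self.fluence_model not in ("layered", "mc"):
            raise ConfigError("fluence_model must be 'layered' or 'mc'")
        if self.lsd_profile not in ("desk", "full"):
            raise ConfigError("lsd_profile must be 'desk' or 'full'")
        if not 0 <= self.noise_sigma_frac < 1:
            raise ConfigError("noise_sigma_frac must lie in [0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f)
        if not isinstance(raw, dict):
            raise ConfigError("config file must hold a mapping")
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "grid_shape" in raw:
            raw["grid_shape"] = tuple(raw["grid_shape"])
        return cls(**raw)

    def lsd_config(self) -> lsd_model.LSDConfig:
        from dataclasses import replace

        n = int(self.wavelength_grid.size)
        model_seed = (self.seed * 10007 + 11) % (2 ** 31)
        if self.lsd_profile == "full":
            cfg = lsd_model.LSDConfig(n_inputs=n, seed=model_seed)
        else:
            cfg = lsd_model.LSDConfig.desk_scale(n, seed=model_seed)
        if self.lsd_overrides:
            cfg = replace(cfg, **self.lsd_overrides)
        return cfg


@dataclass
class ExperimentResult:
    """Outputs of one in-silico train/evaluate experiment."""

    kind: str
    dataset: spectra.SpectraDataset
    model: lsd_model.TrainedLSDModel
    test_indices: np.ndarray
    lsd_estimates: np.ndarray
    lsd_summary: evaluation.ErrorSummary
    lu_estimates: Optional[np.ndarray] = None
    lu_summary: Optional[evaluation.ErrorSummary] = None
    n_phantoms: int = 0
    #: positions within the test split the LU baseline was evaluated on
    lu_rows: Optional[np.ndarray] = None


def load_preset(name: str) -> PipelineConfig:
    """Load one of the bundled preset configs (generic/flow/forearm)."""
    from importlib import resources

    path = resources.files("lsdpa.data.presets").joinpath(f"{name}.yaml")
    try:
        raw = yaml.safe_load(path.read_text())
    except FileNotFoundError as exc:
        raise ConfigError(f"no bundled preset {name!r}") from exc
    if "grid_shape" in raw:
        raw["grid_shape"] = tuple(raw["grid_shape"])
    return PipelineConfig(**raw)


def generate_training_data(cfg: PipelineConfig,
                           table: Optional[ChromophoreTable] = None
                           ) -> Tuple[spectra.SpectraDataset, int]:
    """Simulate phantoms until the spectra budget is met; returns dataset.

    Phantom sampling, forward simulation, and extraction noise all derive
    from ``cfg.seed``.
    """
    table = table or load_chromophore_table()
    rng_phantom = np.random.default_rng((cfg.seed * 10007 + 1) % (2 ** 31))
    rng_noise = np.random.default_rng((cfg.seed * 10007 + 2) % (2 ** 31))
    spec = phantoms.PhantomSpec(cfg.dataset_kind, cfg.grid_shape,
                                cfg.voxel_size_mm, seed=cfg.seed)
    mc_cfg = MCConfig(photon_count=cfg.mc_photons,
                      seed=(cfg.seed * 10007 + 3) % (2 ** 31))
    parts: List[spectra.SpectraDataset] = []
    total = 0
    n_phantoms = 0
    while total < cfg.n_spectra and n_phantoms < cfg.max_phantoms:
        vol = phantoms.sample_phantom(spec, rng_phantom)
        stack = simulate_multispectral(
            vol, cfg.wavelength_grid, table, model=cfg.fluence_model,
            mc_config=mc_cfg if cfg.fluence_model == "mc" else None)
        part = spectra.build_dataset(
            [stack], [vol], cnr_threshold=cfg.cnr_threshold,
            noise_sigma_frac=cfg.noise_sigma_frac, rng=rng_noise)
        if len(part):
            part.phantom_id[:] = n_phantoms
            parts.append(part)
            total += len(part)
        n_phantoms += 1
    if not parts:
        raise DataError("no spectra could be extracted")
    return spectra.SpectraDataset.concatenate(parts), n_phantoms


def run_in_silico_experiment(cfg: PipelineConfig,
                             table: Optional[ChromophoreTable] = None
                             ) -> ExperimentResult:
    """Generate, train, and evaluate one synthetic-domain experiment."""
    table = table or load_chromophore_table()
    dataset, n_phantoms = generate_training_data(cfg, table)
    lsd_cfg = cfg.lsd_config()
    model = lsd_model.train(dataset, lsd_cfg)
    _, _, idx_test = lsd_model.split_dataset(dataset, lsd_cfg)
    if idx_test.size == 0:
        raise DataError("test split is empty")
    x_test = dataset.spectra[idx_test]
    y_test = dataset.labels[idx_test]
    est = model.predict(x_test)
    lsd_summary = evaluation.evaluate_estimates(est, y_test)

    lu_est = lu_summary = None
    lu_rows = np.arange(idx_test.size)
    if cfg.evaluate_lu:
        if idx_test.size > cfg.lu_max_rows:
            lu_rng = np.random.default_rng((cfg.seed * 10007 + 17) % (2 ** 31))
            lu_rows = np.sort(lu_rng.choice(idx_test.size, cfg.lu_max_rows,
                                            replace=False))
        lu_est = np.array([
            unmixing.linear_unmix(row, dataset.wavelengths_nm, table).so2
            for row in x_test[lu_rows]])
        finite = np.isfinite(lu_est)
        lu_summary = evaluation.evaluate_estimates(
            np.clip(lu_est[finite], 0.0, 1.0), y_test[lu_rows][finite])
    return ExperimentResult(cfg.dataset_kind, dataset, model, idx_test,
                            est, lsd_summary, lu_est, lu_summary, n_phantoms,
                            lu_rows)


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config: dict
    package_version: str
    stages: List[str]
    hashes: Dict[str, str]
    timestamps: Dict[str, float]

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(self.__dict__, f, indent=2, default=str)


def _digest(*arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> RunManifest:
    """Execute simulate -> extract -> train -> evaluate, writing artifacts."""
    from . import __version__

    if cfg.out_dir is None:
        raise ConfigError("run_pipeline needs cfg.out_dir")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = ["simulate", "extract", "train", "evaluate"]
    hashes: Dict[str, str] = {}
    stamps: Dict[str, float] = {}

    result = run_in_silico_experiment(cfg)
    stamps["simulate"] = stamps["extract"] = time.time()
    hashes["simulate"] = hashes["extract"] = _digest(
        result.dataset.spectra, result.dataset.labels)

    import h5py

    with h5py.File(out / "dataset.h5", "w") as f:
        g = f.create_group("dataset")
        result.dataset.to_hdf5(g)
        g.attrs["seed"] = cfg.seed
        g.attrs["config_hash"] = _digest(
            np.frombuffer(repr(cfg).encode(), dtype=np.uint8))
    result.dataset.to_csv(out / "dataset.csv")
    with h5py.File(out / "model.h5", "w") as f:
        result.model.to_hdf5(f.create_group("model"))
    stamps["train"] = time.time()
    hashes["train"] = _digest(*result.model.model.weights)

    report = {"lsd": result.lsd_summary.as_dict(),
              "n_phantoms": result.n_phantoms,
              "n_test": int(result.test_indices.size),
              "seed": cfg.seed}
    if result.lu_summary is not None:
        report["lu"] = result.lu_summary.as_dict()
    with open(out / "report.json", "w") as f:
        json.dump(report, f, indent=2)
    stamps["evaluate"] = time.time()
    hashes["evaluate"] = _digest(result.lsd_estimates)

    manifest = RunManifest(
        config={k: (list(v) if isinstance(v, tuple) else v)
                for k, v in cfg.__dict__.items()
                if k != "wavelength_grid"},
        package_version=__version__,
        stages=stages, hashes=hashes, timestamps=stamps)
    manifest.to_json(out / "manifest.json")
    return manifest
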