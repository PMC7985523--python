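"""Pixel-spectrum extraction and labeled-dataset construction.

A pixel spectrum is the p0 value at one pixel as a function of wavelength,
normalized so its components sum to one — the normalization discards the
amplitude (and with it any device calibration) and keeps only the spectral
shape.  Region-of-interest selection mirrors typical photoacoustic
workflows: a contrast-to-noise-ratio threshold at the 800 nm isosbestic
anchor, an absolute amplitude threshold, a minimum connected-component
size, and frame averaging.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import DataError, NormalizationError, NumericalError, \
    ValidationError
from .fluence import MultispectralStack
from .phantoms import LabeledVolume

NORMALIZATION_ATOL = 1e-9
ISOSBESTIC_NM = 800.0


@dataclass
class PixelSpectrum:
    """One per-pixel p0 vector over the wavelength grid."""

    values: np.ndarray
    wavelength_grid: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.wavelength_grid = np.asarray(self.wavelength_grid, dtype=float)
        if self.values.shape != self.wavelength_grid.shape:
            raise ValidationError("spectrum/wavelength length mismatch")
        if self.normalized and abs(self.values.sum() - 1.0) > NORMALIZATION_ATOL:
            raise ValidationError("normalized spectrum does not sum to 1")


def normalize_spectrum(values, wavelength_grid=None) -> PixelSpectrum:
    """Sum-to-one normalization of a raw non-negative spectrum."""
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise NormalizationError("raw spectrum has negative entries")
    total = v.sum()
    if total <= 0:
        raise NormalizationError("cannot normalize an all-zero spectrum")
    wl = (np.arange(v.size, dtype=float)
          if wavelength_grid is None else wavelength_grid)
    return PixelSpectrum(v / total, wl, normalized=True)


def cnr_mask(image, background_region, threshold: float = 2.0) -> np.ndarray:
    """Pixels whose contrast-to-noise ratio against a background is >= t.

    CNR(x) = (S(x) - mean_bg) / std_bg.
    """
    img = np.asarray(image, dtype=float)
    bg = np.asarray(background_region, dtype=bool)
    if bg.shape != img.shape:
        raise ValidationError("background region shape mismatch")
    if not bg.any():
        raise ValidationError("background region is empty")
    mean_bg = img[bg].mean()
    std_bg = img[bg].std()
    if std_bg <= 0:
        raise NumericalError("background has zero variance")
    return (img - mean_bg) / std_bg >= threshold


def amplitude_mask(image, threshold: float = 2e4) -> np.ndarray:
    """Pixels strictly above an absolute signal threshold."""
    return np.asarray(image, dtype=float) > threshold


_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def filter_min_size(mask, min_pixels: int = 20) -> np.ndarray:
    """Drop 4-connected components smaller than ``min_pixels``."""
    m = np.asarray(mask, dtype=bool)
    if min_pixels <= 1 or not m.any():
        return m.copy()
    labeled, n = ndimage.label(m, structure=_FOUR_CONN)
    sizes = np.bincount(labeled.ravel())
    keep = np.flatnonzero(sizes >= min_pixels)
    keep = keep[keep != 0]
    return np.isin(labeled, keep)


def average_frames(frame_sequence, k: int = 10) -> np.ndarray:
    """Arithmetic mean of the first ``k`` consecutive frames."""
    frames = np.asarray(frame_sequence, dtype=float)
    if frames.shape[0] < k:
        raise DataError(f"need >= {k} frames, got {frames.shape[0]}")
    return frames[:k].mean(axis=0)


@dataclass
class SpectraDataset:
    """Matrix of normalized pixel spectra with sO2 labels and metadata."""

    spectra: np.ndarray           # (N, n) rows sum to 1
    labels: np.ndarray            # (N,) sO2 fractions
    wavelengths_nm: np.ndarray
    phantom_id: np.ndarray        # (N,) int
    depth_mm: np.ndarray          # (N,) float
    tissue_label: np.ndarray      # (N,) int

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.labels = np.asarray(self.labels, dtype=float)
        if self.spectra.ndim != 2:
            raise ValidationError("spectra must be a 2D matrix")
        if self.spectra.shape[0] != self.labels.size:
            raise ValidationError("spectra/label count mismatch")
        if self.spectra.shape[1] != np.asarray(self.wavelengths_nm).size:
            raise ValidationError("spectra/wavelength length mismatch")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() > 1):
            raise ValidationError("labels outside [0, 1]")
        if self.spectra.size and np.max(np.abs(
                self.spectra.sum(axis=1) - 1.0)) > NORMALIZATION_ATOL:
            raise ValidationError("dataset rows must sum to 1")

    def __len__(self) -> int:
        return self.spectra.shape[0]

    @classmethod
    def empty(cls, wavelengths_nm) -> "SpectraDataset":
        n = np.asarray(wavelengths_nm).size
        z = np.zeros(0)
        return cls(np.zeros((0, n)), z, np.asarray(wavelengths_nm, float),
                   z.astype(int), z, z.astype(int))

    @classmethod
    def concatenate(cls, parts: Sequence["SpectraDataset"]) -> "SpectraDataset":
        parts = [p for p in parts if len(p)]
        if not parts:
            raise DataError("nothing to concatenate")
        wl = parts[0].wavelengths_nm
        return cls(
            np.vstack([p.spectra for p in parts]),
            np.concatenate([p.labels for p in parts]),
            wl,
            np.concatenate([p.phantom_id for p in parts]),
            np.concatenate([p.depth_mm for p in parts]),
            np.concatenate([p.tissue_label for p in parts]),
        )

    def to_dataframe(self) -> pd.DataFrame:
        cols = {f"wl_{w:g}": self.spectra[:, i]
                for i, w in enumerate(self.wavelengths_nm)}
        cols.update(so2=self.labels, phantom_id=self.phantom_id,
                    depth_mm=self.depth_mm, tissue_label=self.tissue_label)
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_hdf5(self, group) -> None:
        group.create_dataset("spectra", data=self.spectra)
        group.create_dataset("so2", data=self.labels)
        group.create_dataset("wavelengths_nm", data=self.wavelengths_nm)
        group.create_dataset("phantom_id", data=self.phantom_id)
        group.create_dataset("depth_mm", data=self.depth_mm)
        group.create_dataset("tissue_label", data=self.tissue_label)

    @classmethod
    def from_hdf5(cls, group) -> "SpectraDataset":
        return cls(group["spectra"][()], group["so2"][()],
                   group["wavelengths_nm"][()], group["phantom_id"][()],
                   group["depth_mm"][()], group["tissue_label"][()])


def extract_pixel_spectra(stack_values: np.ndarray,
                          mask: np.ndarray) -> np.ndarray:
    """Rows of raw per-pixel spectra for every masked pixel.

    ``stack_values`` has shape (n_lambda, ny, nz); rows follow
    ``np.flatnonzero(mask)`` order (row-major over (y, z))."""
    return stack_values[:, mask].T


def build_dataset(p0_stacks: Iterable[MultispectralStack],
                  volumes: Iterable[LabeledVolume],
                  cnr_threshold: float = 2.0,
                  noise_sigma_frac: float = 0.003,
                  min_component_pixels: int = 0,
                  rng: Optional[np.random.Generator] = None
                  ) -> SpectraDataset:
    """Extract labeled, normalized vessel spectra from simulated stacks.

    Gaussian noise with sigma = ``noise_sigma_frac`` * max(stack) is added
    before masking (noise-free simulations would have unbounded CNR); the
    ROI is vessel-class pixels whose CNR at the 800 nm anchor (nearest grid
    wavelength), computed against the non-vessel background, is >=
    ``cnr_threshold``.  Each surviving pixel yields one sum-normalized row
    labeled with that pixel's ground-truth sO2.
    """
    rng = rng or np.random.default_rng(0)
    parts: List[SpectraDataset] = []
    wavelengths = None
    for pid, (stack, vol) in enumerate(zip(p0_stacks, volumes)):
        wavelengths = stack.wavelengths_nm
        values = stack.values
        if noise_sigma_frac > 0:
            sigma = noise_sigma_frac * values.max()
            values = values + rng.normal(0.0, sigma, values.shape)
        values = np.clip(values, 0.0, None)
        i_ref = int(np.argmin(np.abs(wavelengths - ISOSBESTIC_NM)))
        vmask = vol.vessel_mask()
        roi = vmask & cnr_mask(values[i_ref], ~vmask, cnr_threshold)
        if min_component_pixels > 1:
            roi = filter_min_size(roi, min_component_pixels)
        if not roi.any():
            continue
        raw = extract_pixel_spectra(values, roi)
        sums = raw.sum(axis=1)
        ok = sums > 0
        spectra = raw[ok] / sums[ok, None]
        gt = vol.so2_map()[roi][ok]
        depth = vol.depth_map_mm()[roi][ok]
        tlab = vol.labels[roi][ok]
        parts.append(SpectraDataset(
            spectra, gt, wavelengths,
            np.full(spectra.shape[0], pid, dtype=int), depth, tlab))
    if not parts:
        if wavelengths is None:
            raise DataError("no stacks supplied")
        return SpectraDataset.empty(wavelengths)
    return SpectraDataset.concatenate(parts)
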