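"""Linear spectral unmixing baseline for sO2 estimation.

Each pixel spectrum is fitted as a non-negative combination of the Hb and
HbO2 whole-blood absorption endmembers sampled on the spectrum's
wavelength grid (SLSQP from the starting point (0.5, 0.5)); the oxygen
saturation is the coefficient ratio a_HbO2 / (a_Hb + a_HbO2), which is
invariant to any positive rescaling of the input spectrum.  Linear
unmixing ignores the fluence, so its estimates degrade with spectral
coloring at depth — it is the reference method the learned regressor is
compared against.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy.optimize import minimize

from .chromophores import ChromophoreTable
from .errors import ValidationError


@dataclass
class UnmixResult:
    """Fitted endmember weights and the derived sO2."""

    coef_hb: float
    coef_hbo2: float
    so2: float            # NaN if both coefficients vanish
    residual_norm: float


def endmember_matrix(wavelengths_nm, table: ChromophoreTable) -> np.ndarray:
    """(n, 2) matrix of [mu_a_Hb, mu_a_HbO2] columns on a wavelength grid."""
    wl = np.asarray(wavelengths_nm, dtype=float)
    return np.column_stack([table.hb(wl), table.hbo2(wl)])


def linear_unmix(spectrum_values, wavelengths_nm, table: ChromophoreTable,
                 bounded: bool = True, tol: float = 1e-10) -> UnmixResult:
    """Constrained least-squares fit of Hb/HbO2 to one spectrum."""
    s = np.asarray(spectrum_values, dtype=float)
    wl = np.asarray(wavelengths_nm, dtype=float)
    if s.shape != wl.shape or s.ndim != 1:
        raise ValidationError("spectrum/wavelength shape mismatch")
    if wl.size < 2:
        raise ValidationError("unmixing needs at least 2 wavelengths")
    endmembers = endmember_matrix(wl, table)

    def objective(a):
        r = endmembers @ a - s
        return 0.5 * float(r @ r)

    def gradient(a):
        return endmembers.T @ (endmembers @ a - s)

    bounds = [(0.0, None), (0.0, None)] if bounded else None
    res = minimize(objective, x0=np.array([0.5, 0.5]), jac=gradient,
                   method="SLSQP", bounds=bounds, tol=tol,
                   options={"maxiter": 200})
    a_hb, a_hbo2 = (max(res.x[0], 0.0), max(res.x[1], 0.0)) if bounded \
        else (res.x[0], res.x[1])
    total = a_hb + a_hbo2
    so2 = a_hbo2 / total if total > 1e-12 else float("nan")
    residual = float(np.linalg.norm(endmembers @ res.x - s))
    return UnmixResult(float(a_hb), float(a_hbo2), float(so2), residual)


def unmix_image(stack_values: np.ndarray, wavelengths_nm, mask,
                table: ChromophoreTable,
                bounded: bool = True) -> Tuple[np.ndarray, np.ndarray]:
    """Per-pixel sO2 and residual maps inside a mask (NaN outside)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stack_values.shape[1:]:
        raise ValidationError("mask shape does not match the image")
    so2_map = np.full(mask.shape, np.nan)
    res_map = np.full(mask.shape, np.nan)
    flat = np.flatnonzero(mask)
    raw = stack_values[:, mask].T
    for i, row in enumerate(raw):
        r = linear_unmix(row, wavelengths_nm, table, bounded=bounded)
        so2_map.ravel()[flat[i]] = r.so2
        res_map.ravel()[flat[i]] = r.residual_norm
    return so2_map, res_map


def grid_search_unmix(spectrum_values, wavelengths_nm,
                      table: ChromophoreTable,
                      n_grid: int = 2001) -> float:
    """Brute-force sO2 by scanning the mixing ratio; oracle for tests.

    For any scale c > 0, the best fit of c*(so2*HbO2 + (1-so2)*Hb) over c
    at fixed so2 is a 1D least-squares solve, so scanning so2 on a grid
    bounds the constrained two-parameter fit.
    """
    s = np.asarray(spectrum_values, dtype=float)
    endmembers = endmember_matrix(wavelengths_nm, table)
    ratios = np.linspace(0.0, 1.0, n_grid)
    best_so2, best_res = float("nan"), np.inf
    for ratio in ratios:
        e = endmembers @ np.array([1.0 - ratio, ratio])
        denom = float(e @ e)
        c = max(float(e @ s) / denom, 0.0) if denom > 0 else 0.0
        res = float(np.linalg.norm(c * e - s))
        if res < best_res:
            best_res, best_so2 = res, float(ratio)
    return best_so2
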