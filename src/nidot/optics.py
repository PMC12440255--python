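"""Hemoglobin optics: extinction coefficients and the Beer-Lambert algebra.

The same 2x2 extinction matrix is used by the synthetic forward model (Hb ->
optical density) and by the modified Beer-Lambert inversion (OD -> Hb), so
the round trip is exact by construction.
"""

from __future__ import annotations

import numpy as np

#: Molar extinction coefficients, cm^-1 / (mol/L), natural-log convention,
#: from the Gratzer/Prahl hemoglobin compilation at the two default LUMO-style
#: wavelengths. Keys are wavelength (nm); values are (HbO2, HbR).
EXTINCTION_CM_M: dict[float, tuple[float, float]] = {
    735.0: (450.0, 1102.2),
    850.0: (1058.0, 691.3),
}

#: Unit conversion: cm^-1 M^-1  ->  mm^-1 uM^-1.
_CM_M_TO_MM_UM = 1e-7

#: Differential pathlength factor appropriate for the infant head at both
#: wavelengths.
DEFAULT_DPF = 5.1


def extinction_matrix(wavelengths_nm: tuple[float, float]) -> np.ndarray:
    """2x2 matrix E with E[i] = (eps_HbO, eps_HbR) at wavelength i, mm^-1 uM^-1.

    Raises ``KeyError`` for wavelengths not in the shipped table; callers may
    pass a custom matrix to the conversion routines instead.
    """
    rows = []
    for wl in wavelengths_nm:
        if wl not in EXTINCTION_CM_M:
            raise KeyError(
                f"no shipped extinction coefficients at {wl} nm; "
                "supply an explicit extinction matrix"
            )
        rows.append(EXTINCTION_CM_M[wl])
    return np.asarray(rows, dtype=float) * _CM_M_TO_MM_UM


def hb_to_od(
    dhbo: np.ndarray,
    dhbr: np.ndarray,
    distance_mm: float,
    dpf: float = DEFAULT_DPF,
    extinction: np.ndarray | None = None,
    wavelengths_nm: tuple[float, float] = (735.0, 850.0),
) -> np.ndarray:
    """Forward Beer-Lambert: Hb changes (uM) -> OD changes at two wavelengths.

    Returns an array of shape (2, n_times): rows follow ``wavelengths_nm``.
    """
    E = extinction_matrix(wavelengths_nm) if extinction is None else np.asarray(extinction)
    hb = np.vstack([np.atleast_1d(dhbo), np.atleast_1d(dhbr)])
    return (E @ hb) * distance_mm * dpf


def od_to_hb(
    od_pair: np.ndarray,
    distance_mm: float,
    dpf: float = DEFAULT_DPF,
    extinction: np.ndarray | None = None,
    wavelengths_nm: tuple[float, float] = (735.0, 850.0),
) -> np.ndarray:
    """Invert the modified Beer-Lambert law for one source-detector pair.

    ``od_pair`` is (2, n_times), rows ordered as ``wavelengths_nm``. Returns
    (2, n_times): rows (dHbO, dHbR) in uM.
    """
    E = extinction_matrix(wavelengths_nm) if extinction is None else np.asarray(extinction)
    if abs(np.linalg.det(E)) < 1e-18:
        raise ValueError("extinction matrix is singular; cannot unmix chromophores")
    L = distance_mm * dpf
    return np.linalg.solve(E, np.atleast_2d(od_pair) / L)
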