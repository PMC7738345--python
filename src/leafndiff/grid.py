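"""The fixed 401-1000 nm spectral grid shared by every stage of the pipeline.

All sample tables, difference sets and reductions operate on leaf reflectance
sampled at 1 nm from 401 to 1000 nm inclusive: 600 bands.  Band index ``i``
(0-based) corresponds to wavelength ``401 + i`` nm.
"""

from __future__ import annotations

import numpy as np

WL_MIN: int = 401
WL_MAX: int = 1000
N_BANDS: int = WL_MAX - WL_MIN + 1  # 600

REFLECTANCE_COLUMNS = [f"R{wl}" for wl in range(WL_MIN, WL_MAX + 1)]
DIFFERENCE_COLUMNS = [f"D{wl}" for wl in range(WL_MIN, WL_MAX + 1)]


def wavelengths() -> np.ndarray:
    """Wavelength of every band, in nm (length 600)."""
    return np.arange(WL_MIN, WL_MAX + 1, dtype=float)


def band_index(wavelength_nm: float) -> int:
    """0-based band index of a wavelength on the grid."""
    idx = int(round(wavelength_nm)) - WL_MIN
    if not 0 <= idx < N_BANDS:
        raise ValueError(f"wavelength {wavelength_nm} nm is outside the "
                         f"{WL_MIN}-{WL_MAX} nm grid")
    return idx


def band_wavelength(index: int) -> int:
    """Wavelength (nm) of a 0-based band index."""
    if not 0 <= index < N_BANDS:
        raise ValueError(f"band index {index} outside 0-{N_BANDS - 1}")
    return WL_MIN + index
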