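"""Optical traits of Symbiodiniaceae in hospite.

From the reflectance at the chlorophyll-a absorption peak (675 nm) the
estimated absorbance is De675 = log10(1 / R675); dividing by the areal
photosymbiont density and converting from decadic to natural log gives
the effective light-absorption cross-section per symbiont cell,

    a*_sym = (De675 / density) * ln(10)    [m^2 per cell].

a*_sym rises as cells are lost (self-shading relaxes), which is why cell
loss under heat stress increases the light dose experienced by each
remaining photosymbiont.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["estimated_absorbance", "specific_absorption", "annotate_physiology"]


def estimated_absorbance(r675):
    """Decadic estimated absorbance De675 = log10(1 / R675).

    ``r675`` must lie in (0, 1]; full reflectance (1.0) gives absorbance 0.
    Accepts scalars or arrays.
    """
    r = np.asarray(r675, dtype=float)
    if np.any(~np.isfinite(r)) or np.any(r <= 0) or np.any(r > 1):
        raise ValueError("r675 must be finite and in (0, 1]")
    out = np.log10(1.0 / r)
    return float(out) if np.isscalar(r675) else out


def specific_absorption(de675, density):
    """Symbiont-specific absorption a*_sym = (De675 / density) * ln(10).

    ``density`` is photosymbiont cells per m^2 (> 0); the result has units
    m^2 per cell.  Strictly decreasing in density and increasing in De675.
    """
    d = np.asarray(de675, dtype=float)
    n = np.asarray(density, dtype=float)
    if np.any(~np.isfinite(d)) or np.any(d < 0):
        raise ValueError("de675 must be finite and >= 0")
    if np.any(~np.isfinite(n)) or np.any(n <= 0):
        raise ValueError("density must be finite and > 0")
    out = d / n * np.log(10.0)
    scalar = np.isscalar(de675) and np.isscalar(density)
    return float(out) if scalar else out


def annotate_physiology(records: pd.DataFrame) -> pd.DataFrame:
    """Add ``de675`` and ``a_sym`` columns to a physiology record table.

    Expects columns ``r675`` and ``density`` (cells per m^2); returns a
    copy with the two derived optical traits appended.
    """
    missing = [c for c in ("r675", "density") if c not in records.columns]
    if missing:
        raise KeyError(f"physiology table missing columns: {missing}")
    out = records.copy()
    out["de675"] = estimated_absorbance(out["r675"].to_numpy())
    out["a_sym"] = specific_absorption(
        out["de675"].to_numpy(), out["density"].to_numpy()
    )
    return out
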