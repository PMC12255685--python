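"""Optical constants and the modified Beer-Lambert relation.

A single extinction-coefficient table is used by both the simulator's
forward model (concentration -> optical density -> intensity) and the
analysis inverse (optical density -> concentration), which guarantees that
the two are exact inverses of each other.

Coefficients are the Gratzer/Prahl compilation of hemoglobin molar
extinction, in base-10 units of cm^-1 / (mol/l); they are converted to
natural-log units internally because optical density here is defined with
the natural logarithm, OD = -ln(I / mean(I)).
"""

from __future__ import annotations

import numpy as np

WAVELENGTHS_NM = (760, 850)

#: base-10 molar extinction [cm^-1 M^-1], rows = wavelength, cols = (HbO, HbR)
_EXTINCTION_BASE10 = {
    760: (586.0, 1548.52),
    850: (1058.0, 691.32),
}

LN10 = float(np.log(10.0))


def extinction_matrix(wavelengths=WAVELENGTHS_NM) -> np.ndarray:
    """Natural-log extinction matrix E with E[i] = (eps_HbO, eps_HbR) at wavelength i."""
    try:
        rows = [_EXTINCTION_BASE10[int(w)] for w in wavelengths]
    except KeyError as err:  # pragma: no cover - configuration error path
        raise ValueError(f"no extinction coefficients tabulated for {err} nm") from err
    return np.asarray(rows, dtype=float) * LN10


def hemoglobin_to_od(
    hbo_umol: np.ndarray,
    hbr_umol: np.ndarray,
    distance_cm: float,
    ppf: float = 0.1,
    wavelengths=WAVELENGTHS_NM,
) -> np.ndarray:
    """Forward modified Beer-Lambert: concentration changes -> OD per wavelength.

    Parameters
    ----------
    hbo_umol, hbr_umol : arrays in delta-umol/l
    distance_cm : source-detector separation
    ppf : partial pathlength factor (dimensionless)

    Returns
    -------
    (n_wavelengths, n_samples) array of optical densities (natural log).
    """
    E = extinction_matrix(wavelengths)
    conc_mol = np.vstack([hbo_umol, hbr_umol]) * 1e-6  # mol/l
    return (E @ conc_mol) * (distance_cm * ppf)


def od_to_hemoglobin(
    od: np.ndarray,
    distance_cm: float,
    ppf: float = 0.1,
    wavelengths=WAVELENGTHS_NM,
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse modified Beer-Lambert: OD at two wavelengths -> (HbO, HbR) in umol/l.

    Solves the 2x2 extinction system per sample; ``od`` has shape
    (n_wavelengths, n_samples).
    """
    E = extinction_matrix(wavelengths)
    if abs(np.linalg.det(E)) < 1e-12:
        raise ValueError("extinction matrix is singular for these wavelengths")
    conc_mol = np.linalg.solve(E, np.asarray(od, float) / (distance_cm * ppf))
    hbo, hbr = conc_mol * 1e6
    return hbo, hbr
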