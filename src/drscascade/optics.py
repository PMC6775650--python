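"""Forward optical model used by the synthetic spectra generator.

The generator needs reflectance spectra whose shape responds to tissue
composition the way diffuse reflectance spectroscopy (DRS) measurements do:
absorption bands from blood, water and lipid imprinted on a smooth
scattering background, observed at a fixed source-detector separation.
Three building blocks provide that:

* :func:`chromophore_absorption` - a parametric pseudo-chromophore model.
  Each chromophore is a sum of Gaussian bands at its characteristic
  wavelengths (oxy/deoxyhemoglobin in the visible, lipid near 1210 nm,
  water near 1450 nm).  The band constants are fixed module-level
  stand-ins, not literature extinction tables: the pipeline under test
  needs realistic band structure, not radiometric fidelity.
* :func:`reflectance` - the steady-state diffusion-approximation
  reflectance of a pencil-beam source observed at separation ``rho`` on a
  semi-infinite medium (extrapolated-boundary dipole solution).
* :func:`two_layer_mix` - an exponential depth-weighting rule for tumor
  buried under a layer of healthy wall, with decay scale equal to the
  fiber separation (the separation sets the effective sensing depth).

All coefficients are per millimetre; wavelengths are in nanometres.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .errors import GridMismatchError, OpticsDomainError, WavelengthRangeError

WAVELENGTH_MIN_NM = 400.0
WAVELENGTH_MAX_NM = 1700.0

#: Reference wavelength for the scattering power law and normalization anchor.
REFERENCE_WAVELENGTH_NM = 800.0

# Pseudo-chromophore Gaussian bands: (center nm, width nm, amplitude 1/mm at
# unit volume fraction).  Centers sit at the familiar in vivo features (Soret
# and Q bands of hemoglobin, the 760 nm deoxy band, lipid 930/1210 nm, water
# 970/1450 nm); widths and amplitudes are fixed constants of this module.
OXYHEMOGLOBIN_BANDS = (
    (415.0, 20.0, 150.0),
    (542.0, 18.0, 25.0),
    (577.0, 16.0, 23.0),
)
DEOXYHEMOGLOBIN_BANDS = (
    (432.0, 22.0, 120.0),
    (556.0, 22.0, 28.0),
    (760.0, 30.0, 3.2),
)
WATER_BANDS = (
    (970.0, 45.0, 0.45),
    (1190.0, 60.0, 0.35),
    (1450.0, 60.0, 2.9),
)
LIPID_BANDS = (
    (930.0, 25.0, 0.35),
    (1210.0, 45.0, 1.4),
)

#: Internal-reflection parameter of the extrapolated boundary (index-matched).
BOUNDARY_PARAMETER_A = 1.0


@dataclass(frozen=True)
class OpticalProperties:
    """Latent optical parameters of one measured tissue volume.

    ``scatter_amplitude`` is the reduced scattering coefficient (1/mm) at the
    800 nm reference wavelength and ``scatter_power`` the power-law slope, so
    mu_s'(lambda) = amplitude * (lambda/800)^(-power).  The four fractions are
    volume fractions in [0, 1]; ``oxygen_saturation`` partitions the blood
    fraction between oxy- and deoxyhemoglobin.
    """

    scatter_amplitude: float
    scatter_power: float
    blood_fraction: float
    oxygen_saturation: float
    water_fraction: float
    fat_fraction: float

    def __post_init__(self) -> None:
        if not self.scatter_amplitude > 0:
            raise OpticsDomainError("scatter_amplitude must be > 0")
        for name in ("blood_fraction", "oxygen_saturation", "water_fraction", "fat_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise OpticsDomainError(f"{name}={value!r} outside [0, 1]")

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls))


def _gaussian_bands(wavelengths: np.ndarray, bands) -> np.ndarray:
    mu = np.zeros_like(wavelengths, dtype=float)
    for center, width, amplitude in bands:
        mu += amplitude * np.exp(-0.5 * ((wavelengths - center) / width) ** 2)
    return mu


def _check_wavelengths(wavelengths: np.ndarray) -> np.ndarray:
    wl = np.asarray(wavelengths, dtype=float)
    if wl.size and (wl.min() < WAVELENGTH_MIN_NM or wl.max() > WAVELENGTH_MAX_NM):
        raise WavelengthRangeError(
            f"wavelengths must lie in [{WAVELENGTH_MIN_NM:g}, {WAVELENGTH_MAX_NM:g}] nm"
        )
    return wl


def chromophore_absorption(wavelengths: np.ndarray, props: OpticalProperties) -> np.ndarray:
    """Absorption coefficient spectrum mu_a (1/mm) on the given grid.

    Linear in each concentration: blood contributes its fraction times the
    saturation-weighted mix of the oxy/deoxy band shapes; water and lipid
    contribute their fractions times their band shapes.
    """
    wl = _check_wavelengths(wavelengths)
    blood_shape = props.oxygen_saturation * _gaussian_bands(wl, OXYHEMOGLOBIN_BANDS) + (
        1.0 - props.oxygen_saturation
    ) * _gaussian_bands(wl, DEOXYHEMOGLOBIN_BANDS)
    mu_a = (
        props.blood_fraction * blood_shape
        + props.water_fraction * _gaussian_bands(wl, WATER_BANDS)
        + props.fat_fraction * _gaussian_bands(wl, LIPID_BANDS)
    )
    return mu_a


def reduced_scattering(wavelengths: np.ndarray, props: OpticalProperties) -> np.ndarray:
    """Reduced scattering coefficient mu_s' (1/mm): power law anchored at 800 nm."""
    wl = _check_wavelengths(wavelengths)
    return props.scatter_amplitude * (wl / REFERENCE_WAVELENGTH_NM) ** (-props.scatter_power)


def reflectance(mu_a: np.ndarray, mu_s_prime: np.ndarray, separation: float) -> np.ndarray:
    """Diffuse reflectance at source-detector separation ``separation`` (mm).

    Extrapolated-boundary dipole solution of the diffusion approximation for
    a semi-infinite homogeneous medium: an isotropic source at depth
    z0 = 1/(mu_a + mu_s') and its image above the extrapolated boundary at
    z0 + 2*zb, zb = 2*A*D.  Strictly positive, and strictly decreasing in
    mu_a at fixed mu_s'.
    """
    mu_a = np.asarray(mu_a, dtype=float)
    mu_s_prime = np.asarray(mu_s_prime, dtype=float)
    if np.any(mu_a < 0):
        raise OpticsDomainError("mu_a must be non-negative")
    if np.any(mu_s_prime <= 0):
        raise OpticsDomainError("mu_s_prime must be strictly positive")
    if not separation > 0:
        raise OpticsDomainError("separation must be > 0")

    mu_t = mu_a + mu_s_prime
    z0 = 1.0 / mu_t
    diffusion = 1.0 / (3.0 * mu_t)
    mu_eff = np.sqrt(mu_a / diffusion)
    zb = 2.0 * BOUNDARY_PARAMETER_A * diffusion
    r1 = np.sqrt(z0**2 + separation**2)
    r2 = np.sqrt((z0 + 2.0 * zb) ** 2 + separation**2)
    term1 = z0 * (mu_eff + 1.0 / r1) * np.exp(-mu_eff * r1) / r1**2
    term2 = (z0 + 2.0 * zb) * (mu_eff + 1.0 / r2) * np.exp(-mu_eff * r2) / r2**2
    return (term1 + term2) / (4.0 * np.pi)


def two_layer_mix(
    surface_spectrum: np.ndarray,
    tumor_spectrum: np.ndarray,
    depth_mm: float,
    sensing_depth_mm: float = 1.29,
) -> np.ndarray:
    """Reflectance of tumor buried ``depth_mm`` under healthy surface tissue.

    Convex combination w*tumor + (1-w)*surface with w = exp(-depth/sensing
    depth): at depth 0 the probe sees pure tumor, several sensing depths down
    it sees only the overlying layer.
    """
    surface = np.asarray(surface_spectrum, dtype=float)
    tumor = np.asarray(tumor_spectrum, dtype=float)
    if surface.shape != tumor.shape:
        raise GridMismatchError("surface and tumor spectra must share a grid")
    if depth_mm < 0:
        raise OpticsDomainError("depth_mm must be >= 0")
    if not sensing_depth_mm > 0:
        raise OpticsDomainError("sensing_depth_mm must be > 0")
    weight = float(np.exp(-depth_mm / sensing_depth_mm))
    return weight * tumor + (1.0 - weight) * surface
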