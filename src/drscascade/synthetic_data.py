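"""Synthetic in vivo DRS datasets with the structure the analysis assumes.

The clinical datasets this pipeline targets are not public, so every
downstream stage is exercised on simulated data that reproduces the
*statistical and physical structure* of an intraoperative diffuse
reflectance study of colorectal tissue:

* three tissue classes (subcutaneous/mesenteric **fat**, healthy colorectal
  **wall**, **tumor**) with distinct chromophore and scattering profiles
  over 400-1700 nm;
* two spectrometer bands (visible 400-1100 nm, near-infrared 900-1700 nm)
  with per-patient white and dark reference frames;
* three replicate spectra per measurement location, locations grouped by
  patient;
* buried-tumor depth structure: tumor measurements may have a layer of
  healthy wall between probe and tumor, which mixes the observed spectrum
  toward the wall class with scale set by the fiber separation;
* inconclusive histopathology cases (tumor extent < 0.5 mm on the section)
  that the study protocol excludes;
* a surgeon judgement (healthy/tumor) with a certainty flag, where the
  surgeon over-calls tumor on uncertain locations.

Class optical-parameter distributions are module constants
(:data:`DEFAULT_TISSUE_MODELS`): plausible in vivo values, not fits to any
measured tissue.  Everything is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from . import optics
from .errors import ConfigError
from .optics import OpticalProperties
from .preprocess import Spectrum

CLASSES = ("fat", "wall", "tumor")


@dataclass(frozen=True)
class TissueClassModel:
    """Distribution of optical parameters for one tissue class.

    Parameters for a location are drawn componentwise from normal
    distributions ``N(mean, sd)`` and clipped back to their valid ranges.
    """

    class_name: str
    property_means: OpticalProperties
    property_sds: OpticalProperties

    def sample(self, rng: np.random.Generator) -> OpticalProperties:
        drawn = {}
        for name in OpticalProperties.field_names():
            mean = getattr(self.property_means, name)
            sd = getattr(self.property_sds, name)
            value = rng.normal(mean, sd) if sd > 0 else mean
            if name == "scatter_amplitude":
                value = max(value, 0.05)
            elif name == "scatter_power":
                value = float(np.clip(value, 0.1, 3.0))
            else:
                value = float(np.clip(value, 0.0, 1.0))
            drawn[name] = value
        return OpticalProperties(**drawn)


def _props(amp, power, blood, sat, water, fat) -> OpticalProperties:
    return OpticalProperties(
        scatter_amplitude=amp,
        scatter_power=power,
        blood_fraction=blood,
        oxygen_saturation=sat,
        water_fraction=water,
        fat_fraction=fat,
    )


# sds passed through OpticalProperties for componentwise bookkeeping only;
# a tiny positive scatter_amplitude keeps the constructor's >0 invariant.
def _sds(amp, power, blood, sat, water, fat) -> OpticalProperties:
    return OpticalProperties(
        scatter_amplitude=max(amp, 1e-12),
        scatter_power=power,
        blood_fraction=blood,
        oxygen_saturation=sat,
        water_fraction=water,
        fat_fraction=fat,
    )


#: Default per-class optical parameter distributions.  Fat: strong lipid
#: band, little blood or water, flat scattering slope.  Wall: watery,
#: moderately perfused muscle/submucosa.  Tumor: hypoxic, roughly twice the
#: wall's blood content, steeper scattering slope from denser nuclei.
DEFAULT_TISSUE_MODELS: dict[str, TissueClassModel] = {
    "fat": TissueClassModel(
        "fat",
        property_means=_props(1.20, 0.45, 0.003, 0.75, 0.12, 0.65),
        property_sds=_sds(0.15, 0.08, 0.0012, 0.08, 0.04, 0.08),
    ),
    "wall": TissueClassModel(
        "wall",
        property_means=_props(0.95, 1.10, 0.010, 0.80, 0.72, 0.05),
        property_sds=_sds(0.12, 0.12, 0.004, 0.08, 0.06, 0.02),
    ),
    "tumor": TissueClassModel(
        "tumor",
        property_means=_props(1.35, 1.45, 0.024, 0.55, 0.78, 0.03),
        property_sds=_sds(0.15, 0.15, 0.007, 0.10, 0.06, 0.015),
    ),
}


@dataclass(frozen=True)
class DepthDistribution:
    """Tumor depth model: a point mass at the surface plus an exponential tail.

    With probability ``surface_mass`` the tumor reaches the measurement
    surface (depth 0); otherwise the depth of the first tumor tissue is
    exponential with scale ``exp_scale_mm``, truncated at ``max_depth_mm``
    so every depth bin of the depth-sweep analysis is populated.
    """

    surface_mass: float = 0.25
    exp_scale_mm: float = 2.0
    max_depth_mm: float = 6.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.surface_mass <= 1.0:
            raise ConfigError("surface_mass must be in [0, 1]")
        if self.exp_scale_mm <= 0 or self.max_depth_mm <= 0:
            raise ConfigError("depth scales must be positive")

    def sample(self, rng: np.random.Generator) -> float:
        if rng.random() < self.surface_mass:
            return 0.0
        depth = rng.exponential(self.exp_scale_mm)
        while depth > self.max_depth_mm:
            depth = rng.exponential(self.exp_scale_mm)
        return float(depth)


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulated study.

    Defaults emulate the study design the pipeline was built around:
    32 measured patients; roughly 4:3:2 fat:wall:tumor location imbalance;
    3 replicate spectra per location; 1.29 mm fiber separation; visible and
    near-infrared spectrometer bands; about a fifth of locations judged
    with uncertainty by the surgeon, who over-calls tumor on those at a
    0.69 false-positive rate.
    """

    n_patients: int = 32
    locations_per_patient_per_class: dict[str, int] = field(
        default_factory=lambda: {"fat": 4, "wall": 3, "tumor": 2}
    )
    replicates_per_location: int = 3
    fiber_separation_mm: float = 1.29
    vis_band: tuple[float, float] = (400.0, 1100.0)
    nir_band: tuple[float, float] = (900.0, 1700.0)
    grid_step_nm: float = 5.0
    noise_sd: float = 0.01
    tumor_depth_distribution: DepthDistribution = field(default_factory=DepthDistribution)
    inconclusive_fraction: float = 0.35
    surgeon_uncertain_fraction: float = 0.20
    surgeon_fp_rate_on_uncertain: float = 0.69
    surgeon_error_rate_certain: float = 0.02
    tissue_models: dict[str, TissueClassModel] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_MODELS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if self.replicates_per_location < 1:
            raise ConfigError("replicates_per_location must be >= 1")
        missing = [c for c in CLASSES if c not in self.locations_per_patient_per_class]
        if missing:
            raise ConfigError(f"locations_per_patient_per_class missing classes: {missing}")
        for name in (
            "inconclusive_fraction",
            "surgeon_uncertain_fraction",
            "surgeon_fp_rate_on_uncertain",
            "surgeon_error_rate_certain",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name}={value!r} outside [0, 1]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.fiber_separation_mm <= 0 or self.grid_step_nm <= 0:
            raise ConfigError("fiber_separation_mm and grid_step_nm must be positive")

    def band_grid(self, band: str) -> np.ndarray:
        lo, hi = self.vis_band if band == "VIS" else self.nir_band
        return np.arange(lo, hi + 0.5 * self.grid_step_nm, self.grid_step_nm)


@dataclass
class MeasurementLocation:
    """One physical measurement site with its annotation and raw spectra.

    ``tumor_depth_mm`` is the distance from the measurement surface to the
    first tumor tissue (0 = tumor at the surface); it is defined only for
    tumor locations, as is ``tumor_extent_mm`` (the lateral extent of tumor
    on the histology section; extents below 0.5 mm are what the study
    protocol calls inconclusive).  ``replicate_spectra`` holds one
    ``{"VIS": Spectrum, "NIR": Spectrum}`` pair of raw frames per replicate.
    """

    location_id: str
    patient_id: str
    true_class: str
    tumor_depth_mm: Optional[float]
    tumor_extent_mm: Optional[float]
    surgeon_class: str
    surgeon_certain: bool
    replicate_spectra: list[dict[str, Spectrum]]

    def __post_init__(self) -> None:
        if self.true_class not in CLASSES:
            raise ConfigError(f"unknown class {self.true_class!r}")
        if self.true_class == "tumor":
            if self.tumor_depth_mm is None or self.tumor_depth_mm < 0:
                raise ConfigError("tumor locations need tumor_depth_mm >= 0")
            if self.tumor_extent_mm is None or not self.tumor_extent_mm > 0:
                raise ConfigError("tumor locations need tumor_extent_mm > 0")


@dataclass
class Dataset:
    """A simulated (or loaded) study: locations plus per-patient references."""

    locations: list[MeasurementLocation]
    references: dict[str, dict[str, tuple[Spectrum, Spectrum]]]
    config: SimConfig

    @property
    def patient_ids(self) -> list[str]:
        return sorted({loc.patient_id for loc in self.locations})


def _white_shape(grid: np.ndarray) -> np.ndarray:
    """Smooth lamp-times-detector envelope: 3000 K blackbody with soft band edges."""
    wl_m = grid * 1e-9
    h, c, kb, temp = 6.626e-34, 2.998e8, 1.381e-23, 3000.0
    planck = (1.0 / wl_m**5) / np.expm1(h * c / (wl_m * kb * temp))
    planck = planck / planck.max()
    edge = 1.0 / (1.0 + np.exp(-(grid - grid.min() - 40.0) / 15.0))
    edge *= 1.0 / (1.0 + np.exp((grid - grid.max() + 40.0) / 15.0))
    return planck * edge


def _patient_references(config: SimConfig, rng: np.random.Generator):
    refs = {}
    for band in ("VIS", "NIR"):
        grid = config.band_grid(band)
        gain = 4000.0 * float(rng.lognormal(0.0, 0.03))
        white_values = gain * _white_shape(grid) + 200.0
        dark_values = np.full_like(grid, 100.0) + 5.0 * np.sin(grid / 200.0)
        refs[band] = (
            Spectrum(grid, white_values, state="raw", band=band),
            Spectrum(grid, dark_values, state="raw", band=band),
        )
    return refs


def _band_reflectance(props: OpticalProperties, grid: np.ndarray, separation: float) -> np.ndarray:
    mu_a = optics.chromophore_absorption(grid, props)
    mu_s = optics.reduced_scattering(grid, props)
    return optics.reflectance(mu_a, mu_s, separation)


def expected_reflectance(
    config: SimConfig, tissue_class: str, depth_mm: float = 0.0
) -> dict[str, np.ndarray]:
    """Noise-free mean reflectance per band for a class at a given tumor depth.

    Uses the class mean optical properties; for tumor the spectrum is mixed
    toward the wall-class mean with weight exp(-depth / fiber separation).
    Useful for oracle tests and for plotting the generator's class structure.
    """
    out = {}
    for band in ("VIS", "NIR"):
        grid = config.band_grid(band)
        mean_props = config.tissue_models[tissue_class].property_means
        spectrum = _band_reflectance(mean_props, grid, config.fiber_separation_mm)
        if tissue_class == "tumor":
            wall = _band_reflectance(
                config.tissue_models["wall"].property_means, grid, config.fiber_separation_mm
            )
            spectrum = optics.two_layer_mix(wall, spectrum, depth_mm, config.fiber_separation_mm)
        out[band] = spectrum
    return out


def _location_spectra(
    config: SimConfig,
    refs: dict,
    tissue_class: str,
    depth_mm: float,
    rng: np.random.Generator,
) -> list[dict[str, Spectrum]]:
    props = config.tissue_models[tissue_class].sample(rng)
    wall_props = config.tissue_models["wall"].sample(rng) if tissue_class == "tumor" else None
    replicates = []
    band_reflectances = {}
    for band in ("VIS", "NIR"):
        grid = config.band_grid(band)
        refl = _band_reflectance(props, grid, config.fiber_separation_mm)
        if tissue_class == "tumor":
            wall_refl = _band_reflectance(wall_props, grid, config.fiber_separation_mm)
            refl = optics.two_layer_mix(wall_refl, refl, depth_mm, config.fiber_separation_mm)
        band_reflectances[band] = refl
    for _ in range(config.replicates_per_location):
        pair = {}
        for band in ("VIS", "NIR"):
            grid = config.band_grid(band)
            white, dark = refs[band]
            signal = band_reflectances[band] * (white.values - dark.values)
            noise = rng.normal(0.0, 1.0, size=grid.size) * config.noise_sd * signal
            raw = dark.values + signal + noise
            pair[band] = Spectrum(grid, raw, state="raw", band=band)
        replicates.append(pair)
    return replicates


def _surgeon_call(
    truth_is_tumor: bool, certain: bool, config: SimConfig, rng: np.random.Generator
) -> str:
    if certain:
        correct = rng.random() >= config.surgeon_error_rate_certain
        return ("tumor" if truth_is_tumor else "healthy") if correct else (
            "healthy" if truth_is_tumor else "tumor"
        )
    if truth_is_tumor:
        # an uncertain surgeon still errs on the side of calling tumor
        return "tumor"
    return "tumor" if rng.random() < config.surgeon_fp_rate_on_uncertain else "healthy"


def simulate_dataset(config: SimConfig) -> Dataset:
    """Generate a full study dataset; bit-identical for identical configs."""
    rng = np.random.default_rng(config.seed)
    locations: list[MeasurementLocation] = []
    references = {}
    for p in range(config.n_patients):
        patient_id = f"P{p:03d}"
        refs = _patient_references(config, rng)
        references[patient_id] = refs
        for tissue_class in CLASSES:
            for i in range(config.locations_per_patient_per_class[tissue_class]):
                location_id = f"{patient_id}-{tissue_class}-{i}"
                depth = extent = None
                if tissue_class == "tumor":
                    depth = config.tumor_depth_distribution.sample(rng)
                    if rng.random() < config.inconclusive_fraction:
                        extent = float(rng.uniform(0.05, 0.45))
                    else:
                        extent = float(rng.uniform(1.0, 8.0))
                certain = rng.random() >= config.surgeon_uncertain_fraction
                surgeon = _surgeon_call(tissue_class == "tumor", certain, config, rng)
                spectra = _location_spectra(config, refs, tissue_class, depth or 0.0, rng)
                locations.append(
                    MeasurementLocation(
                        location_id=location_id,
                        patient_id=patient_id,
                        true_class=tissue_class,
                        tumor_depth_mm=depth,
                        tumor_extent_mm=extent,
                        surgeon_class=surgeon,
                        surgeon_certain=certain,
                        replicate_spectra=spectra,
                    )
                )
    return Dataset(locations=locations, references=references, config=config)


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Convenience: copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
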