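"""Raw two-band intensity frames -> one calibrated, normalized spectrum.

The instrument records each measurement on two spectrometers: a visible band
(400-1100 nm) and a near-infrared band (900-1700 nm).  Processing is a fixed
forward-only chain:

1. :func:`calibrate`  - (raw - dark) / (white - dark) per band, using the
   white/dark reference frames recorded for the same patient.
2. :func:`stitch`     - resample both bands onto one uniform 400-1700 nm
   grid and blend them with a linear cross-fade over the 900-1100 nm
   overlap region.
3. :func:`normalize_at_800` - divide by the (interpolated) value at 800 nm,
   so every feature vector equals 1 at the anchor wavelength.

:func:`process_dataset` applies the chain to every replicate spectrum of a
simulated or loaded dataset and returns the feature matrix plus per-spectrum
metadata used downstream by the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .errors import (
    DataError,
    DegenerateReferenceError,
    GridMismatchError,
    NormalizationError,
    StitchError,
)

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic_data import Dataset

#: Anchor wavelength for normalization (nm).
NORMALIZATION_WAVELENGTH_NM = 800.0

#: Default step of the merged wavelength grid (nm).
DEFAULT_GRID_STEP_NM = 5.0

_STATE_ORDER = ("raw", "calibrated", "stitched", "normalized")


@dataclass(frozen=True)
class Spectrum:
    """One spectrum: a strictly increasing wavelength grid plus values.

    ``state`` tracks the processing stage (raw -> calibrated -> stitched ->
    normalized, forward only); ``band`` records instrument provenance
    (``VIS``, ``NIR`` or ``merged``).
    """

    wavelengths: np.ndarray
    values: np.ndarray
    state: str = "raw"
    band: str = "VIS"

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wl.shape != vals.shape or wl.ndim != 1:
            raise GridMismatchError("wavelengths and values must be 1-D and equal length")
        if wl.size >= 2 and not np.all(np.diff(wl) > 0):
            raise GridMismatchError("wavelengths must be strictly increasing")
        if self.state not in _STATE_ORDER:
            raise ValueError(f"unknown state {self.state!r}")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)


def _require_same_grid(*spectra: Spectrum) -> None:
    first = spectra[0].wavelengths
    for s in spectra[1:]:
        if s.wavelengths.shape != first.shape or not np.allclose(s.wavelengths, first):
            raise GridMismatchError("spectra are not on identical wavelength grids")


def calibrate(raw: Spectrum, white: Spectrum, dark: Spectrum) -> Spectrum:
    """Reference calibration: (raw - dark) / (white - dark), clipped at 0.

    The white and dark frames are recorded per patient before the tissue
    measurements; the ratio removes the lamp spectrum, fiber transmission
    and detector offset.  Negative values (noise dipping below the dark
    level) are clipped to zero since reflectance is non-negative.
    """
    _require_same_grid(raw, white, dark)
    denom = white.values - dark.values
    if np.any(denom <= 0):
        raise DegenerateReferenceError("white reference must exceed dark reference everywhere")
    values = np.clip((raw.values - dark.values) / denom, 0.0, None)
    return Spectrum(raw.wavelengths, values, state="calibrated", band=raw.band)


def stitch(vis: Spectrum, nir: Spectrum, grid_step: float = DEFAULT_GRID_STEP_NM) -> Spectrum:
    """Merge the two calibrated bands onto one uniform grid.

    Inside the overlap of the two bands the output is a linear cross-fade:
    the NIR weight ramps 0 -> 1 across the overlap (900 -> 1100 nm for the
    default instrument bands), so neither band introduces a step at its
    edge.  Outside the overlap the owning band is linearly interpolated.
    """
    for s, name in ((vis, "vis"), (nir, "nir")):
        if s.state != "calibrated":
            raise ValueError(f"{name} spectrum must be calibrated, got state {s.state!r}")
    lo, hi = nir.wavelengths.min(), vis.wavelengths.max()
    if hi <= lo:
        raise StitchError("bands do not overlap; cannot cross-fade")
    grid = np.arange(vis.wavelengths.min(), nir.wavelengths.max() + 0.5 * grid_step, grid_step)
    grid = grid[grid <= nir.wavelengths.max() + 1e-9]
    vis_interp = np.interp(grid, vis.wavelengths, vis.values)
    nir_interp = np.interp(grid, nir.wavelengths, nir.values)
    nir_weight = np.clip((grid - lo) / (hi - lo), 0.0, 1.0)
    values = (1.0 - nir_weight) * vis_interp + nir_weight * nir_interp
    return Spectrum(grid, values, state="stitched", band="merged")


def normalize_at_800(s: Spectrum) -> Spectrum:
    """Divide by the value at 800 nm (linear interpolation on the grid).

    Idempotent; scale-invariant (k*spectrum normalizes to the same output).
    """
    if s.state not in ("stitched", "normalized"):
        raise ValueError(f"normalize_at_800 expects a stitched spectrum, got {s.state!r}")
    anchor = float(np.interp(NORMALIZATION_WAVELENGTH_NM, s.wavelengths, s.values))
    if anchor <= 0:
        raise NormalizationError("spectrum value at 800 nm must be positive")
    return replace(s, values=s.values / anchor, state="normalized")


def process_spectrum(
    raw_vis: Spectrum,
    raw_nir: Spectrum,
    references: dict,
    grid_step: float = DEFAULT_GRID_STEP_NM,
) -> Spectrum:
    """Full chain for one measurement: calibrate both bands, stitch, normalize.

    ``references`` maps band name -> (white, dark) Spectrum pair.
    """
    cal_vis = calibrate(raw_vis, *references["VIS"])
    cal_nir = calibrate(raw_nir, *references["NIR"])
    return normalize_at_800(stitch(cal_vis, cal_nir, grid_step=grid_step))


def process_dataset(dataset: "Dataset") -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Preprocess every replicate spectrum of a dataset.

    Returns ``(X, grid, meta)``: the feature matrix (one normalized spectrum
    per row), the merged wavelength grid, and a per-spectrum metadata frame
    with measurement / location / patient identifiers, the generator's true
    class and, for tumor locations, depth and extent annotation plus the
    surgeon's call.
    """
    rows = []
    features = []
    grid = None
    for loc in dataset.locations:
        refs = dataset.references.get(loc.patient_id)
        if refs is None:
            raise DataError(f"no reference frames recorded for patient {loc.patient_id!r}")
        for rep_index, bands in enumerate(loc.replicate_spectra):
            spec = process_spectrum(
                bands["VIS"], bands["NIR"], refs, grid_step=dataset.config.grid_step_nm
            )
            if grid is None:
                grid = spec.wavelengths
            features.append(spec.values)
            rows.append(
                {
                    "measurement_id": f"{loc.location_id}-r{rep_index}",
                    "location_id": loc.location_id,
                    "patient_id": loc.patient_id,
                    "replicate": rep_index,
                    "true_class": loc.true_class,
                    "tumor_depth_mm": loc.tumor_depth_mm,
                    "tumor_extent_mm": loc.tumor_extent_mm,
                    "surgeon_class": loc.surgeon_class,
                    "surgeon_certain": loc.surgeon_certain,
                }
            )
    if grid is None:
        raise DataError("dataset contains no measurement locations")
    return np.vstack(features), grid, pd.DataFrame(rows)
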