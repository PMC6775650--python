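"""File formats: spectra/metadata/reference CSV dialect, configs, reports.

A dataset on disk is three CSV files in one directory:

* ``spectra.csv``    - measurement_id, location_id, band, wavelength_nm,
  intensity (long format, one row per sample of each raw band frame);
* ``metadata.csv``   - one row per measurement location (patient, class,
  depth/extent annotation, surgeon judgement and certainty);
* ``references.csv`` - patient_id, band, kind (white/dark), wavelength_nm,
  intensity.

Configs are YAML or JSON mirrors of :class:`~drscascade.synthetic_data.SimConfig`.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DataError
from .preprocess import Spectrum
from .synthetic_data import (
    Dataset,
    DepthDistribution,
    MeasurementLocation,
    SimConfig,
)


def write_dataset(dataset: Dataset, outdir: str | Path) -> dict[str, Path]:
    """Write the three-CSV dataset dialect; returns the file paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spectra_rows = []
    meta_rows = []
    for loc in dataset.locations:
        meta_rows.append(
            {
                "location_id": loc.location_id,
                "patient_id": loc.patient_id,
                "true_class": loc.true_class,
                "tumor_depth_mm": loc.tumor_depth_mm,
                "tumor_extent_mm": loc.tumor_extent_mm,
                "surgeon_class": loc.surgeon_class,
                "surgeon_certain": loc.surgeon_certain,
            }
        )
        for rep, bands in enumerate(loc.replicate_spectra):
            for band, spec in bands.items():
                spectra_rows.append(
                    pd.DataFrame(
                        {
                            "measurement_id": f"{loc.location_id}-r{rep}",
                            "location_id": loc.location_id,
                            "band": band,
                            "wavelength_nm": spec.wavelengths,
                            "intensity": spec.values,
                        }
                    )
                )
    ref_rows = []
    for patient_id, bands in dataset.references.items():
        for band, (white, dark) in bands.items():
            for kind, spec in (("white", white), ("dark", dark)):
                ref_rows.append(
                    pd.DataFrame(
                        {
                            "patient_id": patient_id,
                            "band": band,
                            "kind": kind,
                            "wavelength_nm": spec.wavelengths,
                            "intensity": spec.values,
                        }
                    )
                )
    paths = {
        "spectra": outdir / "spectra.csv",
        "metadata": outdir / "metadata.csv",
        "references": outdir / "references.csv",
        "config": outdir / "sim_config.json",
    }
    pd.concat(spectra_rows, ignore_index=True).to_csv(paths["spectra"], index=False)
    pd.DataFrame(meta_rows).to_csv(paths["metadata"], index=False)
    pd.concat(ref_rows, ignore_index=True).to_csv(paths["references"], index=False)
    paths["config"].write_text(json.dumps(config_to_dict(dataset.config), indent=2))
    return paths


def read_dataset(indir: str | Path) -> Dataset:
    """Round-trip reader for :func:`write_dataset` output."""
    indir = Path(indir)
    for name in ("spectra.csv", "metadata.csv", "references.csv"):
        if not (indir / name).exists():
            raise DataError(f"dataset directory {indir} is missing {name}")
    config_path = indir / "sim_config.json"
    config = (
        config_from_dict(json.loads(config_path.read_text()))
        if config_path.exists()
        else SimConfig()
    )
    spectra = pd.read_csv(indir / "spectra.csv")
    meta = pd.read_csv(indir / "metadata.csv")
    refs_frame = pd.read_csv(indir / "references.csv")

    references: dict = {}
    for (patient_id, band), group in refs_frame.groupby(["patient_id", "band"]):
        pair = {}
        for kind, sub in group.groupby("kind"):
            sub = sub.sort_values("wavelength_nm")
            pair[kind] = Spectrum(
                sub["wavelength_nm"].to_numpy(), sub["intensity"].to_numpy(),
                state="raw", band=band,
            )
        references.setdefault(patient_id, {})[band] = (pair["white"], pair["dark"])

    locations = []
    grouped = spectra.groupby(["location_id", "measurement_id", "band"], sort=True)
    by_location: dict = {}
    for (location_id, measurement_id, band), group in grouped:
        group = group.sort_values("wavelength_nm")
        spec = Spectrum(
            group["wavelength_nm"].to_numpy(), group["intensity"].to_numpy(),
            state="raw", band=band,
        )
        by_location.setdefault(location_id, {}).setdefault(measurement_id, {})[band] = spec
    for row in meta.itertuples(index=False):
        reps = by_location.get(row.location_id, {})
        replicate_spectra = [reps[mid] for mid in sorted(reps)]
        locations.append(
            MeasurementLocation(
                location_id=row.location_id,
                patient_id=row.patient_id,
                true_class=row.true_class,
                tumor_depth_mm=None if pd.isna(row.tumor_depth_mm) else float(row.tumor_depth_mm),
                tumor_extent_mm=None
                if pd.isna(row.tumor_extent_mm)
                else float(row.tumor_extent_mm),
                surgeon_class=row.surgeon_class,
                surgeon_certain=bool(row.surgeon_certain),
                replicate_spectra=replicate_spectra,
            )
        )
    return Dataset(locations=locations, references=references, config=config)


def config_to_dict(config: SimConfig) -> dict:
    payload = dataclasses.asdict(config)
    payload["tumor_depth_distribution"] = dataclasses.asdict(config.tumor_depth_distribution)
    payload["tissue_models"] = {
        name: {
            "property_means": dataclasses.asdict(model.property_means),
            "property_sds": dataclasses.asdict(model.property_sds),
        }
        for name, model in config.tissue_models.items()
    }
    payload["vis_band"] = list(config.vis_band)
    payload["nir_band"] = list(config.nir_band)
    return payload


def config_from_dict(payload: dict) -> SimConfig:
    from .optics import OpticalProperties
    from .synthetic_data import TissueClassModel

    payload = dict(payload)
    try:
        if "tumor_depth_distribution" in payload:
            payload["tumor_depth_distribution"] = DepthDistribution(
                **payload["tumor_depth_distribution"]
            )
        if "tissue_models" in payload:
            payload["tissue_models"] = {
                name: TissueClassModel(
                    class_name=name,
                    property_means=OpticalProperties(**spec["property_means"]),
                    property_sds=OpticalProperties(**spec["property_sds"]),
                )
                for name, spec in payload["tissue_models"].items()
            }
        for band in ("vis_band", "nir_band"):
            if band in payload:
                payload[band] = tuple(payload[band])
        return SimConfig(**payload)
    except TypeError as exc:
        raise ConfigError(f"malformed simulation config: {exc}") from exc


def load_sim_config(path: str | Path) -> SimConfig:
    """Load a SimConfig from a YAML or JSON document."""
    path = Path(path)
    text = path.read_text()
    payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(payload, dict):
        raise ConfigError(f"config file {path} does not contain a mapping")
    return config_from_dict(payload)


def write_predictions(predictions: pd.DataFrame, path: str | Path) -> None:
    predictions.to_csv(path, index=False)


def write_report(report, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2))


def write_roc_csv(report, outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    written = []
    for cls, (fpr, tpr, auc) in report.roc_points.items():
        path = outdir / f"roc_{cls}.csv"
        pd.DataFrame({"fpr": fpr, "tpr": tpr}).assign(auc=auc).to_csv(path, index=False)
        written.append(path)
    return written


def dataset_hash(indir: str | Path) -> str:
    """SHA-256 over the dataset CSVs, for run logging."""
    import hashlib

    digest = hashlib.sha256()
    for name in ("spectra.csv", "metadata.csv", "references.csv"):
        p = Path(indir) / name
        if p.exists():
            digest.update(p.read_bytes())
    return digest.hexdigest()


def _json_default(value):
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    raise TypeError(f"not JSON serializable: {type(value)}")
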