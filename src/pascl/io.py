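"""Dataset readers/writers (HDF5 and NPZ) and the CSV sample manifest.

The on-disk layout carries aligned first-dimension arrays ``spectra``
[N, 77, 90], ``labels`` [N], ``patient_id`` [N], ``system_id`` [N], plus
the wavelength/frequency grids, units and provenance as attributes. Both
backends round-trip losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import Cohort

__all__ = ["SchemaError", "write_dataset", "read_dataset", "write_manifest"]

SCHEMA_VERSION = 1
_REQUIRED = ("spectra", "labels", "patient_id", "system_id")
_OPTIONAL = ("latent_slope", "latent_intercept")


class SchemaError(ValueError):
    """Raised when a dataset file is missing a required field."""


def write_dataset(cohort: Cohort, path: str | Path, provenance: str = "synthetic") -> Path:
    """Write a cohort to ``path`` (.h5/.hdf5 or .npz, chosen by suffix)."""
    path = Path(path)
    arrays = {name: getattr(cohort, name) for name in _REQUIRED}
    for name in _OPTIONAL:
        value = getattr(cohort, name)
        if value is not None:
            arrays[name] = value
    attrs = {
        "wavelengths_nm": cohort.wavelengths_nm,
        "frequencies_mhz": cohort.frequencies_mhz,
    }
    meta = {"units": "dB", "provenance": provenance, "schema_version": SCHEMA_VERSION}
    if path.suffix == ".npz":
        np.savez(
            path,
            **arrays,
            **attrs,
            meta=np.array(json.dumps(meta)),
        )
    elif path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as f:
            for name, arr in arrays.items():
                f.create_dataset(name, data=arr)
            for name, arr in attrs.items():
                f.attrs[name] = arr
            for key, val in meta.items():
                f.attrs[key] = val
    else:
        raise ValueError(f"unsupported dataset suffix {path.suffix!r}")
    return path


def read_dataset(path: str | Path) -> Cohort:
    """Read a cohort, validating the schema and naming any missing field."""
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as data:
            fields = dict(data)
    elif path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as f:
            fields = {name: f[name][...] for name in f.keys()}
            fields["wavelengths_nm"] = np.asarray(f.attrs["wavelengths_nm"])
            fields["frequencies_mhz"] = np.asarray(f.attrs["frequencies_mhz"])
    else:
        raise ValueError(f"unsupported dataset suffix {path.suffix!r}")
    missing = [name for name in _REQUIRED if name not in fields]
    if missing:
        raise SchemaError(f"dataset file is missing field(s): {missing}")
    from .synth import frequency_grid, wavelength_grid

    return Cohort(
        spectra=fields["spectra"],
        labels=np.asarray(fields["labels"]).astype(int),
        patient_id=np.asarray(fields["patient_id"]).astype(int),
        system_id=np.asarray(fields["system_id"]).astype(int),
        wavelengths_nm=np.asarray(fields.get("wavelengths_nm", wavelength_grid())),
        frequencies_mhz=np.asarray(fields.get("frequencies_mhz", frequency_grid())),
        latent_slope=fields.get("latent_slope"),
        latent_intercept=fields.get("latent_intercept"),
    )


def write_manifest(
    cohort: Cohort, path: str | Path, split_of_patient: dict[int, str] | None = None
) -> Path:
    """CSV manifest: sample_id, patient_id, system_id, label, split."""
    path = Path(path)
    split = (
        [split_of_patient.get(int(p), "") for p in cohort.patient_id]
        if split_of_patient
        else [""] * cohort.n
    )
    pd.DataFrame(
        {
            "sample_id": np.arange(cohort.n),
            "patient_id": cohort.patient_id,
            "system_id": cohort.system_id,
            "label": cohort.labels,
            "split": split,
        }
    ).to_csv(path, index=False)
    return path
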