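"""Serialisation helpers: HDF5 field snapshots and delimited-text profiles."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .tissue import ConcentrationField, GradientFit, LongitudinalProfile, TissueSystem

__all__ = [
    "save_field",
    "load_field",
    "write_profile",
    "read_profile",
    "fit_to_dict",
]


def save_field(field: ConcentrationField, path) -> None:
    """Snapshot a concentration field to HDF5.

    Datasets: ``concentration`` (per compartment), ``volume``,
    ``compartment_kind`` (0 = cytosol pixel, 1 = wall face),
    ``pixel_cell`` (owning cell id per pixel) and a ``time`` attribute.
    """
    sys_ = field.system
    kind = np.zeros(sys_.n, dtype=np.int8)
    kind[sys_.n_pixels:] = 1
    with h5py.File(path, "w") as fh:
        fh.create_dataset("concentration", data=field.values)
        fh.create_dataset("volume", data=sys_.volumes)
        fh.create_dataset("compartment_kind", data=kind)
        fh.create_dataset("pixel_cell", data=sys_.pixel_cell)
        fh.attrs["time"] = field.time
        fh.attrs["n_pixels"] = sys_.n_pixels


def load_field(path, system: TissueSystem) -> ConcentrationField:
    """Load a snapshot saved by :func:`save_field` onto a matching system."""
    with h5py.File(path, "r") as fh:
        values = np.asarray(fh["concentration"])
        time = float(fh.attrs["time"])
        n_pix = int(fh.attrs["n_pixels"])
    if values.shape != (system.n,) or n_pix != system.n_pixels:
        raise ValueError("snapshot does not match the system geometry")
    return system.field_from(values, time)


def write_profile(profile: LongitudinalProfile, path, sep: str = "\t") -> None:
    """Write a longitudinal profile as delimited text with a header."""
    with open(path, "w") as fh:
        fh.write(f"position_um{sep}concentration_au{sep}file\n")
        for x, c in zip(profile.positions, profile.concentrations):
            fh.write(f"{x:.6g}{sep}{c:.10g}{sep}{profile.file}\n")


def read_profile(path, sep: str = "\t") -> LongitudinalProfile:
    pos, conc, name = [], [], "profile"
    with open(path) as fh:
        next(fh)
        for line in fh:
            x, c, name = line.rstrip("\n").split(sep)
            pos.append(float(x))
            conc.append(float(c))
    return LongitudinalProfile(np.asarray(pos), np.asarray(conc), name)


def fit_to_dict(fit: GradientFit | None) -> dict | None:
    if fit is None:
        return None
    return {
        "lambda_um": fit.lambda_fit,
        "C0": fit.C0_fit,
        "alpha_per_um": fit.alpha,
        "window_um": list(fit.window),
        "residual": fit.residual,
        "elbow_um": fit.elbow_position,
    }
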