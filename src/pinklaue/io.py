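"""Readers/writers for geometry JSON, reflection tables, images, and MTZ.

The native tabular format is CSV with a typed-header sidecar
(``<name>.csv`` + ``<name>.csv.types.json``) so fixtures stay inspectable;
geometry travels as a documented JSON schema; images as 16-bit TIFF; final
integrated intensities as MTZ with the columns downstream scaling/merging
tools expect (H K L BATCH I SIGI wavelength XDET YDET).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import (
    BeamModel,
    CrystalModel,
    DetectorModel,
    Experiment,
    GoniometerModel,
    UnitCell,
    axis_angle_matrix,
)

__all__ = [
    "StillsSet",
    "SchemaError",
    "sequence_to_stills",
    "experiment_to_dict",
    "experiment_from_dict",
    "save_experiment",
    "load_experiment",
    "write_reflections",
    "read_reflections",
    "write_image",
    "read_image",
    "write_mtz",
    "read_mtz",
]


class SchemaError(ValueError):
    pass


@dataclass(frozen=True)
class StillsSet:
    """Per-image experiments sharing detector/beam, one crystal each."""

    experiments: tuple

    def __post_init__(self):
        ids = [e.image_ids[0] for e in self.experiments]
        if len(set(ids)) != len(ids):
            raise SchemaError("image_ids must be unique across stills")
        object.__setattr__(self, "experiments", tuple(self.experiments))

    def __len__(self):
        return len(self.experiments)

    def __iter__(self):
        return iter(self.experiments)

    @property
    def image_ids(self):
        return [e.image_ids[0] for e in self.experiments]

    def by_image(self) -> dict:
        return {e.image_ids[0]: e for e in self.experiments}


def sequence_to_stills(experiment: Experiment) -> StillsSet:
    """Split a pseudo-rotation sequence into independent stills.

    Image ``i`` gets its own crystal with ``U_i = R(axis, angle_i) @ U0`` and
    a zero-angle goniometer, so downstream stages treat each image as a still.
    """
    stills = []
    for i, image_id in enumerate(experiment.image_ids):
        R = experiment.goniometer.rotation(i)
        stills.append(
            Experiment(
                crystal=experiment.crystal.rotated(R),
                beam=experiment.beam,
                detector=experiment.detector,
                goniometer=GoniometerModel(
                    axis_hat=experiment.goniometer.axis_hat, angles_deg=np.array([0.0])
                ),
                image_ids=(image_id,),
            )
        )
    return StillsSet(tuple(stills))


# ---------------------------------------------------------------------------
# geometry JSON
# ---------------------------------------------------------------------------


def experiment_to_dict(exp: Experiment) -> dict:
    return {
        "cell": list(exp.crystal.cell.lengths) + list(exp.crystal.cell.angles),
        "U": exp.crystal.U.tolist(),  # row-major
        "s0_hat": exp.beam.s0_hat.tolist(),
        "lambda_nominal": exp.beam.lambda_nominal,
        "lambda_min": exp.beam.lambda_min,
        "lambda_max": exp.beam.lambda_max,
        "spectrum": None if exp.beam.spectrum is None else exp.beam.spectrum.tolist(),
        "detector": {
            "distance": exp.detector.distance,
            "origin_mm": exp.detector.origin_mm.tolist(),
            "fast_hat": exp.detector.fast_hat.tolist(),
            "slow_hat": exp.detector.slow_hat.tolist(),
            "pixel_size": exp.detector.pixel_size,
            "n_fast": exp.detector.n_fast,
            "n_slow": exp.detector.n_slow,
        },
        "goniometer": {
            "axis_hat": exp.goniometer.axis_hat.tolist(),
            "angles_deg": exp.goniometer.angles_deg.tolist(),
        },
        "image_ids": list(exp.image_ids),
    }


def experiment_from_dict(d: dict) -> Experiment:
    try:
        cell = UnitCell(*d["cell"])
        det = d["detector"]
        gon = d["goniometer"]
        return Experiment(
            crystal=CrystalModel(cell=cell, U=np.array(d["U"], dtype=float)),
            beam=BeamModel(
                s0_hat=np.array(d["s0_hat"], dtype=float),
                lambda_nominal=d["lambda_nominal"],
                lambda_min=d["lambda_min"],
                lambda_max=d["lambda_max"],
                spectrum=None if d.get("spectrum") is None else np.array(d["spectrum"]),
            ),
            detector=DetectorModel(
                distance=det["distance"],
                origin_mm=np.array(det["origin_mm"], dtype=float),
                fast_hat=np.array(det["fast_hat"], dtype=float),
                slow_hat=np.array(det["slow_hat"], dtype=float),
                pixel_size=det["pixel_size"],
                n_fast=det["n_fast"],
                n_slow=det["n_slow"],
            ),
            goniometer=GoniometerModel(
                axis_hat=np.array(gon["axis_hat"], dtype=float),
                angles_deg=np.array(gon["angles_deg"], dtype=float),
            ),
            image_ids=tuple(d.get("image_ids", ())),
        )
    except KeyError as exc:
        raise SchemaError(f"geometry JSON missing field {exc}") from exc


def save_experiment(exp: Experiment, path) -> None:
    Path(path).write_text(json.dumps(experiment_to_dict(exp), indent=1, sort_keys=True))


def load_experiment(path) -> Experiment:
    return experiment_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# reflection tables: CSV + typed sidecar
# ---------------------------------------------------------------------------


def write_reflections(df: pd.DataFrame, path) -> None:
    path = Path(path)
    df.to_csv(path, index=False)
    dtypes = {c: str(t) for c, t in df.dtypes.items()}  # insertion order = column order
    Path(str(path) + ".types.json").write_text(json.dumps(dtypes, indent=1))


def read_reflections(path) -> pd.DataFrame:
    path = Path(path)
    sidecar = Path(str(path) + ".types.json")
    df = pd.read_csv(path)
    if sidecar.exists():
        dtypes = json.loads(sidecar.read_text())
        for col, dt in dtypes.items():
            if col not in df.columns:
                raise SchemaError(f"column {col!r} from sidecar missing in {path}")
            if len(df):
                try:
                    df[col] = df[col].astype(dt)
                except (TypeError, ValueError) as exc:
                    raise SchemaError(f"column {col!r} not castable to {dt}") from exc
        df = df[[c for c in dtypes]]
    return df


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------


def write_image(image: np.ndarray, path) -> None:
    """Write a count array as 16-bit TIFF (clipped and rounded)."""
    import tifffile

    arr = np.clip(np.rint(image), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(str(path), arr)


def read_image(path) -> np.ndarray:
    import tifffile

    return tifffile.imread(str(path)).astype(float)


# ---------------------------------------------------------------------------
# MTZ
# ---------------------------------------------------------------------------

_MTZ_COLUMNS = (
    ("H", "H"),
    ("K", "H"),
    ("L", "H"),
    ("BATCH", "B"),
    ("I", "J"),
    ("SIGI", "Q"),
    ("wavelength", "R"),
    ("XDET", "R"),
    ("YDET", "R"),
)


def write_mtz(df: pd.DataFrame, cell: UnitCell, path, spacegroup: str = "P 1") -> None:
    """Export integrated intensities as an MTZ reflection file.

    Expects columns h k l image_id intensity sigma wavelength x_px y_px.
    """
    import gemmi

    mtz = gemmi.Mtz(with_base=False)
    mtz.spacegroup = gemmi.SpaceGroup(spacegroup)
    mtz.set_cell_for_all(gemmi.UnitCell(*cell.lengths, *cell.angles))
    mtz.add_dataset("pinklaue")
    for name, typ in _MTZ_COLUMNS:
        mtz.add_column(name, typ)
    source = {
        "H": "h",
        "K": "k",
        "L": "l",
        "BATCH": "image_id",
        "I": "intensity",
        "SIGI": "sigma",
        "wavelength": "wavelength",
        "XDET": "x_px",
        "YDET": "y_px",
    }
    data = np.column_stack(
        [df[source[name]].to_numpy(dtype=float) for name, _ in _MTZ_COLUMNS]
    )
    mtz.set_data(data.astype(np.float32))
    mtz.write_to_file(str(path))


def read_mtz(path) -> pd.DataFrame:
    import gemmi

    mtz = gemmi.Mtz()
    mtz = gemmi.read_mtz_file(str(path))
    arr = np.array(mtz, copy=True)
    return pd.DataFrame(arr, columns=[c.label for c in mtz.columns])
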