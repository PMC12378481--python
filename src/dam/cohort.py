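"""Domain types and I/O for longitudinal liquid-biopsy cohorts.

A cohort links, per patient, two asynchronously sampled observation
streams — multi-channel tumor-related cell-image crops (CTCs/CECs) and
six-marker serum panels (AFP, CEA, CA19-9, CA72-4, CA125, NSE) — plus a
binary treatment-response label derived from RECIST (CR/PR = responder,
SD/PD = non-responder). Timestamps are real days since the treatment
baseline (day 0); pre-baseline draws carry t_days <= 0.

On disk a cohort is a JSON manifest referencing 8-bit RGB PNG crops and
one marker CSV (``patient_id,t_days,AFP,CEA,CA199,CA724,CA125,NSE``);
missing marker values are NaN in the CSV, imputed downstream.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "MARKER_NAMES", "CellClass", "ResponseLabel", "RecistLabel",
    "MarkerPanel", "MarkerObservation", "CellImage", "CellObservation",
    "PatientRecord", "Cohort", "TimeWindow", "STANDARD_WINDOWS",
    "ValidationError", "read_manifest", "write_manifest",
    "restrict_time_window", "load_image", "save_image",
]

MARKER_NAMES = ("AFP", "CEA", "CA199", "CA724", "CA125", "NSE")

DAYS_PER_MONTH = 30.44
DAYS_PER_YEAR = 365.25


class ValidationError(ValueError):
    """A record violates a cohort invariant."""


class CellClass(str, enum.Enum):
    CTC = "CTC"
    CEC = "CEC"
    UNKNOWN = "unknown"


class ResponseLabel(str, enum.Enum):
    RESPONDER = "responder"
    NON_RESPONDER = "non_responder"
    UNKNOWN = "unknown"


class RecistLabel(str, enum.Enum):
    CR = "CR"
    PR = "PR"
    SD = "SD"
    PD = "PD"
    UNKNOWN = "unknown"


_RECIST_TO_RESPONSE = {
    RecistLabel.CR: ResponseLabel.RESPONDER,
    RecistLabel.PR: ResponseLabel.RESPONDER,
    RecistLabel.SD: ResponseLabel.NON_RESPONDER,
    RecistLabel.PD: ResponseLabel.NON_RESPONDER,
}


@dataclass(frozen=True)
class MarkerPanel:
    """One blood draw's six tumor-marker values (assay units, >= 0).

    Missing values are NaN; the unit strings are metadata only.
    """

    values: tuple  # six floats ordered as MARKER_NAMES, NaN = missing

    def __post_init__(self):
        if len(self.values) != len(MARKER_NAMES):
            raise ValidationError(
                f"marker panel needs {len(MARKER_NAMES)} values, got {len(self.values)}")
        for name, v in zip(MARKER_NAMES, self.values):
            if math.isinf(v):
                raise ValidationError(f"marker {name} is non-finite")
            if not math.isnan(v) and v < 0:
                raise ValidationError(f"marker {name} negative: {v}")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.as_array()).sum())


@dataclass(frozen=True)
class MarkerObservation:
    t_days: float
    panel: MarkerPanel

    def __post_init__(self):
        if not math.isfinite(self.t_days):
            raise ValidationError("marker observation time must be finite")


@dataclass
class CellImage:
    """A single-cell crop: H x W x 3 reals in [0, 1] plus class tag."""

    pixels: np.ndarray
    source_path: str = ""
    cell_class: CellClass = CellClass.UNKNOWN

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValidationError(f"cell image must be HxWx3, got {px.shape}")
        if px.shape[0] < 8 or px.shape[1] < 8:
            raise ValidationError("cell image smaller than 8x8")
        if not np.isfinite(px).all():
            raise ValidationError("cell image has non-finite pixels")
        if px.min() < 0 or px.max() > 1:
            raise ValidationError("cell image pixels outside [0,1]")
        self.pixels = px


@dataclass
class CellObservation:
    t_days: float
    images: list  # of CellImage; order carries no meaning

    def __post_init__(self):
        if not self.images:
            raise ValidationError("cell observation with no images")
        if not math.isfinite(self.t_days):
            raise ValidationError("cell observation time must be finite")


@dataclass
class PatientRecord:
    patient_id: str
    cell_series: list = field(default_factory=list)    # CellObservation
    marker_series: list = field(default_factory=list)  # MarkerObservation
    label: ResponseLabel = ResponseLabel.UNKNOWN
    rec_label: RecistLabel = RecistLabel.UNKNOWN

    def __post_init__(self):
        if not self.cell_series and not self.marker_series:
            raise ValidationError(
                f"patient {self.patient_id}: no observations in either modality")
        self.cell_series = sorted(self.cell_series, key=lambda o: o.t_days)
        self.marker_series = sorted(self.marker_series, key=lambda o: o.t_days)
        implied = _RECIST_TO_RESPONSE.get(self.rec_label)
        if implied is not None and self.label is not ResponseLabel.UNKNOWN \
                and self.label is not implied:
            raise ValidationError(
                f"patient {self.patient_id}: RECIST {self.rec_label.value} "
                f"implies {implied.value}, got label {self.label.value}")
        if implied is not None and self.label is ResponseLabel.UNKNOWN:
            self.label = implied

    @property
    def n_images(self) -> int:
        return sum(len(o.images) for o in self.cell_series)


@dataclass
class Cohort:
    patients: list
    name: str = "cohort"

    def __post_init__(self):
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate patient ids: {dupes}")

    def __len__(self):
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    def labelled(self) -> list:
        return [p for p in self.patients if p.label is not ResponseLabel.UNKNOWN]


@dataclass(frozen=True)
class TimeWindow:
    """Upper time bound on observations (inclusive); pre-baseline kept."""

    name: str
    upper_days: float


STANDARD_WINDOWS = {
    "pre_bl": TimeWindow("pre_bl", 0.0),
    "d45": TimeWindow("d45", 45.0),
    "m3": TimeWindow("m3", 3 * DAYS_PER_MONTH),
    "m6": TimeWindow("m6", 6 * DAYS_PER_MONTH),
    "y1": TimeWindow("y1", DAYS_PER_YEAR),
    "all": TimeWindow("all", math.inf),
}


def restrict_time_window(record: PatientRecord, window: TimeWindow) -> PatientRecord:
    """Copy of `record` keeping observations with t_days <= window bound.

    Pre-baseline observations (t_days <= 0) are always retained. Raises
    ValidationError if nothing remains in either modality.
    """
    keep = lambda t: t <= window.upper_days or t <= 0.0
    cells = [o for o in record.cell_series if keep(o.t_days)]
    markers = [o for o in record.marker_series if keep(o.t_days)]
    if not cells and not markers:
        raise ValidationError(
            f"patient {record.patient_id}: no data in window {window.name}")
    return replace(record, cell_series=cells, marker_series=markers)


# ---------------------------------------------------------------------------
# image I/O

def load_image(path, cell_class: CellClass = CellClass.UNKNOWN) -> CellImage:
    """Load a PNG/TIFF crop and normalise pixel values to [0, 1]."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=float) / 255.0
    return CellImage(pixels=arr, source_path=str(path), cell_class=cell_class)


def save_image(img: CellImage, path) -> None:
    arr = np.clip(np.round(img.pixels * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(path)


# ---------------------------------------------------------------------------
# manifest I/O

def write_manifest(cohort: Cohort, out_dir) -> Path:
    """Serialise a cohort: manifest.json + markers.csv + PNG crops.

    Layout is canonical (sorted keys, fixed file naming) so that
    write -> read -> write is byte-identical.
    """
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)

    marker_rows = []
    patients_json = []
    for p in sorted(cohort.patients, key=lambda q: q.patient_id):
        cells_json = []
        for ti, obs in enumerate(p.cell_series):
            paths, classes = [], []
            for ci, img in enumerate(obs.images):
                rel = f"images/{p.patient_id}_t{ti:02d}_c{ci:03d}.png"
                save_image(img, out_dir / rel)
                paths.append(rel)
                classes.append(img.cell_class.value)
            cells_json.append({"t_days": float(obs.t_days),
                               "images": paths, "classes": classes})
        for obs in p.marker_series:
            row = {"patient_id": p.patient_id, "t_days": float(obs.t_days)}
            row.update({n: v for n, v in zip(MARKER_NAMES, obs.panel.values)})
            marker_rows.append(row)
        patients_json.append({
            "patient_id": p.patient_id,
            "label": p.label.value,
            "recist": p.rec_label.value,
            "cells": cells_json,
            "markers_csv_ref": "markers.csv",
        })

    df = pd.DataFrame(marker_rows,
                      columns=["patient_id", "t_days", *MARKER_NAMES])
    df.to_csv(out_dir / "markers.csv", index=False, float_format="%.10g")

    manifest = {"name": cohort.name, "patients": patients_json}
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def read_manifest(path) -> Cohort:
    """Load and validate a cohort manifest written by :func:`write_manifest`.

    Images are loaded eagerly (crops are small); marker rows are joined
    to patients by ``patient_id``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    base = path.parent
    try:
        manifest = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise ValidationError(f"manifest is not valid JSON: {e}") from e
    if "patients" not in manifest:
        raise ValidationError("manifest missing 'patients' key")

    marker_df = None
    csv_path = base / "markers.csv"
    if csv_path.exists():
        marker_df = pd.read_csv(csv_path)

    patients = []
    for pj in manifest["patients"]:
        pid = pj.get("patient_id")
        if not pid:
            raise ValidationError("patient entry without patient_id")
        try:
            label = ResponseLabel(pj.get("label", "unknown"))
            recist = RecistLabel(pj.get("recist", "unknown"))
        except ValueError as e:
            raise ValidationError(f"patient {pid}: bad label ({e})") from e
        cell_series = []
        for obs in pj.get("cells", []):
            images = []
            classes = obs.get("classes") or ["unknown"] * len(obs["images"])
            for rel, cls in zip(obs["images"], classes):
                images.append(load_image(base / rel, CellClass(cls)))
            cell_series.append(CellObservation(t_days=float(obs["t_days"]),
                                               images=images))
        marker_series = []
        if marker_df is not None:
            rows = marker_df[marker_df["patient_id"] == pid]
            for _, row in rows.iterrows():
                panel = MarkerPanel(tuple(float(row[n]) for n in MARKER_NAMES))
                marker_series.append(
                    MarkerObservation(t_days=float(row["t_days"]), panel=panel))
        try:
            patients.append(PatientRecord(
                patient_id=pid, cell_series=cell_series,
                marker_series=marker_series, label=label, rec_label=recist))
        except ValidationError as e:
            raise ValidationError(f"patient {pid}: {e}") from e
    return Cohort(patients=patients, name=manifest.get("name", "cohort"))
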