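"""Biometry cohort and IOL-database data model, validation, and file I/O.

Units follow the conventions of optical biometers: axial distances in mm,
central corneal thickness in µm, keratometry in diopters (keratometric
index 1.3375), refractions in diopters (spherical equivalent, spectacle
plane).  The preoperative anterior chamber depth is the *external* ACD
(corneal epithelium to crystalline-lens front); routines that need an
endothelium-referenced depth subtract the corneal thickness internally.
"""
from __future__ import annotations

import csv
import json
import math
from pathlib import Path
from typing import Literal, Optional

import pydantic
from pydantic import BaseModel, Field, model_validator

from .errors import CapabilityError, RecordValidationError, SchemaError

#: exact cohort CSV column set, in file order
COHORT_COLUMNS = [
    "patient_id", "eye", "al_mm", "acd_mm", "lt_mm", "cct_um",
    "k1_d", "k2_d", "wtw_mm", "pupil_mm", "iol_model", "iol_power_d",
    "postop_se_d",
]

_OPTIONAL_FIELDS = {"cct_um", "wtw_mm", "pupil_mm", "iol_model",
                    "iol_power_d", "postop_se_d"}


class BiometryRecord(BaseModel):
    """One eye's preoperative measurements plus, when known, the implanted
    IOL and the observed postoperative refraction.

    Optional measurements are ``None`` when absent, never 0.
    """

    patient_id: str
    eye: Literal["OD", "OS"]
    al: float = Field(ge=15, le=40, description="axial length, mm")
    acd: float = Field(ge=1.5, le=5.5,
                       description="external anterior chamber depth, mm")
    lt: float = Field(ge=2.5, le=6.5, description="lens thickness, mm")
    k1: float = Field(ge=30, le=60, description="keratometry K1, D")
    k2: float = Field(ge=30, le=60, description="keratometry K2, D")
    cct: Optional[float] = Field(default=None, ge=400, le=700,
                                 description="central corneal thickness, µm")
    wtw: Optional[float] = Field(default=None, gt=0,
                                 description="corneal diameter, mm")
    pupil: Optional[float] = Field(default=None, gt=0,
                                   description="photopic pupil diameter, mm")
    implanted_model: Optional[str] = None
    implanted_power: Optional[float] = None
    postop_se: Optional[float] = None

    @model_validator(mode="after")
    def _check_axial_budget(self) -> "BiometryRecord":
        if not self.acd + self.lt < self.al:
            raise ValueError(
                f"acd + lt = {self.acd + self.lt:.2f} mm must be smaller "
                f"than al = {self.al:.2f} mm")
        return self

    @property
    def mean_k(self) -> float:
        """Mean keratometry (K1 + K2)/2, D."""
        return 0.5 * (self.k1 + self.k2)

    @property
    def cct_mm(self) -> float:
        """Corneal thickness in mm; 0.54 mm assumed when unmeasured."""
        return self.cct / 1000.0 if self.cct is not None else 0.54


class IOLGeometry(BaseModel):
    """Physical description of one labeled power of an IOL model.

    Radii are signed vertex radii (positive = center of curvature toward
    the retina), so a biconvex optic has ``r_front > 0 > r_back``.
    """

    r_front: float
    r_back: float
    thickness: float = Field(gt=0, lt=2.5)
    n_iol: float = Field(gt=1.4, lt=1.6)
    q_front: float = 0.0
    q_back: float = 0.0

    @model_validator(mode="after")
    def _nonzero_radii(self) -> "IOLGeometry":
        if self.r_front == 0 or self.r_back == 0:
            raise ValueError("vertex radii must be nonzero")
        return self


class IOLModel(BaseModel):
    """Constants and optional physical geometry for one IOL model.

    At least one constant set (A-constant, personalized ACD, surgeon
    factor, or Haigis triplet) must be present.  ``geometry_table`` maps
    labeled power (D) to :class:`IOLGeometry` and is required only for
    ray tracing.
    """

    model_id: str
    a_constant: Optional[float] = None
    pacd: Optional[float] = None
    sf: Optional[float] = None
    a0: Optional[float] = None
    a1: Optional[float] = None
    a2: Optional[float] = None
    geometry_table: dict[float, IOLGeometry] = Field(default_factory=dict)

    model_config = pydantic.ConfigDict(protected_namespaces=())

    @model_validator(mode="after")
    def _check(self) -> "IOLModel":
        has_haigis = all(v is not None for v in (self.a0, self.a1, self.a2))
        if (self.a_constant is None and self.pacd is None
                and self.sf is None and not has_haigis):
            raise ValueError(f"{self.model_id}: no IOL constants given")
        powers = list(self.geometry_table)
        if powers != sorted(powers) or len(set(powers)) != len(powers):
            raise ValueError(f"{self.model_id}: geometry powers must be "
                             "strictly increasing")
        if powers and (powers[0] < -10 or powers[-1] > 40):
            raise ValueError(f"{self.model_id}: labeled powers outside "
                             "[-10, 40] D")
        return self

    @property
    def can_raytrace(self) -> bool:
        return len(self.geometry_table) >= 2

    def require_geometry(self) -> None:
        if not self.can_raytrace:
            raise CapabilityError(
                f"IOL model {self.model_id!r} has no geometry table; "
                "ray tracing is unavailable for it")


def _parse_row(row: dict[str, str], idx: int) -> BiometryRecord:
    pid = (row.get("patient_id") or "").strip()
    kwargs: dict = {"patient_id": pid, "eye": (row.get("eye") or "").strip()}
    mapping = {"al": "al_mm", "acd": "acd_mm", "lt": "lt_mm", "cct": "cct_um",
               "k1": "k1_d", "k2": "k2_d", "wtw": "wtw_mm",
               "pupil": "pupil_mm", "implanted_power": "iol_power_d",
               "postop_se": "postop_se_d"}
    for field, col in mapping.items():
        raw = (row.get(col) or "").strip()
        if raw == "":
            kwargs[field] = None
            continue
        try:
            kwargs[field] = float(raw)
        except ValueError:
            raise RecordValidationError(
                f"column {col!r}: {raw!r} is not a number",
                patient_id=pid, row=idx) from None
    model = (row.get("iol_model") or "").strip()
    kwargs["implanted_model"] = model or None
    for field in ("al", "acd", "lt", "k1", "k2"):
        if kwargs[field] is None:
            raise RecordValidationError(
                f"mandatory field {field!r} is empty", patient_id=pid, row=idx)
    try:
        return BiometryRecord(**kwargs)
    except pydantic.ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"]) or "record"
        raise RecordValidationError(
            f"{loc}: {first['msg']}", patient_id=pid, row=idx) from None


def read_cohort_csv(path: str | Path) -> list[BiometryRecord]:
    """Read a biometry cohort CSV into validated records, preserving order.

    Raises :class:`SchemaError` when a declared column is missing and
    :class:`RecordValidationError` (with patient id and row number) when a
    row violates a physiologic invariant.  There is no silent coercion.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, header row required")
        missing = [c for c in COHORT_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing mandatory column(s) "
                              f"{', '.join(missing)}")
        return [_parse_row(row, i) for i, row in enumerate(reader, start=2)]


def write_cohort_csv(records: list[BiometryRecord], path: str | Path) -> None:
    """Write records using the canonical column set at 4-decimal precision."""
    path = Path(path)

    def fmt(v) -> str:
        if v is None:
            return ""
        if isinstance(v, float):
            return f"{v:.4f}"
        return str(v)

    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(COHORT_COLUMNS)
        for r in records:
            writer.writerow([
                r.patient_id, r.eye, fmt(r.al), fmt(r.acd), fmt(r.lt),
                fmt(r.cct), fmt(r.k1), fmt(r.k2), fmt(r.wtw), fmt(r.pupil),
                fmt(r.implanted_model), fmt(r.implanted_power),
                fmt(r.postop_se)])


def read_iol_database(path: str | Path) -> dict[str, IOLModel]:
    """Load an IOL-constant/geometry database from JSON.

    The file holds a list of objects with keys ``model_id``, the constant
    fields, and an optional ``geometry`` list of per-power entries.
    Duplicate model ids are an error.
    """
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        raw = json.load(fh)
    if not isinstance(raw, list):
        raise SchemaError(f"{path}: expected a JSON list of IOL models")
    db: dict[str, IOLModel] = {}
    for entry in raw:
        try:
            model = iol_model_from_dict(entry)
        except (pydantic.ValidationError, KeyError, TypeError) as exc:
            raise SchemaError(f"{path}: malformed IOL entry: {exc}") from None
        if model.model_id in db:
            raise SchemaError(
                f"{path}: duplicate model_id {model.model_id!r}")
        db[model.model_id] = model
    return db


def iol_model_from_dict(entry: dict) -> IOLModel:
    """Build an :class:`IOLModel` from a plain-dict database entry."""
    geometry = {}
    for g in entry.get("geometry", []) or []:
        geometry[float(g["power_d"])] = IOLGeometry(
            r_front=g["r_front_mm"], r_back=g["r_back_mm"],
            thickness=g["thickness_mm"], n_iol=g["n_iol"],
            q_front=g.get("q_front", 0.0), q_back=g.get("q_back", 0.0))
    return IOLModel(
        model_id=entry["model_id"],
        a_constant=entry.get("a_constant"),
        pacd=entry.get("pacd"), sf=entry.get("sf"),
        a0=entry.get("a0"), a1=entry.get("a1"), a2=entry.get("a2"),
        geometry_table=dict(sorted(geometry.items())))


def write_iol_database(db: dict[str, IOLModel], path: str | Path) -> None:
    """Serialize an IOL database back to the JSON schema of
    :func:`read_iol_database`."""
    out = []
    for model in db.values():
        entry: dict = {"model_id": model.model_id}
        for key in ("a_constant", "pacd", "sf", "a0", "a1", "a2"):
            val = getattr(model, key)
            if val is not None:
                entry[key] = val
        if model.geometry_table:
            entry["geometry"] = [
                {"power_d": p, "r_front_mm": g.r_front, "r_back_mm": g.r_back,
                 "thickness_mm": g.thickness, "n_iol": g.n_iol,
                 "q_front": g.q_front, "q_back": g.q_back}
                for p, g in model.geometry_table.items()]
        out.append(entry)
    Path(path).write_text(json.dumps(out, indent=1), encoding="utf-8")
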