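"""Prediction of the postoperative IOL position (effective lens position).

Two anatomy-driven predictors are provided — one scaling a reference
chamber depth by axial length, one building on the preoperative anterior
chamber depth and crystalline-lens thickness — together with the linear
Haigis predictor.  All positions are referenced to the posterior corneal
vertex; ``elp_center`` locates the optical center of the IOL and
``elp_front_vertex = elp_center - thickness/2`` its anterior vertex.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

from .biometry import BiometryRecord, IOLGeometry, IOLModel
from .errors import CapabilityError, DomainError

ElpMethod = Literal["scaled_al", "lens_thickness", "mean", "haigis"]

#: mean-eye reference constants: chamber depth of a 21 D reference IOL in a
#: mean-sized eye, mean axial length, and the axial-length scaling exponent
CM_MM = 4.6
AM_MM = 23.6
EXPONENT = 0.7


@dataclass(frozen=True)
class ElpPrediction:
    """Predicted IOL position, posterior-cornea referenced, mm."""

    elp_center: float
    elp_front_vertex: float
    method: ElpMethod

    @classmethod
    def from_center(cls, center: float, thickness: float,
                    method: ElpMethod) -> "ElpPrediction":
        return cls(center, center - 0.5 * thickness, method)


@dataclass(frozen=True)
class ElpConfig:
    """Tunables of the anatomical ELP predictors.

    ``mean_eye_depth_mm`` is the model-specific chamber depth (IOL center,
    posterior-cornea referenced) in a mean-sized eye; when ``None`` it is
    derived from the SRK/T A-constant as ``0.62467*A - 68.747 - 0.54``
    (the epithelium-referenced postoperative chamber-depth constant minus
    an average corneal thickness).  ``ref_thickness_mm`` is the central
    thickness of the 21 D reference IOL of the same model.
    """

    mode: ElpMethod | Literal["auto"] = "auto"
    cm_mm: float = CM_MM
    am_mm: float = AM_MM
    exponent: float = EXPONENT
    mean_eye_depth_mm: Optional[float] = None
    ref_thickness_mm: Optional[float] = None


def elp_scaled_al(a: float, mean_eye_depth: float, d: float, d_m: float,
                  c_m: float = CM_MM, a_m: float = AM_MM,
                  exponent: float = EXPONENT) -> ElpPrediction:
    """Axial-length-scaled chamber depth.

    The reference depth ``c_m`` (4.6 mm, a 21 D IOL centered in a mean
    23.6 mm eye) is scaled by ``(a/a_m)**exponent``; the model offset
    ``mean_eye_depth - c_m`` and half the thickness difference against
    the reference IOL complete the prediction::

        A_a = c_m * (a/a_m)**exponent + A_m - c_m - 0.5*(d - d_m)
    """
    if a < 15 or a > 40:
        raise DomainError(f"axial length {a} mm outside [15, 40]")
    if d <= 0 or d_m <= 0:
        raise DomainError("IOL thicknesses must be positive")
    center = (c_m * (a / a_m) ** exponent + mean_eye_depth - c_m
              - 0.5 * (d - d_m))
    return ElpPrediction.from_center(center, d, "scaled_al")


def elp_lens_thickness(a_p: float, t_l: float, d: float, *,
                       validate: bool = True) -> ElpPrediction:
    """Chamber depth from preoperative ACD and crystalline-lens thickness.

    ``a_p`` must be referenced to the posterior cornea (subtract the
    corneal thickness from an externally measured ACD first)::

        A = A_p + 0.574*t_L - 0.632 - 0.5*d

    ``validate=False`` lifts the physiologic range checks (used by
    degenerate-input tests only).
    """
    if validate:
        if not 1.5 <= a_p <= 5.5:
            raise DomainError(f"preoperative ACD {a_p} mm outside [1.5, 5.5]")
        if not 2.5 <= t_l <= 6.5:
            raise DomainError(f"lens thickness {t_l} mm outside [2.5, 6.5]")
    if d < 0:
        raise DomainError("IOL thickness must be nonnegative")
    center = a_p + 0.574 * t_l - 0.632 - 0.5 * d
    return ElpPrediction.from_center(center, d, "lens_thickness")


def elp_haigis(acd: float, al: float, a0: float, a1: float, a2: float,
               thickness: float = 0.0) -> ElpPrediction:
    """Linear Haigis position ``d = a0 + a1*ACD + a2*AL`` (external ACD)."""
    import math
    for name, v in (("a0", a0), ("a1", a1), ("a2", a2)):
        if v is None or not math.isfinite(v):
            raise DomainError(f"Haigis constant {name} must be finite")
    center = a0 + a1 * acd + a2 * al
    return ElpPrediction.from_center(center, max(thickness, 0.0), "haigis")


def _mean_eye_depth(config: ElpConfig, iol: Optional[IOLModel]) -> float:
    if config.mean_eye_depth_mm is not None:
        return config.mean_eye_depth_mm
    if iol is not None and iol.a_constant is not None:
        return 0.62467 * iol.a_constant - 68.747 - 0.54
    raise CapabilityError(
        "scaled_al mode needs mean_eye_depth_mm or an IOL A-constant")


def _ref_thickness(config: ElpConfig, iol: Optional[IOLModel],
                   geometry: IOLGeometry) -> float:
    if config.ref_thickness_mm is not None:
        return config.ref_thickness_mm
    if iol is not None and iol.can_raytrace:
        from .raytrace import interpolate_geometry  # local: avoid cycle
        powers = list(iol.geometry_table)
        p21 = min(max(21.0, powers[0]), powers[-1])
        return interpolate_geometry(iol, p21).thickness
    return geometry.thickness


def predict_iol_position(record: BiometryRecord, geometry: IOLGeometry,
                         mode: ElpMethod | Literal["auto"] = "auto",
                         config: ElpConfig = ElpConfig(),
                         iol: Optional[IOLModel] = None) -> ElpPrediction:
    """Dispatch to an ELP predictor for a concrete eye and IOL geometry.

    ``mode='auto'`` averages the axial-length-scaled and lens-thickness
    predictions when both ACD and LT are present (method tag ``mean``)
    and falls back to ``scaled_al`` otherwise.  The lens-thickness
    predictor receives the endothelium-referenced ACD
    (``record.acd - cct``).
    """
    if mode == "auto":
        mode = "mean" if (record.acd is not None and record.lt is not None) \
            else "scaled_al"
    d = geometry.thickness

    def scaled() -> ElpPrediction:
        return elp_scaled_al(
            record.al, _mean_eye_depth(config, iol), d,
            _ref_thickness(config, iol, geometry),
            config.cm_mm, config.am_mm, config.exponent)

    def lens() -> ElpPrediction:
        if record.acd is None or record.lt is None:
            raise CapabilityError(
                "lens_thickness mode needs both ACD and lens thickness")
        return elp_lens_thickness(record.acd - record.cct_mm, record.lt, d)

    if mode == "scaled_al":
        return scaled()
    if mode == "lens_thickness":
        return lens()
    if mode == "mean":
        center = 0.5 * (scaled().elp_center + lens().elp_center)
        return ElpPrediction.from_center(center, d, "mean")
    if mode == "haigis":
        if iol is None or any(v is None for v in (iol.a0, iol.a1, iol.a2)):
            raise CapabilityError("haigis mode needs a0/a1/a2 constants")
        if record.acd is None:
            raise CapabilityError("haigis mode needs the preoperative ACD")
        return elp_haigis(record.acd, record.al, iol.a0, iol.a1, iol.a2, d)
    raise ValueError(f"unknown ELP mode {mode!r}")
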