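"""Thin-lens (vergence) IOL power formulas: SRK/T, Hoffer Q, Holladay 1,
Haigis, plus the axial-length-based formula selection rule.

Every formula is its own effective-lens-position model feeding one shared
two-element paraxial vergence chain: refraction of a distant object at the
corneal plane, translation to the IOL plane in aqueous (n = 1.336),
addition of the IOL power, and the requirement that the image lands on
the retina.  Predicted refractions are reported as spherical equivalents
at the spectacle plane (vertex distance 12 mm).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Optional

from .biometry import BiometryRecord, IOLModel
from .errors import (CapabilityError, FormulaDomainError,
                     VergenceSingularityError)

FormulaId = Literal["srkt", "hofferq", "holladay1", "haigis", "raytrace"]

#: default IOL power grid, diopters
POWER_STEP = 0.5
POWER_MIN = -10.0
POWER_MAX = 40.0


@dataclass(frozen=True)
class KeratometricConvention:
    """Refractive-index conventions of the keratometer and the eye model."""

    n_k: float = 1.3375          # keratometric index (Haigis uses 1.3315)
    n_aqueous: float = 1.336
    vertex_mm: float = 12.0      # spectacle vertex distance

    def __post_init__(self):
        if not 1.3 < self.n_k < 1.4:
            raise ValueError(f"keratometric index {self.n_k} implausible")


@dataclass(frozen=True)
class FormulaResult:
    """Output of one formula for one eye."""

    formula_id: FormulaId
    emmetropic_power: float      # D, power giving 0.00 predicted refraction
    chosen_power: float          # D, on the configured grid
    predicted_se: float          # D at spectacle plane for chosen_power
    elp_used: float              # mm
    constants_used: dict = field(default_factory=dict)


def corneal_power(k_reading_d: Optional[float] = None,
                  radius_mm: Optional[float] = None,
                  convention: KeratometricConvention = KeratometricConvention()
                  ) -> float:
    """Convert between corneal radius (mm) and keratometric power (D).

    Given a radius, returns ``(n_k - 1) * 1000 / r``; given a reading,
    returns the radius implied by the same relation, so the mapping is an
    exact involution pair.
    """
    if (k_reading_d is None) == (radius_mm is None):
        raise ValueError("give exactly one of k_reading_d or radius_mm")
    if radius_mm is not None:
        if radius_mm <= 0:
            raise FormulaDomainError("corneal radius must be positive")
        return (convention.n_k - 1.0) * 1000.0 / radius_mm
    if k_reading_d <= 0:
        raise FormulaDomainError("corneal power must be positive")
    return (convention.n_k - 1.0) * 1000.0 / k_reading_d


def predict_refraction_vergence(
        al: float, k_d: float, elp: float, p_iol: float,
        convention: KeratometricConvention = KeratometricConvention(),
) -> float:
    """Spectacle-plane refraction of a pseudophakic eye in the thin-lens
    model: axial length ``al`` (mm), corneal power ``k_d`` (D), thin IOL
    of power ``p_iol`` at depth ``elp`` (mm).

    Solved exactly by running the vergence chain backwards from the
    retina; strictly decreasing in ``p_iol``.
    """
    if not 0 < elp < al:
        raise VergenceSingularityError(
            f"ELP {elp} mm must lie inside the eye (AL {al} mm)")
    na = 1000.0 * convention.n_aqueous
    v3 = na / (al - elp)               # vergence leaving the IOL
    v2 = v3 - p_iol                    # vergence arriving at the IOL
    denom = na / v2 + elp if v2 != 0 else math.inf
    if v2 == 0 or denom == 0:
        raise VergenceSingularityError(
            "image at infinity inside the vergence chain "
            f"(al={al}, k={k_d}, elp={elp}, p={p_iol})")
    v1 = na / denom                    # vergence leaving the cornea
    rc = v1 - k_d                      # corneal-plane refraction
    vd = convention.vertex_mm / 1000.0
    if 1.0 + vd * rc == 0:
        raise VergenceSingularityError("refraction singular at vertex")
    return rc / (1.0 + vd * rc)


def emmetropic_power(al: float, k_d: float, elp: float,
                     convention: KeratometricConvention =
                     KeratometricConvention()) -> float:
    """IOL power at depth ``elp`` that images a distant object on the
    retina (predicted refraction exactly zero)."""
    if not 0 < elp < al:
        raise VergenceSingularityError(
            f"ELP {elp} mm must lie inside the eye (AL {al} mm)")
    na = 1000.0 * convention.n_aqueous
    denom = na / k_d - elp
    if denom == 0:
        raise VergenceSingularityError("corneal image at the IOL plane")
    return na / (al - elp) - na / denom


def choose_power_on_grid(predict: Callable[[float], float], target_d: float,
                         emme: float, step: float = POWER_STEP,
                         lo: float = POWER_MIN, hi: float = POWER_MAX,
                         ) -> tuple[float, float]:
    """Pick the grid power whose predicted refraction is closest to the
    target; exact ties resolve to the higher power (myopic outcome).

    Returns ``(chosen_power, predicted_se_at_chosen)``.  The search is a
    local scan around the emmetropic power, which is sufficient because
    predicted refraction is strictly decreasing in power.  When the
    emmetropic power lies beyond the grid altogether (extreme long or
    short eyes) the nearest grid bound is chosen, as in the clinic.
    """
    grid_lo, grid_hi = lo, hi
    lo = max(grid_lo, step * math.floor((emme - 6.0) / step))
    hi = min(grid_hi, step * math.ceil((emme + 6.0) / step))
    if lo > hi:
        lo = hi = grid_lo if emme < grid_lo else grid_hi
    best: tuple[float, float, float] | None = None   # (|diff|, power, se)
    p = lo
    while p <= hi + 1e-9:
        se = predict(p)
        d = abs(se - target_d)
        if best is None or d < best[0] - 1e-12 or (
                abs(d - best[0]) <= 1e-12 and p > best[1]):
            best = (d, p, se)
        p += step
    assert best is not None
    return best[1], best[2]


def _result(formula_id: FormulaId, al_opt: float, kc: float, elp: float,
            target_d: float, convention: KeratometricConvention,
            constants: dict, step: float = POWER_STEP) -> FormulaResult:
    emme = emmetropic_power(al_opt, kc, elp, convention)
    chosen, se = choose_power_on_grid(
        lambda p: predict_refraction_vergence(al_opt, kc, elp, p, convention),
        target_d, emme, step)
    return FormulaResult(formula_id, emme, chosen, se, elp, constants)


def srkt(record: BiometryRecord, constants: IOLModel, target_d: float = 0.0,
         step: float = POWER_STEP, *,
         clamp_corneal_height: bool = False) -> FormulaResult:
    """SRK/T: corneal-height ELP from corneal width, long-eye axial-length
    correction, retinal-thickness term, and the A-constant-to-ACD-constant
    conversion, composed with the shared vergence chain (corneal index
    1.333).

    At extreme steep-cornea/long-eye combinations the corneal-height
    square root goes negative; by default that raises, while
    ``clamp_corneal_height=True`` caps the height at the corneal radius
    (the usual clinical-calculator guard) so batch pipelines stay total.
    """
    if constants.a_constant is None:
        raise CapabilityError(f"{constants.model_id}: SRK/T needs a_constant")
    al, k = record.al, record.mean_k
    r = 337.5 / k
    lcor = al if al <= 24.2 else -3.446 + 1.715 * al - 0.0237 * al * al
    cw = -5.41 + 0.58412 * lcor + 0.098 * k
    arg = r * r - cw * cw / 4.0
    if arg < 0:
        if not clamp_corneal_height:
            raise FormulaDomainError(
                f"SRK/T corneal height undefined for AL={al}, K={k} "
                "(corneal width exceeds corneal diameter)")
        arg = 0.0
    h = r - math.sqrt(arg)
    acd_const = 0.62467 * constants.a_constant - 68.747
    elp = h + acd_const - 3.336
    lopt = al + 0.65696 - 0.02029 * al
    kc = 1000.0 * 0.333 / r
    conv = KeratometricConvention(n_k=1.333)
    return _result("srkt", lopt, kc, elp, target_d, conv,
                   {"a_constant": constants.a_constant}, step)


def hofferq(record: BiometryRecord, constants: IOLModel,
            target_d: float = 0.0, step: float = POWER_STEP) -> FormulaResult:
    """Hoffer Q: tangent-term personalized ACD with axial-length clamping
    to [18.5, 31] mm, composed with the shared vergence chain on the
    measured keratometry."""
    if constants.pacd is None:
        raise CapabilityError(f"{constants.model_id}: Hoffer Q needs pacd")
    al, k = record.al, record.mean_k
    alc = min(max(al, 18.5), 31.0)
    if al <= 23.0:
        m, g = 1.0, 28.0
    else:
        m, g = -1.0, 23.5
    t = math.tan(math.radians(k))
    acd = (constants.pacd + 0.3 * (alc - 23.5) + t * t
           + 0.1 * m * (23.5 - alc) ** 2
           * math.tan(math.radians(0.1 * (g - alc) ** 2)) - 0.99166)
    elp = acd + 0.05
    return _result("hofferq", al, k, elp, target_d, KeratometricConvention(),
                   {"pacd": constants.pacd}, step)


def holladay1(record: BiometryRecord, constants: IOLModel,
              target_d: float = 0.0, step: float = POWER_STEP
              ) -> FormulaResult:
    """Holladay 1: corneal-height anatomical chamber depth plus surgeon
    factor, retinal thickness 0.2 mm, corneal index 4/3."""
    if constants.sf is None:
        raise CapabilityError(
            f"{constants.model_id}: Holladay 1 needs surgeon factor")
    al, k = record.al, record.mean_k
    r = 337.5 / k
    ag = min(12.5 * al / 23.45, 13.5)
    arg = r * r - ag * ag / 4.0
    if arg < 0:
        raise FormulaDomainError(
            f"Holladay 1 corneal height undefined for AL={al}, K={k}")
    elp = 0.56 + r - math.sqrt(arg) + constants.sf
    alm = al + 0.2
    kc = 1000.0 * (4.0 / 3.0 - 1.0) / r
    conv = KeratometricConvention(n_k=4.0 / 3.0)
    return _result("holladay1", alm, kc, elp, target_d, conv,
                   {"sf": constants.sf}, step)


def haigis_formula(record: BiometryRecord, constants: IOLModel,
                   target_d: float = 0.0, step: float = POWER_STEP
                   ) -> FormulaResult:
    """Haigis: linear ELP on preoperative ACD and AL, corneal power from
    the 1.3315 keratometric index."""
    if any(v is None for v in (constants.a0, constants.a1, constants.a2)):
        raise CapabilityError(
            f"{constants.model_id}: Haigis needs a0, a1, a2")
    if record.acd is None:
        raise CapabilityError("Haigis needs the preoperative ACD")
    al, k = record.al, record.mean_k
    elp = constants.a0 + constants.a1 * record.acd + constants.a2 * al
    r = 337.5 / k
    kc = 1000.0 * (1.3315 - 1.0) / r
    conv = KeratometricConvention(n_k=1.3315)
    return _result("haigis", al, kc, elp, target_d, conv,
                   {"a0": constants.a0, "a1": constants.a1,
                    "a2": constants.a2}, step)


def select_formula_by_al(al: float) -> FormulaId:
    """Axial-length rule for formula choice: Hoffer Q below 22 mm,
    Holladay 1 from 22 to 26 mm, SRK/T above 26 mm."""
    if al < 22.0:
        return "hofferq"
    if al <= 26.0:
        return "holladay1"
    return "srkt"


THIN_LENS_FORMULAS: dict[str, Callable[..., FormulaResult]] = {
    "srkt": srkt, "hofferq": hofferq, "holladay1": holladay1,
    "haigis": haigis_formula,
}


def calc_formula(record: BiometryRecord, constants: IOLModel,
                 formula: str, target_d: float = 0.0,
                 step: float = POWER_STEP,
                 clamp_srkt: bool = False) -> FormulaResult:
    """Run one named thin-lens formula, or ``auto`` for the AL-based rule."""
    if formula == "auto":
        formula = select_formula_by_al(record.al)
    try:
        fn = THIN_LENS_FORMULAS[formula]
    except KeyError:
        raise ValueError(f"unknown thin-lens formula {formula!r}") from None
    if formula == "srkt":
        return fn(record, constants, target_d, step,
                  clamp_corneal_height=clamp_srkt)
    return fn(record, constants, target_d, step)


def predicted_refraction_at(record: BiometryRecord, constants: IOLModel,
                            formula: str, power: float,
                            clamp_srkt: bool = False) -> float:
    """Predicted spectacle refraction of a named formula for an arbitrary
    (not necessarily grid) IOL power."""
    res = calc_formula(record, constants, formula, clamp_srkt=clamp_srkt)
    # re-run the chain with the formula's own optical parameters
    if formula == "srkt":
        al = record.al + 0.65696 - 0.02029 * record.al
        r = 337.5 / record.mean_k
        kc = 1000.0 * 0.333 / r
        conv = KeratometricConvention(n_k=1.333)
    elif formula == "holladay1":
        al = record.al + 0.2
        r = 337.5 / record.mean_k
        kc = 1000.0 * (4.0 / 3.0 - 1.0) / r
        conv = KeratometricConvention(n_k=4.0 / 3.0)
    elif formula == "haigis":
        al = record.al
        r = 337.5 / record.mean_k
        kc = 1000.0 * (1.3315 - 1.0) / r
        conv = KeratometricConvention(n_k=1.3315)
    else:  # hofferq
        al = record.al
        kc = record.mean_k
        conv = KeratometricConvention()
    return predict_refraction_vergence(al, kc, res.elp_used, power, conv)
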