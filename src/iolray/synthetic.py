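"""Synthetic biometry cohorts with a known-truth optical forward model.

The generator draws per-patient biometry from distributions calibrated to
the axial-length profile of a cataract-surgery population (mean 23.66 mm,
SD 2.07 mm, range 19-35 mm, with ~60% of eyes between 22 and 24 mm and
heavy-ish tails on the long side), induces physiologic correlations of
chamber depth and lens thickness with axial length, and lets a small
fraction of patients contribute both eyes.  Surgery is then simulated:
the implanted power follows the axial-length formula-selection rule at a
plano target, the *true* postoperative refraction is computed by the
package's own ray tracer at a noisily perturbed lens position, and the
observed refraction adds measurement noise and phoropter rounding.

Because the truth model is the package's own ray tracer, the ray-trace
method's superiority over the thin-lens formulas in a simulated cohort
is a construction artifact: the simulation validates the analysis
machinery, not the clinical ranking of methods.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .biometry import BiometryRecord, IOLGeometry, IOLModel
from .elp import ElpConfig, predict_iol_position
from .errors import IolrayError
from .raytrace import (RayTraceConfig, interpolate_geometry,
                       predict_refraction_raytrace)
from .thinlens import (THIN_LENS_FORMULAS, calc_formula,
                       predicted_refraction_at, select_formula_by_al)

DEFAULT_IOL_ID = "GENERIC-BICONVEX"


class ALMixture(BaseModel):
    """Truncated two-component normal mixture for axial length (mm):
    a dominant normal-eye component and a broad component carrying the
    short- and long-eye tails."""

    means: tuple[float, float] = (23.21, 24.0)
    sds: tuple[float, float] = (0.90, 4.60)
    weights: tuple[float, float] = (0.76, 0.24)
    truncation: tuple[float, float] = (19.0, 35.0)
    eye_jitter_sd: float = 0.10   # mm, within-patient between-eye difference

    @model_validator(mode="after")
    def _check(self) -> "ALMixture":
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if any(s < 0 for s in self.sds) or self.eye_jitter_sd < 0:
            raise ValueError("standard deviations must be nonnegative")
        lo, hi = self.truncation
        if hi <= lo:
            raise ValueError("infeasible truncation interval")
        return self


class LinearOnAL(BaseModel):
    """Linear predictor on axial length with Gaussian noise and a
    physiologic clip range."""

    intercept: float
    slope: float
    sd: float = Field(ge=0)
    clip: tuple[float, float]


class CohortConfig(BaseModel):
    """Distributional parameters and noise model of the synthetic study.

    Defaults are the study conditions: axial lengths matching the target
    population, mean keratometry ~43.5 D, external ACD and lens thickness
    correlated with AL, 2.1 µm-scale corneal thickness spread, a lens
    position uncertainty of 0.3 mm (half of it shared between fellow
    eyes), 0.35 D of refraction measurement noise, 0.25 D phoropter
    rounding, and 8 bilateral patients per 180.
    """

    n: int = Field(default=188, ge=1)
    al_mixture: ALMixture = ALMixture()
    k_mean: float = 43.5
    k_sd: float = Field(default=1.4, ge=0)
    cyl_sd: float = Field(default=0.75, ge=0)
    acd_model: LinearOnAL = LinearOnAL(intercept=0.85, slope=0.12, sd=0.25,
                                       clip=(2.0, 5.2))
    lt_model: LinearOnAL = LinearOnAL(intercept=6.40, slope=-0.08, sd=0.30,
                                      clip=(3.0, 5.8))
    cct_mean: float = 540.0
    cct_sd: float = Field(default=33.0, ge=0)
    wtw_mean: float = 11.8
    wtw_sd: float = Field(default=0.40, ge=0)
    pupil_mean: float = 4.5
    pupil_sd: float = Field(default=0.8, ge=0)
    elp_noise_sd: float = Field(default=0.30, ge=0)       # mm
    elp_patient_share: float = Field(default=0.5, ge=0, le=1)
    refraction_noise_sd: float = Field(default=0.35, ge=0)  # D
    refraction_rounding: float = Field(default=0.25, ge=0)  # D, 0 = off
    bilateral_fraction: float = Field(default=8.0 / 180.0, ge=0, le=1)
    iol_model_id: str = DEFAULT_IOL_ID
    target_refraction: float = 0.0
    seed: int = 0


@dataclass
class SimulatedEye:
    """A generated eye: its biometry record, the standardized noise draws
    (so noise scales can be changed without regenerating), and — after
    simulated surgery — the true lens position and refraction."""

    record: BiometryRecord
    z_elp: float
    z_refraction: float
    true_elp_center: Optional[float] = None
    true_se: Optional[float] = None
    diagnostics: dict = field(default_factory=dict)


def _sample_truncnorm(rng: np.random.Generator, mu: np.ndarray,
                      sd: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Rejection sampling of N(mu, sd) restricted to [lo, hi]."""
    x = rng.normal(mu, sd)
    bad = (x < lo) | (x > hi)
    while bad.any():
        x[bad] = rng.normal(mu[bad], sd[bad])
        bad = (x < lo) | (x > hi)
    return x


def generate_biometry(config: CohortConfig) -> list[SimulatedEye]:
    """Draw a cohort of ``config.n`` eyes, reproducibly from the seed.

    Patient axial lengths come from the truncated mixture; fellow eyes
    of bilateral patients share the patient draw up to a small jitter,
    and a patient-level component of the lens-position noise makes
    fellow-eye prediction errors positively correlated.
    """
    rng = np.random.default_rng(config.seed)
    mix = config.al_mixture
    f = config.bilateral_fraction
    n_patients = max(1, int(round(config.n / (1.0 + f))))
    n_bilateral = min(int(round(f * n_patients)), n_patients)
    while n_patients + n_bilateral < config.n:
        n_patients += 1
    n_bilateral = config.n - n_patients
    if n_bilateral < 0:
        n_patients, n_bilateral = config.n, 0

    comp = (rng.random(n_patients) < mix.weights[1]).astype(int)
    mu = np.where(comp == 1, mix.means[1], mix.means[0])
    sd = np.where(comp == 1, mix.sds[1], mix.sds[0])
    lo, hi = mix.truncation
    al_patient = _sample_truncnorm(rng, mu, sd, lo, hi)
    z_patient_elp = rng.normal(0.0, 1.0, n_patients)
    bilateral = np.zeros(n_patients, dtype=bool)
    if n_bilateral:
        bilateral[rng.choice(n_patients, n_bilateral, replace=False)] = True

    share = config.elp_patient_share
    eyes: list[SimulatedEye] = []
    for i in range(n_patients):
        pid = f"P{i + 1:05d}"
        sides = ("OD", "OS") if bilateral[i] else ("OD",)
        first_side = rng.random() < 0.5
        if bilateral[i] and first_side:
            sides = ("OS", "OD")
        elif not bilateral[i] and first_side:
            sides = ("OS",)
        for side in sides:
            al = float(np.clip(al_patient[i]
                               + rng.normal(0.0, mix.eye_jitter_sd), lo, hi))
            k_mean = float(np.clip(rng.normal(config.k_mean, config.k_sd),
                                   36.0, 52.0))
            cyl = min(abs(rng.normal(0.0, config.cyl_sd)), 3.0)
            acd = float(np.clip(
                config.acd_model.intercept + config.acd_model.slope * al
                + rng.normal(0.0, config.acd_model.sd),
                *config.acd_model.clip))
            lt = float(np.clip(
                config.lt_model.intercept + config.lt_model.slope * al
                + rng.normal(0.0, config.lt_model.sd),
                *config.lt_model.clip))
            cct = float(np.clip(rng.normal(config.cct_mean, config.cct_sd),
                                420.0, 660.0))
            wtw = float(np.clip(rng.normal(config.wtw_mean, config.wtw_sd),
                                10.0, 13.5))
            pupil = float(np.clip(
                rng.normal(config.pupil_mean, config.pupil_sd), 2.0, 7.0))
            record = BiometryRecord(
                patient_id=pid, eye=side, al=round(al, 4),
                acd=round(acd, 4), lt=round(lt, 4), cct=round(cct, 1),
                k1=round(k_mean - 0.5 * cyl, 4),
                k2=round(k_mean + 0.5 * cyl, 4),
                wtw=round(wtw, 2), pupil=round(pupil, 2),
                implanted_model=config.iol_model_id)
            z_eye = rng.normal(0.0, 1.0)
            z_elp = (math.sqrt(share) * z_patient_elp[i]
                     + math.sqrt(1.0 - share) * z_eye)
            eyes.append(SimulatedEye(record=record, z_elp=z_elp,
                                     z_refraction=rng.normal(0.0, 1.0)))
    return eyes


def default_iol_database() -> dict[str, IOLModel]:
    """A generic biconvex hydrophilic-acrylic IOL family (n = 1.46) with
    geometry from -10 D to +40 D and a consistent constant set.

    Surface powers follow a shifted equi-biconvex design (front surface
    carries 12 D more than the back) solved so the thick-lens power in
    aqueous equals the labeled power; the thin-lens constants are the
    standard conversions from an A-constant of 118.4.
    """
    n_iol, n_aq = 1.46, 1.336
    a_constant = 118.4
    acd_const = 0.62467 * a_constant - 68.747

    geometry = []
    for p in range(-10, 41):
        thick = min(max(0.55 + 0.012 * (p - 21.0), 0.30), 1.00)
        c = thick / 1000.0 / n_iol
        # front surface carries 0.5*P + 8 D (never zero on [-10, 40]);
        # back surface solves P = phi1 + phi2 - c*phi1*phi2 exactly, so
        # the design glides from biconvex at high powers to meniscus at
        # negative powers, as real lens families do
        phi1 = 0.5 * p + 8.0
        phi2 = (p - phi1) / (1.0 - c * phi1)
        r_back = (-1000.0 * (n_iol - n_aq) / phi2 if abs(phi2) > 1e-3
                  else -1.0e5)
        geometry.append({
            "power_d": float(p),
            "r_front_mm": 1000.0 * (n_iol - n_aq) / phi1,
            "r_back_mm": r_back,
            "thickness_mm": thick, "n_iol": n_iol,
            "q_front": 0.0, "q_back": 0.0})

    from .biometry import iol_model_from_dict
    model = iol_model_from_dict({
        "model_id": DEFAULT_IOL_ID,
        "a_constant": a_constant,
        "pacd": 0.58357 * a_constant - 63.896,
        "sf": 0.5663 * a_constant - 65.60,
        "a0": acd_const - 0.4 * 3.37 - 0.1 * 23.39,
        "a1": 0.4, "a2": 0.1,
        "geometry": geometry})
    return {model.model_id: model}


def simulate_surgery(eye: SimulatedEye, iol_db: dict[str, IOLModel],
                     config: CohortConfig,
                     raytrace_config: RayTraceConfig = RayTraceConfig(),
                     elp_config: ElpConfig = ElpConfig()) -> BiometryRecord:
    """Implant an IOL and observe the postoperative refraction.

    The implanted power is the axial-length-selected thin-lens formula's
    grid choice at the configured target; the true refraction is the
    ray-traced refraction at the anatomy-predicted lens position
    perturbed by the lens-position noise, and the observed refraction
    adds measurement noise and rounding.
    """
    record = eye.record
    iol = iol_db[record.implanted_model or config.iol_model_id]
    formula = select_formula_by_al(record.al)
    choice = calc_formula(record, iol, formula, config.target_refraction,
                          clamp_srkt=True)
    power = choice.chosen_power
    geometry = interpolate_geometry(iol, power)
    predicted = predict_iol_position(record, geometry, "auto", elp_config,
                                     iol)
    true_center = predicted.elp_center + config.elp_noise_sd * eye.z_elp
    true_elp = type(predicted).from_center(true_center, geometry.thickness,
                                           predicted.method)
    true_se = predict_refraction_raytrace(record, geometry, true_elp,
                                          raytrace_config)
    observed = true_se + config.refraction_noise_sd * eye.z_refraction
    if config.refraction_rounding > 0:
        observed = (config.refraction_rounding
                    * round(observed / config.refraction_rounding))
    completed = record.model_copy(update={
        "implanted_power": power, "postop_se": observed})
    eye.record = completed
    eye.true_elp_center = true_center
    eye.true_se = true_se
    eye.diagnostics = {"selection_formula": formula,
                       "emmetropic_power": choice.emmetropic_power}
    return completed


METHODS = ("srkt", "hofferq", "holladay1", "haigis", "raytrace")


def predict_all_methods(eyes: list[SimulatedEye],
                        iol_db: dict[str, IOLModel],
                        config: CohortConfig,
                        raytrace_config: RayTraceConfig = RayTraceConfig(),
                        elp_config: ElpConfig = ElpConfig()):
    """Predicted refraction of every method for every implanted eye,
    as a long DataFrame with the per-eye prediction errors."""
    import pandas as pd

    from .analysis import assign_al_bin, compute_pe

    rows = []
    for eye in eyes:
        record = eye.record
        if record.implanted_power is None or record.postop_se is None:
            raise IolrayError("eye has not been through simulate_surgery")
        iol = iol_db[record.implanted_model or config.iol_model_id]
        power = record.implanted_power
        preds = {f: predicted_refraction_at(record, iol, f, power,
                                            clamp_srkt=True)
                 for f in THIN_LENS_FORMULAS}
        geometry = interpolate_geometry(iol, power)
        elp = predict_iol_position(record, geometry, "auto", elp_config, iol)
        preds["raytrace"] = predict_refraction_raytrace(
            record, geometry, elp, raytrace_config)
        for f in METHODS:
            pe = compute_pe(preds[f], record.postop_se)
            rows.append({
                "patient_id": record.patient_id, "eye": record.eye,
                "formula": f, "al": record.al,
                "al_bin": assign_al_bin(record.al),
                "predicted_se": preds[f], "actual_se": record.postop_se,
                "pe": pe, "ae": abs(pe)})
    return pd.DataFrame(rows)


def run_study_pipeline(config: CohortConfig,
                       iol_db: Optional[dict[str, IOLModel]] = None,
                       raytrace_config: RayTraceConfig = RayTraceConfig(),
                       elp_config: ElpConfig = ElpConfig()) -> dict:
    """Generate, operate, predict with all five methods, and analyze.

    Returns a JSON-serializable report: per-formula error summaries,
    mixed-model pairwise AE contrasts, Levene heterogeneity of the PE,
    GEE within-threshold comparisons, and axial-length subgroup blocks.
    The run is fully determined by ``config`` (including its seed).
    """
    from .analysis import (compare_mae_mixed, gee_threshold_comparison,
                           levene_heterogeneity, subgroup_report,
                           summarize_errors)

    if iol_db is None:
        iol_db = default_iol_database()
    eyes = generate_biometry(config)
    for eye in eyes:
        simulate_surgery(eye, iol_db, config, raytrace_config, elp_config)
    errors = predict_all_methods(eyes, iol_db, config, raytrace_config,
                                 elp_config)

    summaries = {f: summarize_errors(
        errors.loc[errors["formula"] == f, "pe"]).to_dict()
        for f in METHODS}
    contrasts = compare_mae_mixed(errors).to_dict("records")
    lev_stat, lev_p = levene_heterogeneity(
        [errors.loc[errors["formula"] == f, "pe"].to_numpy()
         for f in METHODS])
    gee = gee_threshold_comparison(errors)
    subgroups = subgroup_report(errors)

    report = {
        "n_eyes": int(config.n),
        "n_patients": int(errors["patient_id"].nunique()),
        "seed": int(config.seed),
        "methods": list(METHODS),
        "summaries": summaries,
        "mixed_model_contrasts": contrasts,
        "levene": {"statistic": lev_stat, "p": lev_p},
        "gee": gee,
        "subgroups": subgroups,
    }
    return report


def report_to_json(report: dict) -> str:
    """Canonical (byte-stable) JSON serialization of a pipeline report;
    NaN (undefined p-values) becomes null so the output is strict JSON."""
    import json

    def clean(o):
        if isinstance(o, dict):
            return {k: clean(v) for k, v in o.items()}
        if isinstance(o, (list, tuple)):
            return [clean(v) for v in o]
        if isinstance(o, (np.floating, np.integer)):
            o = o.item()
        if isinstance(o, float) and not math.isfinite(o):
            return None
        return o

    return json.dumps(clean(report), sort_keys=True, indent=1)
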