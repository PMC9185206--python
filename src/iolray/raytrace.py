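"""Exact meridional ray tracing through a four-surface pseudophakic eye.

The eye is modeled as an ordered chain of conicoid refracting surfaces —
anterior cornea, posterior cornea, anterior IOL, posterior IOL — with the
retina as the image plane and an iris stop between the posterior cornea
and the IOL.  Rays are meridional (2-D); each is intersected exactly with
the conic of revolution and refracted with the exact (non-paraxial)
Snell's law, so spherical aberration and pupil dependence are captured.

The refraction of the eye is defined by the best-focus criterion of the
IOL bench standard: per principal meridian, the reference ray is the one
crossing the iris plane at ``pupil_radius / sqrt(2)`` — the zonal height
that halves the encircled pupil area — and the reported value is the
spectacle-plane lens power that brings this ray to a focus exactly on
the fovea.  The spherical equivalent is the mean of the two meridians.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

from scipy.optimize import brentq

from .biometry import BiometryRecord, IOLGeometry, IOLModel
from .elp import ElpConfig, ElpPrediction, predict_iol_position
from .errors import (CapabilityError, GeometryError, NonPhysiologicEyeError,
                     PupilClipError, RayEscapeError)
from .thinlens import FormulaResult, POWER_STEP

N_AIR = 1.0


@dataclass(frozen=True)
class Surface:
    """One conicoid refracting interface.

    ``radius`` is the signed vertex radius (positive when the center of
    curvature lies toward the retina); ``q`` the conic constant (0 for a
    sphere, -1 for a paraboloid).
    """

    z_vertex: float
    radius: float
    n_before: float
    n_after: float
    q: float = 0.0
    half_aperture: float = 6.0

    def __post_init__(self):
        if abs(self.radius) <= 0.5:
            raise GeometryError(f"|radius| = {abs(self.radius)} mm too small")
        if self.n_before < 1 or self.n_after < 1:
            raise GeometryError("refractive indices must be >= 1")
        if self.half_aperture <= 0:
            raise GeometryError("half aperture must be positive")


@dataclass(frozen=True)
class Ray:
    """Meridional ray: height ``y`` (mm), axial position ``z`` (mm), and
    slope ``u = dy/dz``; ``forward`` is False for retina-to-cornea rays."""

    y: float
    z: float
    u: float
    forward: bool = True

    def __post_init__(self):
        if not (math.isfinite(self.y) and math.isfinite(self.z)
                and math.isfinite(self.u)):
            raise ValueError("ray state must be finite")
        if abs(self.u) >= 1.5:
            raise ValueError(f"|u| = {abs(self.u)} too steep for meridional "
                             "tracing")

    def at(self, z: float) -> float:
        """Height after straight propagation to axial position ``z``."""
        return self.y + self.u * (z - self.z)


@dataclass(frozen=True)
class EyeModel:
    """Ordered four-surface pseudophakic eye with iris stop and retina."""

    surfaces: tuple[Surface, ...]
    pupil_z: float
    pupil_diameter: float
    retina_z: float

    def __post_init__(self):
        zs = [s.z_vertex for s in self.surfaces]
        if any(b <= a for a, b in zip(zs, zs[1:])):
            raise GeometryError(f"surfaces not strictly ordered in z: {zs}")
        if self.retina_z <= zs[-1]:
            raise GeometryError(
                f"retina at {self.retina_z} mm not behind the last surface "
                f"({zs[-1]:.3f} mm); IOL position too deep for this eye")
        if len(self.surfaces) >= 3 and not (
                zs[1] < self.pupil_z < zs[2]):
            raise GeometryError(
                f"iris plane {self.pupil_z:.3f} mm must lie between the "
                "posterior cornea and the anterior IOL surface")


@dataclass(frozen=True)
class RayTraceConfig:
    """Physical constants and tunables of the ray-traced eye model."""

    pupil_diameter: float = 2.5          # mm, at the iris plane
    n_cornea: float = 1.376
    n_aqueous: float = 1.336
    n_vitreous: float = 1.336
    posterior_anterior_corneal_ratio: float = 0.883   # Gullstrand 6.8/7.7
    keratometric_index: float = 1.3375
    vertex_mm: float = 12.0
    focus_ray_fraction: float = 1.0 / math.sqrt(2.0)
    sc_beta: float = 0.116               # Stiles-Crawford, mm^-2
    mode: str = "iso_single_ray"         # or "rms_multiray"
    cornea_q: float = 0.0
    power_bracket: float = 30.0          # D, spectacle-plane search limit

    def __post_init__(self):
        if not 0.1 < self.pupil_diameter < 8:
            raise ValueError("pupil diameter outside (0.1, 8) mm")
        if not 0.7 < self.posterior_anterior_corneal_ratio < 1.0:
            raise ValueError("posterior/anterior corneal ratio implausible")


def intersect_conic(ray: Ray, surface: Surface
                    ) -> tuple[float, float, float, float]:
    """Exact intersection of a meridional ray with a conic of revolution.

    Returns ``(y, z, ny, nz)``: the intersection point and the unit
    surface normal oriented against the ray.  The conic is
    ``y**2 = 2*R*s - (1+q)*s**2`` with sag ``s = z - z_vertex``; of the
    two quadratic roots the branch closest to the vertex is physical.
    """
    r_, q = surface.radius, surface.q
    a = ray.y + ray.u * (surface.z_vertex - ray.z)   # height at vertex plane
    qa = ray.u * ray.u + 1.0 + q
    qb = 2.0 * (a * ray.u - r_)
    qc = a * a
    if qc == 0.0:
        s = 0.0
    else:
        disc = qb * qb - 4.0 * qa * qc
        if disc < 0.0:
            raise RayEscapeError("ray misses the surface")
        sq = math.sqrt(disc)
        # stable quadratic roots; pick the vertex branch (smallest |s|)
        qq = -0.5 * (qb + math.copysign(sq, qb))
        roots = []
        if qa != 0.0:
            roots.append(qq / qa)
        if qq != 0.0:
            roots.append(qc / qq)
        if not roots:
            raise RayEscapeError("degenerate ray-surface intersection")
        s = min(roots, key=abs)
    z_i = surface.z_vertex + s
    y_i = ray.at(z_i)
    if abs(y_i) > surface.half_aperture:
        raise RayEscapeError(
            f"ray height {y_i:.3f} mm exceeds surface aperture")
    # gradient of F = y^2 - 2 R s + (1+q) s^2
    gy = 2.0 * y_i
    gz = -2.0 * r_ + 2.0 * (1.0 + q) * s
    norm = math.hypot(gy, gz)
    ny, nz = gy / norm, gz / norm
    # orient the normal against the direction of propagation
    dz = 1.0 if ray.forward else -1.0
    dn = math.hypot(1.0, ray.u)
    dy, dzc = ray.u * dz / dn, dz / dn
    if dy * ny + dzc * nz > 0.0:
        ny, nz = -ny, -nz
    return y_i, z_i, ny, nz


def refract_snell(ray: Ray, normal: tuple[float, float], n1: float,
                  n2: float) -> Ray:
    """Exact vector Snell refraction of a meridional ray at a surface
    normal; raises :class:`RayEscapeError` on total internal reflection."""
    ny, nz = normal
    dz = 1.0 if ray.forward else -1.0
    dn = math.hypot(1.0, ray.u)
    dy, dzc = ray.u * dz / dn, dz / dn
    cosi = -(dy * ny + dzc * nz)
    if cosi < 0.0:
        ny, nz, cosi = -ny, -nz, -cosi
    eta = n1 / n2
    sin2t = eta * eta * max(0.0, 1.0 - cosi * cosi)
    if sin2t > 1.0:
        raise RayEscapeError(
            f"total internal reflection (n1={n1}, n2={n2})")
    cost = math.sqrt(1.0 - sin2t)
    ty = eta * dy + (eta * cosi - cost) * ny
    tz = eta * dzc + (eta * cosi - cost) * nz
    if tz == 0.0:
        raise RayEscapeError("refracted ray perpendicular to the axis")
    return Ray(ray.y, ray.z, ty / tz, forward=tz > 0)


def _propagate(ray: Ray, y: float, z: float) -> Ray:
    return replace(ray, y=y, z=z)


def trace_to_retina(eye: EyeModel, ray: Ray, *, clip_at_pupil: bool = True
                    ) -> tuple[float, list[tuple[float, float]]]:
    """Trace a forward ray through all surfaces to the retina.

    Returns the retinal height (mm) and the ray path as ``(y, z)`` pairs.
    Pupil-clipped or escaping rays raise, never silently vanish.
    """
    if not ray.forward:
        raise ValueError("trace_to_retina expects a forward ray")
    if ray.z >= eye.surfaces[0].z_vertex:
        raise ValueError("entry ray must start before the first surface")
    path = [(ray.y, ray.z)]
    n_chain = [s.n_before for s in eye.surfaces] + [eye.surfaces[-1].n_after]
    for i, surface in enumerate(eye.surfaces):
        if i == 2:  # crossing the iris plane before the anterior IOL surface
            y_p = ray.at(eye.pupil_z)
            if clip_at_pupil and abs(y_p) > 0.5 * eye.pupil_diameter:
                raise PupilClipError(
                    f"ray blocked at iris plane (|y| = {abs(y_p):.3f} mm > "
                    f"{0.5 * eye.pupil_diameter:.3f} mm)")
            path.append((y_p, eye.pupil_z))
        y_i, z_i, ny, nz = intersect_conic(ray, surface)
        ray = _propagate(ray, y_i, z_i)
        ray = refract_snell(ray, (ny, nz), n_chain[i], n_chain[i + 1])
        path.append((y_i, z_i))
    y_ret = ray.at(eye.retina_z)
    path.append((y_ret, eye.retina_z))
    return y_ret, path


def trace_from_retina(eye: EyeModel, u_r: float
                      ) -> tuple[float, Ray]:
    """Trace a ray backwards from the foveal point into air.

    The ray starts on-axis at the retina with slope ``u_r`` and is traced
    through the surfaces in reverse.  Returns the height at the iris
    plane and the emerging ray in air (still flagged backward, at the
    anterior corneal surface).
    """
    ray = Ray(0.0, eye.retina_z, u_r, forward=False)
    y_pupil = math.nan
    n_chain = [s.n_before for s in eye.surfaces] + [eye.surfaces[-1].n_after]
    for i in range(len(eye.surfaces) - 1, -1, -1):
        y_i, z_i, ny, nz = intersect_conic(ray, eye.surfaces[i])
        if abs(y_i) > eye.surfaces[i].half_aperture:
            raise RayEscapeError("backward ray exceeds surface aperture")
        ray = _propagate(ray, y_i, z_i)
        ray = refract_snell(ray, (ny, nz), n_chain[i + 1], n_chain[i])
        if i == 2:  # just crossed the anterior IOL surface, heading to iris
            y_pupil = ray.at(eye.pupil_z)
    return y_pupil, ray


def stiles_crawford_weight(y_pupil: float, beta: float = 0.116) -> float:
    """Photometric pupil apodization ``10**(-beta * y**2)``."""
    if beta < 0:
        raise ValueError("beta must be nonnegative")
    return 10.0 ** (-beta * y_pupil * y_pupil)


def build_pseudophakic_eye(record: BiometryRecord, geometry: IOLGeometry,
                           elp: ElpPrediction,
                           config: RayTraceConfig = RayTraceConfig(),
                           k_d: Optional[float] = None) -> EyeModel:
    """Assemble the four-surface eye for one principal meridian.

    The anterior corneal radius is recovered from the keratometric
    reading (``r = (n_k - 1)*1000 / K``) and the posterior radius is a
    fixed fraction of it; the IOL anterior vertex sits at
    ``cct + elp_front_vertex`` (the ELP being referenced to the posterior
    corneal vertex) and the retina at the axial length.  ``k_d`` selects
    the meridian (defaults to the mean keratometry).
    """
    k = record.mean_k if k_d is None else k_d
    r_ant = (config.keratometric_index - 1.0) * 1000.0 / k
    r_post = config.posterior_anterior_corneal_ratio * r_ant
    cct = record.cct_mm
    z_front = cct + elp.elp_front_vertex
    z_back = z_front + geometry.thickness
    optic_half = 3.0
    surfaces = (
        Surface(0.0, r_ant, N_AIR, config.n_cornea, config.cornea_q, 6.0),
        Surface(cct, r_post, config.n_cornea, config.n_aqueous,
                config.cornea_q, 6.0),
        Surface(z_front, geometry.r_front, config.n_aqueous, geometry.n_iol,
                geometry.q_front, optic_half),
        Surface(z_back, geometry.r_back, geometry.n_iol, config.n_vitreous,
                geometry.q_back, optic_half),
    )
    # iris stop just anterior to the optic, clear of the corneal dome
    pupil_z = max(z_front - 0.5, cct + 0.6 * (z_front - cct))
    try:
        return EyeModel(surfaces, pupil_z, config.pupil_diameter, record.al)
    except GeometryError as exc:
        raise GeometryError(
            f"cannot build eye for AL={record.al} mm, ELP center "
            f"{elp.elp_center:.2f} mm: {exc}") from None


def _iso_meridian_refraction(eye: EyeModel, config: RayTraceConfig) -> float:
    """Spectacle power focusing the zonal reference ray on the fovea.

    Solved by reverse tracing: the ray leaving the foveal point that
    crosses the iris plane at the reference height is traced out of the
    eye; by reversibility of light, the forward conjugate ray enters
    through a spectacle lens whose power follows in closed form from the
    emerging ray's height and slope at the spectacle plane.
    """
    h = 0.5 * eye.pupil_diameter * config.focus_ray_fraction

    # parameterize by t = -u_r > 0: a backward ray from the fovea rises
    # above the axis only with a negative slope; pupil height grows with t
    def g(t: float) -> float:
        y_p, _ = trace_from_retina(eye, -t)
        return y_p - h

    t0 = h / (eye.retina_z - eye.pupil_z)
    lo, hi = 0.25 * t0, 4.0 * t0

    def g_safe(t: float) -> float:
        try:
            return g(t)
        except RayEscapeError:
            return math.inf   # overshot an aperture: treat as too high

    glo, ghi = g_safe(lo), g_safe(hi)
    tries = 0
    while glo * ghi > 0 and tries < 60:
        if glo > 0:
            lo *= 0.5
            glo = g_safe(lo)
        else:
            hi *= 1.4
            ghi = g_safe(hi)
        tries += 1
    if not glo < 0 < ghi:
        raise NonPhysiologicEyeError(
            "no retinal ray reaches the reference pupil height")
    while not math.isfinite(ghi):   # pull the top of the bracket inside
        mid = 0.5 * (lo + hi)
        gm = g_safe(mid)
        if gm > 0:
            hi, ghi = mid, gm
        else:
            lo, glo = mid, gm
    t_r = brentq(g, lo, hi, xtol=1e-12, rtol=8.881784197001252e-16)
    _, out = trace_from_retina(eye, -t_r)
    # emerging ray in air at the anterior cornea, traveling backward (-z);
    # reverse it and read off the spectacle power that makes it parallel
    y0, z0, u = out.y, out.z, out.u
    y_s = y0 + u * (-config.vertex_mm - z0)
    if abs(y_s) < 1e-9:
        raise NonPhysiologicEyeError(
            "reference ray crosses the axis at the spectacle plane")
    power = -1000.0 * u / y_s
    if abs(power) > config.power_bracket:
        raise NonPhysiologicEyeError(
            f"required correction {power:.1f} D outside +/-"
            f"{config.power_bracket:.0f} D")
    return power


def _rms_meridian_refraction(eye: EyeModel, config: RayTraceConfig,
                             n_rays: int = 9) -> float:
    """Multi-ray mode: spectacle power minimizing the Stiles-Crawford
    weighted RMS retinal spot of a fan filling the pupil, searched in a
    window around the single-ray best focus."""
    from scipy.optimize import minimize_scalar

    center = _iso_meridian_refraction(eye, config)
    half = 0.45 * eye.pupil_diameter   # stay clear of the stop edge
    heights = [(-1.0 + 2.0 * (i + 0.5) / n_rays) * half
               for i in range(n_rays)]

    def through_cornea(y_s: float, s_power: float) -> Ray:
        u = -y_s * s_power / 1000.0
        ray = Ray(y_s + u * (config.vertex_mm - 1.0), -1.0, u)
        ns = (N_AIR, config.n_cornea, config.n_aqueous)
        for i, surface in enumerate(eye.surfaces[:2]):
            y_i, z_i, ny, nz = intersect_conic(ray, surface)
            ray = _propagate(ray, y_i, z_i)
            ray = refract_snell(ray, (ny, nz), ns[i], ns[i + 1])
        return ray

    def entry_for_pupil_height(hp: float, s_power: float) -> float:
        # the pupil height is nearly proportional to the entry height;
        # estimate the magnification on a safe probe ray, then refine
        probe = 0.25
        m = through_cornea(probe, s_power).at(eye.pupil_z) / probe
        guess = hp / m

        def resid(y_s: float) -> float:
            return through_cornea(y_s, s_power).at(eye.pupil_z) - hp

        lo, hi = 0.6 * guess, 1.6 * guess
        if lo > hi:
            lo, hi = hi, lo
        flo, fhi = resid(lo), resid(hi)
        for _ in range(30):
            if flo * fhi <= 0:
                break
            lo -= 0.3 * abs(guess)
            hi += 0.3 * abs(guess)
            flo, fhi = resid(lo), resid(hi)
        return brentq(resid, lo, hi, xtol=1e-10)

    def spot(s_power: float) -> float:
        num = den = 0.0
        for hp in heights:
            try:
                y_s = entry_for_pupil_height(hp, s_power)
                u = -y_s * s_power / 1000.0
                ray = Ray(y_s + u * (config.vertex_mm - 1.0), -1.0, u)
                y_ret, _ = trace_to_retina(eye, ray)
            except (RayEscapeError, ValueError):
                continue
            w = stiles_crawford_weight(hp, config.sc_beta)
            num += w * y_ret * y_ret
            den += w
        return math.sqrt(num / den) if den else math.inf

    res = minimize_scalar(spot, bounds=(center - 3.0, center + 3.0),
                          method="bounded", options={"xatol": 1e-6})
    return float(res.x)


def best_focus_refraction(eye: EyeModel,
                          config: RayTraceConfig = RayTraceConfig()
                          ) -> float:
    """Best-focus spectacle refraction of a single-meridian eye (D)."""
    if config.mode == "rms_multiray":
        return _rms_meridian_refraction(eye, config)
    return _iso_meridian_refraction(eye, config)


def predict_refraction_raytrace(record: BiometryRecord,
                                geometry: IOLGeometry, elp: ElpPrediction,
                                config: RayTraceConfig = RayTraceConfig()
                                ) -> float:
    """Spherical-equivalent ray-traced refraction: mean of the two
    principal meridians built from K1 and K2."""
    total = 0.0
    for k in (record.k1, record.k2):
        eye = build_pseudophakic_eye(record, geometry, elp, config, k_d=k)
        total += best_focus_refraction(eye, config)
    return 0.5 * total


def interpolate_geometry(iol: IOLModel, power: float) -> IOLGeometry:
    """Geometry at an arbitrary power, linear in surface curvature,
    thickness, and asphericity between the bracketing labeled powers."""
    iol.require_geometry()
    powers = list(iol.geometry_table)
    if not powers[0] - 1e-9 <= power <= powers[-1] + 1e-9:
        raise CapabilityError(
            f"power {power} D outside the geometry table "
            f"[{powers[0]}, {powers[-1]}] of {iol.model_id!r}")
    if power in iol.geometry_table:
        return iol.geometry_table[power]
    import bisect
    j = bisect.bisect_left(powers, power)
    j = min(max(j, 1), len(powers) - 1)
    p0, p1 = powers[j - 1], powers[j]
    g0, g1 = iol.geometry_table[p0], iol.geometry_table[p1]
    w = (power - p0) / (p1 - p0)

    def lerp(a, b):
        return a + w * (b - a)

    def lerp_curv(r0, r1):
        return 1.0 / lerp(1.0 / r0, 1.0 / r1)

    return IOLGeometry(
        r_front=lerp_curv(g0.r_front, g1.r_front),
        r_back=lerp_curv(g0.r_back, g1.r_back),
        thickness=lerp(g0.thickness, g1.thickness),
        n_iol=lerp(g0.n_iol, g1.n_iol),
        q_front=lerp(g0.q_front, g1.q_front),
        q_back=lerp(g0.q_back, g1.q_back))


def _raytrace_se_at_power(record: BiometryRecord, iol: IOLModel,
                          power: float, config: RayTraceConfig,
                          elp_mode: str, elp_config: ElpConfig) -> float:
    geometry = interpolate_geometry(iol, power)
    elp = predict_iol_position(record, geometry, elp_mode, elp_config, iol)
    return predict_refraction_raytrace(record, geometry, elp, config)


def solve_iol_power_raytrace(record: BiometryRecord, iol: IOLModel,
                             target_d: float = 0.0,
                             config: RayTraceConfig = RayTraceConfig(),
                             elp_mode: str = "auto",
                             elp_config: ElpConfig = ElpConfig(),
                             step: float = POWER_STEP) -> FormulaResult:
    """Choose the grid IOL power whose ray-traced refraction is closest
    to the target (ties to the higher power).

    Because the ray-traced refraction is strictly decreasing in power,
    the grid is searched by bisection on the sign of
    ``predicted - target`` rather than exhaustively.
    """
    iol.require_geometry()
    powers = list(iol.geometry_table)
    lo = step * math.ceil(powers[0] / step)
    hi = step * math.floor(powers[-1] / step)
    n = int(round((hi - lo) / step))
    cache: dict[int, float] = {}

    def se(i: int) -> float:
        if i not in cache:
            cache[i] = _raytrace_se_at_power(
                record, iol, lo + i * step, config, elp_mode, elp_config)
        return cache[i]

    a, b = 0, n
    if se(a) - target_d <= 0:
        b = a
    elif se(b) - target_d >= 0:
        a = b
    else:
        while b - a > 1:
            mid = (a + b) // 2
            if se(mid) - target_d > 0:
                a = mid
            else:
                b = mid
    # a and b now bracket the sign change (or coincide at a boundary)
    cand = sorted({a, b})
    best = None
    for i in cand:
        d = abs(se(i) - target_d)
        p = lo + i * step
        if best is None or d < best[0] - 1e-12 or (
                abs(d - best[0]) <= 1e-12 and p > best[1]):
            best = (d, p, se(i))
    chosen, predicted = best[1], best[2]
    geometry = interpolate_geometry(iol, chosen)
    elp = predict_iol_position(record, geometry, elp_mode, elp_config, iol)
    # emmetropic power by secant refinement between the bracketing grid SEs
    emme = chosen
    if len(cand) == 2 and cache[cand[0]] != cache[cand[1]]:
        p0, p1 = lo + cand[0] * step, lo + cand[1] * step
        s0, s1 = cache[cand[0]], cache[cand[1]]
        emme = p0 + (0.0 - s0) * (p1 - p0) / (s1 - s0)
    return FormulaResult("raytrace", emme, chosen, predicted,
                         elp.elp_center, {"elp_mode": elp.method})
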