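"""Independent oracles used by the tests.

These deliberately avoid the package's own computational paths: the
paraxial oracle propagates (height, reduced angle) pairs through the
2x2 Gaussian optics of the same surface list, and the closed-form
helpers are direct transcriptions of textbook formulas.
"""
from __future__ import annotations


def paraxial_refraction_oracle(eye, vertex_mm: float = 12.0) -> float:
    """Spectacle power focusing a paraxial parallel ray on the retina of
    an :class:`iolray.raytrace.EyeModel`, from linear Gaussian optics.

    Propagation uses reduced angles w = n*u: translation by t adds
    ``t*w/n`` to the height, refraction at a surface of power
    ``(n2-n1)/R`` subtracts ``phi*y`` from w.  A spectacle lens of power
    S (D) at the vertex turns a parallel ray of height y into
    ``w = -S*y/1000`` (R in mm), so the retinal height is linear in S
    and the focusing power follows in closed form.
    """
    ns = [s.n_before for s in eye.surfaces] + [eye.surfaces[-1].n_after]

    def retinal_height(y: float, w: float) -> float:
        z = -vertex_mm
        for i, s in enumerate(eye.surfaces):
            y = y + (s.z_vertex - z) * w / ns[i]
            w = w - (ns[i + 1] - ns[i]) / s.radius * y
            z = s.z_vertex
        return y + (eye.retina_z - z) * w / ns[-1]

    a = retinal_height(1.0, 0.0)
    b = retinal_height(0.0, 1.0)
    return 1000.0 * a / b


def conic_sag_oracle(y: float, radius: float, q: float = 0.0) -> float:
    """Closed-form sag of a conicoid at height y (sphere: R - sqrt)."""
    import math
    if q == 0.0:
        return radius - math.copysign(
            math.sqrt(radius * radius - y * y), radius)
    return y * y / (radius * (1.0 + math.sqrt(
        1.0 - (1.0 + q) * y * y / (radius * radius))))
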