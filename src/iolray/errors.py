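"""Exception hierarchy shared across the package."""


class IolrayError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(IolrayError):
    """A required column or field is missing from an input file."""


class RecordValidationError(IolrayError):
    """A biometry row violates a physiologic invariant; carries its location."""

    def __init__(self, message: str, patient_id: str | None = None,
                 row: int | None = None):
        self.patient_id = patient_id
        self.row = row
        loc = []
        if row is not None:
            loc.append(f"row {row}")
        if patient_id is not None:
            loc.append(f"patient_id={patient_id!r}")
        super().__init__(f"{message}" + (f" ({', '.join(loc)})" if loc else ""))


class CapabilityError(IolrayError):
    """An operation was requested that the inputs cannot support
    (e.g. ray tracing an IOL model without a geometry table)."""


class DomainError(IolrayError, ValueError):
    """An input is outside the mathematical domain of a formula."""


class FormulaDomainError(DomainError):
    """A thin-lens formula failed on an extreme biometry combination
    (e.g. the SRK/T corneal-height square root going negative)."""


class VergenceSingularityError(DomainError):
    """A vergence chain produced an image at infinity inside the eye."""


class GeometryError(IolrayError):
    """Eye-model surfaces are not physically ordered."""


class RayEscapeError(IolrayError):
    """A traced ray missed a surface, exceeded an aperture, or was
    totally internally reflected."""


class PupilClipError(RayEscapeError):
    """A ray was blocked at the iris plane."""


class NonPhysiologicEyeError(IolrayError):
    """Best-focus search failed: no spectacle power in the search bracket
    brings the reference ray to the retina."""


class EmptyGroupError(IolrayError):
    """A statistical summary was requested for an empty group."""


class ContractError(IolrayError):
    """A statistical routine was called with a design it cannot analyse."""
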