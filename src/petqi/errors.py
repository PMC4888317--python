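"""Exception hierarchy for the petqi toolkit."""


class PetqiError(Exception):
    """Base class for all petqi errors."""


class TerminologyError(PetqiError, KeyError):
    """A symbolic terminology role does not resolve to a coded concept."""

    def __str__(self) -> str:  # KeyError quotes its args; keep the message plain
        return Exception.__str__(self)


class GeometryError(PetqiError, ValueError):
    """Image geometry is degenerate or two grids do not align."""


class ChronologyError(PetqiError, ValueError):
    """Timestamps are out of order (e.g. series time before injection)."""


class MetadataError(PetqiError, ValueError):
    """A required metadata attribute is missing or malformed."""


class PhantomSpecError(PetqiError, ValueError):
    """A synthetic-study specification violates its invariants."""


class EmptyROIError(PetqiError, ValueError):
    """An operation that needs a non-empty region of interest got none."""


class UnsupportedInputError(PetqiError, ValueError):
    """Input is valid DICOM but outside what this toolkit supports."""


class DicomParseError(PetqiError, ValueError):
    """A file could not be parsed as the expected DICOM object type."""


class TemplateError(PetqiError, ValueError):
    """A structured-report content tree violates its template."""
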