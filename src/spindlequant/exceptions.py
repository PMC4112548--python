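"""Exception hierarchy shared across the package."""


class SpindleQuantError(Exception):
    """Base class for all package errors."""


class GeometryError(SpindleQuantError):
    """A generative or measured geometry violates its invariants."""


class DetectionError(SpindleQuantError):
    """An image-analysis step found nothing to work with."""


class SchemaError(SpindleQuantError):
    """A table or config does not match the expected schema."""
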