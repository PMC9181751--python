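"""Exception hierarchy shared across the package."""


class ChoroidNetError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ChoroidNetError, ValueError):
    """A configuration object violates one of its invariants."""


class GeometryError(ChoroidNetError, ValueError):
    """A patch geometry or cropping request is inconsistent with the image."""


class AnnotationError(ChoroidNetError, ValueError):
    """A boundary annotation is malformed (e.g. CSI above BM)."""
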