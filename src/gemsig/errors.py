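"""Exception types shared across the package."""


class GemsigError(Exception):
    """Base class for all package errors."""


class FormatError(GemsigError):
    """A file could not be parsed in its declared format."""


class IntegrityError(GemsigError):
    """A model violates referential integrity (e.g. a reaction cites an
    undeclared metabolite or gene)."""
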