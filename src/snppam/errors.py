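"""Exception types shared across the package."""


class SnppamError(Exception):
    """Base class for all package errors."""


class ValidationError(SnppamError, ValueError):
    """A sequence, allele or motif failed validation."""


class RegistryError(SnppamError, ValueError):
    """Invalid registry operation (duplicate name, bad motif, empty registry)."""


class BatchFormatError(SnppamError, ValueError):
    """A batch/VCF input file is malformed."""


class GenerationError(SnppamError, RuntimeError):
    """The synthetic-fixture generator exhausted its attempt budget."""
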