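"""Exception hierarchy for the pipeline.

Argument errors (bad boxes, shape mismatches) raise ``ValueError`` directly;
the classes here cover I/O formats, configuration, degenerate inputs and
phantom generation/validation.
"""


class SynconnError(Exception):
    """Base class for package-specific errors."""


class VolumeFormatError(SynconnError):
    """A volume on disk violates the expected layout (slice shapes, dtype, attributes)."""


class ConfigError(SynconnError):
    """Invalid or unknown configuration key/value."""


class DegenerateInputError(SynconnError):
    """Input is valid but degenerate for the requested operation (e.g. constant volume for Otsu)."""


class GenerationError(SynconnError):
    """Phantom generation could not place the requested objects."""


class PhantomValidationError(SynconnError):
    """A generated dataset violates one of its ground-truth invariants."""
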