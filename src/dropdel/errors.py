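"""Exception types shared across the package."""


class DropDelError(Exception):
    """Base class for package-specific errors."""


class InvalidDesignError(DropDelError, ValueError):
    """A library design violates a structural invariant (e.g. an empty cycle)."""


class CapacityError(DropDelError, ValueError):
    """A codebook of the requested size and minimum distance cannot be built."""


class CorruptTableError(DropDelError, ValueError):
    """A hit table refers to members outside the library design."""


class ConfigError(DropDelError, ValueError):
    """A run configuration is missing or has an invalid field."""
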