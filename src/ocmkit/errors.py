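"""Exception hierarchy shared across the package."""


class OcmKitError(Exception):
    """Base class for all ocmkit errors."""


class InvalidInputError(OcmKitError, ValueError):
    """An argument violates a documented precondition."""


class InsufficientDataError(OcmKitError, ValueError):
    """Not enough samples/frames to perform the requested analysis."""


class CensoredEndpointError(OcmKitError, ValueError):
    """Operation requires an uncensored endpoint but the record ended early."""


class ConfigError(OcmKitError, ValueError):
    """Run configuration is malformed or contains unknown keys."""
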