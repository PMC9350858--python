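"""Exception hierarchy for sdfmc."""


class SdfmcError(Exception):
    """Base class for all sdfmc errors."""


class ParameterError(SdfmcError, ValueError):
    """Invalid parameter for a primitive, distribution or operator."""


class ConfigError(SdfmcError, ValueError):
    """Invalid or inconsistent run configuration / scene description."""


class OutOfDomainError(SdfmcError, ValueError):
    """Query point outside the simulation bounding box."""


class DegenerateNormalError(SdfmcError, ArithmeticError):
    """Surface-normal evaluation hit a vanishing gradient (medial axis)."""


class GeometryError(SdfmcError, ValueError):
    """Inconsistent geometric state during transport (e.g. wrong-facing normal)."""
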