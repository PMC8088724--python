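"""Exception hierarchy shared across habmock modules."""


class HabmockError(Exception):
    """Base class for all habmock errors."""


class ParseError(HabmockError):
    """A file did not conform to its expected dialect."""


class StructuralError(HabmockError):
    """A parsed structure violates an invariant (e.g. taxonomy cycle)."""


class DataError(HabmockError):
    """Input data is unusable (empty file, bad alphabet, bad quality)."""


class ConfigurationError(HabmockError):
    """An invalid parameter combination was requested."""


class SimulationError(HabmockError):
    """Read simulation could not proceed (e.g. genome too short)."""
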