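"""Exception types shared across pipeline stages."""


class WsyrnetError(Exception):
    """Base class for all package errors."""


class ParameterError(WsyrnetError, ValueError):
    """An argument is outside its documented range."""


class ParseError(WsyrnetError, ValueError):
    """A row or file could not be interpreted; message names the offender."""


class VocabularyError(WsyrnetError, ValueError):
    """An herb label is not in the declared vocabulary."""


class AssemblyError(WsyrnetError, ValueError):
    """A network edge references an unknown node."""
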