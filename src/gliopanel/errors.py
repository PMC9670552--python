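"""Exception hierarchy shared across the pipeline."""


class GlioPanelError(Exception):
    """Base class for all gliopanel errors."""


class ConfigError(GlioPanelError):
    """A configuration file is missing required content or violates an invariant."""


class ParseError(GlioPanelError):
    """An input row or token could not be parsed."""


class MissingDataError(GlioPanelError):
    """A computation was requested on data that is entirely absent."""
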