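"""Exception hierarchy shared across the pipeline."""


class BabyfeedError(Exception):
    """Base class for all package errors."""


class ConfigError(BabyfeedError):
    """Invalid configuration (bad probabilities, missing lexicon category, ...).

    Mapped to exit code 2 by the command-line interface.
    """


class DataIntegrityError(BabyfeedError):
    """Inconsistent inputs (observation without a registry record, missing
    trajectory, ...). Mapped to exit code 3 by the command-line interface.
    """
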