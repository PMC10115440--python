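"""Exception hierarchy shared by all boutonquant modules."""


class BoutonQuantError(Exception):
    """Base class for all boutonquant errors."""


class ConfigError(BoutonQuantError, ValueError):
    """Invalid configuration; ``violations`` lists every offending field."""

    def __init__(self, violations):
        if isinstance(violations, str):
            violations = [violations]
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


class GenerationError(BoutonQuantError, ValueError):
    """Synthetic-scene construction failed (geometry constraints, bounds)."""


class FitError(BoutonQuantError, RuntimeError):
    """A model fit could not be performed; carries diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = dict(diagnostics or {})


class PairingError(BoutonQuantError, ValueError):
    """Pre/post tables could not be paired; carries the unmatched ids."""

    def __init__(self, message, unmatched):
        super().__init__(f"{message}: {sorted(unmatched)}")
        self.unmatched = sorted(unmatched)


class MissingArtifactError(BoutonQuantError, FileNotFoundError):
    """An upstream pipeline artifact is absent."""
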